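"""Iterative FPM reconstruction with embedded pupil recovery (EPRY).

The high-resolution object spectrum is estimated on an upsampled frequency
grid whose sampling interval equals that of the raw (camera-grid) images, so
each raw image corresponds to one pupil-sized *subregion* of the spectrum,
centred at ``-k_m`` for illumination wave vector ``k_m``.  A full sweep
visits every subregion and applies three steps:

1. forward: extract the subregion window, multiply by the current pupil,
   inverse-transform to the modeled low-resolution field ``psi_m``;
2. intensity constraint: replace the field magnitude with the square root of
   the measured intensity, keeping the modeled phase
   (``phi_m = sqrt(I_m) * psi_m / |psi_m|``; where ``|psi_m| = 0`` the phase
   factor is taken as 1);
3. Gauss-Newton update: with ``dPsi = F[phi_m] - Psi_m``, the spectrum
   window and (optionally) the pupil receive regularized conjugate-weighted
   steps of the EPRY form; the pupil is re-clipped to the ideal-disk support
   and its magnitude capped at 1 after each update.

Sweeps repeat until the relative change of the data residual falls below the
tolerance or the sweep budget is exhausted.  The result is reported in a
piston gauge: the phase of the brightest amplitude pixel is set to zero, so
outputs are comparable across runs (the global phase of a Fourier
ptychographic reconstruction is unconstrained by the data).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Literal

import numpy as np
from numpy.fft import fft2, ifft2, fftshift, ifftshift

from .forward import RawStack, grid_shift_px
from .optics import ConfigurationError, PupilFunction, TWO_PI, make_pupil


@dataclasses.dataclass
class ReconstructionOptions:
    """Knobs of the iterative solver.

    ``delta1``/``delta2`` are the spectrum/pupil step regularizers; when left
    ``None`` they default to ``1e-8 * max|.|^2`` of the respective factor,
    recomputed per update.  ``ordering="spiral"`` visits subregions from the
    lowest ``|k_m|`` outward (bright-field first); ``"plan"`` follows the
    acquisition order of the stack.  ``initial_pupil`` overrides the ideal
    disk built from the stack's optical configuration (its nonzero support
    also defines the pupil-recovery support mask).
    """

    max_iterations: int = 50
    tolerance: float = 1e-4
    ordering: Literal["spiral", "plan"] = "spiral"
    delta1: float | None = None
    delta2: float | None = None
    pupil_recovery: bool = True
    initial_pupil: PupilFunction | None = None
    callback: Callable[..., None] | None = None   # callback(m, psi, phi)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for name in ("delta1", "delta2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class ReconstructionState:
    """Mutable solver state: spectrum estimate, pupil, and bookkeeping."""

    spectrum: np.ndarray              # (N, N) complex, centred layout
    pupil: PupilFunction              # (n, n), centred layout
    support: np.ndarray               # bool (n, n): pupil-recovery support
    windows: np.ndarray               # (n_led, 2) top-left corners (ty, tx)
    upsampling: int
    n_low: int
    iteration: int = 0
    residual_history: list[float] = dataclasses.field(default_factory=list)

    @property
    def n_high(self) -> int:
        return int(self.spectrum.shape[0])


@dataclasses.dataclass
class ReconstructionResult:
    """Recovered complex image, pupil, and per-sweep residuals."""

    amplitude: np.ndarray
    phase: np.ndarray
    pupil: PupilFunction
    residual_history: list[float]
    options: ReconstructionOptions
    pixel_um: float                   # reconstruction pixel at the object plane

    @property
    def complex_image(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


# ---------------------------------------------------------------------------
# solver steps
# ---------------------------------------------------------------------------

def initialize_reconstruction(stack: RawStack, upsampling: int,
                              options: ReconstructionOptions | None = None
                              ) -> ReconstructionState:
    """Set up the solver: Fourier-upsampled on-axis amplitude, ideal pupil.

    The initial spectrum is the zero-padded (sinc-interpolated) transform of
    the square root of the on-axis intensity image with zero phase — an
    exactly shift-equivariant upsampling, so reconstructing a circularly
    shifted scene yields the circularly shifted reconstruction.
    """
    options = options or ReconstructionOptions()
    n_led, h, w = stack.images.shape
    if h != w:
        raise ValueError("reconstruction requires square raw images")
    if upsampling < 1 or int(upsampling) != upsampling:
        raise ValueError("upsampling must be an integer >= 1")
    n = h
    big = n * upsampling
    dk = TWO_PI / (n * stack.pixel_um)
    cfg = stack.config

    if options.initial_pupil is not None:
        pupil = options.initial_pupil.copy()
        if pupil.shape != (n, n):
            raise ConfigurationError("initial pupil shape mismatch")
    else:
        pupil = make_pupil((n, n), dk, cfg.objective_na, cfg.wavelength_um)
    support = np.abs(pupil.array) > 0

    windows = np.empty((n_led, 2), dtype=int)
    for i, entry in enumerate(stack.plan.entries):
        (cy, cx), _ = grid_shift_px(entry.kx_per_um, entry.ky_per_um, dk)
        ty = big // 2 - cy - n // 2
        tx = big // 2 - cx - n // 2
        if not (0 <= ty <= big - n and 0 <= tx <= big - n):
            raise ConfigurationError(
                f"upsampling {upsampling} too small: subregion for LED "
                f"{entry.led_index} falls outside the spectrum grid")
        windows[i] = (ty, tx)

    on_axis = stack.plan.on_axis_index
    amp_lo = np.sqrt(stack.images[on_axis])
    spec_lo = fftshift(fft2(amp_lo))
    spectrum = np.zeros((big, big), dtype=complex)
    lo0 = big // 2 - n // 2
    spectrum[lo0:lo0 + n, lo0:lo0 + n] = spec_lo * upsampling ** 2
    return ReconstructionState(spectrum, pupil, support, windows,
                               int(upsampling), n)


def forward_subregion(state: ReconstructionState, m: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Model the low-resolution field for subregion ``m``: (Psi_m, psi_m)."""
    n = state.n_low
    ty, tx = state.windows[m]
    window = state.spectrum[ty:ty + n, tx:tx + n]
    big_psi = window * state.pupil.array
    psi = ifft2(ifftshift(big_psi)) / state.upsampling ** 2
    return big_psi, psi


def intensity_constraint(psi: np.ndarray, measured: np.ndarray) -> np.ndarray:
    """Replace the modeled magnitude with sqrt(measured), keep the phase.

    Where the modeled field vanishes the phase factor is 1, so the output is
    real and positive there.  ``|phi|^2`` equals the measured intensity
    exactly, by construction.
    """
    measured = np.asarray(measured)
    if measured.shape != psi.shape:
        raise ValueError("field/intensity shape mismatch")
    if (measured < 0).any():
        raise ValueError("measured intensities must be non-negative")
    mag = np.abs(psi)
    phase_factor = np.where(mag > 0, psi / np.where(mag > 0, mag, 1.0), 1.0)
    return np.sqrt(measured) * phase_factor


def gauss_newton_update(state: ReconstructionState, m: int,
                        phi: np.ndarray,
                        options: ReconstructionOptions) -> None:
    """Regularized EPRY step on the spectrum window and (optionally) pupil."""
    n = state.n_low
    up2 = state.upsampling ** 2
    ty, tx = state.windows[m]
    window = state.spectrum[ty:ty + n, tx:tx + n]
    pupil_arr = state.pupil.array

    big_phi = fftshift(fft2(phi)) * up2
    d_psi = big_phi - window * pupil_arr
    w_pre = window.copy() if options.pupil_recovery else None

    abs_p = np.abs(pupil_arr)
    max_p = abs_p.max()
    if max_p > 0:
        d1 = options.delta1 if options.delta1 is not None else 1e-8 * max_p ** 2
        window += (np.conj(pupil_arr) * abs_p
                   / (max_p * (abs_p ** 2 + d1))) * d_psi

    if options.pupil_recovery:
        abs_w = np.abs(w_pre)
        max_w = abs_w.max()
        if max_w > 0:
            d2 = options.delta2 if options.delta2 is not None \
                else 1e-8 * max_w ** 2
            pupil_arr += (np.conj(w_pre) * abs_w
                          / (max_w * (abs_w ** 2 + d2))) * d_psi
            pupil_arr *= state.support
            mag = np.abs(pupil_arr)
            over = mag > 1.0
            if over.any():
                pupil_arr[over] /= mag[over]


def _sweep_order(stack: RawStack, state: ReconstructionState,
                 ordering: str) -> np.ndarray:
    if ordering == "plan":
        return np.arange(stack.n_images)
    if ordering == "spiral":
        k = stack.plan.k_array
        norm = np.hypot(k[:, 0], k[:, 1])
        ang = np.arctan2(k[:, 1], k[:, 0])
        return np.lexsort((ang, np.round(norm, 12)))
    raise ValueError(f"unknown ordering {ordering!r}")


def reconstruct(stack: RawStack, upsampling: int = 4,
                options: ReconstructionOptions | None = None
                ) -> ReconstructionResult:
    """Run full EPRY sweeps until convergence or the sweep budget.

    The per-sweep data residual is the relative amplitude mismatch
    ``sqrt(sum_m sum_r (|psi_m| - sqrt(I_m))^2 / sum_m sum_r I_m)`` evaluated
    with the pre-update fields as the sweep progresses.
    """
    options = options or ReconstructionOptions()
    state = initialize_reconstruction(stack, upsampling, options)
    order = _sweep_order(stack, state, options.ordering)
    sqrt_i = np.sqrt(stack.images)
    denom = float(stack.images.sum())
    if denom <= 0:
        raise ValueError("stack carries no intensity")

    for sweep in range(options.max_iterations):
        num = 0.0
        for m in order:
            _, psi = forward_subregion(state, m)
            num += float(((np.abs(psi) - sqrt_i[m]) ** 2).sum())
            phi = intensity_constraint(psi, stack.images[m])
            if options.callback is not None:
                options.callback(m, psi, phi)
            gauss_newton_update(state, m, phi, options)
        residual = math.sqrt(num / denom)
        if not math.isfinite(residual):
            raise FloatingPointError(
                f"non-finite residual at sweep {sweep}; aborting")
        state.residual_history.append(residual)
        state.iteration = sweep + 1
        if sweep > 0:
            prev = state.residual_history[-2]
            if prev > 0 and abs(prev - residual) / prev < options.tolerance:
                break

    img = ifft2(ifftshift(state.spectrum))
    flat = np.argmax(np.abs(img))
    piston = np.angle(img.flat[flat])
    img = img * np.exp(-1j * piston)
    return ReconstructionResult(
        amplitude=np.abs(img),
        phase=np.angle(img),
        pupil=state.pupil,
        residual_history=state.residual_history,
        options=options,
        pixel_um=stack.pixel_um / upsampling,
    )
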