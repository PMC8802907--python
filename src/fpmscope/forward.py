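"""Coherent FPM forward model: simulate one low-resolution intensity image
per LED of the illumination plan.

For LED ``m`` with transverse wave vector ``k_m`` the sample is illuminated
by the tilted plane wave ``exp(i k_m . x)``; its spectrum is the object
spectrum translated by ``k_m``, the objective pupil low-passes it (the raw
image therefore samples the object spectrum disk centred at ``-k_m``), and
the camera records the squared magnitude of the filtered field, integrated
over camera pixels (intensity-domain box averaging by ``downsample_factor``).
Illumination wave vectors are rounded to the spectrum grid (standard FPM
practice — it keeps the forward and inverse models consistent); the rounding
residual is recorded on the stack.

Exposure normalization assumes equal LED radiance: the on-axis bright-field
image of a unit-transmission object has mean 1 by construction.

:func:`brute_force_forward` recomputes the same physics by explicit DFT
sums (no FFT routines) for small objects and serves as an independent oracle
for the FFT path.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal

import numpy as np
from numpy.fft import fft2, ifft2, fftshift, ifftshift

from .optics import (IlluminationPlan, OpticalSystemConfig, PupilFunction,
                     TWO_PI, make_pupil)
from .phantoms import ComplexObject


@dataclasses.dataclass(frozen=True)
class AcquisitionOptions:
    """Camera/defocus/noise options for a simulated acquisition.

    ``downsample_factor`` maps the high-resolution object grid to the camera
    grid (must divide the object shape); ``defocus_um`` displaces the sample
    from the focal plane, identically for every LED; noise is off by default
    and exists for robustness experiments only.
    """

    downsample_factor: int = 1
    defocus_um: float = 0.0
    noise: Literal["none", "gaussian", "poisson"] = "none"
    noise_sigma: float = 0.0          # gaussian std, in mean-bright-field units
    photon_scale: float = 1e4         # photons per unit intensity (poisson)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.downsample_factor < 1 or int(self.downsample_factor) != self.downsample_factor:
            raise ValueError("downsample_factor must be an integer >= 1")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclasses.dataclass
class RawStack:
    """Per-LED low-resolution intensity images plus acquisition metadata."""

    images: np.ndarray                # (n_led, h, w), float, >= 0
    plan: IlluminationPlan
    config: OpticalSystemConfig
    options: AcquisitionOptions
    pixel_um: float                   # camera pixel at the object plane
    shift_px: np.ndarray | None = None          # (n, 2) grid shifts (cy, cx)
    shift_residual: np.ndarray | None = None    # (n, 2) rounding residual, px

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_led, h, w) array")
        if len(self.plan) != self.images.shape[0]:
            raise ValueError(
                f"plan has {len(self.plan)} LEDs but stack has "
                f"{self.images.shape[0]} images")
        if (self.images < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]  # type: ignore[return-value]


def box_downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    """Intensity-domain pixel integration: non-overlapping box means."""
    if factor == 1:
        return arr
    ny, nx = arr.shape
    if ny % factor or nx % factor:
        raise ValueError(f"downsample factor {factor} does not divide "
                         f"shape {arr.shape}")
    return arr.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


def grid_shift_px(kx: float, ky: float, dk: float) -> tuple[tuple[int, int],
                                                            tuple[float, float]]:
    """Round a wave vector to whole spectrum pixels; return (cy, cx), residual."""
    cx = int(round(kx / dk))
    cy = int(round(ky / dk))
    return (cy, cx), (ky / dk - cy, kx / dk - cx)


def simulate_acquisition(obj: ComplexObject, config: OpticalSystemConfig,
                         plan: IlluminationPlan,
                         options: AcquisitionOptions | None = None
                         ) -> RawStack:
    """Simulate the full LED-array acquisition of ``obj``.

    Per LED: shift the object spectrum by the (grid-rounded) illumination
    wave vector, multiply by the (possibly defocused) pupil, inverse
    transform, square, and box-average down to the camera sampling.
    Deterministic given ``options.seed``.
    """
    options = options or AcquisitionOptions()
    ny, nx = obj.shape
    if ny != nx:
        raise ValueError("simulation requires a square object grid")
    f = options.downsample_factor
    if ny % f:
        raise ValueError(f"downsample factor {f} does not divide object "
                         f"shape {obj.shape}")
    dx = obj.pixel_um
    dk = TWO_PI / (ny * dx)
    lam = config.wavelength_um

    na_synth = config.objective_na + plan.max_illumination_na()
    if dx > lam / (2.0 * na_synth):
        warnings.warn(
            f"object pixel {dx:.3f} um undersamples the synthesized band "
            f"(recommend <= {lam / (2 * na_synth):.3f} um)", stacklevel=2)
    cam_pixel = dx * f
    if abs(cam_pixel - config.object_pixel_um) > 0.01 * config.object_pixel_um:
        warnings.warn(
            f"camera sampling {cam_pixel:.4f} um differs from the configured "
            f"object-plane pixel {config.object_pixel_um:.4f} um", stacklevel=2)

    pupil = make_pupil((ny, nx), dk, config.objective_na, lam,
                       options.defocus_um)
    spectrum = fftshift(fft2(obj.field))
    images = np.empty((len(plan), ny // f, nx // f))
    shifts = np.empty((len(plan), 2), dtype=int)
    residuals = np.empty((len(plan), 2))
    for i, entry in enumerate(plan.entries):
        (cy, cx), res = grid_shift_px(entry.kx_per_um, entry.ky_per_um, dk)
        shifts[i] = (cy, cx)
        residuals[i] = res
        shifted = np.roll(spectrum, (cy, cx), axis=(0, 1))
        field = ifft2(ifftshift(shifted * pupil.array))
        images[i] = box_downsample(np.abs(field) ** 2, f)

    if options.noise != "none":
        rng = np.random.default_rng(options.seed)
        if options.noise == "gaussian":
            images = images + rng.normal(0.0, options.noise_sigma, images.shape)
            np.clip(images, 0.0, None, out=images)
        else:  # poisson
            scale = options.photon_scale
            images = rng.poisson(np.clip(images, 0.0, None) * scale) / scale

    return RawStack(images, plan, config, options, cam_pixel,
                    shift_px=shifts, shift_residual=residuals)


def brute_force_forward(obj: ComplexObject, pupil: PupilFunction,
                        kx_per_um: float, ky_per_um: float,
                        downsample_factor: int = 1) -> np.ndarray:
    """Single-LED forward model by explicit DFT sums (independent oracle).

    Computes the same physics as :func:`simulate_acquisition` — tilted plane
    wave, spectrum low-pass by the pupil, intensity at the camera — with the
    DFT written out as explicit complex-exponential sums (dense DFT matrices,
    no FFT library involvement).  The illumination wave vector is rounded to
    the spectrum grid exactly as in the FFT path.  Guarded to objects
    <= 64 x 64 (O(N^4) cost).
    """
    ny, nx = obj.shape
    if ny != nx:
        raise ValueError("square objects only")
    if ny > 64:
        raise ValueError("brute-force oracle is limited to 64x64 objects")
    n = ny
    dk = pupil.spectrum_sampling
    (cy, cx), _ = grid_shift_px(kx_per_um, ky_per_um, dk)

    idx = np.arange(n)
    # tilted illumination at the grid-rounded wave vector: an exact ramp
    ramp = np.exp(2j * np.pi * (cy * idx[:, None] + cx * idx[None, :]) / n)
    s2 = obj.field * ramp

    w = np.exp(-2j * np.pi * np.outer(idx, idx) / n)   # forward DFT matrix
    spectrum = w @ s2 @ w.T                             # S(u, v), numpy order
    filtered = spectrum * ifftshift(pupil.array)
    winv = np.conj(w)
    field = (winv @ filtered @ winv.T) / (n * n)
    return box_downsample(np.abs(field) ** 2, downsample_factor)
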