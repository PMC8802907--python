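"""Optical bookkeeping for an LED-array Fourier ptychographic microscope.

This module is the single source of truth for scale conversions shared by the
simulator, the reconstructor and the evaluator: effective magnification of an
infinity-corrected system with a non-standard tube lens, illumination wave
vectors of individual LEDs, numerical-aperture arithmetic (objective +
illumination = synthesized equivalent NA), USAF 1951 group/element spatial
frequencies, Rayleigh-criterion conversions, and construction of the circular
(possibly defocused) pupil function of the objective.

Conventions
-----------
* Lateral lengths on the LED stage are in mm, wavelengths and pixel sizes in
  um, angular spatial frequencies ``k`` in rad/um, and engineering spatial
  frequencies in line pairs per mm (one line pair = one full bright+dark
  period; a bar half-pitch of ``r`` um corresponds to ``1000/(2 r)`` lp/mm).
* An LED displaced toward +x produces ``kx > 0``; the raw image for that LED
  samples the object spectrum disk centred at ``-k_m`` on the reconstruction
  grid (the spectrum-shift convention used consistently by
  :mod:`fpmscope.forward` and :mod:`fpmscope.recon`).
* Pupil arrays are stored in *centred* (fftshifted) layout: DC sits at index
  ``(n // 2, n // 2)``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np

TWO_PI = 2.0 * math.pi

#: Standard reference focal length (mm) of Olympus infinity-corrected optics.
OLYMPUS_REFERENCE_FOCAL_MM = 180.0

#: Rayleigh two-point resolution constant: half-pitch = 0.61 * lambda / NA.
RAYLEIGH_CONSTANT = 0.61


class ConfigurationError(ValueError):
    """An optical/geometry configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------

def effective_magnification(nominal_mag: float, tube_mm: float,
                            reference_mm: float = OLYMPUS_REFERENCE_FOCAL_MM) -> float:
    """Actual magnification of an infinity-corrected objective.

    A nominal ``M x`` objective is rated for a tube lens of focal length
    ``reference_mm``; with a tube lens of ``tube_mm`` the actual magnification
    scales proportionally: ``M * tube_mm / reference_mm``.
    """
    if nominal_mag <= 0 or tube_mm <= 0 or reference_mm <= 0:
        raise ValueError("magnification and focal lengths must be positive")
    return nominal_mag * tube_mm / reference_mm


def wavevector_for_led(x_mm: float, y_mm: float, distance_mm: float,
                       wavelength_um: float) -> tuple[float, float]:
    """Transverse illumination wave vector (kx, ky) in rad/um for one LED.

    ``sin(theta_x) = x / sqrt(x^2 + y^2 + z^2)`` (and symmetrically for y);
    the component is ``2 pi sin(theta) / lambda``.
    """
    if distance_mm <= 0:
        raise ValueError("stage distance must be positive")
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    hyp = math.sqrt(x_mm * x_mm + y_mm * y_mm + distance_mm * distance_mm)
    return (TWO_PI * (x_mm / hyp) / wavelength_um,
            TWO_PI * (y_mm / hyp) / wavelength_um)


def equivalent_na(objective_na: float, illumination_na: float) -> float:
    """Synthesized equivalent NA of an FPM system: objective + illumination."""
    if not 0 < objective_na < 1:
        raise ValueError("objective NA must be in (0, 1)")
    if not 0 <= illumination_na < 1:
        raise ValueError("illumination NA must be in [0, 1)")
    return objective_na + illumination_na


def coherent_cutoff_lp_per_mm(na: float, wavelength_um: float) -> float:
    """Coherent cutoff NA/lambda as lp/mm (2pi-free form of 2 pi NA / lambda)."""
    if na <= 0 or wavelength_um <= 0:
        raise ValueError("NA and wavelength must be positive")
    return 1000.0 * na / wavelength_um


def usaf_frequency(group: int, element: int) -> float:
    """Spatial frequency (lp/mm) of USAF 1951 element: 2**(group + (element-1)/6)."""
    if not 1 <= int(element) <= 6 or int(element) != element:
        raise ValueError(f"element must be an integer in 1..6, got {element!r}")
    return 2.0 ** (group + (element - 1) / 6.0)


def usaf_frequency_rounded(group: int, element: int) -> int:
    """``usaf_frequency`` rounded to the nearest integer (chart-label form)."""
    return int(round(usaf_frequency(group, element)))


def rayleigh_halfpitch_um(na: float, wavelength_um: float) -> float:
    """Rayleigh two-point resolution expressed as a bar half-pitch in um."""
    if na <= 0 or wavelength_um <= 0:
        raise ValueError("NA and wavelength must be positive")
    return RAYLEIGH_CONSTANT * wavelength_um / na


def na_from_halfpitch(halfpitch_um: float, wavelength_um: float) -> float:
    """Inverse of :func:`rayleigh_halfpitch_um` (exact round trip)."""
    if halfpitch_um <= 0 or wavelength_um <= 0:
        raise ValueError("half-pitch and wavelength must be positive")
    return RAYLEIGH_CONSTANT * wavelength_um / halfpitch_um


def halfpitch_to_lp_per_mm(halfpitch_um: float) -> float:
    """Bar half-pitch in um -> engineering frequency 1/(2 r) in lp/mm."""
    if halfpitch_um <= 0:
        raise ValueError("half-pitch must be positive")
    return 1000.0 / (2.0 * halfpitch_um)


def lp_per_mm_to_halfpitch(lp_per_mm: float) -> float:
    """Engineering frequency in lp/mm -> bar half-pitch in um."""
    if lp_per_mm <= 0:
        raise ValueError("frequency must be positive")
    return 1000.0 / (2.0 * lp_per_mm)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class OpticalSystemConfig:
    """Objective / camera configuration; single source of truth for scales.

    Parameters
    ----------
    objective_na
        Rated numerical aperture of the objective, in (0, 1).
    nominal_magnification
        Rated magnification (e.g. 4 for a 4x objective).
    tube_focal_length_mm
        Focal length of the tube lens actually installed.
    wavelength_um
        Central illumination wavelength in um.
    camera_pixel_um
        Physical camera pixel pitch in um.
    reference_focal_length_mm
        Reference tube focal length the objective is rated for
        (180 mm for the Olympus infinity standard).
    """

    objective_na: float
    nominal_magnification: float
    tube_focal_length_mm: float
    wavelength_um: float
    camera_pixel_um: float
    reference_focal_length_mm: float = OLYMPUS_REFERENCE_FOCAL_MM

    def __post_init__(self) -> None:
        if not 0 < self.objective_na < 1:
            raise ConfigurationError("objective_na must be in (0, 1)")
        for name in ("nominal_magnification", "tube_focal_length_mm",
                     "wavelength_um", "camera_pixel_um",
                     "reference_focal_length_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def effective_magnification(self) -> float:
        return effective_magnification(self.nominal_magnification,
                                       self.tube_focal_length_mm,
                                       self.reference_focal_length_mm)

    @property
    def object_pixel_um(self) -> float:
        """Camera pixel pitch back-projected to the object plane."""
        return self.camera_pixel_um / self.effective_magnification

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["object_pixel_um"] = self.object_pixel_um
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalSystemConfig":
        d = dict(d)
        derived = d.pop("object_pixel_um", None)
        cfg = cls(**d)
        if derived is not None and not math.isclose(
                derived, cfg.object_pixel_um, rel_tol=1e-9):
            raise ConfigurationError(
                "object_pixel_um inconsistent with magnification: "
                f"{derived} != {cfg.object_pixel_um}")
        return cfg


@dataclasses.dataclass(frozen=True)
class LEDArrayGeometry:
    """Planar LED matrix below the stage; a centred sub-grid is illuminated."""

    grid_rows: int = 32
    grid_cols: int = 32
    pitch_mm: float = 4.0
    stage_distance_mm: float = 70.0
    used_rows: int = 15
    used_cols: int = 15

    def __post_init__(self) -> None:
        if self.pitch_mm <= 0 or self.stage_distance_mm <= 0:
            raise ConfigurationError("pitch and stage distance must be positive")
        if min(self.grid_rows, self.grid_cols,
               self.used_rows, self.used_cols) < 1:
            raise ConfigurationError("grid sizes must be >= 1")
        if self.used_rows > self.grid_rows or self.used_cols > self.grid_cols:
            raise ConfigurationError("used sub-grid must fit inside full grid")

    def led_offsets_mm(self) -> np.ndarray:
        """(n, 2) array of (x, y) lateral offsets of the used, centred sub-grid."""
        xs = (np.arange(self.used_cols) - (self.used_cols - 1) / 2.0) * self.pitch_mm
        ys = (np.arange(self.used_rows) - (self.used_rows - 1) / 2.0) * self.pitch_mm
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LEDArrayGeometry":
        return cls(**d)


def illumination_na(geometry: LEDArrayGeometry,
                    mode: Literal["diagonal", "axis"] = "diagonal") -> float:
    """Maximum illumination NA of the used LED sub-grid.

    ``mode="diagonal"`` returns the true maximum of
    ``sqrt(sin^2 theta_x + sin^2 theta_y)`` over all used LEDs (attained at a
    corner LED); ``mode="axis"`` returns the axis-aligned maximum, i.e. the
    sine of the tilt of the outermost LED on a principal axis.  Both numbers
    are reported because chart-style NA bookkeeping conventionally quotes the
    axis-aligned value.
    """
    offsets = geometry.led_offsets_mm()
    if offsets.size == 0:
        raise ConfigurationError("empty illumination plan")
    z = geometry.stage_distance_mm
    if mode == "diagonal":
        r2 = (offsets ** 2).sum(axis=1)
        return float(np.sqrt((r2 / (r2 + z * z)).max()))
    if mode == "axis":
        off = float(np.abs(offsets).max())
        return off / math.hypot(off, z)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# illumination plan
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LEDEntry:
    led_index: int          # raster index in the used sub-grid
    x_mm: float
    y_mm: float
    kx_per_um: float
    ky_per_um: float

    @property
    def k_norm(self) -> float:
        return math.hypot(self.kx_per_um, self.ky_per_um)


@dataclasses.dataclass(frozen=True)
class IlluminationPlan:
    """Ordered LED acquisition sequence with derived spatial-frequency offsets."""

    entries: tuple[LEDEntry, ...]
    ordering_rule: str
    wavelength_um: float

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def k_array(self) -> np.ndarray:
        """(n, 2) array of (kx, ky) in rad/um, in acquisition order."""
        return np.array([[e.kx_per_um, e.ky_per_um] for e in self.entries])

    @property
    def on_axis_index(self) -> int:
        """Position (in acquisition order) of the LED closest to the axis."""
        return int(np.argmin([e.k_norm for e in self.entries]))

    def max_illumination_na(self) -> float:
        """Max sqrt(sin^2x + sin^2y) over the plan, from the wave vectors."""
        k = self.k_array
        return float(np.sqrt((k ** 2).sum(axis=1)).max()
                     * self.wavelength_um / TWO_PI)

    def to_dict(self) -> dict:
        return {
            "ordering_rule": self.ordering_rule,
            "wavelength_um": self.wavelength_um,
            "entries": [dataclasses.asdict(e) for e in self.entries],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IlluminationPlan":
        return cls(entries=tuple(LEDEntry(**e) for e in d["entries"]),
                   ordering_rule=d["ordering_rule"],
                   wavelength_um=d["wavelength_um"])


def build_illumination_plan(geometry: LEDArrayGeometry, wavelength_um: float,
                            ordering: Literal["spiral", "raster"] = "spiral"
                            ) -> IlluminationPlan:
    """Enumerate the used LEDs and their wave vectors in acquisition order.

    ``spiral`` orders LEDs from the optical axis outward (bright-field first),
    breaking ties by polar angle — the de-facto FPM acquisition/update order.
    ``raster`` keeps row-major order.  The on-axis LED of an odd-sized grid
    maps exactly to (kx, ky) = (0, 0).
    """
    offsets = geometry.led_offsets_mm()
    entries = []
    for idx, (x, y) in enumerate(offsets):
        kx, ky = wavevector_for_led(float(x), float(y),
                                    geometry.stage_distance_mm, wavelength_um)
        entries.append(LEDEntry(idx, float(x), float(y), kx, ky))
    if ordering == "spiral":
        entries.sort(key=lambda e: (round(e.k_norm, 12),
                                    math.atan2(e.ky_per_um, e.kx_per_um)))
    elif ordering != "raster":
        raise ValueError(f"unknown ordering {ordering!r}")
    return IlluminationPlan(tuple(entries), ordering, wavelength_um)


# ---------------------------------------------------------------------------
# pupil function
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PupilFunction:
    """Complex pupil over the spectrum grid, centred (DC at ``n//2``).

    The ideal pupil is a binary disk of radius ``2 pi NA / lambda`` in
    spectrum units; a defocus of ``z`` um multiplies the interior by
    ``exp(i z kz)`` with ``kz = sqrt((2 pi n / lambda)^2 - |k|^2)`` and
    refractive index n = 1 (air objective).
    """

    array: np.ndarray
    na: float
    wavelength_um: float
    spectrum_sampling: float   # rad/um per spectrum pixel
    defocus_um: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape  # type: ignore[return-value]

    @property
    def support(self) -> np.ndarray:
        return np.abs(self.array) > 0

    def copy(self) -> "PupilFunction":
        return PupilFunction(self.array.copy(), self.na, self.wavelength_um,
                             self.spectrum_sampling, self.defocus_um)

    @classmethod
    def flat(cls, shape: tuple[int, int], spectrum_sampling: float,
             wavelength_um: float) -> "PupilFunction":
        """All-pass pupil (identity filter); useful for degenerate tests."""
        return cls(np.ones(shape, dtype=complex), na=1.0 - 1e-12,
                   wavelength_um=wavelength_um,
                   spectrum_sampling=spectrum_sampling)


def make_pupil(shape: tuple[int, int] | int, spectrum_sampling: float,
               na: float, wavelength_um: float,
               defocus_um: float = 0.0) -> PupilFunction:
    """Circular low-pass pupil of the objective, optionally defocused.

    Raises :class:`ConfigurationError` if the pupil disk would exceed the
    Nyquist extent of the grid (radius > ``min(shape)//2`` pixels).
    """
    if isinstance(shape, int):
        shape = (shape, shape)
    ny, nx = shape
    if ny < 2 or nx < 2:
        raise ConfigurationError("pupil grid must be at least 2x2")
    if spectrum_sampling <= 0:
        raise ConfigurationError("spectrum sampling must be positive")
    k_radius = TWO_PI * na / wavelength_um
    radius_px = k_radius / spectrum_sampling
    if radius_px > min(ny, nx) // 2:
        raise ConfigurationError(
            f"pupil radius {radius_px:.2f} px exceeds the Nyquist extent "
            f"{min(ny, nx) // 2} px of the {ny}x{nx} grid")
    iy = np.arange(ny) - ny // 2
    ix = np.arange(nx) - nx // 2
    dist2 = iy[:, None] ** 2 + ix[None, :] ** 2      # integer pixel distances
    mask = dist2 <= radius_px ** 2 * (1 + 1e-12)
    if defocus_um == 0.0:
        return PupilFunction(mask.astype(complex), na, wavelength_um,
                             spectrum_sampling, 0.0)
    k0 = TWO_PI / wavelength_um
    k2 = dist2 * spectrum_sampling ** 2
    kz = np.sqrt(np.maximum(k0 ** 2 - k2, 0.0))
    arr = np.where(mask, np.exp(1j * defocus_um * kz), 0.0)
    return PupilFunction(arr, na, wavelength_um, spectrum_sampling, defocus_um)
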