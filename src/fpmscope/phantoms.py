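"""Synthetic ground-truth objects: USAF 1951 bar targets and G-banded
metaphase-chromosome phantoms.

Both generators return a :class:`ComplexObject` — a complex transmission
function (amplitude in [0, 1], phase in radians) on a square pixel grid —
plus a machine-readable truth record used by the evaluation module:

* the USAF generator returns a :class:`BarPatternIndex` locating every
  rendered three-bar element (group, element, orientation, rectangle, lp/mm);
* the chromosome generator returns a :class:`ChromosomeTruth` with per-rod
  centerlines, band boundaries along arclength, band polarity, and the band
  spatial-frequency profile.

Rendering is antialiased by supersampling (default 4x) followed by box
downsampling, which keeps gridding artifacts out of bar-contrast (MTF)
measurements.  Chromosome bands are smooth (cosine) absorption profiles with
a correlated phase component, emulating Giemsa-stained chromatin, which is a
partial phase object; band contrast defaults are visual choices, not claims
about Giemsa optical density.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .optics import ConfigurationError, usaf_frequency, lp_per_mm_to_halfpitch


class GenerationError(RuntimeError):
    """Phantom generation failed (e.g. placement retries exhausted)."""


@dataclasses.dataclass
class ComplexObject:
    """High-resolution complex transmission function with pixel size in um."""

    amplitude: np.ndarray
    phase: np.ndarray
    pixel_um: float
    truth: object | None = None

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase must have identical shape")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape  # type: ignore[return-value]

    @property
    def field(self) -> np.ndarray:
        """Complex transmission amplitude * exp(i phase)."""
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def fov_um(self) -> tuple[float, float]:
        ny, nx = self.shape
        return (ny * self.pixel_um, nx * self.pixel_um)


# ---------------------------------------------------------------------------
# USAF 1951 target
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BarTarget:
    """One rendered three-bar element: location and nominal frequency."""

    group: int
    element: int
    orientation: str                      # "vertical" | "horizontal"
    rect_um: tuple[float, float, float, float]   # (x0, y0, x1, y1), object um
    lp_per_mm: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class BarPatternIndex:
    elements: tuple[BarTarget, ...]

    def __iter__(self):
        return iter(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def to_dict(self) -> dict:
        return {"elements": [e.to_dict() for e in self.elements]}

    @classmethod
    def from_dict(cls, d: dict) -> "BarPatternIndex":
        return cls(tuple(BarTarget(group=e["group"], element=e["element"],
                                   orientation=e["orientation"],
                                   rect_um=tuple(e["rect_um"]),
                                   lp_per_mm=e["lp_per_mm"])
                         for e in d["elements"]))


def _shelf_pack(blocks: list[tuple[float, float]], width: float,
                gap: float) -> list[tuple[float, float]]:
    """Greedy shelf packing of (w, h) blocks into rows of given width.

    Returns the (x, y) origin of each block in input order.  Blocks are
    assumed pre-sorted (tallest first) by the caller for decent packing.
    """
    origins: list[tuple[float, float]] = []
    x = y = row_h = 0.0
    for (w, h) in blocks:
        if x > 0 and x + w > width:
            x = 0.0
            y += row_h + gap
            row_h = 0.0
        origins.append((x, y))
        x += w + gap
        row_h = max(row_h, h)
    return origins


def _fill_rect(canvas: np.ndarray, ss_pitch: float,
               x0: float, y0: float, x1: float, y1: float,
               value: float) -> None:
    i0 = int(round(y0 / ss_pitch)); i1 = int(round(y1 / ss_pitch))
    j0 = int(round(x0 / ss_pitch)); j1 = int(round(x1 / ss_pitch))
    canvas[max(i0, 0):i1, max(j0, 0):j1] = value


def generate_usaf_phantom(groups: Sequence[int], pixel_um: float,
                          amplitude_contrast: float = 1.0,
                          phase_contrast: float = 0.0,
                          elements: Sequence[int] = (1, 2, 3, 4, 5, 6),
                          orientations: Sequence[str] = ("vertical",
                                                         "horizontal"),
                          shape: tuple[int, int] | None = None,
                          margin_um: float = 1.0,
                          supersample: int = 4,
                          ) -> tuple[ComplexObject, BarPatternIndex]:
    """Render a compact USAF-1951-style bar chart as a complex object.

    ``groups`` is either a list of group numbers (crossed with ``elements``)
    or an explicit list of (group, element) pairs.  Each requested
    (group, element) is drawn as the standard three-bar
    pattern (bar length : width = 5 : 1, inter-bar gap = bar width) in the
    requested orientations.  Dark bars transmit ``1 - amplitude_contrast``
    and optionally carry a phase step of ``phase_contrast`` radians; the
    background is a clear field (transmission 1, phase 0).

    The finest requested element must keep >= 2 samples per half-pitch at
    ``pixel_um`` (Nyquist guard), otherwise a :class:`ConfigurationError`
    names the offending element.
    """
    if not 0 <= amplitude_contrast <= 1:
        raise ValueError("amplitude_contrast must be in [0, 1]")
    if groups and isinstance(groups[0], (tuple, list)):
        specs = [(int(g), int(e)) for g, e in groups]   # explicit pairs
    else:
        specs = [(int(g), int(e)) for g in groups for e in elements]
    if not specs:
        raise ValueError("no elements requested")
    for g, e in specs:
        w = lp_per_mm_to_halfpitch(usaf_frequency(g, e))
        if w / pixel_um < 2.0:
            raise ConfigurationError(
                f"element {g}-{e} (half-pitch {w:.3f} um) has fewer than 2 "
                f"samples per half-pitch at pixel {pixel_um} um")

    # blocks: one per (group, element); orientations stacked inside a block
    n_or = len(orientations)
    block_dims = []
    for g, e in specs:
        w = lp_per_mm_to_halfpitch(usaf_frequency(g, e))
        bw = 5 * w
        bh = 5 * w * n_or + w * (n_or - 1)
        block_dims.append((bw, bh))
    order = sorted(range(len(specs)), key=lambda i: -block_dims[i][1])

    gap = 1.5 * margin_um
    if shape is None:
        area = sum(bw * bh for bw, bh in block_dims)
        width = max(1.5 * math.sqrt(area), max(bw for bw, _ in block_dims))
        origins_sorted = _shelf_pack([block_dims[i] for i in order], width,
                                     gap=gap)
        height = max(oy + block_dims[i][1]
                     for (ox, oy), i in zip(origins_sorted, order))
        side = max(width, height) + 2 * margin_um
        n = int(math.ceil(side / pixel_um))
        shape = (n, n)
    else:
        width = shape[1] * pixel_um - 2 * margin_um
        origins_sorted = _shelf_pack([block_dims[i] for i in order], width,
                                     gap=gap)
        height = max(oy + block_dims[i][1]
                     for (ox, oy), i in zip(origins_sorted, order))
        if height > shape[0] * pixel_um - 2 * margin_um:
            raise ConfigurationError(
                f"requested elements need {height:.1f} um of height but the "
                f"field of view provides {shape[0] * pixel_um:.1f} um")
    origins = [None] * len(specs)
    for (ox, oy), i in zip(origins_sorted, order):
        origins[i] = (ox + margin_um, oy + margin_um)

    ss = int(supersample)
    ss_pitch = pixel_um / ss
    canvas = np.zeros((shape[0] * ss, shape[1] * ss))  # bar mask (1 on bars)
    targets = []
    for (g, e), (ox, oy) in zip(specs, origins):
        f = usaf_frequency(g, e)
        w = lp_per_mm_to_halfpitch(f)
        for k, orientation in enumerate(orientations):
            ty = oy + k * (5 * w + w)
            if orientation == "vertical":      # bars elongated along y
                for b in range(3):
                    _fill_rect(canvas, ss_pitch,
                               ox + 2 * b * w, ty, ox + (2 * b + 1) * w,
                               ty + 5 * w, 1.0)
            elif orientation == "horizontal":  # bars elongated along x
                for b in range(3):
                    _fill_rect(canvas, ss_pitch,
                               ox, ty + 2 * b * w, ox + 5 * w,
                               ty + (2 * b + 1) * w, 1.0)
            else:
                raise ValueError(f"unknown orientation {orientation!r}")
            targets.append(BarTarget(g, e, orientation,
                                     (ox, ty, ox + 5 * w, ty + 5 * w), f))

    mask = canvas.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))
    amplitude = 1.0 - amplitude_contrast * mask
    phase = phase_contrast * mask
    index = BarPatternIndex(tuple(targets))
    obj = ComplexObject(amplitude, phase, pixel_um, truth=index)
    return obj, index


# ---------------------------------------------------------------------------
# chromosome phantom
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ChromosomeRecord:
    """Ground truth for one rendered chromosome rod."""

    centerline_um: np.ndarray        # (M, 2) (x, y) points, ~equal arclength
    arclength_um: np.ndarray         # (M,) cumulative arclength
    band_boundaries_um: tuple[float, ...]   # along arclength, increasing
    band_polarity: tuple[str, ...]          # "dark"/"bright", one per band
    freq_profile_lp_mm: tuple[float, float]  # (f at s=0, f at s=L)
    length_um: float
    width_um: float

    def mean_band_period_um(self) -> float:
        f0, f1 = self.freq_profile_lp_mm
        return 1000.0 / (0.5 * (f0 + f1))

    def to_dict(self) -> dict:
        return {
            "centerline_um": self.centerline_um.tolist(),
            "arclength_um": self.arclength_um.tolist(),
            "band_boundaries_um": list(self.band_boundaries_um),
            "band_polarity": list(self.band_polarity),
            "freq_profile_lp_mm": list(self.freq_profile_lp_mm),
            "length_um": self.length_um,
            "width_um": self.width_um,
        }


@dataclasses.dataclass(frozen=True)
class ChromosomeTruth:
    chromosomes: tuple[ChromosomeRecord, ...]

    def __len__(self) -> int:
        return len(self.chromosomes)

    def to_dict(self) -> dict:
        return {"chromosomes": [c.to_dict() for c in self.chromosomes]}


def _bezier_centerline(rng: np.random.Generator, length_um: float,
                       center: np.ndarray, angle: float,
                       n_points: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Slightly curved centerline (quadratic Bezier) re-sampled by arclength."""
    u = np.array([math.cos(angle), math.sin(angle)])
    nvec = np.array([-u[1], u[0]])
    bow = rng.uniform(0.03, 0.15) * length_um * rng.choice([-1.0, 1.0])
    a = center - 0.5 * length_um * u
    b = center + 0.5 * length_um * u
    c = center + bow * nvec
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    pts = (1 - t) ** 2 * a + 2 * t * (1 - t) * c + t ** 2 * b
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def _band_boundaries(f0: float, f1: float, total_s: float) -> list[float]:
    """Zero crossings of cos(phi(s)) with phi quadratic in s (linear chirp).

    phi(s) = 2 pi (f0 s + (f1 - f0) s^2 / (2 L)) / 1000, s and L in um,
    f in lp/mm.  Boundaries sit where phi = pi/2 + k pi.
    """
    bounds = []
    k = 0
    while True:
        target = (0.5 + k) * math.pi
        # solve 2*pi*(f0*s + c*s^2)/1000 = target, c = (f1-f0)/(2L)
        c = (f1 - f0) / (2.0 * total_s)
        a2, a1, a0 = c, f0, -target * 1000.0 / (2.0 * math.pi)
        if abs(a2) < 1e-12:
            s = -a0 / a1
        else:
            disc = a1 * a1 - 4 * a2 * a0
            if disc < 0:
                break
            s = (-a1 + math.sqrt(disc)) / (2 * a2)
        if not 0 < s < total_s:
            break
        bounds.append(s)
        k += 1
    return bounds


def generate_chromosome_phantom(n_chromosomes: int,
                                pixel_um: float,
                                band_freq_range_lp_mm: tuple[float, float]
                                = (200.0, 800.0),
                                phase_amplitude: float = 1.0,
                                seed: int = 0,
                                shape: tuple[int, int] = (256, 256),
                                length_range_um: tuple[float, float]
                                = (4.0, 9.0),
                                width_um: float = 1.4,
                                min_transmission: float = 0.35,
                                supersample: int = 4,
                                max_retries: int = 80,
                                ) -> tuple[ComplexObject, ChromosomeTruth]:
    """Render elongated, randomly oriented, slightly curved banded rods.

    Bands alternate dark/bright perpendicular to the centerline with a linear
    spatial-frequency chirp drawn from ``band_freq_range_lp_mm`` (kept below
    1000 lp/mm by default, the regime of real G-band patterns).  Absorption
    (transmission down to ``min_transmission`` at dark-band centres) carries a
    correlated phase component scaled by ``phase_amplitude``.  Deterministic
    for a fixed seed.
    """
    if not 0 < band_freq_range_lp_mm[0] <= band_freq_range_lp_mm[1]:
        raise ValueError("invalid band frequency range")
    if not 0 <= min_transmission < 1:
        raise ValueError("min_transmission must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    fov_y, fov_x = ny * pixel_um, nx * pixel_um
    ss = int(supersample)
    ss_pitch = pixel_um / ss
    absorb = np.zeros((ny * ss, nx * ss))   # normalized absorbance in [0, 1]
    depth = 1.0 - min_transmission

    records: list[ChromosomeRecord] = []
    placed: list[tuple[np.ndarray, float]] = []   # (centerline pts, half-width)
    half_w = 0.5 * width_um
    edge = min(0.3, 0.45 * half_w)                # lateral taper width, um

    for _ in range(n_chromosomes):
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise GenerationError(
                    "could not place a chromosome without overlap; "
                    "reduce n_chromosomes or enlarge the field of view")
            length = rng.uniform(*length_range_um)
            margin = 0.5 * length + width_um
            if 2 * margin >= min(fov_x, fov_y):
                raise GenerationError("field of view too small for the "
                                      "requested chromosome length")
            center = np.array([rng.uniform(margin, fov_x - margin),
                               rng.uniform(margin, fov_y - margin)])
            angle = rng.uniform(0.0, math.pi)
            pts, s = _bezier_centerline(rng, length, center, angle)
            ok = True
            for other_pts, other_hw in placed:
                tree = cKDTree(other_pts)
                d, _ = tree.query(pts, k=1)
                if d.min() < (half_w + other_hw) * 1.6:
                    ok = False
                    break
            if ok:
                break
        placed.append((pts, half_w))
        total_s = float(s[-1])
        f0, f1 = sorted(rng.uniform(*band_freq_range_lp_mm, size=2))
        if rng.random() < 0.5:
            f0, f1 = f1, f0
        bounds = _band_boundaries(f0, f1, total_s)
        polarity = tuple("dark" if i % 2 == 0 else "bright"
                         for i in range(len(bounds) + 1))

        # rasterize: nearest-centerline lookup on the supersampled grid
        tree = cKDTree(pts)
        x0 = max(pts[:, 0].min() - width_um, 0.0)
        x1 = min(pts[:, 0].max() + width_um, fov_x)
        y0 = max(pts[:, 1].min() - width_um, 0.0)
        y1 = min(pts[:, 1].max() + width_um, fov_y)
        j0, j1 = int(x0 / ss_pitch), int(math.ceil(x1 / ss_pitch))
        i0, i1 = int(y0 / ss_pitch), int(math.ceil(y1 / ss_pitch))
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        px = (jj.ravel() + 0.5) * ss_pitch
        py = (ii.ravel() + 0.5) * ss_pitch
        d, idx = tree.query(np.column_stack([px, py]), k=1,
                            distance_upper_bound=half_w)
        inside = np.isfinite(d)
        if not inside.any():
            records.append(ChromosomeRecord(pts, s, tuple(bounds), polarity,
                                            (f0, f1), total_s, width_um))
            continue
        s_near = s[np.clip(idx[inside], 0, len(s) - 1)]
        # linear-chirp band modulation along arclength
        phi = 2 * math.pi * (f0 * s_near
                             + (f1 - f0) * s_near ** 2 / (2 * total_s)) / 1000.0
        band = 0.5 + 0.5 * np.cos(phi)          # 1 at dark-band centres
        lateral = np.ones(inside.sum())
        t = (d[inside] - (half_w - edge)) / edge
        roll = t > 0
        lateral[roll] = 0.5 * (1 + np.cos(math.pi * np.clip(t[roll], 0, 1)))
        a_flat = np.zeros(d.shape[0])
        a_flat[inside] = band * lateral
        block = a_flat.reshape(ii.shape)
        sub = absorb[i0:i1, j0:j1]
        np.maximum(sub, block, out=sub)
        records.append(ChromosomeRecord(pts, s, tuple(bounds), polarity,
                                        (f0, f1), total_s, width_um))

    absorb_lo = absorb.reshape(ny, ss, nx, ss).mean(axis=(1, 3))
    amplitude = np.clip(1.0 - depth * absorb_lo, 0.0, 1.0)
    phase = phase_amplitude * absorb_lo
    truth = ChromosomeTruth(tuple(records))
    obj = ComplexObject(amplitude, phase, pixel_um, truth=truth)
    return obj, truth
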