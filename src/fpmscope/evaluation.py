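"""Resolving-power evaluation from bar-target images.

The contrast of a three-bar element is ``C = (Imax - Imin) / (Imax + Imin)``
where ``Imax``/``Imin`` average the bright-ridge and dark-valley extrema of
the intensity profile taken perpendicular to the bars and averaged along the
bar length.  A three-bar element must show its full complement of interior
extrema (three of the bar polarity, two between) to count as resolved;
otherwise it contributes contrast 0 with a not-resolved flag.

Contrast samples over a ladder of element frequencies form an MTF whose
smooth monotone fit (isotonic regression followed by monotone piecewise-cubic
interpolation, or an optional logistic-decay parametric fit) yields the
cutoff frequency — the lowest frequency where the fitted contrast drops to a
configurable level (default 0.02; fitted curves only reach zero
asymptotically) — and inverse frequency-at-contrast lookups.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks
from sklearn.isotonic import IsotonicRegression

from .phantoms import BarPatternIndex, BarTarget


@dataclasses.dataclass(frozen=True)
class MTFSample:
    frequency_lp_mm: float
    contrast: float                 # normalized, in [0, 1]
    group: int
    element: int
    orientation: str                # "vertical" | "horizontal" | "average"
    resolved: bool


@dataclasses.dataclass
class MTFCurve:
    """Fitted monotone MTF with cutoff and inverse-lookup accessors."""

    samples: tuple[MTFSample, ...]
    cutoff_lp_mm: float             # nan if the fit never reaches the level
    cutoff_level: float
    fit_method: str
    _interp: Callable[[np.ndarray], np.ndarray]
    f_max: float

    def __call__(self, frequency_lp_mm) -> np.ndarray:
        f = np.clip(np.asarray(frequency_lp_mm, dtype=float), 0.0, self.f_max)
        return np.clip(self._interp(f), 0.0, 1.0)

    def frequency_at_contrast(self, contrast: float) -> float:
        """Smallest frequency at which the fitted curve falls to ``contrast``."""
        if contrast >= 1.0:
            return 0.0
        grid = np.linspace(0.0, self.f_max, 2048)
        vals = self(grid)
        below = np.nonzero(vals <= contrast)[0]
        if below.size == 0:
            return float("nan")
        i = below[0]
        if i == 0:
            return 0.0
        return float(brentq(lambda f: float(self(f)) - contrast,
                            grid[i - 1], grid[i]))


def _rect_to_slices(rect_um: tuple[float, float, float, float],
                    pixel_um: float, shape: tuple[int, int]
                    ) -> tuple[slice, slice]:
    x0, y0, x1, y1 = rect_um
    j0 = max(int(round(x0 / pixel_um)), 0)
    j1 = min(int(round(x1 / pixel_um)), shape[1])
    i0 = max(int(round(y0 / pixel_um)), 0)
    i1 = min(int(round(y1 / pixel_um)), shape[0])
    if i1 <= i0 or j1 <= j0:
        raise ValueError(f"element rectangle {rect_um} lies outside the image")
    return slice(i0, i1), slice(j0, j1)


def bar_contrast(image: np.ndarray, rect_um: tuple[float, float, float, float],
                 orientation: str, pixel_um: float,
                 n_bars: int = 3, margin_um: float = 1.0) -> tuple[float, bool]:
    """Michelson-type contrast of one three-bar element.

    Returns ``(contrast, resolved)``.  The profile across the bars is the
    mean along the bar length; ridges and valleys are located with a minimum
    separation of roughly one bar width.  If fewer than ``n_bars`` extrema of
    the bar polarity (with ``n_bars - 1`` opposite extrema between them) are
    found, the element is flagged unresolved and the contrast is 0.
    Invariant to multiplying the image by a positive constant.

    The region of interest is widened along the profile axis by up to one
    bar width (capped at ``margin_um``) so that the outer bars keep their
    extrema under small registration offsets between the image and the
    truth coordinates.
    """
    x0, y0, x1, y1 = rect_um
    bar_w = (x1 - x0) / (2 * n_bars - 1) if orientation == "vertical" \
        else (y1 - y0) / (2 * n_bars - 1)
    pad = min(bar_w, margin_um)
    if orientation == "vertical":
        rect_um = (x0 - pad, y0, x1 + pad, y1)
    else:
        rect_um = (x0, y0 - pad, x1, y1 + pad)
    sl_i, sl_j = _rect_to_slices(rect_um, pixel_um, image.shape)
    roi = np.asarray(image, dtype=float)[sl_i, sl_j]
    if orientation == "vertical":      # bars along y, profile across x
        profile = roi.mean(axis=0)
    elif orientation == "horizontal":
        profile = roi.mean(axis=1)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if profile.size < 2 * n_bars:
        return 0.0, False
    # nominal valley/ridge separation is 2 bar widths; a 1.4-bar-width
    # exclusion zone merges plateau micro-extrema without losing real bars
    dist = max(int(1.4 * bar_w / pixel_um), 1)
    lo, _ = find_peaks(-profile, distance=dist)
    hi, _ = find_peaks(profile, distance=dist)
    bar_px = bar_w / pixel_um
    pad_px = pad / pixel_um
    expected = pad_px + (2 * np.arange(n_bars) + 0.5) * bar_px
    for bars, gaps in ((lo, hi), (hi, lo)):
        if len(bars) < n_bars or len(gaps) < n_bars - 1:
            continue
        # keep the n_bars most extreme bar peaks and the gaps between them
        vals = profile[bars]
        if bars is lo:
            pick = bars[np.argsort(vals)[:n_bars]]
        else:
            pick = bars[np.argsort(vals)[-n_bars:]]
        pick.sort()
        # the picked extrema must sit at the bar centres, up to a global
        # registration shift; leakage ripple just past cutoff fails this
        shift = np.mean(pick - expected)
        if abs(shift) > 1.5 * bar_px or \
                np.max(np.abs(pick - expected - shift)) > 0.5 * bar_px + 0.51:
            continue
        inner = gaps[(gaps > pick[0]) & (gaps < pick[-1])]
        if len(inner) < n_bars - 1:
            continue
        bar_mean = float(profile[pick].mean())
        gap_vals = profile[inner]
        gap_pick = np.sort(gap_vals)[-(n_bars - 1):] if bars is lo \
            else np.sort(gap_vals)[:n_bars - 1]
        gap_mean = float(gap_pick.mean())
        i_max, i_min = max(bar_mean, gap_mean), min(bar_mean, gap_mean)
        if i_max + i_min <= 0 or i_max <= i_min:
            return 0.0, False
        c = (i_max - i_min) / (i_max + i_min)
        return float(np.clip(c, 0.0, 1.0)), True
    return 0.0, False


def build_mtf(image: np.ndarray, index: BarPatternIndex, pixel_um: float,
              average_orientations: bool = True) -> list[MTFSample]:
    """One contrast sample per element (orientations averaged by default),
    normalized so the lowest-frequency sample anchors the curve at 1."""
    if len(index) == 0:
        raise ValueError("empty bar-pattern index")
    by_key: dict[tuple[int, int], list[tuple[BarTarget, float, bool]]] = {}
    for t in index:
        c, ok = bar_contrast(image, t.rect_um, t.orientation, pixel_um)
        by_key.setdefault((t.group, t.element), []).append((t, c, ok))
    raw: list[MTFSample] = []
    for (g, e), rows in sorted(by_key.items(),
                               key=lambda kv: rows_freq(kv[1])):
        if average_orientations:
            c = float(np.mean([c for _, c, _ in rows]))
            ok = all(ok for _, _, ok in rows)
            raw.append(MTFSample(rows[0][0].lp_per_mm, c, g, e, "average", ok))
        else:
            for t, c, ok in rows:
                raw.append(MTFSample(t.lp_per_mm, c, g, e, t.orientation, ok))
    raw.sort(key=lambda s: s.frequency_lp_mm)
    anchor = raw[0].contrast
    if anchor <= 0:
        raise ValueError("lowest-frequency element is unresolved; cannot "
                         "normalize the MTF")
    return [dataclasses.replace(s, contrast=float(np.clip(s.contrast / anchor,
                                                          0.0, 1.0)))
            for s in raw]


def rows_freq(rows) -> float:
    return rows[0][0].lp_per_mm


def fit_mtf_curve(samples: Sequence[MTFSample], cutoff_level: float = 0.02,
                  method: str = "isotonic_pchip") -> MTFCurve:
    """Fit a smooth monotone non-increasing curve through MTF samples.

    ``isotonic_pchip`` (default): decreasing isotonic regression of the
    samples followed by monotone piecewise-cubic interpolation — it
    interpolates already-monotone samples exactly.  ``logistic``: parametric
    decay ``1 / (1 + exp((f - f0) / s))`` rescaled to 1 at f = 0.  The curve
    is anchored to contrast 1 at frequency 0.
    """
    if len(samples) < 4:
        raise ValueError("need >= 4 MTF samples to fit a curve")
    f = np.array([s.frequency_lp_mm for s in samples])
    c = np.array([s.contrast for s in samples])
    order = np.argsort(f)
    f, c = f[order], c[order]
    if np.all(c <= 0):
        raise ValueError("all MTF samples are zero; degenerate curve")
    x = np.concatenate([[0.0], f])
    y = np.concatenate([[1.0], c])

    if method == "isotonic_pchip":
        iso = IsotonicRegression(increasing=False)
        y_fit = iso.fit_transform(x, y)
        y_fit[0] = 1.0
        keep = np.concatenate([[True], np.diff(x) > 0])
        interp = PchipInterpolator(x[keep], y_fit[keep], extrapolate=False)
        base = interp

        def evaluate(ff, _b=base, _xmax=x[-1], _ymin=y_fit[-1]):
            ff = np.asarray(ff, dtype=float)
            out = _b(np.clip(ff, 0.0, _xmax))
            return np.where(ff > _xmax, _ymin, out)
    elif method == "logistic":
        def model(ff, f0, s):
            return (1.0 / (1.0 + np.exp((ff - f0) / s))) \
                / (1.0 / (1.0 + np.exp(-f0 / s)))
        p0 = (np.median(f), max(np.ptp(f) / 4, 1.0))
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000)

        def evaluate(ff, _p=popt):
            return model(np.asarray(ff, dtype=float), *_p)
    else:
        raise ValueError(f"unknown fit method {method!r}")

    f_max = float(x[-1])
    grid = np.linspace(0.0, f_max, 4096)
    vals = np.clip(evaluate(grid), 0.0, 1.0)
    below = np.nonzero(vals <= cutoff_level)[0]
    if below.size and below[0] > 0:
        i = below[0]
        cutoff = float(brentq(
            lambda ff: float(np.clip(evaluate(ff), 0.0, 1.0)) - cutoff_level,
            grid[i - 1], grid[i]))
    elif below.size:
        cutoff = 0.0
    else:
        cutoff = float("nan")
    return MTFCurve(tuple(samples), cutoff, cutoff_level, method,
                    evaluate, f_max)


def smallest_resolved_element(image: np.ndarray, index: BarPatternIndex,
                              pixel_um: float,
                              contrast_threshold: float = 0.1
                              ) -> tuple[int, int] | None:
    """Finest (group, element) resolved in both orientations, or ``None``.

    An element counts as resolved when every rendered orientation passes the
    ridge/valley-count check and exceeds ``contrast_threshold``.
    """
    if len(index) == 0:
        raise ValueError("empty bar-pattern index")
    by_key: dict[tuple[int, int], list[BarTarget]] = {}
    for t in index:
        by_key.setdefault((t.group, t.element), []).append(t)
    best: tuple[float, tuple[int, int]] | None = None
    for key, targets in by_key.items():
        ok = True
        for t in targets:
            c, resolved = bar_contrast(image, t.rect_um, t.orientation,
                                       pixel_um)
            if not resolved or c < contrast_threshold:
                ok = False
                break
        if ok:
            freq = targets[0].lp_per_mm
            if best is None or freq > best[0]:
                best = (freq, key)
    return best[1] if best else None


def prepare_phase_display(phase: np.ndarray) -> np.ndarray:
    """Rescale a phase image to [0, 255] and invert, as an 8-bit image.

    Inversion makes the (zero-phase-shift) background bright, the display
    convention for reconstructed phase.  A constant input maps to all-255.
    """
    phase = np.asarray(phase, dtype=float)
    if not np.isfinite(phase).all():
        raise ValueError("phase image contains non-finite values")
    lo, hi = phase.min(), phase.max()
    if hi == lo:
        return np.full(phase.shape, 255, dtype=np.uint8)
    scaled = (phase - lo) / (hi - lo) * 255.0
    return np.round(255.0 - scaled).astype(np.uint8)
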