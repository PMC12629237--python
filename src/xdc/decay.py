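"""Contact probability P(s), its smoothed log-derivative, and the mean
extruded-loop size.

P(s) is the mean balanced contact per valid pixel, aggregated on a
log-spaced separation grid (8 bins per decade from 2 x bin_size) and
normalised to unit sum. Loop-extrusion factories add a shoulder to P(s)
whose signature is a local maximum in d log10 P / d log10 s; the separation
of the highest interior maximum inside the search range (default 20 kb --
2 Mb) estimates the mean loop size. A left shift of this maximum on the X
relative to the autosomes is the distance-decay signature of an
X-chromosome-specific loop extruder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeModel
from .matrix import ContactMatrix, expected_by_distance, ice_balance

GRID_BINS_PER_DECADE = 8
DEFAULT_SEARCH_RANGE = (20_000.0, 2_000_000.0)


def log_grid(
    bin_size: int, max_separation: float, bins_per_decade: int = GRID_BINS_PER_DECADE
) -> np.ndarray:
    """Log-spaced grid edges from 2 x bin_size up to max_separation."""
    lo = np.log10(2 * bin_size)
    hi = np.log10(max_separation)
    n = max(int(np.ceil((hi - lo) * bins_per_decade)), 2)
    return np.logspace(lo, hi, n + 1)


@dataclass
class PsCurve:
    chromosome: str
    separation: np.ndarray  # geometric bin centres, bp
    probability: np.ndarray  # unit-sum over defined bins; NaN gaps
    n_pixels: np.ndarray  # valid pixels per grid bin


@dataclass
class SlopeCurve:
    chromosome: str
    separation: np.ndarray
    slope: np.ndarray  # d log10 P / d log10 s, smoothed; NaN gaps
    n_pixels: np.ndarray
    source: str = "observed"  # observed | permuted


@dataclass
class LoopSizeEstimate:
    name: str
    loop_size: float | None  # bp; None when undefined
    peak_height: float | None
    search_range: tuple[float, float]
    reason: str = "ok"  # ok | no_interior_maximum | insufficient_points


def contact_probability(
    m: ContactMatrix,
    grid: np.ndarray | None = None,
    min_separation: float = 10_000.0,
) -> PsCurve:
    """Aggregate the per-diagonal expected curve onto the log grid.

    Grid-bin values are pixel-count-weighted means of the per-diagonal
    balanced averages; bins with no valid pixel are NaN gaps. The curve is
    normalised to unit sum over defined bins.
    """
    max_sep = m.n_bins * m.bin_size
    if max_sep <= min_separation:
        raise ValueError("chromosome shorter than min_separation")
    if grid is None:
        grid = log_grid(m.bin_size, max_sep)
    exp = expected_by_distance(m)
    sep = exp.separation.astype(float)
    use = (sep >= min_separation) & np.isfinite(exp.expected)

    centers = np.sqrt(grid[:-1] * grid[1:])
    prob = np.full(len(centers), np.nan)
    n_pixels = np.zeros(len(centers), dtype=int)
    which = np.digitize(sep, grid) - 1
    for k in range(len(centers)):
        sel = use & (which == k)
        if sel.any():
            wts = exp.n_valid[sel]
            prob[k] = np.average(exp.expected[sel], weights=wts)
            n_pixels[k] = int(wts.sum())
    total = np.nansum(prob)
    if total > 0:
        prob = prob / total
    return PsCurve(
        chromosome=m.chromosome, separation=centers, probability=prob, n_pixels=n_pixels
    )


def log_derivative(p: PsCurve, smoothing_halfwidth: int = 2) -> SlopeCurve:
    """Central finite differences of log10 P vs log10 s, then moving-average
    smoothing with the given halfwidth. NaN gaps propagate through both
    stages."""
    if len(p.separation) < 5:
        raise ValueError("need >= 5 grid points")
    if not np.isfinite(p.probability).any():
        raise ValueError("all-gap P(s) curve")
    logs = np.log10(p.separation)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p.probability > 0, np.log10(p.probability), np.nan)
    n = len(logs)
    raw = np.full(n, np.nan)
    # central differences; one-sided at the ends
    raw[1:-1] = (logp[2:] - logp[:-2]) / (logs[2:] - logs[:-2])
    raw[0] = (logp[1] - logp[0]) / (logs[1] - logs[0])
    raw[-1] = (logp[-1] - logp[-2]) / (logs[-1] - logs[-2])

    h = smoothing_halfwidth
    if h > 0:
        smoothed = np.full(n, np.nan)
        for i in range(n):
            seg = raw[max(0, i - h) : i + h + 1]
            if np.isfinite(seg).all():
                smoothed[i] = seg.mean()
        slope = smoothed
    else:
        slope = raw
    return SlopeCurve(
        chromosome=p.chromosome,
        separation=p.separation,
        slope=slope,
        n_pixels=p.n_pixels,
        source="observed",
    )


_MAXIMA_EPS = 1e-9  # ignores pure floating-point wiggle on flat slopes


def _interior_local_maxima(s: np.ndarray, y: np.ndarray) -> list[int]:
    """Indices i with finite y[i] strictly greater than both finite
    neighbours (plateaus resolved to their left edge)."""
    out = []
    for i in range(1, len(y) - 1):
        if not np.isfinite(y[i - 1 : i + 2]).all():
            continue
        if y[i] <= y[i - 1] + _MAXIMA_EPS:
            continue
        if y[i] > y[i + 1] + _MAXIMA_EPS:
            out.append(i)
        elif abs(y[i] - y[i + 1]) <= _MAXIMA_EPS:
            # plateau: require a strict drop somewhere right of it
            j = i + 1
            while j < len(y) - 1 and abs(y[j] - y[i]) <= _MAXIMA_EPS:
                j += 1
            if np.isfinite(y[j]) and y[j] < y[i] - _MAXIMA_EPS:
                out.append(i)
    return out


def _refine_peak(sc: SlopeCurve, i: int) -> tuple[float, float]:
    """Sub-grid peak location by a 3-point parabola in log10 separation.

    Returns (separation bp, height). Falls back to the grid point when the
    neighbours do not bracket a concave vertex."""
    x = np.log10(sc.separation[i - 1 : i + 2])
    y = sc.slope[i - 1 : i + 2]
    denom = y[0] - 2 * y[1] + y[2]
    if not np.isfinite(denom) or denom >= 0:
        return float(sc.separation[i]), float(sc.slope[i])
    delta = 0.5 * (y[0] - y[2]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dx = 0.5 * (x[2] - x[0])
    height = y[1] - 0.25 * (y[0] - y[2]) * delta
    return float(10 ** (x[1] + delta * dx)), float(height)


def slope_local_maxima(
    sc: SlopeCurve,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
) -> np.ndarray:
    """Separations (bp) of every interior local maximum of the smoothed
    slope inside the search range — the tick-mark positions whose average
    is the chromosome's mean loop size. Each position is refined to
    sub-grid precision by parabolic interpolation in log separation."""
    lo, hi = search_range
    in_range = (sc.separation >= lo) & (sc.separation <= hi)
    out = []
    for i in _interior_local_maxima(sc.separation, sc.slope):
        if not in_range[i]:
            continue
        s_ref, _ = _refine_peak(sc, i)
        out.append(min(max(s_ref, lo), hi))
    return np.array(out)


def mean_loop_size(
    sc: SlopeCurve,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
) -> LoopSizeEstimate:
    """Separation of the highest interior local maximum of the smoothed
    slope inside the search range; ties break to the smaller separation.
    A monotone slope (no interior maximum) yields loop_size = None with a
    stated reason — undefined is a value, not an error."""
    lo, hi = search_range
    name = sc.chromosome
    in_range = (sc.separation >= lo) & (sc.separation <= hi)
    if (in_range & np.isfinite(sc.slope)).sum() < 3:
        return LoopSizeEstimate(name, None, None, search_range, "insufficient_points")
    maxima = [
        i
        for i in _interior_local_maxima(sc.separation, sc.slope)
        if in_range[i]
    ]
    if not maxima:
        return LoopSizeEstimate(name, None, None, search_range, "no_interior_maximum")
    heights = sc.slope[maxima]
    best_h = heights.max()
    # ties to smaller s: maxima are in increasing s order already
    best = next(i for i in maxima if sc.slope[i] == best_h)
    s_ref, h_ref = _refine_peak(sc, best)
    lo_, hi_ = search_range
    return LoopSizeEstimate(
        name, float(min(max(s_ref, lo_), hi_)), h_ref, search_range, "ok"
    )


WINDOW_SEARCH_RANGE = (20_000.0, 1_000_000.0)


def windowed_slope_curves(
    m: ContactMatrix,
    window_bp: int = 2_000_000,
    bins_per_decade: int = GRID_BINS_PER_DECADE,
    smoothing_halfwidth: int = 2,
) -> dict[str, SlopeCurve]:
    """Slope curves for non-overlapping diagonal windows of one chromosome.

    Each window's block of the raw matrix is re-balanced and analysed as a
    miniature chromosome, giving quasi-independent replicate observations of
    the local extrusion scale; keys are ``chrom:window_start_bin``. The
    returned curves carry the parent chromosome name, so class labels follow
    the chromosome. Windows shorter than ``window_bp`` (chromosome tail) are
    dropped.
    """
    w = window_bp // m.bin_size
    if w < 10:
        raise ValueError("window too small for a P(s) curve")
    out: dict[str, SlopeCurve] = {}
    grid = log_grid(m.bin_size, w * m.bin_size, bins_per_decade)
    for w0 in range(0, m.n_bins - w + 1, w):
        sub = ContactMatrix(
            chromosome=m.chromosome,
            bin_size=m.bin_size,
            counts=m.counts[w0 : w0 + w, w0 : w0 + w],
            bad_bins=m.bad_bins[w0 : w0 + w],
        )
        if sub.bad_bins.all():
            continue
        sub = ice_balance(sub)
        try:
            ps = contact_probability(sub, grid=grid)
            out[f"{m.chromosome}:{w0}"] = log_derivative(
                ps, smoothing_halfwidth=smoothing_halfwidth
            )
        except ValueError:
            continue
    return out


def collapse_autosomes(
    curves: dict[str, SlopeCurve], genome: GenomeModel
) -> tuple[SlopeCurve, SlopeCurve]:
    """Pixel-count-weighted mean slope per grid point for the autosome group
    (A) and the X group, on the union grid."""
    a_names = [c for c in genome.autosomes if c in curves]
    x_names = [c for c in genome.x_chromosomes if c in curves]
    if not a_names or not x_names:
        raise ValueError("need slope curves for both autosomes and X")

    def combine(names: list[str], label: str) -> SlopeCurve:
        seps = np.unique(np.concatenate([curves[n].separation for n in names]))
        num = np.zeros(len(seps))
        den = np.zeros(len(seps))
        npx = np.zeros(len(seps), dtype=int)
        for n in names:
            c = curves[n]
            pos = np.searchsorted(seps, c.separation)
            ok = np.isfinite(c.slope)
            w = c.n_pixels.astype(float)
            num[pos[ok]] += (c.slope * w)[ok]
            den[pos[ok]] += w[ok]
            npx[pos[ok]] += c.n_pixels[ok]
        with np.errstate(invalid="ignore"):
            slope = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        return SlopeCurve(
            chromosome=label, separation=seps, slope=slope, n_pixels=npx
        )

    return combine(a_names, "A"), combine(x_names, "X")
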