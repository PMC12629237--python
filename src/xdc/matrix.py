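"""Binned cis contact matrices: text I/O, bad-bin masking, ICE balancing,
and the distance-expected curve.

A :class:`ContactMatrix` is a dense symmetric per-chromosome matrix of raw
contact counts plus per-bin balancing weights and a bad-bin mask. Dense
storage is deliberate: at 5 kb resolution a 30 Mb nematode chromosome is
~6,000 bins, comfortably in memory.

Balancing follows matrix iterative correction (ICE): weights are updated so
that every good bin's balanced marginal (excluding the first ``ignore_diags``
diagonals) converges to a common value. Defaults mirror the standard cooler
invocation: ``max_iters=500``, ``mad_max=5``, ``ignore_diags=2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ContactMatrix:
    chromosome: str
    bin_size: int
    counts: np.ndarray  # (n, n) symmetric, nonnegative
    weights: np.ndarray | None = None  # (n,), NaN on bad bins
    bad_bins: np.ndarray | None = None  # (n,) bool
    balanced_flag: bool = False
    converged: bool | None = None
    achieved_cv: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = c
        if self.bad_bins is None:
            self.bad_bins = np.zeros(self.n_bins, dtype=bool)
        else:
            self.bad_bins = np.asarray(self.bad_bins, dtype=bool).copy()

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def good_bins(self) -> np.ndarray:
        return ~self.bad_bins

    def balanced(self) -> np.ndarray:
        """weights[i] * counts[i, j] * weights[j]; NaN on bad rows/columns."""
        if self.weights is None:
            raise ValueError("matrix is not balanced; call ice_balance first")
        w = self.weights
        return self.counts * w[:, None] * w[None, :]


def from_dense(
    chromosome: str, bin_size: int, dense: np.ndarray, **kw
) -> ContactMatrix:
    return ContactMatrix(chromosome=chromosome, bin_size=bin_size, counts=dense, **kw)


# ---------------------------------------------------------------------------
# text I/O (bin table + pixel triplets, cooler-style but plain TSV)
# ---------------------------------------------------------------------------

def write_contact_matrices(
    matrices: dict[str, ContactMatrix],
    bin_table_path: str | Path,
    pixels_path: str | Path,
) -> None:
    """Write a genome-wide bin table (chrom, start, end, bin_id; global ids)
    and an upper-triangle pixel TSV (bin1_id, bin2_id, count)."""
    bins = []
    pixels = []
    offset = 0
    for name, m in matrices.items():
        n = m.n_bins
        starts = np.arange(n) * m.bin_size
        bins.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "start": starts,
                    "end": starts + m.bin_size,
                    "bin_id": np.arange(n) + offset,
                }
            )
        )
        iu = np.triu_indices(n)
        vals = m.counts[iu]
        nz = vals != 0
        pixels.append(
            pd.DataFrame(
                {
                    "bin1_id": iu[0][nz] + offset,
                    "bin2_id": iu[1][nz] + offset,
                    "count": vals[nz].astype(np.int64),
                }
            )
        )
        offset += n
    pd.concat(bins).to_csv(bin_table_path, sep="\t", index=False)
    pd.concat(pixels).to_csv(pixels_path, sep="\t", index=False)


def read_contact_matrix(
    bin_table: str | Path, pixels: str | Path, chromosome: str
) -> ContactMatrix:
    """Load one chromosome's dense matrix from bin-table + pixel TSVs.

    Upper-triangle pixels are mirrored; missing pixels are zero; pixels whose
    two bins fall on different chromosomes (trans) are ignored with a logged
    count. Duplicate pixels and out-of-range bin ids are errors.
    """
    bins = pd.read_csv(bin_table, sep="\t")
    px = pd.read_csv(pixels, sep="\t")
    cbins = bins[bins["chrom"] == chromosome]
    if cbins.empty:
        raise ValueError(f"chromosome {chromosome!r} not in bin table")
    widths = (cbins["end"] - cbins["start"]).to_numpy()
    if len(widths) > 1 and not (widths[:-1] == widths[0]).all():
        raise ValueError("bin table must have constant width (except last bin)")
    bin_size = int(widths[0])
    ids = cbins["bin_id"].to_numpy()
    lo, hi = ids.min(), ids.max()
    n = len(ids)

    if px.empty:
        return ContactMatrix(
            chromosome=chromosome, bin_size=bin_size, counts=np.zeros((n, n))
        )
    if px["bin1_id"].max() > bins["bin_id"].max() or px["bin1_id"].min() < 0:
        raise ValueError("pixel bin_id out of range of bin table")
    if px["bin2_id"].max() > bins["bin_id"].max() or px["bin2_id"].min() < 0:
        raise ValueError("pixel bin_id out of range of bin table")
    if px.duplicated(subset=["bin1_id", "bin2_id"]).any():
        raise ValueError("duplicate pixel (bin1_id, bin2_id)")

    in1 = px["bin1_id"].between(lo, hi)
    in2 = px["bin2_id"].between(lo, hi)
    cis = px[in1 & in2]
    n_trans = int((in1 ^ in2).sum())
    if n_trans:
        logger.info("ignored %d trans pixels for %s", n_trans, chromosome)

    mat = np.zeros((n, n))
    i = cis["bin1_id"].to_numpy() - lo
    j = cis["bin2_id"].to_numpy() - lo
    mat[i, j] = cis["count"].to_numpy()
    # mirror the upper triangle; the diagonal must not be doubled
    mat = mat + mat.T - np.diag(np.diag(mat))
    return ContactMatrix(chromosome=chromosome, bin_size=bin_size, counts=mat)


# ---------------------------------------------------------------------------
# masking and balancing
# ---------------------------------------------------------------------------

def _marginals(counts: np.ndarray, ignore_diags: int) -> np.ndarray:
    """Row sums excluding the first ``ignore_diags`` diagonals (|i-j| <
    ignore_diags)."""
    n = counts.shape[0]
    marg = counts.sum(axis=1)
    if ignore_diags > 0:
        idx = np.arange(n)
        for d in range(ignore_diags):
            diag = np.diagonal(counts, offset=d)
            marg[idx[: n - d]] -= diag
            if d > 0:
                marg[idx[d:]] -= diag
    return marg


def mask_bad_bins(
    m: ContactMatrix, mad_max: float = 5.0, ignore_diags: int = 2
) -> ContactMatrix:
    """Flag low-coverage bins.

    A bin is bad when its marginal (excluding the first ``ignore_diags``
    diagonals) is zero, or when the log of its nonzero marginal lies strictly
    more than ``mad_max`` median-absolute-deviations below the median log
    marginal. Idempotent.
    """
    if mad_max <= 0:
        raise ValueError("mad_max must be > 0")
    marg = _marginals(m.counts, ignore_diags)
    bad = m.bad_bins.copy()
    bad |= marg <= 0
    nz = marg > 0
    if nz.any():
        logm = np.log(marg[nz])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        cutoff = med - mad_max * mad
        low = np.zeros_like(bad)
        low[nz] = np.log(marg[nz]) < cutoff
        bad |= low
    if bad.all():
        raise ValueError("matrix unusable: all bins bad")
    out = replace(m, bad_bins=bad)
    return out


def ice_balance(
    m: ContactMatrix,
    max_iters: int = 500,
    tol: float = 1e-5,
    ignore_diags: int = 2,
) -> ContactMatrix:
    """Iterative correction: divide weights by the square root of the current
    balanced marginals (scaled to their mean) until the coefficient of
    variation of good-bin marginals drops below ``tol``.

    On exit the weights are rescaled so that the mean balanced marginal over
    good bins equals 1. Non-convergence is a warning, never a silent success;
    the achieved CV is stored on the result.
    """
    n = m.n_bins
    bad = m.bad_bins
    good = ~bad
    if not good.any():
        raise ValueError("matrix unusable: all bins bad")
    counts = m.counts.copy()
    counts[bad, :] = 0.0
    counts[:, bad] = 0.0

    w = np.ones(n)
    cv = np.inf
    converged = False
    for _ in range(max_iters):
        bal = counts * w[:, None] * w[None, :]
        marg = _marginals(bal, ignore_diags)
        mg = marg[good]
        mean = mg.mean()
        if mean == 0:
            raise ValueError("matrix unusable: zero total after masking")
        cv = mg.std() / mean
        if cv < tol:
            converged = True
            break
        scale = np.ones(n)
        scale[good] = np.sqrt(marg[good] / mean)
        # guard bins whose marginal hit zero without being masked
        scale[scale == 0] = 1.0
        w = w / scale
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iters} iterations (CV={cv:.3g})",
            RuntimeWarning,
        )
    # fix the overall scale: mean balanced marginal on good bins == 1
    bal = counts * w[:, None] * w[None, :]
    mean = _marginals(bal, ignore_diags)[good].mean()
    if mean > 0:
        w = w / np.sqrt(mean)
    weights = np.where(good, w, np.nan)
    return replace(
        m,
        weights=weights,
        balanced_flag=True,
        converged=converged,
        achieved_cv=float(cv),
    )


# ---------------------------------------------------------------------------
# distance-expected curve
# ---------------------------------------------------------------------------

@dataclass
class ExpectedCurve:
    chromosome: str
    separation: np.ndarray  # bp, diagonal index * bin_size
    expected: np.ndarray  # NaN where no valid pixel
    n_valid: np.ndarray  # valid pixels per diagonal


def expected_by_distance(m: ContactMatrix) -> ExpectedCurve:
    """Per-diagonal mean balanced contact over pixels whose two bins are both
    good. Diagonals with zero valid pixels are NaN gaps, not zeros."""
    bal = m.balanced()
    n = m.n_bins
    good = m.good_bins
    expected = np.full(n, np.nan)
    n_valid = np.zeros(n, dtype=int)
    for d in range(n):
        vals = np.diagonal(bal, offset=d)
        ok = good[: n - d] & good[d:]
        if ok.any():
            expected[d] = vals[ok].mean()
            n_valid[d] = int(ok.sum())
    return ExpectedCurve(
        chromosome=m.chromosome,
        separation=np.arange(n) * m.bin_size,
        expected=expected,
        n_valid=n_valid,
    )


def observed_over_expected(m: ContactMatrix) -> np.ndarray:
    """Balanced matrix divided by its distance-expected value; NaN on bad
    rows/columns and on gap diagonals."""
    exp = expected_by_distance(m)
    n = m.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = exp.expected[d]
    with np.errstate(invalid="ignore", divide="ignore"):
        return m.balanced() / denom
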