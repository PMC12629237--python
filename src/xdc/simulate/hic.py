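"""Synthetic binned cis Hi-C contact matrices.

The expected contact at separation s follows a power law s^(-decay_exponent),
optionally multiplied by a loop-extrusion factor shaped so that the
log-derivative of P(s) gains a single clean Gaussian local maximum of height
``loop_amplitude`` exactly at log10(loop_size) (width 0.25 decades): the
multiplier is the antiderivative form 10^(A * sigma * sqrt(2 pi) * Phi(z)),
z = (log10 s - log10 L) / sigma. Downstream, the separation of that slope
maximum is read as the mean extruded-loop size, so planted sizes are
recoverable by construction. The surface is further modulated by
planted-domain factors that reproduce the three visual criteria of a
loop-anchored domain: elevated within-domain contacts (an insulation dip at
each boundary), a corner dot where the two boundaries meet, and a stripe
along the first row/column inside the domain.

Counts are Poisson samples of the expected matrix scaled to ``total_reads``
per chromosome; a random fraction of bins is then emptied (rows and columns
zeroed) to emulate unmappable regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from ..genome import GenomeModel
from ..matrix import ContactMatrix

LOOP_BUMP_WIDTH_DECADES = 0.25


@dataclass(frozen=True)
class TadSpec:
    """One planted domain boundary pair: bins [start_bin, end_bin)."""

    start_bin: int
    end_bin: int
    boundary_strength: float = 1.0  # within-domain contact multiplier - 1
    dot_strength: float = 0.0  # corner-dot multiplier - 1
    stripe_strength: float = 0.0  # first row/column multiplier - 1

    def __post_init__(self) -> None:
        if self.end_bin <= self.start_bin:
            raise ValueError("TAD end_bin must exceed start_bin")
        for v in (self.boundary_strength, self.dot_strength, self.stripe_strength):
            if v < 0:
                raise ValueError("TAD strengths must be >= 0")


@dataclass(frozen=True)
class HiCSimParams:
    """Per-chromosome-class Hi-C simulation parameters.

    ``loop_size`` maps chromosome class ("autosome"/"X") or chromosome name to
    the mean extruded-loop size in bp; absent key = no extruder on that
    chromosome. ``tads`` maps chromosome name to planted domains.
    """

    decay_exponent: float = 1.0
    loop_size: dict[str, float] = field(default_factory=dict)
    loop_amplitude: float = 0.0
    tads: dict[str, tuple[TadSpec, ...]] = field(default_factory=dict)
    total_reads: int = 1_000_000
    empty_bin_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not 0 <= self.empty_bin_fraction < 0.5:
            raise ValueError("empty_bin_fraction must be in [0, 0.5)")
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        if self.loop_amplitude < 0:
            raise ValueError("loop_amplitude must be >= 0")
        if self.total_reads == 0 and (
            (self.loop_amplitude > 0 and self.loop_size) or self.tads
        ):
            raise ValueError(
                "total_reads = 0 cannot carry loop or domain structure"
            )


def _loop_size_for(params: HiCSimParams, genome: GenomeModel, name: str) -> float | None:
    if name in params.loop_size:
        return params.loop_size[name]
    cls = genome.chrom_class(name)
    return params.loop_size.get(cls)


def expected_contact_matrix(
    genome: GenomeModel, params: HiCSimParams, chromosome: str
) -> np.ndarray:
    """Noise-free expected matrix (arbitrary scale) for one chromosome."""
    bs = genome.bin_size
    n = genome.n_bins(chromosome)
    idx = np.arange(n)
    sep_bins = np.abs(np.subtract.outer(idx, idx))
    # diagonal treated as one-bin separation so the power law stays finite
    s = np.maximum(sep_bins, 1).astype(float) * bs

    expected = s ** (-params.decay_exponent)

    loop = _loop_size_for(params, genome, chromosome)
    if loop is not None and params.loop_amplitude > 0:
        if loop < 2 * bs:
            raise ValueError(
                f"loop_size {loop} must be >= 2 bins ({2 * bs} bp)"
            )
        sigma = LOOP_BUMP_WIDTH_DECADES
        z = (np.log10(s) - np.log10(loop)) / sigma
        log10_bump = params.loop_amplitude * sigma * np.sqrt(2 * np.pi) * ndtr(z)
        expected = expected * 10.0**log10_bump

    for tad in params.tads.get(chromosome, ()):
        a, b = tad.start_bin, tad.end_bin
        if not (0 <= a < b <= n):
            raise ValueError(f"TAD [{a}, {b}) outside chromosome ({n} bins)")
        inside = slice(a, b)
        expected[inside, inside] *= 1.0 + tad.boundary_strength
        if tad.stripe_strength > 0:
            expected[a, inside] *= 1.0 + tad.stripe_strength
            expected[inside, a] *= 1.0 + tad.stripe_strength
            # keep symmetry exact: the (a, a) pixel got the factor twice on
            # purpose (it sits on both the row and the column stripe)
        if tad.dot_strength > 0:
            expected[a, b - 1] *= 1.0 + tad.dot_strength
            expected[b - 1, a] *= 1.0 + tad.dot_strength
    return expected


def simulate_contact_matrix(
    genome: GenomeModel, params: HiCSimParams
) -> dict[str, ContactMatrix]:
    """Poisson-sampled contact matrices, one per chromosome.

    Expected counts are the power-law/loop/domain surface scaled so the full
    matrix sums to ``total_reads`` per chromosome; sampling is on the upper
    triangle and mirrored, so matrices are exactly symmetric. A fraction of
    bins is emptied afterwards and flagged bad.
    """
    rng = np.random.default_rng(params.seed)
    out: dict[str, ContactMatrix] = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom)
        if params.total_reads == 0:
            counts = np.zeros((n, n))
            bad = np.ones(n, dtype=bool)
            out[chrom] = ContactMatrix(chrom, genome.bin_size, counts, bad_bins=bad)
            continue
        expected = expected_contact_matrix(genome, params, chrom)
        expected = expected * (params.total_reads / expected.sum())
        iu = np.triu_indices(n)
        lam = expected[iu]
        sampled = rng.poisson(lam).astype(float)
        counts = np.zeros((n, n))
        counts[iu] = sampled
        counts = counts + counts.T - np.diag(np.diag(counts))

        bad = np.zeros(n, dtype=bool)
        n_empty = int(np.floor(params.empty_bin_fraction * n))
        if n_empty:
            empty = rng.choice(n, size=n_empty, replace=False)
            counts[empty, :] = 0.0
            counts[:, empty] = 0.0
            bad[empty] = True
        out[chrom] = ContactMatrix(chrom, genome.bin_size, counts, bad_bins=bad)
    return out
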