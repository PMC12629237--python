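"""Simulation-based calibration and power checks for the loop-size
permutation test.

Each replicate simulates per-chromosome contact matrices, balances them,
computes P(s) slopes and runs the permutation test; the suite reports the
rejection rate at the chosen alpha with a Clopper–Pearson binomial interval.
Under the null every chromosome shares the same extrusion parameters; under
the alternative the X loop size is smaller than the autosomal one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import pandas as pd
from scipy.stats import beta

from .decay import (
    WINDOW_SEARCH_RANGE,
    contact_probability,
    log_derivative,
    windowed_slope_curves,
)
from .genome import GenomeModel, make_genome
from .matrix import ice_balance, mask_bad_bins
from .permutation import maxima_observations, permutation_test, slope_observations
from .simulate.hic import HiCSimParams, simulate_contact_matrix


def small_hic_genome(
    n_autosomes: int = 5, chrom_mb: float = 6.0, bin_size: int = 10_000
) -> GenomeModel:
    """Desk-scale nematode-like karyotype (5 autosomes + X) for replicated
    simulation studies."""
    length = int(chrom_mb * 1e6)
    spec = [(f"chr{i+1}", length, "autosome") for i in range(n_autosomes)]
    spec.append(("chrX", length, "X"))
    return make_genome(spec, bin_size=bin_size)


def run_loop_test_once(
    genome: GenomeModel,
    params: HiCSimParams,
    n_permutations: int = 200,
    search_range: tuple[float, float] = WINDOW_SEARCH_RANGE,
    permute_unit: str = "maxima",
    window_bp: int = 2_000_000,
):
    """Simulate -> mask -> balance -> windowed P(s) slopes -> permutation
    test. Observations are slope local maxima per 2-Mb window by default;
    the "curve" unit falls back to whole-chromosome grid-bin slope values."""
    mats = simulate_contact_matrix(genome, params)
    curves = {}
    whole = {}
    for chrom, m in mats.items():
        m = mask_bad_bins(m)
        if permute_unit == "curve":
            mb = ice_balance(m)
            whole[chrom] = log_derivative(contact_probability(mb))
        else:
            curves.update(windowed_slope_curves(m, window_bp=window_bp))
    if permute_unit == "curve":
        obs = slope_observations(whole, genome)
    else:
        obs = maxima_observations(curves, genome, search_range)
    return permutation_test(
        obs,
        n=n_permutations,
        seed=params.seed + 77,
        search_range=search_range,
        permute_unit="maxima" if permute_unit == "maxima" else permute_unit,
    )


@dataclass
class RejectionRate:
    condition: str
    n_replicates: int
    n_rejections: int
    rate: float
    ci_low: float
    ci_high: float
    alpha: float


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson interval."""
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else beta.ppf(a, k, n - k + 1)
    hi = 1.0 if k == n else beta.ppf(1 - a, k + 1, n - k)
    return float(lo), float(hi)


def rejection_rate(
    genome: GenomeModel,
    params: HiCSimParams,
    condition: str,
    n_replicates: int,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
) -> RejectionRate:
    k = 0
    for r in range(n_replicates):
        p = dc_replace(params, seed=seed + 1000 * r)
        res = run_loop_test_once(genome, p, n_permutations=n_permutations)
        if res.p_two_sided < alpha:
            k += 1
    lo, hi = _binom_ci(k, n_replicates)
    return RejectionRate(
        condition=condition,
        n_replicates=n_replicates,
        n_rejections=k,
        rate=k / n_replicates,
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
    )


def null_params(
    loop_size: float = 300_000.0,
    loop_amplitude: float = 0.6,
    total_reads: int = 400_000,
    seed: int = 0,
) -> HiCSimParams:
    """Both classes share one extruder scale: exchangeable null."""
    return HiCSimParams(
        decay_exponent=1.0,
        loop_size={"autosome": loop_size, "X": loop_size},
        loop_amplitude=loop_amplitude,
        total_reads=total_reads,
        seed=seed,
    )


def alternative_params(
    autosome_loop: float = 400_000.0,
    x_loop: float = 200_000.0,
    loop_amplitude: float = 0.8,
    total_reads: int = 400_000,
    seed: int = 0,
) -> HiCSimParams:
    """X-specific extruder: smaller loops on X (default 2x ratio)."""
    return HiCSimParams(
        decay_exponent=1.0,
        loop_size={"autosome": autosome_loop, "X": x_loop},
        loop_amplitude=loop_amplitude,
        total_reads=total_reads,
        seed=seed,
    )


def type1_power_suite(
    n_replicates: int = 50,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    genome: GenomeModel | None = None,
) -> pd.DataFrame:
    """Rejection rates under the exchangeable null and the X-extruder
    alternative, with binomial confidence intervals."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    genome = genome or small_hic_genome()
    rows = []
    for condition, params in (
        ("null", null_params(seed=seed)),
        ("alternative", alternative_params(seed=seed + 555_000)),
    ):
        rr = rejection_rate(
            genome,
            params,
            condition,
            n_replicates,
            alpha=alpha,
            n_permutations=n_permutations,
            seed=params.seed,
        )
        rows.append(rr.__dict__)
    return pd.DataFrame(rows)
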