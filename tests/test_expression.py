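"""TPM, expressed/soma filters, fold-change normalisation, one-vs-rest
rank-sum tests and the dosage-compensation verdict."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xdc.expression import (
    ChromTestResult,
    compute_tpm,
    dc_verdict,
    filter_expressed,
    normalize_and_log2fc,
    one_vs_rest_test,
    size_factors_median_of_ratios,
    soma_filter,
)
from xdc.genome import make_genome
from xdc.simulate.expression import (
    ExpressionSimParams,
    ExpressionTable,
    simulate_expression,
)


def _table(counts, lengths=None, chroms=None, n_rep=2):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    assert n_samples == 2 * n_rep
    samples = []
    cols = {}
    for i in range(n_rep):
        cols[f"herm_rep{i+1}"] = counts[:, i]
        samples.append((f"herm_rep{i+1}", "herm_or_female", i + 1))
    for i in range(n_rep):
        cols[f"male_rep{i+1}"] = counts[:, n_rep + i]
        samples.append((f"male_rep{i+1}", "male", i + 1))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": chroms or ["I"] * n_genes,
            "length": lengths or [1000] * n_genes,
        }
    )
    return ExpressionTable(
        genes=genes,
        counts=pd.DataFrame(cols),
        samples=pd.DataFrame(samples, columns=["sample", "sex", "replicate"]),
    )


# -------------------------------------------------------------------- TPM ---

def test_single_gene_tpm_is_one_million():
    t = _table([[10, 20, 5, 8]])
    tpm = compute_tpm(t)
    assert np.allclose(tpm, 1e6)


def test_three_gene_tpm_hand_arithmetic():
    # counts 10/20/30, lengths 1/2/3 kb -> equal rates -> each TPM 1e6/3
    t = _table(
        [[10] * 4, [20] * 4, [30] * 4],
        lengths=[1000, 2000, 3000],
    )
    tpm = compute_tpm(t)
    assert np.allclose(tpm, 1e6 / 3)


def test_tpm_scale_invariance():
    t1 = _table([[10, 3, 5, 8], [30, 9, 15, 24]])
    t2 = _table([[20, 3, 5, 8], [60, 9, 15, 24]])
    assert np.allclose(compute_tpm(t1), compute_tpm(t2))


def test_zero_total_sample_rejected():
    t = _table([[0, 5, 5, 5]])
    with pytest.raises(ValueError, match="zero-total"):
        compute_tpm(t)


# ---------------------------------------------------------------- filters ---

def test_expressed_requires_both_sexes_above_threshold():
    # one highly expressed reference gene keeps totals sane; the second
    # gene is above 1 TPM in hermaphrodites only
    counts = np.array([[100_000, 100_000, 100_000, 100_000],
                       [200, 220, 40, 38]])
    t = _table(counts, lengths=[1000, 1000])
    tpm = compute_tpm(t)
    herm_mean = tpm.iloc[1, :2].mean()
    male_mean = tpm.iloc[1, 2:].mean()
    assert herm_mean > 1 and male_mean > 1  # sanity: TPM scale here is large
    flags = filter_expressed(t, tpm, threshold=herm_mean + 1)
    assert not flags[1]
    # an all-zero gene is never expressed
    counts = np.array([[100, 100, 100, 100], [0, 0, 0, 0]])
    t = _table(counts)
    assert not filter_expressed(t, compute_tpm(t))[1]


def test_threshold_zero_keeps_any_double_positive_gene():
    counts = np.array([[5, 0, 3, 1], [1, 1, 1, 1]])
    t = _table(counts)
    flags = filter_expressed(t, compute_tpm(t), threshold=0)
    assert flags[0] and flags[1]


def test_soma_filter_cutoff_behavior():
    tab = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "chrom": ["I"] * 3,
            "log2fc": [3.2, 0.0, -2.9],
            "expressed": [True, True, True],
            "soma": [False] * 3,
        }
    )
    from xdc.expression import SexBiasResult

    r = SexBiasResult(table=tab, size_factors=pd.Series(dtype=float), pseudocount=0.5)
    r = soma_filter(r, cutoff=3.0)
    assert list(r.table["soma"]) == [False, True, True]
    # monotone in the cutoff and idempotent
    r2 = soma_filter(r, cutoff=2.0)
    assert list(r2.table["soma"]) == [False, True, False]
    r3 = soma_filter(r2, cutoff=2.0)
    assert list(r3.table["soma"]) == [False, True, False]


# ----------------------------------------------------------- normalisation ---

def test_size_factors_match_hand_oracle():
    counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
    sf = size_factors_median_of_ratios(counts)
    # geometric means: sqrt(200), sqrt(800), sqrt(1800); ratios per sample
    # are constant 1/sqrt2 and sqrt2
    assert np.allclose(sf.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)])


def test_identical_counts_give_zero_log2fc():
    counts = np.tile(np.array([[50], [500], [5000]]), (1, 4))
    t = _table(counts)
    expressed = filter_expressed(t, compute_tpm(t))
    r = normalize_and_log2fc(t, expressed)
    assert np.allclose(r.table["log2fc"].dropna(), 0.0)


def test_sex_label_swap_negates_log2fc(four_chrom_genome):
    t = simulate_expression(
        four_chrom_genome,
        ExpressionSimParams(genes_per_chromosome=200, seed=7, x_imbalance_log2=0.5),
    )
    expressed = filter_expressed(t, compute_tpm(t))
    r = normalize_and_log2fc(t, expressed, genome=four_chrom_genome)

    swapped_samples = t.samples.copy()
    swapped_samples["sex"] = swapped_samples["sex"].map(
        {"herm_or_female": "male", "male": "herm_or_female"}
    )
    t2 = ExpressionTable(genes=t.genes, counts=t.counts, samples=swapped_samples)
    r2 = normalize_and_log2fc(t2, expressed, genome=four_chrom_genome)
    a = r.table["log2fc"].to_numpy()
    b = r2.table["log2fc"].to_numpy()
    ok = np.isfinite(a)
    assert np.allclose(a[ok], -b[ok])


def test_planted_x_shift_recovered(four_chrom_genome):
    t = simulate_expression(
        four_chrom_genome,
        ExpressionSimParams(genes_per_chromosome=700, seed=21, x_imbalance_log2=1.0),
    )
    expressed = filter_expressed(t, compute_tpm(t))
    r = soma_filter(normalize_and_log2fc(t, expressed, genome=four_chrom_genome))
    x_mean = r.table.loc[(r.table["chrom"] == "X") & r.table["soma"], "log2fc"].mean()
    assert abs(x_mean - 1.0) < 0.1


# ------------------------------------------------------------- rank tests ---

def _ranksum_enumeration_oracle(x, y, alternative="two-sided"):
    """Exact rank-sum p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_stat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    observed = u_stat(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(combo)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.array(us)
    if alternative == "two-sided":
        mu = len(x) * len(y) / 2
        return np.mean(np.abs(us - mu) >= abs(observed - mu) - 1e-12)
    if alternative == "greater":
        return np.mean(us >= observed - 1e-12)
    return np.mean(us <= observed + 1e-12)


def test_tiny_rank_sum_matches_enumeration():
    x = np.array([1.2, 3.4, 2.2])
    y = np.array([0.1, 0.5, 2.8, 0.9])
    from scipy.stats import mannwhitneyu

    for alt in ("two-sided", "greater", "less"):
        p_oracle = _ranksum_enumeration_oracle(x, y, alt)
        p = mannwhitneyu(x, y, alternative=alt, method="exact").pvalue
        assert np.isclose(p, p_oracle)


def test_one_vs_rest_planted_shift(four_chrom_genome):
    t = simulate_expression(
        four_chrom_genome,
        ExpressionSimParams(genes_per_chromosome=500, seed=2, x_imbalance_log2=1.0),
    )
    expressed = filter_expressed(t, compute_tpm(t))
    r = soma_filter(normalize_and_log2fc(t, expressed, genome=four_chrom_genome))
    results = one_vs_rest_test(r, four_chrom_genome, gene_set="soma")
    by = {c.chromosome: c for c in results}
    assert by["X"].p_two_sided < 0.01
    assert abs(by["X"].mean_log2fc - 1.0) < 0.15


# ----------------------------------------------------------------- verdict ---

def _mk_results(devs, ps, names=None):
    names = names or ["I", "II", "III", "X"]
    out = []
    for name, d, p in zip(names, devs, ps):
        out.append(
            ChromTestResult(
                chromosome=name,
                n_genes=500,
                mean_log2fc=d,
                deviation=d,
                p_two_sided=p,
                neg_log10_p=-np.log10(p),
            )
        )
    return out


def test_verdict_rules(four_chrom_genome):
    g = four_chrom_genome
    # X clustered with autosomes -> compensated
    v = dc_verdict(_mk_results([0.02, -0.03, 0.01, 0.02], [0.4, 0.2, 0.6, 0.5]), g)
    assert v.verdict == "compensated"
    # X strongly shifted and alone significant -> not compensated
    v = dc_verdict(_mk_results([0.02, -0.03, 0.01, 0.9], [0.4, 0.2, 0.6, 1e-30]), g)
    assert v.verdict == "not_compensated"
    # X significant but its deviation within the autosome range -> mixed
    v = dc_verdict(_mk_results([0.5, -0.03, 0.01, 0.3], [1e-5, 0.2, 0.6, 1e-6]), g)
    assert v.verdict in ("compensated", "inconclusive")
    # missing chromosome is an error
    with pytest.raises(ValueError, match="missing"):
        dc_verdict(_mk_results([0, 0, 0], [1, 1, 1], ["I", "II", "III"]), g)


def test_verdict_invariant_under_autosome_relabeling(four_chrom_genome):
    res = _mk_results([0.1, -0.2, 0.05, 0.4], [0.3, 0.01, 0.8, 0.001])
    v1 = dc_verdict(res, four_chrom_genome)
    relabeled = make_genome(
        [
            ("III", 3_000_000, "autosome"),
            ("I", 3_000_000, "autosome"),
            ("II", 3_000_000, "autosome"),
            ("X", 3_000_000, "X"),
        ],
        bin_size=10_000,
    )
    v2 = dc_verdict(res, relabeled)
    assert v1.verdict == v2.verdict


def test_null_simulation_verdict_compensated(four_chrom_genome):
    t = simulate_expression(
        four_chrom_genome, ExpressionSimParams(genes_per_chromosome=600, seed=31)
    )
    expressed = filter_expressed(t, compute_tpm(t))
    r = soma_filter(normalize_and_log2fc(t, expressed, genome=four_chrom_genome))
    v = dc_verdict(one_vs_rest_test(r, four_chrom_genome, gene_set="soma"),
                   four_chrom_genome)
    assert v.verdict == "compensated"


def test_uncompensated_simulation_verdict(four_chrom_genome):
    t = simulate_expression(
        four_chrom_genome,
        ExpressionSimParams(genes_per_chromosome=600, seed=32, x_imbalance_log2=1.0),
    )
    expressed = filter_expressed(t, compute_tpm(t))
    r = soma_filter(normalize_and_log2fc(t, expressed, genome=four_chrom_genome))
    v = dc_verdict(one_vs_rest_test(r, four_chrom_genome, gene_set="soma"),
                   four_chrom_genome)
    assert v.verdict == "not_compensated"


def test_partial_x_shift_not_called_compensated(four_chrom_genome):
    """A fusion-like X where only part of the chromosome is shifted should
    never be reported as cleanly compensated."""
    t = simulate_expression(
        four_chrom_genome,
        ExpressionSimParams(genes_per_chromosome=600, seed=33, x_imbalance_log2=0.0),
    )
    # shift half the X genes by +1 in hermaphrodites directly in the counts
    x_genes = np.flatnonzero((t.genes["chrom"] == "X").to_numpy())
    shifted = x_genes[: len(x_genes) // 2]
    herm_cols = [c for c in t.counts if c.startswith("herm")]
    t.counts.loc[shifted, herm_cols] = (
        t.counts.loc[shifted, herm_cols] * 2
    ).astype(int)
    expressed = filter_expressed(t, compute_tpm(t))
    r = soma_filter(normalize_and_log2fc(t, expressed, genome=four_chrom_genome))
    v = dc_verdict(one_vs_rest_test(r, four_chrom_genome, gene_set="soma"),
                   four_chrom_genome)
    assert v.verdict in ("not_compensated", "inconclusive")


def test_segment_means_report_partial_shift(four_chrom_genome):
    """Per-segment means expose which part of a chromosome carries a sex
    bias, even when the chromosome-level mean dilutes it."""
    from xdc.expression import SexBiasResult, segment_means

    tab = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(40)],
            "chrom": ["X"] * 40,
            "start": np.arange(40) * 10_000,
            "log2fc": [1.0] * 20 + [0.0] * 20,
            "expressed": [True] * 40,
            "soma": [True] * 40,
        }
    )
    r = SexBiasResult(table=tab, size_factors=pd.Series(dtype=float),
                      pseudocount=0.5)
    segments = pd.DataFrame(
        [("X", 0, 200_000, "left"), ("X", 200_000, 400_000, "right")],
        columns=["chrom", "start", "end", "name"],
    )
    out = segment_means(r, segments).set_index("segment")
    assert np.isclose(out.loc["left", "mean_log2fc"], 1.0)
    assert np.isclose(out.loc["right", "mean_log2fc"], 0.0)
    assert (out["n_genes"] == 20).all()
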