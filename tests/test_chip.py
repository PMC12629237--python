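"""Region builders, log2(ChIP/input) enrichment, z-scoring and one-sided
one-vs-rest tests."""

import numpy as np
import pandas as pd
import pytest

from xdc.chip import (
    build_regions,
    enrichment_analysis,
    one_vs_rest_enrichment_test,
    region_enrichment,
    zscore,
)
from xdc.genome import make_genome
from xdc.simulate.chip import ChipSimParams, EnrichmentTrack, simulate_chip_tracks
from xdc.simulate.expression import ExpressionSimParams, place_genes, simulate_expression


def _tiny_genome():
    return make_genome(
        [("a", 10_000, "autosome"), ("x", 10_000, "X")], bin_size=1000
    )


def _genes(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                       "strand"])


# ----------------------------------------------------------------- regions ---

def test_tss_window_truncated_at_chromosome_start():
    g = _tiny_genome()
    genes = _genes([("a", 100, 2000, "g1", 0, "+")])
    tss = build_regions(genes, g, "tss").intervals
    assert tss.iloc[0]["start"] == 0
    assert tss.iloc[0]["end"] == 350  # 100 - 250 clipped, 100 + 250


def test_tss_strand_aware():
    g = _tiny_genome()
    genes = _genes([("a", 1000, 3000, "g1", 0, "-")])
    tss = build_regions(genes, g, "tss").intervals
    # first transcribed base of a minus-strand gene is end - 1 = 2999
    assert tss.iloc[0]["start"] == 2999 - 250
    assert tss.iloc[0]["end"] == 2999 + 250


def test_gene_body_equals_annotation():
    g = _tiny_genome()
    genes = _genes([("a", 1200, 4200, "g1", 0, "+")])
    gb = build_regions(genes, g, "gene_body").intervals
    assert (gb.iloc[0]["start"], gb.iloc[0]["end"]) == (1200, 4200)


def test_intergenic_complement_hand_case():
    g = _tiny_genome()
    genes = _genes([
        ("a", 2000, 3000, "g1", 0, "+"),
        ("a", 5000, 6000, "g2", 0, "+"),
    ])
    inter = build_regions(genes, g, "intergenic").intervals
    a = inter[inter["chrom"] == "a"][["start", "end"]].to_numpy()
    assert a.tolist() == [[0, 2000], [3000, 5000], [6000, 10000]]
    # chromosome without genes is one whole intergenic block
    x = inter[inter["chrom"] == "x"][["start", "end"]].to_numpy()
    assert x.tolist() == [[0, 10_000]]


def test_intergenic_complement_matches_base_level_oracle(rng):
    g = _tiny_genome()
    rows = []
    for chrom in ("a", "x"):
        for i in range(4):
            start = int(rng.integers(0, 9000))
            end = int(start + rng.integers(100, 1000))
            rows.append((chrom, start, min(end, 10_000), f"{chrom}{i}", 0, "+"))
    genes = _genes(rows)
    inter = build_regions(genes, g, "intergenic").intervals
    for chrom in ("a", "x"):
        covered = np.zeros(10_000, bool)
        for _, r in genes[genes["chrom"] == chrom].iterrows():
            covered[r["start"]:r["end"]] = True
        from_regions = np.zeros(10_000, bool)
        for _, r in inter[inter["chrom"] == chrom].iterrows():
            from_regions[r["start"]:r["end"]] = True
        assert np.array_equal(from_regions, ~covered)


def test_bin10kb_tiles_chromosomes():
    g = make_genome([("a", 25_000, "autosome"), ("x", 10_000, "X")], 1000)
    bins = build_regions(_genes([]), g, "bin10kb").intervals
    a = bins[bins["chrom"] == "a"][["start", "end"]].to_numpy().tolist()
    assert a == [[0, 10_000], [10_000, 20_000], [20_000, 25_000]]


def test_out_of_bounds_gene_rejected():
    g = _tiny_genome()
    with pytest.raises(ValueError, match="outside"):
        build_regions(_genes([("a", 9000, 12_000, "g", 0, "+")]), g, "gene_body")


# -------------------------------------------------------------- enrichment ---

def _flat_tracks(g, chip_mult=None, value=10.0, step=10):
    chip_vals, in_vals = {}, {}
    for c in g.chromosomes:
        n = -(-c.length // step)
        in_vals[c.name] = np.full(n, value)
        m = chip_mult(c.name) if chip_mult else 1.0
        chip_vals[c.name] = np.full(n, value * m)
    return (EnrichmentTrack("chip", step, chip_vals),
            EnrichmentTrack("input", step, in_vals))


def test_equal_tracks_give_zero_enrichment():
    g = _tiny_genome()
    chip, inp = _flat_tracks(g)
    regions = build_regions(_genes([("a", 2000, 3000, "g1", 0, "+")]),
                            g, "gene_body")
    df = region_enrichment(chip, inp, regions)
    assert np.allclose(df["log2_ratio"], 0.0)
    assert np.allclose(df["chip_minus_input"], 0.0)


def test_doubled_chip_on_x_is_plus_one():
    g = _tiny_genome()
    chip, inp = _flat_tracks(g, chip_mult=lambda c: 2.0 if c == "x" else 1.0)
    genes = _genes([("a", 1000, 2000, "g1", 0, "+"),
                    ("x", 1000, 2000, "g2", 0, "+")])
    regions = build_regions(genes, g, "gene_body")
    df = region_enrichment(chip, inp, regions, pseudocount=0.0)
    by = df.set_index("id")["log2_ratio"]
    assert np.isclose(by["g2"], 1.0)
    assert np.isclose(by["g1"], 0.0)


def test_region_means_match_direct_averaging(rng):
    g = _tiny_genome()
    step = 10
    vals = {c.name: rng.random(-(-c.length // step)) * 5 for c in g.chromosomes}
    track = EnrichmentTrack("chip", step, vals)
    regions = build_regions(
        _genes([("a", 123, 1571, "g1", 0, "+"),
                ("a", 2000, 2010, "g2", 0, "+"),
                ("x", 55, 9999, "g3", 0, "+")]),
        g, "gene_body")
    from xdc.chip import _region_means

    means = _region_means(track, regions.intervals)
    for k, (_, r) in enumerate(regions.intervals.iterrows()):
        base = np.repeat(vals[r["chrom"]], step)[: g.length(r["chrom"])]
        assert np.isclose(means[k], base[r["start"]:r["end"]].mean())


def test_scaling_both_tracks_with_pseudocount_is_invariant():
    g = _tiny_genome()
    chip, inp = _flat_tracks(g, chip_mult=lambda c: 1.7)
    regions = build_regions(_genes([("a", 1000, 2000, "g", 0, "+")]), g,
                            "gene_body")
    base = region_enrichment(chip, inp, regions, pseudocount=1.0)
    chip2 = EnrichmentTrack("chip", chip.step,
                            {k: v * 3 for k, v in chip.values.items()})
    inp2 = EnrichmentTrack("input", inp.step,
                           {k: v * 3 for k, v in inp.values.items()})
    scaled = region_enrichment(chip2, inp2, regions, pseudocount=3.0)
    assert np.allclose(base["log2_ratio"], scaled["log2_ratio"])


def test_zero_width_region_rejected():
    g = _tiny_genome()
    chip, inp = _flat_tracks(g)
    regions = build_regions(_genes([("a", 100, 200, "g", 0, "+")]), g, "gene_body")
    regions.intervals.loc[0, "end"] = 100
    with pytest.raises(ValueError, match="zero-width"):
        region_enrichment(chip, inp, regions)


# ----------------------------------------------------------------- z-score ---

def test_zscore_standardises():
    z = zscore(np.array([1.0, 2.0, 3.0]))
    assert np.allclose(z, [-np.sqrt(1.5), 0, np.sqrt(1.5)])
    assert np.isclose(z.mean(), 0) and np.isclose(z.std(), 1)


def test_zscore_sample_sd_option():
    z = zscore(np.array([1.0, 2.0, 3.0]), ddof=1)
    assert np.allclose(z, [-1.0, 0.0, 1.0])


def test_constant_values_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        zscore(np.array([2.0, 2.0, 2.0]))


def test_rank_tests_invariant_under_zscoring(rng):
    g = _tiny_genome()
    vals = rng.normal(0, 1, 40)
    chroms = np.array(["a"] * 20 + ["x"] * 20)
    df = pd.DataFrame({"chrom": chroms, "zscore": vals})
    raw = one_vs_rest_enrichment_test(df, g, side="greater")
    df2 = pd.DataFrame({"chrom": chroms, "zscore": zscore(vals)})
    z = one_vs_rest_enrichment_test(df2, g, side="greater")
    assert np.allclose(raw["p_one_sided"], z["p_one_sided"])


# --------------------------------------------------------------- one-vs-rest ---

def _simulated_analysis(four_chrom_genome, x_effect, seed=0, side="greater"):
    t = simulate_expression(
        four_chrom_genome, ExpressionSimParams(genes_per_chromosome=200, seed=seed)
    )
    genes = place_genes(four_chrom_genome, t, np.random.default_rng(seed))
    chip, inp = simulate_chip_tracks(
        four_chrom_genome, genes, ChipSimParams(x_log2_effect=x_effect, seed=seed)
    )
    return enrichment_analysis(chip, inp, genes, four_chrom_genome,
                               kind="gene_body", side=side)


def test_x_enrichment_detected(four_chrom_genome):
    _, tests = _simulated_analysis(four_chrom_genome, x_effect=1.0)
    by = tests.set_index("chromosome")
    assert by.loc["X", "p_one_sided"] < 1e-6
    assert (by.loc[["I", "II", "III"], "p_one_sided"] > 0.05).all()


def test_x_depletion_detected_with_side_less(four_chrom_genome):
    _, tests = _simulated_analysis(four_chrom_genome, x_effect=-1.0, side="less")
    by = tests.set_index("chromosome")
    assert by.loc["X", "p_one_sided"] < 1e-6


def test_planted_x_effect_recovered(four_chrom_genome):
    df, _ = _simulated_analysis(four_chrom_genome, x_effect=1.0)
    on_x = df["chrom"] == "X"
    diff = df.loc[on_x, "log2_ratio"].mean() - df.loc[~on_x, "log2_ratio"].mean()
    assert abs(diff - 1.0) < 0.1


def test_gene_density_confound_stays_null():
    """Unequal genes per chromosome with zero X effect: 10-kb-bin and
    intergenic analyses stay non-significant for X."""
    g = make_genome(
        [("I", 2_000_000, "autosome"), ("II", 2_000_000, "autosome"),
         ("III", 2_000_000, "autosome"), ("X", 2_000_000, "X")],
        bin_size=10_000,
    )
    rows = []
    rng = np.random.default_rng(0)
    per_chrom = {"I": 120, "II": 80, "III": 60, "X": 15}  # X gene-poor
    for chrom, n in per_chrom.items():
        starts = np.sort(rng.choice(np.arange(0, 1_990_000, 2000), n, replace=False))
        for k, s in enumerate(starts):
            rows.append((chrom, int(s), int(s) + 1500, f"{chrom}g{k}", 0, "+"))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                        "score", "strand"])
    chip, inp = simulate_chip_tracks(g, genes, ChipSimParams(x_log2_effect=0.0,
                                                             seed=3))
    for kind in ("bin10kb", "intergenic"):
        _, tests = enrichment_analysis(chip, inp, genes, g, kind=kind,
                                       side="greater")
        assert tests.set_index("chromosome").loc["X", "p_one_sided"] > 0.05
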