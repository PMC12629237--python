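"""Chromosome-scale ChIP enrichment: region builders, log2(ChIP/input),
z-scoring and one-sided one-vs-rest rank-sum tests.

Regions come in four kinds — gene bodies (annotated start to end), TSS
windows (250 bp either side of the first transcribed base, strand-aware),
10-kb tiling bins, and the intergenic complement of merged gene bodies.
Per-region enrichment is log2 of the ratio of mean ChIP to mean input
coverage (pseudocount 1 on each mean); values are z-scored genome-wide
within a region kind, so chromosome-scale differences survive, and each
chromosome is compared to the pooled rest with a one-sided Wilcoxon
rank-sum test (H4K20me1-style X enrichment tests side="greater"; depletion
tests side="less").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genome import GenomeModel
from .simulate.chip import EnrichmentTrack

TSS_FLANK = 250  # bp either side of the first transcribed base
BIN10KB = 10_000

REGION_KINDS = ("gene_body", "tss", "bin10kb", "intergenic")


@dataclass
class RegionSet:
    kind: str
    intervals: pd.DataFrame  # chrom, start, end, id (0-based half-open)


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def build_regions(
    genes: pd.DataFrame, genome: GenomeModel, kind: str
) -> RegionSet:
    """Construct a region set of the given kind from a BED6-like gene frame
    (chrom, start, end, name, score, strand)."""
    if kind not in REGION_KINDS:
        raise ValueError(f"kind must be one of {REGION_KINDS}")
    rows = []
    if kind in ("gene_body", "tss"):
        for _, g in genes.iterrows():
            size = genome.length(g["chrom"])
            if g["start"] < 0 or g["end"] > size:
                raise ValueError(
                    f"gene {g.get('name', '?')} outside chromosome bounds"
                )
            if kind == "gene_body":
                rows.append((g["chrom"], int(g["start"]), int(g["end"]), g["name"]))
            else:
                strand = g.get("strand", "+")
                first = int(g["start"]) if strand == "+" else int(g["end"]) - 1
                start = max(first - TSS_FLANK, 0)
                end = min(first + TSS_FLANK, size)
                rows.append((g["chrom"], start, end, f"{g['name']}_tss"))
    elif kind == "bin10kb":
        for chrom in genome.names:
            size = genome.length(chrom)
            starts = np.arange(0, size, BIN10KB)
            for s in starts:
                rows.append((chrom, int(s), int(min(s + BIN10KB, size)), f"{chrom}:{s}"))
    else:  # intergenic = complement of merged gene bodies, per chromosome
        for chrom in genome.names:
            size = genome.length(chrom)
            merged = _merge_intervals(
                [
                    (int(s), int(e))
                    for s, e in genes.loc[
                        genes["chrom"] == chrom, ["start", "end"]
                    ].itertuples(index=False)
                ]
            )
            pos = 0
            k = 0
            for s, e in merged:
                if s > pos:
                    rows.append((chrom, pos, s, f"{chrom}_ig{k}"))
                    k += 1
                pos = max(pos, e)
            if pos < size:
                rows.append((chrom, pos, size, f"{chrom}_ig{k}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    df["kind"] = kind
    return RegionSet(kind=kind, intervals=df)


def _region_means(track: EnrichmentTrack, regions: pd.DataFrame) -> np.ndarray:
    """Mean coverage per region via prefix sums on the step grid; partial
    step overlap at region edges is weighted by overlap length."""
    step = track.step
    out = np.empty(len(regions))
    csums = {
        chrom: np.concatenate([[0.0], np.cumsum(vals)])
        for chrom, vals in track.values.items()
    }
    for r, (chrom, start, end) in enumerate(
        regions[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if end <= start:
            raise ValueError(f"zero-width region at {chrom}:{start}")
        vals = track.values[chrom]
        cs = csums[chrom]
        i0, i1 = start // step, (end - 1) // step
        if i0 == i1:
            out[r] = vals[i0]
            continue
        total = 0.0
        # left partial step
        left_cover = (i0 + 1) * step - start
        total += vals[i0] * left_cover
        # full steps
        total += (cs[i1] - cs[i0 + 1]) * step
        # right partial step
        right_cover = end - i1 * step
        total += vals[i1] * right_cover
        out[r] = total / (end - start)
    return out


def region_enrichment(
    chip: EnrichmentTrack,
    inp: EnrichmentTrack,
    regions: RegionSet,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-region log2((mean chip + c) / (mean input + c)), plus the
    chip-minus-input difference used for display tracks."""
    if chip.step != inp.step:
        raise ValueError("chip and input tracks must share a step size")
    df = regions.intervals.copy()
    chip_mean = _region_means(chip, df)
    inp_mean = _region_means(inp, df)
    df["chip_mean"] = chip_mean
    df["input_mean"] = inp_mean
    df["log2_ratio"] = np.log2((chip_mean + pseudocount) / (inp_mean + pseudocount))
    df["chip_minus_input"] = chip_mean - inp_mean
    return df


def zscore(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """(v - mean) / sd over all values (population sd by default). The
    scope is genome-wide within one region kind, so chromosome differences
    survive the transform."""
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need >= 2 regions")
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("degenerate enrichment: sd = 0")
    return (values - values.mean()) / sd


def one_vs_rest_enrichment_test(
    enrich: pd.DataFrame,
    genome: GenomeModel,
    side: str = "greater",
    value_col: str = "zscore",
) -> pd.DataFrame:
    """One-sided rank-sum of each chromosome's region values against the
    pooled rest. side="greater" asks whether the chromosome is enriched."""
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    rows = []
    vals = enrich[value_col].to_numpy()
    chroms = enrich["chrom"].to_numpy()
    for chrom in genome.names:
        mine = vals[chroms == chrom]
        rest = vals[chroms != chrom]
        low_power = min(len(mine), len(rest)) < 10
        if len(mine) == 0 or len(rest) == 0:
            rows.append(
                {
                    "chromosome": chrom,
                    "class": genome.chrom_class(chrom),
                    "n_regions": len(mine),
                    "mean_value": np.nan,
                    "p_one_sided": np.nan,
                    "neg_log10_p": np.nan,
                    "low_power": True,
                }
            )
            continue
        p = float(mannwhitneyu(mine, rest, alternative=side).pvalue)
        rows.append(
            {
                "chromosome": chrom,
                "class": genome.chrom_class(chrom),
                "n_regions": len(mine),
                "mean_value": float(mine.mean()),
                "p_one_sided": p,
                "neg_log10_p": float(-np.log10(p)) if p > 0 else np.inf,
                "low_power": low_power,
            }
        )
    return pd.DataFrame(rows)


def enrichment_analysis(
    chip: EnrichmentTrack,
    inp: EnrichmentTrack,
    genes: pd.DataFrame,
    genome: GenomeModel,
    kind: str = "gene_body",
    side: str = "greater",
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full region pipeline: build regions, compute log2 ratios, z-score,
    test each chromosome one-vs-rest. Returns (per-region, per-chromosome)."""
    regions = build_regions(genes, genome, kind)
    df = region_enrichment(chip, inp, regions, pseudocount=pseudocount)
    df["zscore"] = zscore(df["log2_ratio"].to_numpy())
    tests = one_vs_rest_enrichment_test(df, genome, side=side)
    return df, tests
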