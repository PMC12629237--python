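"""Two-sex replicated RNA-seq counts with a soma/germline sex-bias mixture.

Each gene draws a true sex effect (log2 hermaphrodite-or-female over male)
from a two-component mixture: soma genes are centred at zero with a small sd,
germline genes at ``germline_log2_bias_mean`` (default 4, i.e. most germline
genes beyond the 8-fold mark) with random sign, so the absolute fold change
distribution is bimodal with an antimode near 3. X-linked soma genes are
additionally shifted by ``x_imbalance_log2`` in hermaphrodites — 0 models a
dosage-compensated X, 1 models the uncompensated two-fold imbalance of an XX
vs XO comparison. Germline genes are by default depleted from the X (half
the autosomal germline fraction), as observed in nematodes.

Counts are negative binomial with mean-variance var = mu + dispersion * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genome import GenomeModel, X

HERM = "herm_or_female"
MALE = "male"


@dataclass(frozen=True)
class ExpressionSimParams:
    genes_per_chromosome: int = 1000
    germline_fraction: float = 0.3
    germline_log2_bias_mean: float = 4.0
    germline_log2_bias_sd: float = 0.5
    soma_log2_bias_sd: float = 0.5
    x_imbalance_log2: float = 0.0
    dispersion: float = 0.05
    replicates_per_sex: int = 3
    library_size: int = 2_000_000
    gene_length_range: tuple[int, int] = (500, 5000)
    deplete_x_germline: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_chromosome < 1:
            raise ValueError("genes_per_chromosome must be >= 1")
        if self.replicates_per_sex < 2:
            raise ValueError("need >= 2 replicates per sex")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.germline_fraction <= 1:
            raise ValueError("germline_fraction must be in [0, 1]")
        if self.germline_fraction == 1 and self.x_imbalance_log2 != 0:
            raise ValueError(
                "germline_fraction = 1 leaves no soma genes to carry the "
                "X imbalance"
            )
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")


@dataclass
class ExpressionTable:
    """Genes x samples counts with chromosome assignment and sex labels.

    ``truth`` carries the generating parameters (per-gene true log2 effect
    and germline flag) for recovery tests; analysis code never reads it.
    """

    genes: pd.DataFrame  # gene_id, chrom, length
    counts: pd.DataFrame  # genes x samples, integer
    samples: pd.DataFrame  # sample, sex, replicate
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sexes = set(self.samples["sex"])
        if not {HERM, MALE} <= sexes:
            raise ValueError(f"samples must include both sexes {HERM!r}, {MALE!r}")
        for sex in (HERM, MALE):
            if (self.samples["sex"] == sex).sum() < 2:
                raise ValueError("need >= 2 replicates per sex")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # numpy's NB(n, p): mean n(1-p)/p; with n = 1/dispersion, p = n/(n+mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_expression(
    genome: GenomeModel, params: ExpressionSimParams
) -> ExpressionTable:
    rng = np.random.default_rng(params.seed)
    rows = []
    for chrom in genome.names:
        is_x = genome.chrom_class(chrom) == X
        gfrac = params.germline_fraction
        if is_x and params.deplete_x_germline:
            gfrac = gfrac / 2.0
        for g in range(params.genes_per_chromosome):
            rows.append((f"{chrom}_g{g:05d}", chrom, is_x, gfrac))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "is_x", "gfrac"])
    n_genes = len(genes)

    lo, hi = params.gene_length_range
    genes["length"] = rng.integers(lo, hi + 1, size=n_genes)

    germline = rng.random(n_genes) < genes["gfrac"].to_numpy()
    effect = rng.normal(0.0, params.soma_log2_bias_sd, size=n_genes)
    n_germ = int(germline.sum())
    if n_germ:
        sign = rng.choice([-1.0, 1.0], size=n_germ)
        effect[germline] = sign * rng.normal(
            params.germline_log2_bias_mean, params.germline_log2_bias_sd, size=n_germ
        )
    is_x = genes["is_x"].to_numpy()
    soma_x = is_x & ~germline
    effect[soma_x] += params.x_imbalance_log2

    # baseline expression spans ~3 decades, log-normal in log2 space
    base = 2.0 ** rng.normal(5.0, 2.0, size=n_genes)

    # expected read share: expression level x gene length, sex effect split
    # symmetrically so swapping labels negates every true effect
    lengths = genes["length"].to_numpy().astype(float)
    herm_level = base * 2.0 ** (effect / 2.0)
    male_level = base * 2.0 ** (-effect / 2.0)

    counts = {}
    samples = []
    for sex, level in ((HERM, herm_level), (MALE, male_level)):
        share = level * lengths
        mu = params.library_size * share / share.sum()
        for rep in range(1, params.replicates_per_sex + 1):
            sid = f"{sex}_rep{rep}"
            counts[sid] = _nb_sample(rng, mu, params.dispersion)
            samples.append((sid, sex, rep))

    truth = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "true_log2_effect": effect,
            "germline": germline,
        }
    )
    return ExpressionTable(
        genes=genes[["gene_id", "chrom", "length"]].copy(),
        counts=pd.DataFrame(counts),
        samples=pd.DataFrame(samples, columns=["sample", "sex", "replicate"]),
        truth=truth,
    )


def place_genes(
    genome: GenomeModel, table: ExpressionTable, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Assign non-overlapping genomic intervals to the table's genes, for use
    as a BED6 annotation (random strand, sorted within chromosome)."""
    rng = rng or np.random.default_rng(0)
    out = []
    for chrom, sub in table.genes.groupby("chrom", sort=False):
        length = genome.length(chrom)
        total = int(sub["length"].sum())
        if total >= length:
            raise ValueError(f"genes do not fit on {chrom}")
        gap = (length - total) // (len(sub) + 1)
        pos = 0
        for _, row in sub.iterrows():
            start = pos + gap
            end = start + int(row["length"])
            out.append((chrom, start, end, row["gene_id"],
                        0, rng.choice(["+", "-"])))
            pos = end
    return pd.DataFrame(out, columns=["chrom", "start", "end", "name", "score", "strand"])
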