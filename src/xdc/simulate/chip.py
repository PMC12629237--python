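"""ChIP/input coverage tracks with gene-body enrichment and an X-wide effect.

The input track is flat background plus Gaussian noise, clipped at zero. The
ChIP track multiplies the clean background by 2^gene_body_signal inside gene
bodies and by 2^x_log2_effect everywhere on X chromosomes, then adds its own
noise. A positive ``x_log2_effect`` models the H4K20me1-style enrichment of a
repressed, dosage-compensated X; a negative value models depletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genome import GenomeModel, X


@dataclass(frozen=True)
class ChipSimParams:
    x_log2_effect: float = 0.0
    gene_body_signal: float = 1.0
    background_signal: float = 20.0
    noise_sd: float = 2.0
    step: int = 10  # bp, matches display-track bin size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_signal <= 0:
            raise ValueError("background_signal must be > 0")
        if self.gene_body_signal < 0:
            raise ValueError("gene_body_signal must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class EnrichmentTrack:
    """Strandless step-function coverage: one value per ``step``-bp window,
    tiling each chromosome exactly (last window may be short)."""

    label: str  # "chip" | "input"
    step: int
    values: dict[str, np.ndarray]  # chromosome -> per-step coverage

    def n_steps(self, chrom: str) -> int:
        return len(self.values[chrom])

    def to_bedgraph(self, chrom_sizes: dict[str, int]) -> pd.DataFrame:
        rows = []
        for chrom, vals in self.values.items():
            starts = np.arange(len(vals)) * self.step
            ends = np.minimum(starts + self.step, chrom_sizes[chrom])
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": vals}
                )
            )
        return pd.concat(rows, ignore_index=True)


def track_from_bedgraph(
    df: pd.DataFrame, step: int, chrom_sizes: dict[str, int], label: str
) -> EnrichmentTrack:
    """Rasterise a bedGraph (constant-step or arbitrary intervals) onto the
    fixed step grid; uncovered positions are zero."""
    values = {}
    for chrom, size in chrom_sizes.items():
        n = -(-size // step)
        vals = np.zeros(n)
        sub = df[df["chrom"] == chrom]
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            i0 = start // step
            i1 = -(-end // step)
            vals[i0:i1] = value
        values[chrom] = vals
    return EnrichmentTrack(label=label, step=step, values=values)


def simulate_chip_tracks(
    genome: GenomeModel, genes: pd.DataFrame, params: ChipSimParams
) -> tuple[EnrichmentTrack, EnrichmentTrack]:
    """Return (chip, input) tracks. ``genes`` is a BED-like frame with
    chrom/start/end columns; genes must lie within chromosome bounds."""
    rng = np.random.default_rng(params.seed)
    step = params.step
    chip_values = {}
    input_values = {}
    for chrom in genome.names:
        size = genome.length(chrom)
        n = -(-size // step)
        gene_mask = np.zeros(n, dtype=bool)
        sub = genes[genes["chrom"] == chrom]
        for start, end in sub[["start", "end"]].itertuples(index=False):
            if start < 0 or end > size:
                raise ValueError(f"gene [{start}, {end}) outside {chrom}")
            gene_mask[start // step : -(-end // step)] = True

        background = np.full(n, params.background_signal)
        input_vals = background + rng.normal(0, params.noise_sd, size=n)
        chip_clean = background * 2.0 ** (params.gene_body_signal * gene_mask)
        if genome.chrom_class(chrom) == X:
            chip_clean = chip_clean * 2.0**params.x_log2_effect
        chip_vals = chip_clean + rng.normal(0, params.noise_sd, size=n)

        input_values[chrom] = np.clip(input_vals, 0, None)
        chip_values[chrom] = np.clip(chip_vals, 0, None)
    chip = EnrichmentTrack(label="chip", step=step, values=chip_values)
    inp = EnrichmentTrack(label="input", step=step, values=input_values)
    return chip, inp
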