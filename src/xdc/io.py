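"""Plain-text interchange formats.

Everything the package reads or writes is text: bin-table/pixel TSVs for
contact matrices, two-column chromosome-sizes TSV, BED6 gene annotations,
bedGraph coverage tracks, and counts + sample-sheet TSVs for expression.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    """Write a BED6 file; df must carry chrom/start/end/name and may carry
    score and strand (defaulted to 0 / '+')."""
    out = df.copy()
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "+"
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )


def write_counts(path: str | Path, genes: pd.DataFrame, counts: pd.DataFrame) -> None:
    """Counts TSV: gene_id, chrom, length, then one column per sample."""
    out = pd.concat(
        [genes[["gene_id", "chrom", "length"]].reset_index(drop=True),
         counts.reset_index(drop=True)],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["gene_id", "chrom", "length"]
    genes = df[meta_cols].copy()
    counts = df.drop(columns=meta_cols)
    return genes, counts


def write_sample_sheet(path: str | Path, samples: pd.DataFrame) -> None:
    samples[["sample", "sex", "replicate"]].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "sex", "replicate"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return df
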