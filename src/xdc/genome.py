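"""Genome model: chromosome names, lengths and autosome/X class labels.

Nematode genomes analysed at this scale have 5--7 chromosomes of a few tens
of megabases; every two-group (autosomes-vs-X) comparison in the package is
driven by the class labels held here.
"""

from __future__ import annotations

from dataclasses import dataclass

AUTOSOME = "autosome"
X = "X"

_VALID_CLASSES = frozenset({AUTOSOME, X})


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int  # bp
    chrom_class: str  # "autosome" | "X"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.chrom_class not in _VALID_CLASSES:
            raise ValueError(
                f"chromosome {self.name}: class must be one of {sorted(_VALID_CLASSES)}"
            )


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes plus the analysis bin size.

    Parameters
    ----------
    chromosomes
        Ordered chromosome records. At least one autosome and one X are
        required so that one-vs-rest and A-vs-X tests are defined.
    bin_size
        Hi-C bin width in bp (5 kb is the convention used throughout).
    """

    chromosomes: tuple[Chromosome, ...]
    bin_size: int = 5000

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        classes = {c.chrom_class for c in self.chromosomes}
        if not {AUTOSOME, X} <= classes:
            raise ValueError("need at least one autosome and one X chromosome")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def autosomes(self) -> list[str]:
        return [c.name for c in self.chromosomes if c.chrom_class == AUTOSOME]

    @property
    def x_chromosomes(self) -> list[str]:
        return [c.name for c in self.chromosomes if c.chrom_class == X]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def length(self, name: str) -> int:
        return self.chromosome(name).length

    def chrom_class(self, name: str) -> str:
        return self.chromosome(name).chrom_class

    def n_bins(self, name: str) -> int:
        length = self.length(name)
        return -(-length // self.bin_size)  # ceil division


def make_genome(
    spec: list[tuple[str, int, str]] | None = None, bin_size: int = 5000
) -> GenomeModel:
    """Convenience constructor from (name, length, class) triples."""
    if spec is None:
        spec = [
            ("I", 15_000_000, AUTOSOME),
            ("II", 15_000_000, AUTOSOME),
            ("III", 14_000_000, AUTOSOME),
            ("IV", 16_000_000, AUTOSOME),
            ("V", 17_000_000, AUTOSOME),
            ("X", 18_000_000, X),
        ]
    chroms = tuple(Chromosome(n, ln, cl) for n, ln, cl in spec)
    return GenomeModel(chromosomes=chroms, bin_size=bin_size)
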