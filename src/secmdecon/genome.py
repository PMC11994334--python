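"""Reference genome description: ordered chromosome names and lengths.

The package never touches sequence; a genome here is just the coordinate
system reads and bins live in.  The default test genome is the hg19
chromosome set scaled down 50-fold so that a desk-scale simulation with
~1 Mb-equivalent bins finishes in seconds while keeping the relative
chromosome sizes (and therefore the read-count dilution arithmetic) of the
real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import ParameterError

# GRCh37/hg19 chromosome lengths (bp).
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

SEX_CHROMOSOMES = ("chrX", "chrY")


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths (0-based coordinates)."""

    name: str
    lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ParameterError(f"chromosome {chrom} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in SEX_CHROMOSOMES]

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ParameterError(f"chromosome {chrom!r} not in genome {self.name!r}") from None

    @classmethod
    def scaled_hg19(cls, scale: int = 50) -> "Genome":
        """hg19 chromosome set with every length divided by ``scale``.

        ``scale=1`` returns the full hg19 coordinate system.
        """
        if scale < 1:
            raise ParameterError("scale must be >= 1")
        return cls(
            name=f"hg19/{scale}" if scale != 1 else "hg19",
            lengths={c: max(1, n // scale) for c, n in HG19_LENGTHS.items()},
        )

    @classmethod
    def from_intervals(cls, chroms, ends, name: str = "inferred") -> "Genome":
        """Build a genome from observed intervals (length = max end per chromosome).

        Used when a per-read table is loaded without an explicit genome.
        """
        import pandas as pd

        s = pd.Series(ends).groupby(pd.Series(chroms).values).max()
        return cls(name=name, lengths={str(c): int(v) for c, v in s.items()})
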