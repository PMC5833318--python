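"""Reference genome container for a circular haploid chromosome.

Coordinates are 1-based and inclusive throughout the package, matching
pileup and VCF conventions.  Distances between sites are measured on the
circle (the shorter of the linear and wrap-around distance), as
appropriate for a circular bacterial chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest distance between two 1-based positions on a circle."""
    d = abs(int(a) - int(b)) % length
    return min(d, length - d)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A protein-coding interval, 1-based inclusive; length must be a
    multiple of 3 so that codon positions are well defined."""

    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid gene interval [{self.start}, {self.end}]")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"gene {self.name or self.start} length is not a multiple of 3"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """Circular reference genome with optional gene annotation.

    ``terminus`` is the 1-based coordinate of the replication terminus,
    used by the chromosomal-position tests; it may be None.
    """

    name: str
    sequence: str
    genes: list[Gene] = field(default_factory=list)
    terminus: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"genome sequence contains non-ACGT characters: {bad}")
        for g in self.genes:
            if g.end > self.length:
                raise ValueError(f"gene {g.name or g.start} extends past genome end")
        if self.terminus is not None and not (1 <= self.terminus <= self.length):
            raise ValueError("terminus outside genome")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(f"position {position} outside genome of {self.length}")
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for 1-based inclusive [start, end] (no wrap)."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"invalid slice [{start}, {end}]")
        return self.sequence[start - 1 : end]

    @cached_property
    def codes(self) -> np.ndarray:
        """Sequence as int8 codes 0..3 in A,C,G,T order."""
        raw = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
        lut = np.zeros(128, dtype=np.int8)
        for b, i in BASE_INDEX.items():
            lut[ord(b)] = i
        return lut[raw]

    @cached_property
    def base_counts(self) -> dict[str, int]:
        counts = np.bincount(self.codes, minlength=4)
        return {b: int(counts[i]) for b, i in BASE_INDEX.items()}

    @property
    def gc_sites(self) -> int:
        c = self.base_counts
        return c["G"] + c["C"]

    @property
    def at_sites(self) -> int:
        c = self.base_counts
        return c["A"] + c["T"]

    def gc_fraction(self) -> float:
        return self.gc_sites / self.length

    @cached_property
    def coding_mask(self) -> np.ndarray:
        """Boolean mask of length ``length``: True where any gene covers the
        site (0-based index = position - 1).  Overlaps count once."""
        mask = np.zeros(self.length, dtype=bool)
        for g in self.genes:
            mask[g.start - 1 : g.end] = True
        return mask

    @property
    def coding_sites(self) -> int:
        return int(self.coding_mask.sum())

    def gene_at(self, position: int) -> Gene | None:
        """First annotated gene covering a 1-based position, if any."""
        for g in self.genes:
            if g.start <= position <= g.end:
                return g
        return None
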