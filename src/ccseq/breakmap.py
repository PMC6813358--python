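"""Sparse strand-specific break maps.

A :class:`BreakMap` records, per contig and strand, how many read pairs
placed their protein-linked 5' terminus at each 1-based reference
coordinate.  Watson is the reference top strand, Crick the bottom strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

WATSON = "W"
CRICK = "C"
STRANDS = (WATSON, CRICK)


@dataclass
class BreakMap:
    """Strand-specific sparse map of 5'-terminus coordinates to counts.

    Coordinates are 1-based inclusive on the reference top strand.  The
    0-based half-open convention of BED/bedGraph is applied only at file
    boundaries.
    """

    counts: dict[tuple[str, str], Counter] = field(default_factory=dict)
    total_mapped_pairs: int = 0
    genome_id: str = ""
    sample_id: str = ""

    def strand_counts(self, contig: str, strand: str) -> Counter:
        """Counter of coordinate -> count for one (contig, strand)."""
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        return self.counts.setdefault((contig, strand), Counter())

    def add(self, contig: str, strand: str, pos: int, n: int = 1) -> None:
        if pos < 1:
            raise ValueError(f"coordinate must be >= 1, got {pos}")
        if n <= 0:
            raise ValueError(f"count increment must be positive, got {n}")
        self.strand_counts(contig, strand)[pos] += n

    @property
    def contigs(self) -> list[str]:
        return sorted({c for (c, _s) in self.counts})

    def total_count(self) -> int:
        """Sum of all stored counts (every accepted pair contributes one)."""
        return sum(sum(c.values()) for c in self.counts.values())

    def iter_sites(self) -> Iterator[tuple[str, str, int, int]]:
        """Yield (contig, strand, pos, count), deterministically ordered."""
        for (contig, strand) in sorted(self.counts):
            ctr = self.counts[(contig, strand)]
            for pos in sorted(ctr):
                yield contig, strand, pos, ctr[pos]

    def copy(self) -> "BreakMap":
        return BreakMap(
            counts={k: Counter(v) for k, v in self.counts.items()},
            total_mapped_pairs=self.total_mapped_pairs,
            genome_id=self.genome_id,
            sample_id=self.sample_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BreakMap):
            return NotImplemented
        a = {k: v for k, v in self.counts.items() if v}
        b = {k: v for k, v in other.counts.items() if v}
        return a == b


@dataclass
class MappingStats:
    """Accounting of every read pair seen by the mapper.

    ``pairs_seen`` always equals the sum of the four outcome categories.
    """

    pairs_seen: int = 0
    pairs_flag_rejected: int = 0
    pairs_mapq_rejected: int = 0
    pairs_ambiguous_end: int = 0
    pairs_counted: int = 0

    def check(self) -> None:
        parts = (
            self.pairs_flag_rejected
            + self.pairs_mapq_rejected
            + self.pairs_ambiguous_end
            + self.pairs_counted
        )
        if parts != self.pairs_seen:
            raise AssertionError(
                f"stats do not partition: seen={self.pairs_seen} sum={parts}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "pairs_seen": self.pairs_seen,
            "pairs_flag_rejected": self.pairs_flag_rejected,
            "pairs_mapq_rejected": self.pairs_mapq_rejected,
            "pairs_ambiguous_end": self.pairs_ambiguous_end,
            "pairs_counted": self.pairs_counted,
        }
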