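"""Genomic intervals in 0-based, half-open coordinates.

The interval is the shared currency of every genomic stage of the
pipeline: read placements, tiling windows, called methylated regions,
miRNA stem-loops and transcript models all use the same convention
(BED-style: ``start`` inclusive, ``end`` exclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Strand defaults to ``"."``: DNA methylation is strandless, so most
    of the pipeline ignores strand; transcript models carry it for TSS
    placement.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: GenomicInterval) -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: GenomicInterval) -> bool:
        """True when ``other`` lies fully within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Number of bases strictly between two intervals.

    Returns 0 for overlapping (or book-ended) intervals and ``inf``
    when the intervals sit on different chromosomes.  Symmetric.  Under
    half-open coordinates the gap between ``[.., e)`` and ``[s, ..)``
    with ``e <= s`` is exactly ``s - e`` bases.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(a.start - b.end, b.start - a.end, 0)
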