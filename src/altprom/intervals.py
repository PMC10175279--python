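"""Core genomic domain types.

All coordinates in the package are 0-based half-open; a single base at
position ``p`` is the interval ``[p, p+1)``.  Strand is one of ``+``, ``-``
or ``.`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-annotated half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptModel:
    """A transcript with strand-aware 5' end (TSS).

    ``exons`` are stored in 5'→3' transcript order (reversed genomic order on
    the minus strand).  ``tss`` is the 0-based position of the 5'-most
    transcribed base: the start of the first exon on ``+``, ``end - 1`` of the
    last genomic exon on ``-``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)


class RegionIndex:
    """Overlap index over a set of intervals (per chrom; strand ignored).

    Thin wrapper over :mod:`intervaltree` so callers never touch tree
    internals.
    """

    def __init__(self, regions: list[GenomicInterval] | None = None):
        self._trees: dict[str, IntervalTree] = {}
        self.n = 0
        for r in regions or []:
            self.add(r)

    def add(self, region: GenomicInterval) -> None:
        self._trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region
        )
        self.n += 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda r: (r.start, r.end))

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        """Total number of bases of [start,end) covered by >=1 region."""
        tree = self._trees.get(chrom)
        if tree is None:
            return 0
        hits = sorted(
            (max(start, iv.begin), min(end, iv.end)) for iv in tree.overlap(start, end)
        )
        covered = 0
        cur_s = cur_e = None
        for s, e in hits:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered
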