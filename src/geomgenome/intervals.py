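"""Genomic interval primitives.

All coordinates are 0-based, half-open ([start, end)), BED-native. 1-based
closed conventions (GTF) are converted at the file boundary and never appear
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomicInterval", "ChromosomeLayout", "merge_intervals", "complement"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome identifier.
    start, end : int
        0-based half-open bp offsets; ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At-least-1-bp overlap under half-open semantics."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(starts, ends):
    """Merge overlapping/adjacent sorted intervals; returns (starts, ends) arrays."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def complement(starts, ends, length):
    """Complement of disjoint sorted intervals within [0, length)."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    gap_s = np.concatenate([[0], ends])
    gap_e = np.concatenate([starts, [length]])
    keep = gap_e > gap_s
    return gap_s[keep], gap_e[keep]


@dataclass
class ChromosomeLayout:
    """Ordered, non-overlapping exon intervals on one orientation of one
    chromosome; everything else is non-exonic (NE).

    The exon arrays are sorted and strictly disjoint so exon + NE intervals
    tile ``[0, length)`` exactly (the conservation invariant of every
    downstream operation).
    """

    chrom: str
    orientation: str  # "+" (positive) or "-" (negative)
    length: int
    exon_starts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    exon_ends: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self):
        self.exon_starts = np.asarray(self.exon_starts, dtype=np.int64)
        self.exon_ends = np.asarray(self.exon_ends, dtype=np.int64)
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")
        if self.exon_starts.size:
            order = np.argsort(self.exon_starts, kind="stable")
            self.exon_starts = self.exon_starts[order]
            self.exon_ends = self.exon_ends[order]
            if np.any(self.exon_starts >= self.exon_ends):
                raise ValueError("empty or inverted exon interval in layout")
            if np.any(self.exon_starts[1:] < self.exon_ends[:-1]):
                raise ValueError("overlapping exons in layout")
            if self.exon_starts[0] < 0 or self.exon_ends[-1] > self.length:
                raise ValueError("exon outside [0, length)")

    @property
    def n_exons(self) -> int:
        return int(self.exon_starts.size)

    @property
    def exon_bp(self) -> int:
        return int(np.sum(self.exon_ends - self.exon_starts))

    @property
    def ne_bp(self) -> int:
        return self.length - self.exon_bp

    def ne_intervals(self):
        """(starts, ends) of the NE complement within [0, length)."""
        return complement(self.exon_starts, self.exon_ends, self.length)

    def exon_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, int(s), int(e), self.orientation)
            for s, e in zip(self.exon_starts, self.exon_ends)
        ]
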