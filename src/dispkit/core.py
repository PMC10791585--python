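"""Core genomic data model shared across the toolkit.

All coordinates are 0-based, half-open (BED convention). An interval of
length L covers exactly L bases; abutting intervals do not overlap.
Inputs in 1-based conventions (GTF-style annotations, residue numbering)
are converted at the file boundary, never internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."

_VALID_STRANDS = {STRAND_PLUS, STRAND_MINUS, STRAND_NONE}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(_VALID_STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if on different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_length(other) >= min_bp

    def distance(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 for overlapping or abutting intervals.

        Raises ValueError across chromosomes, where distance is undefined.
        """
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, other.start - self.end, self.start - other.end)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class ReadPair:
    """A proper paired-end alignment: two mates on one chromosome.

    Mate coordinates are 0-based half-open alignment spans. ``proper_pair``
    mirrors the SAM flag; improper pairs are carried through so callers can
    count and drop them explicitly.
    """

    chrom: str
    mate1_start: int
    mate1_end: int
    mate2_start: int
    mate2_end: int
    proper_pair: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.mate1_end <= self.mate1_start or self.mate2_end <= self.mate2_start:
            raise ValueError("mate coordinates must satisfy start < end")

    @property
    def span(self) -> tuple[int, int]:
        """Fragment span: min of all mate starts to max of all mate ends."""
        return (
            min(self.mate1_start, self.mate2_start),
            max(self.mate1_end, self.mate2_end),
        )


class Genome:
    """Ordered chromosome-name -> length (bp) map."""

    def __init__(self, chrom_sizes: dict[str, int] | Iterable[tuple[str, int]]):
        items = list(chrom_sizes.items()) if isinstance(chrom_sizes, dict) else list(chrom_sizes)
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if length <= 0:
                raise ValueError(f"chromosome length must be > 0: {name}={length}")
        self._sizes: dict[str, int] = dict(items)

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        """Read a two-column (name, length) chrom-sizes text file."""
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 'name length'")
                items.append((fields[0], int(fields[1])))
        return cls(items)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def n_bins(self, chrom: str, resolution: int) -> int:
        return -(-self._sizes[chrom] // resolution)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genome({self._sizes!r})"


@dataclass
class Peak:
    """A scored interval, e.g. a peak call with optional significance.

    ``qvalue`` is the q-value itself (a probability); file readers convert
    the -log10 column of narrowPeak/broadPeak at the boundary.
    """

    interval: GenomicInterval
    signal: float = 0.0
    qvalue: float | None = None
    name: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class MergedRegion:
    """A cluster of peaks stitched by a distance rule.

    The interval spans all constituents; total_signal is the sum of the
    constituent peak signals.
    """

    interval: GenomicInterval
    peaks: list[Peak]
    total_signal: float

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("a merged region needs at least one constituent peak")
        if self.total_signal < 0:
            raise ValueError("total_signal must be >= 0")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose edge-to-edge gap is <= ``gap`` (transitively).

    ``gap=0`` merges overlapping and abutting intervals; ``gap=-1`` merges
    only intervals that actually share bases (overlap-collapse).
    Returns merged spans sorted by (chrom, start).
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur: GenomicInterval | None = None
    for iv in by_pos:
        if cur is not None and iv.chrom == cur.chrom and iv.start - cur.end <= gap:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
            continue
        if cur is not None:
            merged.append(cur)
        cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        merged.append(cur)
    return merged


def interval_jaccard(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> float:
    """Base-pair Jaccard index between two interval sets.

    Each set is first self-merged so internal overlap is not double counted.
    Returns 0.0 when both sets are empty.
    """
    a_m = merge_intervals(a, gap=-1)
    b_m = merge_intervals(b, gap=-1)
    inter = 0
    for iv_a in a_m:
        for iv_b in b_m:
            inter += iv_a.overlap_length(iv_b)
    len_a = sum(iv.length for iv in a_m)
    len_b = sum(iv.length for iv in b_m)
    union = len_a + len_b - inter
    return inter / union if union > 0 else 0.0


def as_interval_array(intervals: list[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    """Starts/ends of a same-chromosome interval list as numpy arrays."""
    starts = np.fromiter((iv.start for iv in intervals), dtype=np.int64, count=len(intervals))
    ends = np.fromiter((iv.end for iv in intervals), dtype=np.int64, count=len(intervals))
    return starts, ends
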