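"""Peak filtering and annotation: significance, promoter/distal, chromatin state."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .core import GenomicInterval, Peak

DEFAULT_Q_MAX = 1e-5
DEFAULT_PROMOTER_RADIUS = 2000
BACKGROUND_STATE = "background"


@dataclass
class StateSegmentation:
    """A chromatin-state segmentation: labelled, non-overlapping segments.

    ``states`` is the vocabulary in priority order (most active first);
    it is used to break dominant-overlap ties deterministically. Genome
    regions not covered by any segment count as ``background``, which has
    the lowest priority.
    """

    segments: list[tuple[GenomicInterval, str]]
    states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.states:
            seen: list[str] = []
            for _, label in self.segments:
                if label not in seen:
                    seen.append(label)
            self.states = seen
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv, _ in self.segments:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")

    def trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for iv, label in self.segments:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, label)
        return trees


def filter_peaks_by_q(peaks: list[Peak], q_max: float = DEFAULT_Q_MAX) -> list[Peak]:
    """Keep peaks with q-value strictly below ``q_max`` (order preserved)."""
    kept = []
    for p in peaks:
        if p.qvalue is None:
            raise ValueError(f"peak {p.name or p.interval} has no q-value")
        if p.qvalue < q_max:
            kept.append(p)
    return kept


def classify_promoter_distal(
    peaks: list[Peak],
    tss: list[tuple[str, int]],
    radius: int = DEFAULT_PROMOTER_RADIUS,
) -> tuple[list[str], dict[str, float]]:
    """Label each peak promoter/distal by distance to the nearest TSS.

    Distance is measured from the peak edge (0 when the TSS lies inside the
    peak) and the radius is inclusive. Returns per-peak labels plus the
    promoter/distal fractions.
    """
    if not tss:
        raise ValueError("TSS list must be non-empty")
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss:
        by_chrom.setdefault(chrom, []).append(pos)
    for positions in by_chrom.values():
        positions.sort()
    labels = []
    for p in peaks:
        positions = by_chrom.get(p.chrom, [])
        d = min((_edge_distance(p, pos) for pos in positions), default=None)
        labels.append("promoter" if d is not None and d <= radius else "distal")
    n = len(labels) or 1
    fractions = {
        "promoter": labels.count("promoter") / n,
        "distal": labels.count("distal") / n,
    }
    return labels, fractions


def _edge_distance(peak: Peak, pos: int) -> int:
    return max(0, peak.start - pos, pos - peak.end)


def assign_dominant_state(
    peaks: list[Peak],
    seg: StateSegmentation,
    priority: list[str] | None = None,
) -> list[str]:
    """Assign each peak the chromatin state covering most of its bases.

    Uncovered bases count toward ``background``. Ties are broken by the
    priority order (default: the segmentation's state order, most active
    first; background always last). Peaks on chromosomes absent from the
    segmentation get the background label with a warning.
    """
    order = list(priority) if priority is not None else list(seg.states)
    rank = {s: i for i, s in enumerate(order)}
    rank.setdefault(BACKGROUND_STATE, len(rank))
    trees = seg.trees()
    labels = []
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            warnings.warn(f"peak {p.name or p.interval}: chromosome not in segmentation")
            labels.append(BACKGROUND_STATE)
            continue
        bases: dict[str, int] = {}
        covered = 0
        for hit in tree.overlap(p.start, p.end):
            ov = min(p.end, hit.end) - max(p.start, hit.begin)
            bases[hit.data] = bases.get(hit.data, 0) + ov
            covered += ov
        gap = p.interval.length - covered
        if gap > 0:
            bases[BACKGROUND_STATE] = bases.get(BACKGROUND_STATE, 0) + gap
        best = max(bases.items(), key=lambda kv: (kv[1], -rank.get(kv[0], len(rank))))
        labels.append(best[0])
    return labels
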