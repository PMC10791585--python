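"""Island calling: stitch peaks into regions, rank by total signal, and cut
the scaled rank-signal curve at the tangent of slope 1.

This is the hockey-stick criterion familiar from super-enhancer calling:
regions are sorted by total signal, rank and signal are min-max scaled to
[0, 1], and islands are the regions beyond the point where the curve's
tangent reaches slope 1. Discretely, that point is the one whose slope-1
line leaves the fewest points below it (the line slid up from below until
it touches the convex part of the curve).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, MergedRegion, Peak

DEFAULT_MERGE_GAP = 20_000


@dataclass
class IslandCallResult:
    """Regions sorted ascending by total signal with the cutoff and flags.

    ``scaled_rank``/``scaled_signal`` are the [0,1] curve (as plotted in the
    rank-signal figure), ``cutoff_index`` the discrete tangent point, and
    ``is_island[i]`` True for regions strictly above ``cutoff_signal``.
    """

    regions: list[MergedRegion]
    scaled_rank: np.ndarray
    scaled_signal: np.ndarray
    cutoff_index: int
    cutoff_signal: float
    is_island: np.ndarray

    @property
    def islands(self) -> list[MergedRegion]:
        return [r for r, flag in zip(self.regions, self.is_island) if flag]

    @property
    def non_islands(self) -> list[MergedRegion]:
        return [r for r, flag in zip(self.regions, self.is_island) if not flag]


@dataclass
class IslandSummary:
    n_regions: int
    n_islands: int
    median_island_span: float
    median_single_peak_span: float
    island_signal_fraction: float


def merge_peaks_into_regions(
    peaks: list[Peak], gap: int = DEFAULT_MERGE_GAP
) -> list[MergedRegion]:
    """Transitively merge peaks whose edge-to-edge gap is <= ``gap`` bp.

    The default 20-kb gap is the stitching distance used to group peaks
    into candidate islands. Total signal is the sum of constituent peak
    signals; chains longer than the gap overall are allowed.
    """
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    regions: list[MergedRegion] = []
    group: list[Peak] = []
    span_end = -1
    for p in ordered:
        if group and p.chrom == group[-1].chrom and p.start - span_end <= gap:
            group.append(p)
            span_end = max(span_end, p.end)
            continue
        if group:
            regions.append(_finish_region(group))
        group = [p]
        span_end = p.end
    if group:
        regions.append(_finish_region(group))
    return regions


def _finish_region(group: list[Peak]) -> MergedRegion:
    start = min(p.start for p in group)
    end = max(p.end for p in group)
    return MergedRegion(
        interval=GenomicInterval(group[0].chrom, start, end),
        peaks=list(group),
        total_signal=float(sum(p.signal for p in group)),
    )


def compute_cutoff_index(signals) -> tuple[int, float]:
    """Discrete tangent-slope-1 point of the scaled rank-signal curve.

    Signals are sorted ascending; rank is scaled to x in [0, 1] and signal
    min-max scaled to y in [0, 1]. For each candidate point the slope-1
    line through it is y = x + (y_i - x_i); the cutoff is the point whose
    line leaves the fewest curve points below it, i.e. the point where the
    shifted diagonal touches the curve from below. Ties break toward the
    higher index (fewer, more conservative islands). Returns the cutoff
    index into the sorted order and the unscaled signal there.

    Degenerate inputs: all-equal signals put the cutoff at the top value
    (zero islands under a strict > rule); a single signal is handled by
    the caller (`call_islands` flags it as an island).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("no signals")
    if n == 1:
        return 0, float(s[0])
    smin, smax = s[0], s[-1]
    if smax == smin:
        return n - 1, float(smax)
    x = np.arange(n) / (n - 1)
    y = (s - smin) / (smax - smin)
    c = y - x  # the slope-1 line through point i is y = x + c[i]
    order = np.sort(c)
    n_below = np.searchsorted(order, c, side="right")
    i = n - 1 - int(np.argmin(n_below[::-1]))  # tie -> higher index
    return i, float(s[i])


def call_islands(regions: list[MergedRegion]) -> IslandCallResult:
    """Rank regions by total signal and flag those beyond the tangent cutoff.

    Islands are the regions with total signal strictly greater than the
    cutoff signal (the tangent-point region itself is not an island). The
    full scaled curve is returned for plotting. A single region is flagged
    as an island by convention.
    """
    if not regions:
        raise ValueError("no regions to call islands on")
    ordered = sorted(regions, key=lambda r: r.total_signal)
    signals = np.array([r.total_signal for r in ordered], dtype=float)
    n = signals.size
    scaled_rank = np.zeros(n) if n == 1 else np.arange(n) / (n - 1)
    span = signals[-1] - signals[0]
    scaled_signal = np.zeros(n) if span == 0 else (signals - signals[0]) / span
    cutoff_index, cutoff_signal = compute_cutoff_index(signals)
    if n == 1:
        is_island = np.array([True])
    else:
        is_island = signals > cutoff_signal
    return IslandCallResult(
        regions=ordered,
        scaled_rank=scaled_rank,
        scaled_signal=scaled_signal,
        cutoff_index=cutoff_index,
        cutoff_signal=cutoff_signal,
        is_island=is_island,
    )


def island_summary(result: IslandCallResult) -> IslandSummary:
    """Headline statistics: island count, span medians, signal fraction.

    The single-peak comparator is the span of non-island regions made of
    exactly one peak, mirroring the island-vs-single-peak length contrast.
    """
    islands = result.islands
    singles = [r for r in result.non_islands if r.n_peaks == 1]
    total = sum(r.total_signal for r in result.regions)
    island_signal = sum(r.total_signal for r in islands)
    return IslandSummary(
        n_regions=len(result.regions),
        n_islands=len(islands),
        median_island_span=float(np.median([r.interval.length for r in islands])) if islands else 0.0,
        median_single_peak_span=float(np.median([r.interval.length for r in singles])) if singles else 0.0,
        island_signal_fraction=island_signal / total if total > 0 else 0.0,
    )


def curve_table(result: IslandCallResult):
    """The rank-signal curve as a pandas DataFrame (one row per region)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": np.arange(len(result.regions)),
            "scaled_rank": result.scaled_rank,
            "chrom": [r.interval.chrom for r in result.regions],
            "start": [r.interval.start for r in result.regions],
            "end": [r.interval.end for r in result.regions],
            "n_peaks": [r.n_peaks for r in result.regions],
            "total_signal": [r.total_signal for r in result.regions],
            "scaled_signal": result.scaled_signal,
            "is_island": result.is_island.astype(bool),
        }
    )
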