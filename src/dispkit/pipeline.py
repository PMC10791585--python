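"""End-to-end wiring: fragments -> track -> peaks -> regions -> islands.

Thin orchestration over the library modules with the standard parameter
set (10 M normalization, 10-bp bins, 1-kb window signal, 20-kb stitching).
The peak-calling threshold is expressed as a multiple of the genome-wide
mean normalized depth so it transfers across library sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

from .core import Genome, Peak
from .coverage import (
    CoverageTrack,
    FragmentSet,
    build_normalized_track,
    call_peaks_threshold,
    score_peaks,
)
from .islands import IslandCallResult, call_islands, merge_peaks_into_regions


@dataclass
class PipelineResult:
    track: CoverageTrack
    peaks: list[Peak]
    islands: IslandCallResult | None


def islands_from_fragments(
    fs: FragmentSet,
    genome: Genome,
    resolution: int = 10,
    target_reads: int = 10_000_000,
    threshold_fold: float = 5.0,
    min_len: int = 300,
    merge_gap_peaks: int = 200,
    window: int = 1000,
    stitch_gap: int = 20_000,
    control: CoverageTrack | None = None,
) -> PipelineResult:
    """Run the default single-sample pipeline on a fragment set.

    Peaks are maximal runs of depth >= threshold_fold x genome mean, scored
    by their 1-kb window signal, stitched within 20 kb, and the stitched
    regions passed to the tangent-cutoff island caller. With no peaks the
    islands field is None.
    """
    track = build_normalized_track(fs, genome, resolution=resolution, target_reads=target_reads)
    min_signal = threshold_fold * track.genome_mean()
    raw_peaks = call_peaks_threshold(
        track, control=control, min_signal=min_signal, min_len=min_len, merge_gap=merge_gap_peaks
    )
    peaks = score_peaks(track, raw_peaks, window=window, mode="window")
    islands = None
    if peaks:
        regions = merge_peaks_into_regions(peaks, gap=stitch_gap)
        islands = call_islands(regions)
    return PipelineResult(track=track, peaks=peaks, islands=islands)
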