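"""Fragment reconstruction and normalized coverage tracks.

The assay recovers whole precipitated fragments from paired-end alignments
by filling the gap between mates. Fragment pileups are binned (default
10 bp) and scaled to a common library size of 10 million fragments so that
signal is comparable across samples; per-locus signal is then the mean
normalized depth in a 1-kb window centered on the locus.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Genome, GenomicInterval, Peak, ReadPair

DEFAULT_RESOLUTION = 10
DEFAULT_TARGET_READS = 10_000_000
DEFAULT_WINDOW = 1000


@dataclass
class FragmentSet:
    """A set of sequenced fragments from one library."""

    fragments: list[GenomicInterval]
    label: str = ""
    n_improper_dropped: int = 0
    n_duplicates_removed: int = 0

    @property
    def library_size(self) -> int:
        return len(self.fragments)

    @property
    def total_bases(self) -> int:
        return sum(f.length for f in self.fragments)


@dataclass
class CoverageTrack:
    """Per-chromosome normalized depth at a fixed bin resolution.

    ``values[chrom][b]`` is the mean per-base fragment depth over bin b,
    already multiplied by ``scale_factor``. The final bin of a chromosome
    may be narrower than ``resolution``; bin widths are honoured wherever
    mass is integrated.
    """

    genome: Genome
    values: dict[str, np.ndarray]
    resolution: int
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        for chrom in self.genome:
            expect = self.genome.n_bins(chrom, self.resolution)
            got = self.values[chrom].size
            if got != expect:
                raise ValueError(f"{chrom}: expected {expect} bins, got {got}")

    def bin_widths(self, chrom: str) -> np.ndarray:
        n = self.values[chrom].size
        widths = np.full(n, self.resolution, dtype=float)
        if n:
            widths[-1] = self.genome[chrom] - (n - 1) * self.resolution
        return widths

    def total_mass(self) -> float:
        """Integral of the track over the genome (signal x bp)."""
        return float(
            sum((self.values[c] * self.bin_widths(c)).sum() for c in self.genome)
        )

    def genome_mean(self) -> float:
        return self.total_mass() / self.genome.total_length

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of per-base signal over [start, end), clipped to bounds."""
        chrom_len = self.genome[chrom]
        start, end = max(0, start), min(end, chrom_len)
        if end <= start:
            return 0.0
        res = self.resolution
        vals = self.values[chrom]
        b0, b1 = start // res, (end - 1) // res
        if b0 == b1:
            return float(vals[b0]) * (end - start)
        total = float(vals[b0]) * ((b0 + 1) * res - start)
        total += float(vals[b1]) * (end - b1 * res)
        if b1 > b0 + 1:
            total += float(vals[b0 + 1 : b1].sum()) * res
        return total

    def region_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base signal over the in-bounds part of [start, end)."""
        chrom_len = self.genome[chrom]
        s, e = max(0, start), min(end, chrom_len)
        if e <= s:
            return 0.0
        return self.region_sum(chrom, s, e) / (e - s)


@dataclass
class CompositeMatrix:
    """Tiled mean-signal matrix around a set of centers.

    Rows are centers, columns are ``2*flank/bin`` tiles read left to right;
    ``column_means`` is the composite profile over rows.
    """

    centers: list[tuple[str, int]]
    flank: int
    bin: int
    matrix: np.ndarray

    @property
    def column_means(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def reconstruct_fragments(pairs: list[ReadPair], label: str = "") -> FragmentSet:
    """Fill the gap between paired reads to recover whole fragments.

    Each proper pair yields one fragment spanning the minimum mate start to
    the maximum mate end. Improper pairs (different chromosomes or flagged
    improper) are dropped and counted on the returned FragmentSet.
    """
    fragments: list[GenomicInterval] = []
    dropped = 0
    for rp in pairs:
        if not rp.proper_pair:
            dropped += 1
            continue
        start, end = rp.span
        fragments.append(GenomicInterval(rp.chrom, start, end))
    return FragmentSet(fragments=fragments, label=label, n_improper_dropped=dropped)


def deduplicate_fragments(fs: FragmentSet) -> FragmentSet:
    """Collapse fragments with identical (chrom, start, end) to one copy.

    This is the paired-end analogue of coordinate-based duplicate marking:
    a PCR duplicate reproduces both fragment ends exactly.
    """
    seen: set[tuple[str, int, int]] = set()
    kept: list[GenomicInterval] = []
    for f in fs.fragments:
        key = (f.chrom, f.start, f.end)
        if key in seen:
            continue
        seen.add(key)
        kept.append(f)
    return FragmentSet(
        fragments=kept,
        label=fs.label,
        n_improper_dropped=fs.n_improper_dropped,
        n_duplicates_removed=fs.library_size - len(kept),
    )


def extend_reads(
    reads: list[GenomicInterval],
    length: int = 200,
    genome: Genome | None = None,
    label: str = "",
) -> FragmentSet:
    """Extend single-end reads to an approximate fragment length.

    A + strand read becomes [start, start+length); a - strand read becomes
    [end-length, end), clipped at chromosome bounds when a genome is given.
    """
    fragments = []
    for r in reads:
        if r.strand == "+":
            start, end = r.start, r.start + length
        elif r.strand == "-":
            start, end = r.end - length, r.end
        else:
            raise ValueError(f"read {r} has no strand; cannot extend")
        if genome is not None:
            start = max(0, start)
            end = min(end, genome[r.chrom])
        else:
            start = max(0, start)
        fragments.append(GenomicInterval(r.chrom, start, end, r.strand))
    return FragmentSet(fragments=fragments, label=label)


def build_normalized_track(
    fs: FragmentSet,
    genome: Genome,
    resolution: int = DEFAULT_RESOLUTION,
    target_reads: int = DEFAULT_TARGET_READS,
) -> CoverageTrack:
    """Bin the full-body fragment pileup and scale to a common library size.

    scale_factor = target_reads / library_size, so the track integral equals
    scale_factor times the summed fragment lengths regardless of depth.
    """
    if fs.library_size == 0:
        raise ValueError("cannot normalize an empty fragment set")
    scale = target_reads / fs.library_size
    per_chrom_frags: dict[str, list[GenomicInterval]] = {c: [] for c in genome}
    for f in fs.fragments:
        if f.chrom not in genome:
            raise ValueError(f"fragment {f} not on genome")
        if f.end > genome[f.chrom]:
            raise ValueError(f"fragment {f} beyond chromosome end")
        per_chrom_frags[f.chrom].append(f)
    values: dict[str, np.ndarray] = {}
    for chrom in genome:
        chrom_len = genome[chrom]
        frags = per_chrom_frags[chrom]
        diff = np.zeros(chrom_len + 1)
        if frags:
            starts = np.fromiter((f.start for f in frags), dtype=np.int64, count=len(frags))
            ends = np.fromiter((f.end for f in frags), dtype=np.int64, count=len(frags))
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        depth = np.cumsum(diff[:-1])
        edges = np.arange(0, chrom_len, resolution)
        sums = np.add.reduceat(depth, edges)
        widths = np.minimum(resolution, chrom_len - edges)
        values[chrom] = sums / widths * scale
    return CoverageTrack(genome=genome, values=values, resolution=resolution, scale_factor=scale)


def window_signal(
    track: CoverageTrack,
    locus: GenomicInterval | tuple[str, int],
    window: int = DEFAULT_WINDOW,
) -> float:
    """Mean normalized depth in a window centered on a locus midpoint.

    Overhang beyond the chromosome is excluded from the mean rather than
    zero-padded; a window entirely outside covered territory returns 0.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if isinstance(locus, GenomicInterval):
        chrom, center = locus.chrom, locus.midpoint
    else:
        chrom, center = locus
    if chrom not in track.genome:
        raise ValueError(f"chromosome {chrom!r} not in track genome")
    start = center - window // 2
    return track.region_mean(chrom, start, start + window)


def score_peaks(
    track: CoverageTrack,
    peaks: list[Peak],
    window: int = DEFAULT_WINDOW,
    mode: str = "window",
) -> list[Peak]:
    """Attach per-peak signal: 1-kb window mean (default) or integrated depth."""
    if mode not in {"window", "integrated"}:
        raise ValueError("mode must be 'window' or 'integrated'")
    out = []
    for p in peaks:
        if mode == "window":
            s = window_signal(track, p.interval, window=window)
        else:
            s = track.region_sum(p.chrom, p.start, p.end)
        out.append(Peak(interval=p.interval, signal=s, qvalue=p.qvalue, name=p.name, score=p.score))
    return out


def composite_matrix(
    track: CoverageTrack,
    centers: list[GenomicInterval],
    flank: int = 5000,
    bin: int = 100,
    strand_aware: bool = False,
) -> CompositeMatrix:
    """Tiled mean-signal matrix over +/- ``flank`` around interval midpoints.

    Each cell is the mean track value over its ``bin``-bp tile; with
    ``strand_aware`` rows on the - strand are reversed so columns read
    5'->3'. Centers on chromosomes absent from the track are dropped with
    a warning.
    """
    if flank % bin != 0:
        raise ValueError("bin must divide flank")
    n_cols = 2 * flank // bin
    rows = []
    kept_centers: list[tuple[str, int]] = []
    for iv in centers:
        if iv.chrom not in track.genome:
            warnings.warn(f"composite_matrix: dropping center on unknown chromosome {iv.chrom!r}")
            continue
        c = iv.midpoint
        row = np.empty(n_cols)
        for j in range(n_cols):
            t0 = c - flank + j * bin
            row[j] = track.region_mean(iv.chrom, t0, t0 + bin)
        if strand_aware and iv.strand == "-":
            row = row[::-1]
        rows.append(row)
        kept_centers.append((iv.chrom, c))
    matrix = np.vstack(rows) if rows else np.empty((0, n_cols))
    return CompositeMatrix(centers=kept_centers, flank=flank, bin=bin, matrix=matrix)


def call_peaks_threshold(
    track: CoverageTrack,
    control: CoverageTrack | None = None,
    min_signal: float = 1.0,
    min_len: int = 200,
    merge_gap: int = 100,
) -> list[Peak]:
    """Simple threshold peak caller over (signal - control) binned depth.

    Maximal runs of bins at or above ``min_signal`` are reported after
    bridging sub-threshold gaps of at most ``merge_gap`` bp and discarding
    runs shorter than ``min_len`` bp. Peak signal is the integrated
    normalized depth over the run. Intended for synthetic end-to-end runs,
    not as a model-based caller.
    """
    if control is not None and (
        control.genome != track.genome or control.resolution != track.resolution
    ):
        raise ValueError("control track must share genome and resolution")
    res = track.resolution
    gap_bins = merge_gap // res
    peaks: list[Peak] = []
    for chrom in track.genome:
        sig = track.values[chrom]
        if control is not None:
            sig = sig - control.values[chrom]
        above = sig >= min_signal
        if not above.any():
            continue
        # run boundaries over the boolean mask
        padded = np.concatenate(([False], above, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        # bridge short gaps
        merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= gap_bins:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        chrom_len = track.genome[chrom]
        for b0, b1 in merged:
            gstart, gend = b0 * res, min(b1 * res, chrom_len)
            if gend - gstart < min_len:
                continue
            widths = np.minimum(res, chrom_len - np.arange(b0, b1) * res)
            integrated = float((sig[b0:b1] * widths).sum())
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, gstart, gend),
                    signal=max(integrated, 0.0),
                    name=f"peak_{chrom}_{gstart}",
                )
            )
    return peaks
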