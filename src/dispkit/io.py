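"""Readers and writers for the plain-text genomic formats the toolkit speaks.

Supported: BED3/6, narrowPeak, broadPeak, BEDPE, bedGraph, SAM (via pysam,
coordinates/flags only) and two-column chrom-sizes files. All coordinates
are interpreted as 0-based half-open on read and written back the same way.

The narrowPeak/broadPeak q-value column stores -log10(q) per the UCSC
definition; readers convert it to the q-value proper, so a column value of
5.0 becomes q = 1e-5.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .core import GenomicInterval, Peak, ReadPair

_FORMATS = {"bed", "narrowpeak", "broadpeak", "bedpe"}


class FormatError(ValueError):
    """A malformed line in a genomic text file; the message names the line."""


def _parse_coords(fields: Sequence[str], path, lineno: int) -> tuple[str, int, int]:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: line {lineno}: malformed record: {exc}") from exc
    if end <= start:
        raise FormatError(f"{path}: line {lineno}: end ({end}) <= start ({start})")
    return chrom, start, end


def _neg_log10_to_q(value: float) -> float | None:
    # -1 is the conventional missing marker in MACS output columns
    return None if value < 0 else 10.0 ** (-value)


def read_intervals(path, format: str = "bed"):
    """Read a BED-family file.

    Returns GenomicInterval for ``bed``, Peak for ``narrowpeak``/``broadpeak``
    (score and q-value retained), ReadPair for ``bedpe``. Input order is
    preserved; header/track/comment lines are skipped.
    """
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_FORMATS)}")
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "bedpe":
                records.append(_parse_bedpe_line(fields, path, lineno))
                continue
            chrom, start, end = _parse_coords(fields, path, lineno)
            if fmt == "bed":
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
                records.append(GenomicInterval(chrom, start, end, strand))
                continue
            # narrowPeak: 10 columns, broadPeak: 9; both carry
            # name/score/strand/signalValue/pValue/qValue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            try:
                score = float(fields[4]) if len(fields) > 4 else None
                signal = float(fields[6]) if len(fields) > 6 else 0.0
                qcol = float(fields[8]) if len(fields) > 8 else -1.0
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: malformed record: {exc}") from exc
            records.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    signal=max(signal, 0.0),
                    qvalue=_neg_log10_to_q(qcol),
                    name=name,
                    score=score,
                )
            )
    return records


def _parse_bedpe_line(fields: Sequence[str], path, lineno: int) -> ReadPair:
    if len(fields) < 6:
        raise FormatError(f"{path}: line {lineno}: BEDPE needs >= 6 columns")
    c1, s1, e1 = _parse_coords(fields[0:3], path, lineno)
    c2, s2, e2 = _parse_coords(fields[3:6], path, lineno)
    name = fields[6] if len(fields) > 6 else ""
    if c1 != c2:
        # inter-chromosomal pairs are carried but flagged improper
        return ReadPair(c1, s1, e1, s2, e2, proper_pair=False, name=name)
    return ReadPair(c1, s1, e1, s2, e2, proper_pair=True, name=name)


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    """BED6+ with signal in column 5 slot's neighbour: name, signal, strand."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name or f"peak_{i + 1}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.signal:.6g}\t.\n")


def write_bedpe(pairs: Iterable[ReadPair], path) -> None:
    with open(path, "w") as fh:
        for i, rp in enumerate(pairs):
            name = rp.name or f"pair_{i + 1}"
            fh.write(
                f"{rp.chrom}\t{rp.mate1_start}\t{rp.mate1_end}"
                f"\t{rp.chrom}\t{rp.mate2_start}\t{rp.mate2_end}\t{name}\n"
            )


def read_sam_pairs(path) -> list[ReadPair]:
    """Extract proper read pairs from a SAM file (coordinates and flags only).

    Primary alignments are paired by query name; pairs whose mates map to
    different chromosomes or with the proper-pair flag unset are returned
    with ``proper_pair=False`` so downstream code can drop and count them.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[ReadPair] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            same_chrom = mate.reference_name == aln.reference_name
            proper = bool(aln.is_proper_pair and mate.is_proper_pair and same_chrom)
            first, second = (mate, aln) if mate.reference_start <= aln.reference_start else (aln, mate)
            pairs.append(
                ReadPair(
                    chrom=first.reference_name,
                    mate1_start=first.reference_start,
                    mate1_end=first.reference_end,
                    mate2_start=second.reference_start,
                    mate2_end=second.reference_end,
                    proper_pair=proper,
                    name=aln.query_name,
                )
            )
    return pairs


def write_bedgraph(track, path, name: str = "track") -> None:
    """Write a CoverageTrack as bedGraph, collapsing equal-value runs.

    Zero-valued runs are omitted (bedGraph convention: absent means 0), so
    an all-zero track yields a header-only file. Values are printed with
    Python's shortest round-trip float repr, making read->write->read exact.
    """
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name={name}\n")
        for chrom in track.genome:
            values = track.values[chrom]
            if values.size == 0:
                continue
            chrom_len = track.genome[chrom]
            res = track.resolution
            # run-length encode over bins
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for b0, b1 in zip(starts, ends):
                v = values[b0]
                if v == 0:
                    continue
                gstart = int(b0) * res
                gend = min(int(b1) * res, chrom_len)
                fh.write(f"{chrom}\t{gstart}\t{gend}\t{float(v)!r}\n")


def read_bedgraph(path, genome, resolution: int, scale_factor: float = 1.0):
    """Read a bedGraph written at a known bin resolution back into a track.

    Line boundaries must align to the resolution grid (as produced by
    ``write_bedgraph``); unlisted bins are zero.
    """
    from .coverage import CoverageTrack

    values = {c: np.zeros(genome.n_bins(c, resolution)) for c in genome}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = _parse_coords(fields, path, lineno)
            if chrom not in genome:
                raise FormatError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
            if end > genome[chrom]:
                raise FormatError(f"{path}: line {lineno}: interval beyond chromosome end")
            value = float(fields[3])
            b0, b1 = start // resolution, -(-end // resolution)
            values[chrom][b0:b1] = value
    return CoverageTrack(genome=genome, values=values, resolution=resolution, scale_factor=scale_factor)


def overlap_flags(
    query: list[GenomicInterval],
    subject: list[GenomicInterval],
    min_bp: int = 1,
) -> tuple[list[bool], list[int]]:
    """Per-query overlap flag and count against a subject interval set.

    A query is flagged when some subject interval shares at least ``min_bp``
    bases with it. Symmetric counts are available by swapping arguments.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for iv in subject:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    flags: list[bool] = []
    counts: list[int] = []
    for q in query:
        tree = trees.get(q.chrom)
        n = 0
        if tree is not None:
            for hit in tree.overlap(q.start, q.end):
                if min(q.end, hit.end) - max(q.start, hit.begin) >= min_bp:
                    n += 1
        flags.append(n > 0)
        counts.append(n)
    return flags, counts


def intervals_of(records) -> list[GenomicInterval]:
    """Coerce a mixed list of Peak/MergedRegion/GenomicInterval to intervals."""
    out = []
    for r in records:
        out.append(r if isinstance(r, GenomicInterval) else r.interval)
    return out
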