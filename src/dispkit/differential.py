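"""Two-condition comparison of peaks and islands.

Covers the knockdown-style analyses: a union peak table with replicate-
averaged window signals, fold-change classification, lost/gained island
sets, the four island patterns (lost with/without an anchor factor;
gained with/without an up-regulated partner factor), distance-stratified
co-binding changes, and island-to-gene association with expression filters.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval, MergedRegion, Peak, merge_intervals
from .coverage import CoverageTrack, window_signal
from .io import intervals_of, overlap_flags

DEFAULT_FOLD = 2.0
DEFAULT_PSEUDOCOUNT = 1.0
DISTANCE_BINS = ((0, 150), (150, 1000), (1000, 5000), (5000, None))


@dataclass
class DifferentialPeak:
    """A union site with replicate-averaged signals in both conditions."""

    interval: GenomicInterval
    signal_a: float
    signal_b: float
    fold: float
    klass: str  # up / down / unchanged

    @property
    def change(self) -> float:
        return self.signal_b - self.signal_a


@dataclass
class IslandPattern:
    island: MergedRegion
    direction: str  # lost / gained
    pattern: str  # A / B / C / D


def build_union_signal_table(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    tracks_a: list[CoverageTrack],
    tracks_b: list[CoverageTrack],
    window: int = 1000,
) -> pd.DataFrame:
    """Union peak set with per-condition replicate-averaged window signals.

    Peaks from both conditions are pooled and overlap-collapsed into single
    sites; per condition the signal is the mean over replicates of the 1-kb
    window signal at the site midpoint.
    """
    if not tracks_a or not tracks_b:
        raise ValueError("need at least one replicate track per condition")
    genome = tracks_a[0].genome
    for t in tracks_a + tracks_b:
        if t.genome != genome:
            raise ValueError("replicate tracks are on different genomes")
    sites = merge_intervals(intervals_of(peaks_a) + intervals_of(peaks_b), gap=-1)
    rows = []
    for iv in sites:
        sa = float(np.mean([window_signal(t, iv, window=window) for t in tracks_a]))
        sb = float(np.mean([window_signal(t, iv, window=window) for t in tracks_b]))
        rows.append((iv.chrom, iv.start, iv.end, sa, sb))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal_a", "signal_b"])


def classify_differential_peaks(
    table: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DifferentialPeak]:
    """Classify union sites as up/down/unchanged by a strict fold rule.

    up when (b + eps)/(a + eps) > fold_threshold, down when the ratio is
    below 1/fold_threshold; changes of exactly the threshold fold are
    unchanged ("greater than twofold").
    """
    out = []
    for row in table.itertuples(index=False):
        a, b = float(row.signal_a), float(row.signal_b)
        if a < 0 or b < 0:
            raise ValueError(f"negative signal at {row.chrom}:{row.start}-{row.end}")
        num, den = b + pseudocount, a + pseudocount
        if den == 0:
            ratio = float("inf") if num > 0 else 1.0
        else:
            ratio = num / den
        if ratio > fold_threshold:
            klass = "up"
        elif ratio < 1.0 / fold_threshold:
            klass = "down"
        else:
            klass = "unchanged"
        out.append(
            DifferentialPeak(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                signal_a=a,
                signal_b=b,
                fold=ratio,
                klass=klass,
            )
        )
    return out


def diff_island_sets(
    islands_a: list[MergedRegion], islands_b: list[MergedRegion]
) -> tuple[list[MergedRegion], list[MergedRegion]]:
    """Condition-specific islands: lost (A-only) and gained (B-only).

    An island is lost when it overlaps (>= 1 bp) no island of the other
    condition, and vice versa for gained.
    """
    ivs_a, ivs_b = intervals_of(islands_a), intervals_of(islands_b)
    flags_a, _ = overlap_flags(ivs_a, ivs_b)
    flags_b, _ = overlap_flags(ivs_b, ivs_a)
    lost = [r for r, hit in zip(islands_a, flags_a) if not hit]
    gained = [r for r, hit in zip(islands_b, flags_b) if not hit]
    return lost, gained


def classify_island_patterns(
    lost: list[MergedRegion],
    gained: list[MergedRegion],
    anchor_peaks: list[Peak],
    partner_diff: list[DifferentialPeak],
) -> list[IslandPattern]:
    """Subdivide lost/gained islands by their factor content.

    Lost islands: pattern A when they overlap at least one anchor-factor
    peak, else B. Gained islands: pattern C when they overlap at least one
    partner peak classified up (> twofold increase), else D.
    """
    anchors = intervals_of(anchor_peaks)
    up_partners = [dp.interval for dp in partner_diff if dp.klass == "up"]
    out: list[IslandPattern] = []
    if lost:
        flags, _ = overlap_flags(intervals_of(lost), anchors)
        out.extend(
            IslandPattern(r, "lost", "A" if hit else "B") for r, hit in zip(lost, flags)
        )
    if gained:
        flags, _ = overlap_flags(intervals_of(gained), up_partners)
        out.extend(
            IslandPattern(r, "gained", "C" if hit else "D") for r, hit in zip(gained, flags)
        )
    return out


def stratify_changes_by_distance(
    subjects: list[DifferentialPeak],
    anchors: list[Peak],
    island_membership: list[bool],
    bins=DISTANCE_BINS,
) -> pd.DataFrame:
    """Group subject signal changes by nearest-anchor distance and island flag.

    Distance is edge-to-edge (0 for overlap) and bins are closed on the
    left, open on the right; the last bin is unbounded. For each
    (bin, membership) group the median change (condition B minus A) and n
    are reported, plus a two-sided two-sample t-test between in-island and
    out-of-island changes within the bin.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    if len(island_membership) != len(subjects):
        raise ValueError("island_membership must align with subjects")
    anchor_by_chrom: dict[str, list[Peak]] = {}
    for a in anchors:
        anchor_by_chrom.setdefault(a.chrom, []).append(a)
    dists = []
    for s in subjects:
        cands = anchor_by_chrom.get(s.interval.chrom, [])
        d = min((s.interval.distance(a.interval) for a in cands), default=None)
        dists.append(d)
    rows = []
    for lo, hi in bins:
        in_bin = [
            i
            for i, d in enumerate(dists)
            if d is not None and d >= lo and (hi is None or d < hi)
        ]
        changes = {True: [], False: []}
        for i in in_bin:
            changes[bool(island_membership[i])].append(subjects[i].change)
        if changes[True] and changes[False]:
            pvalue = float(stats.ttest_ind(changes[True], changes[False]).pvalue)
        else:
            pvalue = float("nan")
        label = f"{lo}-{hi}" if hi is not None else f">={lo}"
        for member in (True, False):
            vals = changes[member]
            rows.append(
                {
                    "distance_bin": label,
                    "in_island": member,
                    "n": len(vals),
                    "median_change": float(np.median(vals)) if vals else float("nan"),
                    "ttest_p": pvalue,
                }
            )
    return pd.DataFrame(rows)


def link_islands_to_genes(
    islands: list[MergedRegion],
    genes: pd.DataFrame,
    flank: int = 100_000,
    up_fold: float = 2.0,
    min_expr: float = 5.0,
) -> pd.DataFrame:
    """Associate islands with nearby up-regulated genes.

    ``genes`` needs columns gene, chrom, start, end, expr_a, expr_b. A gene
    is linked when its interval lies within ``flank`` bp of the island span
    (edge-to-edge, overlap = 0) and retained when expr_b/expr_a >= up_fold
    and expr_b >= min_expr (both inclusive). Returns one row per retained
    (island, gene) pair.
    """
    required = {"gene", "chrom", "start", "end", "expr_a", "expr_b"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"genes table missing columns: {sorted(missing)}")
    rows = []
    for r in islands:
        for g in genes.itertuples(index=False):
            if g.chrom != r.interval.chrom:
                continue
            giv = GenomicInterval(g.chrom, int(g.start), int(g.end))
            if r.interval.distance(giv) > flank:
                continue
            a, b = float(g.expr_a), float(g.expr_b)
            fold = b / a if a > 0 else float("inf") if b > 0 else 0.0
            if fold >= up_fold and b >= min_expr:
                rows.append(
                    {
                        "island_chrom": r.interval.chrom,
                        "island_start": r.interval.start,
                        "island_end": r.interval.end,
                        "gene": g.gene,
                        "fold": fold,
                        "expr_b": b,
                    }
                )
    return pd.DataFrame(rows, columns=["island_chrom", "island_start", "island_end", "gene", "fold", "expr_b"])


def filter_differential_genes(
    expression: pd.DataFrame, fold: float = 1.5, p_max: float = 0.05
) -> pd.DataFrame:
    """Flag differentially expressed genes from a precomputed fit table.

    ``expression`` needs columns gene, fold (expression ratio b/a) and p.
    Differential when the fold change reaches ``fold`` in either direction
    (inclusive) and p < p_max; direction is up or down by the fold side.
    """
    for col in ("gene", "fold", "p"):
        if col not in expression.columns:
            raise ValueError(f"expression table missing column {col!r}")
    out = expression.copy()
    up = (out["fold"] >= fold) & (out["p"] < p_max)
    down = (out["fold"] <= 1.0 / fold) & (out["p"] < p_max)
    out["differential"] = up | down
    out["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return out
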