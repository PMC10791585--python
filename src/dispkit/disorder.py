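"""Disorder-content statistics for precipitated proteomes.

The chemical precipitation enriches proteins with intrinsically disordered
regions (IDRs). This module calls IDRs from per-residue disorder scores
(>= 0.5 over at least 50 consecutive residues), summarises total disorder
length per protein (large-IDR proteins have > 100 disordered residues),
tests enrichment of a precipitated set against the proteome by size-matched
permutation subsampling, and compares amino-acid composition of IDR
sequences between a foreground and a background set.

Residue intervals are 1-based inclusive in files (the biological
convention) and 0-based half-open internally.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_MIN_IDR_LEN = 50
DEFAULT_LARGE_IDR = 100
DEFAULT_N_PERM = 3000
NUCLEAR_LABEL = "Nucleus"


@dataclass
class ProteinRecord:
    """A protein with disorder-region annotations.

    ``regions`` are 0-based half-open residue intervals, normalized
    (merged, sorted) on construction. ``nuclear`` is set from an external
    localization table when available.
    """

    id: str
    length: int
    regions: list[tuple[int, int]] = field(default_factory=list)
    sequence: str | None = None
    nuclear: bool | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.id}: protein length must be > 0")
        for start, end in self.regions:
            if start < 0 or end > self.length or end <= start:
                raise ValueError(
                    f"{self.id}: region [{start}, {end}) outside protein of length {self.length}"
                )
        self.regions = merge_residue_intervals(self.regions)
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.id}: sequence length != annotated length")

    @classmethod
    def from_one_based(
        cls, id: str, length: int, regions_1based: Iterable[tuple[int, int]], **kw
    ) -> "ProteinRecord":
        """Build from 1-based inclusive residue intervals (file convention)."""
        regions = [(s - 1, e) for s, e in regions_1based]
        return cls(id=id, length=length, regions=regions, **kw)

    def idr_sequences(self) -> list[str]:
        if self.sequence is None:
            raise ValueError(f"{self.id}: no sequence available")
        return [self.sequence[s:e] for s, e in self.regions]


@dataclass
class PermutationResult:
    p_empirical: float
    z: float
    p_normal: float
    p_ranksum: float
    observed_stat: float
    perm_mean: float
    perm_sd: float
    n_perm: int
    seed: int


@dataclass
class DisorderSummary:
    n_proteins: int
    median_total_idr_length: float
    large_idr_fraction: float
    large_threshold: int
    permutation: PermutationResult | None = None


def merge_residue_intervals(regions: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of residue intervals: sorted, overlap/abutment collapsed."""
    merged: list[list[int]] = []
    for start, end in sorted(regions):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def call_idr_regions_from_scores(
    scores,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
    min_len: int = DEFAULT_MIN_IDR_LEN,
) -> list[tuple[int, int]]:
    """Call IDRs as runs of per-residue scores >= threshold, >= min_len long.

    A score exactly at the threshold is part of a run ("equal to or
    higher"); runs shorter than ``min_len`` residues are discarded. Returns
    0-based half-open residue intervals.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        return []
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    above = arr >= threshold
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def total_disorder_length(protein: ProteinRecord) -> int:
    """Total disordered residues (regions are already a merged union)."""
    return sum(e - s for s, e in protein.regions)


def disorder_summary(
    proteins: list[ProteinRecord], large_threshold: int = DEFAULT_LARGE_IDR
) -> DisorderSummary:
    """Median total IDR length and large-IDR fraction (strictly > threshold)."""
    if not proteins:
        raise ValueError("no proteins")
    totals = np.array([total_disorder_length(p) for p in proteins], dtype=float)
    return DisorderSummary(
        n_proteins=len(proteins),
        median_total_idr_length=float(np.median(totals)),
        large_idr_fraction=float(np.mean(totals > large_threshold)),
        large_threshold=large_threshold,
    )


def _statistic_fn(statistic: str, large_threshold: int) -> Callable[[np.ndarray], np.ndarray]:
    if statistic == "median":
        return lambda x: np.median(x, axis=-1)
    if statistic == "large_fraction":
        return lambda x: np.mean(x > large_threshold, axis=-1)
    raise ValueError("statistic must be 'median' or 'large_fraction'")


def permutation_enrichment_test(
    observed: list[ProteinRecord],
    background: list[ProteinRecord],
    statistic: str = "median",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    large_threshold: int = DEFAULT_LARGE_IDR,
) -> PermutationResult:
    """Size-matched permutation test of disorder enrichment.

    Draws ``n_perm`` samples of len(observed) proteins without replacement
    from the background proteome and compares the chosen statistic (median
    total IDR length, or large-IDR fraction). The one-sided empirical p
    uses the add-one rule, p = (1 + #{perm >= observed}) / (n_perm + 1),
    so it is never exactly zero; a z-score against the permutation null and
    a rank-sum p on the underlying lengths are reported alongside.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_obs, n_bg = len(observed), len(background)
    if n_obs == 0:
        raise ValueError("observed set is empty")
    if n_bg < n_obs:
        raise ValueError("background must be at least as large as observed")
    obs_lengths = np.array([total_disorder_length(p) for p in observed], dtype=float)
    bg_lengths = np.array([total_disorder_length(p) for p in background], dtype=float)
    fn = _statistic_fn(statistic, large_threshold)
    observed_stat = float(fn(obs_lengths))
    rng = np.random.default_rng(seed)
    # uniform subsets without replacement, vectorized: the n_obs smallest
    # of i.i.d. uniforms per row index a uniform random subset
    keys = rng.random((n_perm, n_bg))
    idx = np.argpartition(keys, n_obs - 1, axis=1)[:, :n_obs]
    perm_stats = fn(bg_lengths[idx])
    perm_mean = float(perm_stats.mean())
    perm_sd = float(perm_stats.std(ddof=1)) if n_perm > 1 else 0.0
    p_emp = (1.0 + float(np.sum(perm_stats >= observed_stat))) / (n_perm + 1.0)
    z = (observed_stat - perm_mean) / perm_sd if perm_sd > 0 else float("nan")
    p_normal = float(stats.norm.sf(z)) if np.isfinite(z) else float("nan")
    p_ranksum = float(
        stats.mannwhitneyu(obs_lengths, bg_lengths, alternative="greater").pvalue
    )
    return PermutationResult(
        p_empirical=p_emp,
        z=z,
        p_normal=p_normal,
        p_ranksum=p_ranksum,
        observed_stat=observed_stat,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        n_perm=n_perm,
        seed=seed,
    )


def aa_composition_enrichment(
    foreground_idr_sequences: list[str],
    background_idr_sequences: list[str],
    floor: float = 1e-4,
) -> pd.DataFrame:
    """Per-amino-acid frequency in IDR sequences and foreground/background
    log2 ratio.

    Frequencies are over the 20 canonical residues and sum to 1 in each
    set; other letters are counted but excluded. The ``floor`` bounds both
    frequencies in the ratio so absent residues give finite enrichment.
    """
    if not foreground_idr_sequences or not any(foreground_idr_sequences):
        raise ValueError("foreground IDR sequences are empty")

    def freqs(seqs: list[str]) -> tuple[np.ndarray, int]:
        counts = {aa: 0 for aa in AMINO_ACIDS}
        other = 0
        for seq in seqs:
            for ch in seq.upper():
                if ch in counts:
                    counts[ch] += 1
                else:
                    other += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError("no canonical residues in sequence set")
        return np.array([counts[aa] / total for aa in AMINO_ACIDS]), other

    fg, fg_other = freqs(foreground_idr_sequences)
    bg, bg_other = freqs(background_idr_sequences)
    log2_ratio = np.log2(np.maximum(fg, floor) / np.maximum(bg, floor))
    return pd.DataFrame(
        {
            "aa": AMINO_ACIDS,
            "fg_freq": fg,
            "bg_freq": bg,
            "log2_ratio": log2_ratio,
        }
    )


def select_nuclear(
    proteins: list[ProteinRecord],
    localization: dict[str, set[str]] | pd.DataFrame,
    label: str = NUCLEAR_LABEL,
    strict: bool = False,
) -> list[ProteinRecord]:
    """Keep proteins whose compartment annotation includes the nuclear label.

    ``localization`` maps accession to a compartment set (or a DataFrame
    with accession/compartments columns, compartments ';'-separated).
    Accessions absent from the table are excluded with a warning, or raise
    in strict mode.
    """
    import warnings

    if isinstance(localization, pd.DataFrame):
        localization = {
            str(r.accession): {c.strip() for c in str(r.compartments).split(";") if c.strip()}
            for r in localization.itertuples(index=False)
        }
    kept = []
    for p in proteins:
        compartments = localization.get(p.id)
        if compartments is None:
            if strict:
                raise KeyError(f"accession {p.id} absent from localization table")
            warnings.warn(f"accession {p.id} absent from localization table; excluded")
            continue
        if label in compartments:
            p.nuclear = True
            kept.append(p)
        else:
            p.nuclear = False
    return kept


# --- file boundary -----------------------------------------------------------

def read_disorder_regions_tsv(path, lengths: dict[str, int] | None = None) -> list[ProteinRecord]:
    """Read (accession, start, end) disorder annotations, 1-based inclusive.

    ``lengths`` supplies protein lengths; without it the protein length is
    taken as the maximum annotated end (adequate for length statistics).
    An optional fourth column carries the protein length per row.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None).iloc[:, :4]
    df.columns = ["accession", "start", "end", "length"][: df.shape[1]]
    by_acc: dict[str, list[tuple[int, int]]] = {}
    acc_len: dict[str, int] = dict(lengths or {})
    for row in df.itertuples(index=False):
        acc = str(row.accession)
        by_acc.setdefault(acc, []).append((int(row.start), int(row.end)))
        if hasattr(row, "length") and not pd.isna(row.length):
            acc_len[acc] = int(row.length)
    records = []
    for acc, regions in by_acc.items():
        length = acc_len.get(acc, max(e for _, e in regions))
        records.append(ProteinRecord.from_one_based(acc, length, regions))
    return records


def read_scores_table(path) -> dict[str, np.ndarray]:
    """Read per-residue scores (accession, position, score; 1-based) as
    accession -> score vector."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    df.columns = ["accession", "position", "score"]
    out = {}
    for acc, grp in df.groupby("accession", sort=False):
        grp = grp.sort_values("position")
        n = int(grp["position"].max())
        vec = np.full(n, np.nan)
        vec[grp["position"].to_numpy(dtype=int) - 1] = grp["score"].to_numpy(dtype=float)
        if np.isnan(vec).any():
            raise ValueError(f"{acc}: missing positions in score table")
        out[str(acc)] = vec
    return out


def read_fasta_sequences(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
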