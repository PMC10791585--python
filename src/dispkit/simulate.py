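"""Synthetic fixtures with planted ground truth for every pipeline stage.

The genomic generator plants two feature kinds on a uniform fragment
background: isolated single peaks, and islands (clusters of peaks spaced
well under the 20-kb stitching distance, with everything else spaced well
over it). A second condition rescales planted peak enrichment per feature,
giving lost islands, gained islands and up/down single peaks with known
truth. The proteome generator draws per-protein total disorder lengths
from a lognormal calibrated so that 20% of the background exceeds 100
disordered residues (median 31), and samples a "precipitated" subset with
weight increasing in disorder length so its median lands near 138 - the
regime the permutation test is meant to detect.

Everything is deterministic under an integer seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import Genome, GenomicInterval, Peak, ReadPair
from .coverage import FragmentSet
from .differential import DifferentialPeak
from .disorder import ProteinRecord

CONDITIONS = ("A", "B")


@dataclass
class SimulationConfig:
    """Knobs for the genomic and proteome generators (units: bp, residues)."""

    # genome
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    # background fragments
    n_background_fragments: int = 50_000
    fragment_len_median: float = 200.0
    fragment_len_sigma: float = 0.25
    fragment_len_min: int = 50
    fragment_len_max: int = 600
    read_len: int = 50
    # planted features
    n_islands: int = 20
    peaks_per_island: int = 6
    intra_island_gap: tuple[int, int] = (2_000, 15_000)  # < 20-kb stitch rule
    n_single_peaks: int = 150
    peak_width_median: float = 900.0
    peak_width_sigma: float = 0.35
    peak_width_min: int = 300
    peak_width_max: int = 3_000
    enrichment: float = 10.0
    inter_feature_gap_min: int = 21_000  # > 20-kb stitch rule
    inter_feature_gap_mean: float = 15_000.0  # exponential excess over the minimum
    # two-condition design
    n_replicates: int = 2
    n_lost_islands: int = 4
    n_gained_islands: int = 4
    frac_up_singles: float = 0.15
    frac_down_singles: float = 0.15
    single_fold: float = 4.0
    island_lost_fold: float = 0.1
    # proteome
    n_background_proteins: int = 2_000
    n_precipitated: int = 150
    idr_median: float = 31.0
    idr_sigma: float = 1.3915  # P(total IDR > 100) = 0.20 at median 31
    enrichment_weight_exponent: float = 0.7716  # enriched median ~ 138
    max_regions_per_protein: int = 3
    idr_bias_residues: str = "GYK"
    idr_bias_multiplier: float = 2.0

    @property
    def genome(self) -> Genome:
        return Genome(self.chrom_sizes)

    @property
    def mean_fragment_len(self) -> float:
        return self.fragment_len_median * float(np.exp(self.fragment_len_sigma**2 / 2))

    @property
    def background_depth(self) -> float:
        """Expected per-base background fragment depth."""
        return (
            self.n_background_fragments
            * self.mean_fragment_len
            / self.genome.total_length
        )


@dataclass
class PlantedPeak:
    """A planted enrichment with its per-condition extra fragment counts."""

    interval: GenomicInterval
    kind: str  # single / island / gained_island
    island_id: int | None
    extra_a: int
    extra_b: int
    fold: float  # design fold of planted signal, condition B over A


@dataclass
class DispSimulation:
    config: SimulationConfig
    genome: Genome
    planted_peaks: list[PlantedPeak]
    truth_islands: dict[str, list[GenomicInterval]]
    fragments: dict[tuple[str, int], FragmentSet]
    planned_counts: dict[tuple[str, int], int]

    def truth_peaks(self, condition: str = "A") -> list[GenomicInterval]:
        key = "extra_a" if condition == "A" else "extra_b"
        return [p.interval for p in self.planted_peaks if getattr(p, key) > 0]

    def read_pairs(self, condition: str = "A", replicate: int = 0) -> list[ReadPair]:
        return fragments_to_pairs(self.fragments[(condition, replicate)], self.config.read_len)


def _draw_lengths(rng, n, median, sigma, lo, hi) -> np.ndarray:
    lengths = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    return np.clip(np.rint(lengths), lo, hi).astype(np.int64)


def _plan_features(config: SimulationConfig, rng) -> list[dict]:
    """Lay out islands and single peaks with the spacing rules baked in."""
    features: list[dict] = []
    lo, hi = config.intra_island_gap
    n_clusters = config.n_islands + config.n_gained_islands
    for i in range(n_clusters):
        widths = _draw_lengths(
            rng,
            config.peaks_per_island,
            config.peak_width_median,
            config.peak_width_sigma,
            config.peak_width_min,
            config.peak_width_max,
        )
        gaps = rng.integers(lo, hi + 1, size=config.peaks_per_island - 1)
        gained = i >= config.n_islands
        lost = (not gained) and i < config.n_lost_islands
        features.append(
            {
                "kind": "gained_island" if gained else "island",
                "island_id": i,
                "widths": widths,
                "gaps": gaps,
                "lost": lost,
            }
        )
    n_up = int(round(config.frac_up_singles * config.n_single_peaks))
    n_down = int(round(config.frac_down_singles * config.n_single_peaks))
    single_widths = _draw_lengths(
        rng,
        config.n_single_peaks,
        config.peak_width_median,
        config.peak_width_sigma,
        config.peak_width_min,
        config.peak_width_max,
    )
    for j in range(config.n_single_peaks):
        if j < n_up:
            fold = config.single_fold
        elif j < n_up + n_down:
            fold = 1.0 / config.single_fold
        else:
            fold = 1.0
        features.append({"kind": "single", "width": int(single_widths[j]), "fold": fold})
    rng.shuffle(features)
    return features


def _place_features(config: SimulationConfig, features: list[dict], rng) -> list[PlantedPeak]:
    genome = config.genome
    chrom_names = list(genome)
    depth = config.background_depth
    mlen = config.mean_fragment_len

    def extra_count(width: int, multiplier: float) -> int:
        return int(round((multiplier - 1.0) * depth * width / mlen))

    planted: list[PlantedPeak] = []
    chrom_idx, pos = 0, 1_000
    for feat in features:
        if feat["kind"] == "single":
            span = feat["width"]
        else:
            span = int(feat["widths"].sum() + feat["gaps"].sum())
        placed = False
        while chrom_idx < len(chrom_names):
            gap = config.inter_feature_gap_min + rng.exponential(config.inter_feature_gap_mean)
            start = pos + int(gap)
            chrom = chrom_names[chrom_idx]
            if start + span <= genome[chrom] - 1_000:
                placed = True
                break
            chrom_idx, pos = chrom_idx + 1, 1_000
        if not placed:
            raise ValueError("planted features exceed the genome; enlarge it or plant fewer")
        if feat["kind"] == "single":
            mult_a = config.enrichment
            mult_b = 1.0 + (config.enrichment - 1.0) * feat["fold"]
            iv = GenomicInterval(chrom, start, start + span)
            planted.append(
                PlantedPeak(
                    interval=iv,
                    kind="single",
                    island_id=None,
                    extra_a=extra_count(span, mult_a),
                    extra_b=extra_count(span, mult_b),
                    fold=feat["fold"],
                )
            )
        else:
            if feat["kind"] == "gained_island":
                mult_a, mult_b, fold = 1.0, config.enrichment, float("inf")
            elif feat["lost"]:
                mult_a = config.enrichment
                mult_b = 1.0 + (config.enrichment - 1.0) * config.island_lost_fold
                fold = config.island_lost_fold
            else:
                mult_a = mult_b = config.enrichment
                fold = 1.0
            cursor = start
            for k, width in enumerate(feat["widths"]):
                iv = GenomicInterval(chrom, cursor, cursor + int(width))
                planted.append(
                    PlantedPeak(
                        interval=iv,
                        kind=feat["kind"],
                        island_id=feat["island_id"],
                        extra_a=extra_count(int(width), mult_a),
                        extra_b=extra_count(int(width), mult_b),
                        fold=fold,
                    )
                )
                cursor = iv.end
                if k < len(feat["gaps"]):
                    cursor += int(feat["gaps"][k])
        pos = start + span
    return planted


def _truth_islands(planted: list[PlantedPeak]) -> dict[str, list[GenomicInterval]]:
    spans: dict[int, tuple[str, int, int, str]] = {}
    for p in planted:
        if p.island_id is None:
            continue
        chrom, s, e = p.interval.chrom, p.interval.start, p.interval.end
        if p.island_id in spans:
            c, s0, e0, kind = spans[p.island_id]
            spans[p.island_id] = (c, min(s0, s), max(e0, e), kind)
        else:
            spans[p.island_id] = (chrom, s, e, p.kind)
    truth = {"A": [], "B": []}
    for island_id in sorted(spans):
        chrom, s, e, kind = spans[island_id]
        iv = GenomicInterval(chrom, s, e)
        peaks = [p for p in planted if p.island_id == island_id]
        if kind == "island":
            truth["A"].append(iv)
            # lost islands drop below peak-calling depth in condition B
            if peaks[0].fold == 1.0:
                truth["B"].append(iv)
        else:  # gained: background in A, enriched in B
            truth["B"].append(iv)
    return truth


def _sample_fragments(config: SimulationConfig, rng, n: int, chrom_p, chrom_names, genome) -> list[GenomicInterval]:
    if n == 0:
        return []
    chroms = rng.choice(len(chrom_names), size=n, p=chrom_p)
    lengths = _draw_lengths(
        rng, n, config.fragment_len_median, config.fragment_len_sigma,
        config.fragment_len_min, config.fragment_len_max,
    )
    out = []
    for ci, ln in zip(chroms, lengths):
        chrom = chrom_names[int(ci)]
        start = int(rng.integers(0, genome[chrom] - int(ln)))
        out.append(GenomicInterval(chrom, start, start + int(ln)))
    return out


def _peak_fragments(config: SimulationConfig, rng, peak: PlantedPeak, n: int, genome) -> list[GenomicInterval]:
    if n == 0:
        return []
    iv = peak.interval
    mids = rng.integers(iv.start, iv.end, size=n)
    lengths = _draw_lengths(
        rng, n, config.fragment_len_median, config.fragment_len_sigma,
        config.fragment_len_min, config.fragment_len_max,
    )
    chrom_len = genome[iv.chrom]
    out = []
    for mid, ln in zip(mids, lengths):
        start = max(0, int(mid) - int(ln) // 2)
        end = min(chrom_len, start + int(ln))
        out.append(GenomicInterval(iv.chrom, start, end))
    return out


def simulate_disp_dataset(
    config: SimulationConfig | None = None,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
    n_replicates: int | None = None,
) -> DispSimulation:
    """Generate planted fragment libraries plus truth peaks and islands.

    Background fragments are uniform over the genome; each planted peak
    receives extra fragments bringing its local depth to the configured
    enrichment multiple, rescaled in condition B by the feature's fold.
    Replicates share the layout but draw fragments independently.
    """
    config = config or SimulationConfig()
    genome = config.genome
    layout_rng = np.random.default_rng([seed, 997])
    features = _plan_features(config, layout_rng)
    planted = _place_features(config, features, layout_rng)
    truth = _truth_islands(planted)
    chrom_names = list(genome)
    sizes = np.array([genome[c] for c in chrom_names], dtype=float)
    chrom_p = sizes / sizes.sum()
    reps = n_replicates if n_replicates is not None else config.n_replicates
    fragments: dict[tuple[str, int], FragmentSet] = {}
    planned: dict[tuple[str, int], int] = {}
    for ci, cond in enumerate(conditions):
        for rep in range(reps):
            rng = np.random.default_rng([seed, ci, rep])
            frags = _sample_fragments(
                config, rng, config.n_background_fragments, chrom_p, chrom_names, genome
            )
            total = config.n_background_fragments
            for p in planted:
                n = p.extra_a if cond == "A" else p.extra_b
                frags.extend(_peak_fragments(config, rng, p, n, genome))
                total += n
            fragments[(cond, rep)] = FragmentSet(fragments=frags, label=f"{cond}_rep{rep}")
            planned[(cond, rep)] = total
    return DispSimulation(
        config=config,
        genome=genome,
        planted_peaks=planted,
        truth_islands=truth,
        fragments=fragments,
        planned_counts=planned,
    )


def fragments_to_pairs(fs: FragmentSet, read_len: int = 50) -> list[ReadPair]:
    """Represent each fragment as a proper read pair covering its two ends."""
    pairs = []
    for f in fs.fragments:
        rl = min(read_len, f.length)
        pairs.append(
            ReadPair(
                chrom=f.chrom,
                mate1_start=f.start,
                mate1_end=f.start + rl,
                mate2_start=f.end - rl,
                mate2_end=f.end,
                proper_pair=True,
            )
        )
    return pairs


# --- proteome ----------------------------------------------------------------

@dataclass
class ProteomeSimulation:
    config: SimulationConfig
    background: list[ProteinRecord]
    precipitated: list[ProteinRecord]
    precipitated_idx: np.ndarray


def _idr_alphabet_weights(config: SimulationConfig) -> np.ndarray:
    from .disorder import AMINO_ACIDS

    w = np.ones(len(AMINO_ACIDS))
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in config.idr_bias_residues:
            w[i] = config.idr_bias_multiplier
    return w / w.sum()


def simulate_proteome(
    config: SimulationConfig | None = None,
    seed: int = 0,
    with_sequences: bool = True,
) -> ProteomeSimulation:
    """Generate a background proteome and a disorder-enriched subset.

    Total IDR length per protein is lognormal (median 31, sigma chosen so
    20% exceed 100 residues), split over 1-3 annotated regions separated by
    ordered linkers. The precipitated subset is drawn without replacement
    with weight proportional to length^exponent, shifting its median
    disorder length roughly 4.5-fold. Sequences, when generated, use a
    uniform residue alphabet for ordered segments and a composition tilted
    toward the configured residues (default G/Y/K) inside IDRs.
    """
    from .disorder import AMINO_ACIDS

    config = config or SimulationConfig()
    rng = np.random.default_rng([seed, 7919])
    n = config.n_background_proteins
    totals = _draw_lengths(rng, n, config.idr_median, config.idr_sigma, 1, 10**6)
    aa = np.array(list(AMINO_ACIDS))
    idr_w = _idr_alphabet_weights(config)
    background: list[ProteinRecord] = []
    for i in range(n):
        total = int(totals[i])
        k = int(rng.integers(1, config.max_regions_per_protein + 1))
        k = min(k, total)  # cannot split fewer residues than regions
        cuts = np.sort(rng.choice(np.arange(1, total), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        part_lens = np.diff(np.concatenate(([0], cuts, [total])))
        linkers = rng.integers(10, 200, size=k + 1)
        regions = []
        cursor = int(linkers[0])
        for j, plen in enumerate(part_lens):
            regions.append((cursor, cursor + int(plen)))
            cursor += int(plen) + int(linkers[j + 1])
        length = cursor
        sequence = None
        if with_sequences:
            chars = rng.choice(aa, size=length).astype(object)
            for s, e in regions:
                chars[s:e] = rng.choice(aa, size=e - s, p=idr_w)
            sequence = "".join(chars)
        background.append(
            ProteinRecord(id=f"P{i:05d}", length=length, regions=regions, sequence=sequence)
        )
    weights = totals.astype(float) ** config.enrichment_weight_exponent
    weights /= weights.sum()
    idx = rng.choice(n, size=config.n_precipitated, replace=False, p=weights)
    precipitated = [background[int(i)] for i in idx]
    return ProteomeSimulation(
        config=config,
        background=background,
        precipitated=precipitated,
        precipitated_idx=np.sort(idx),
    )


def draw_weighted_subset(
    proteins: list[ProteinRecord],
    n: int,
    exponent: float,
    seed: int,
) -> list[ProteinRecord]:
    """Sample proteins without replacement, weight ~ total IDR length^exponent.

    The sampling rule behind the enriched (precipitated) regime; exponent 0
    gives a uniform size-matched draw (the null regime).
    """
    from .disorder import total_disorder_length

    rng = np.random.default_rng(seed)
    totals = np.array([total_disorder_length(p) for p in proteins], dtype=float)
    weights = np.maximum(totals, 1.0) ** exponent
    weights /= weights.sum()
    idx = rng.choice(len(proteins), size=n, replace=False, p=weights)
    return [proteins[int(i)] for i in idx]


def simulate_anchor_coupling(
    seed: int = 0,
    n_subjects: int = 400,
    base_signal: float = 10.0,
    drop: float = 0.6,
    decay: float = 500.0,
    island_boost: float = 1.3,
    noise_sd: float = 0.3,
) -> tuple[list[DifferentialPeak], list[Peak], list[bool]]:
    """Anchor-coupled two-condition subjects with distance-decaying loss.

    Each subject sits a known distance from its own anchor; its condition-B
    signal drops by ``drop * exp(-distance/decay)``, amplified inside
    islands. Emulates the coordinated loss of a partner factor around an
    anchor factor, strongest within 150 bp.
    """
    rng = np.random.default_rng([seed, 31337])
    subjects: list[DifferentialPeak] = []
    anchors: list[Peak] = []
    flags: list[bool] = []
    bins = ((0, 150), (150, 1000), (1000, 5000), (5000, 20000))
    pos = 10_000
    for i in range(n_subjects):
        lo, hi = bins[i % len(bins)]
        d = int(rng.integers(lo, hi))
        in_island = bool(rng.integers(0, 2))
        anchor = Peak(interval=GenomicInterval("chr1", pos, pos + 200), signal=base_signal)
        s_start = anchor.end + d
        width = 200
        a = base_signal * float(np.exp(rng.normal(0, 0.1)))
        eff = drop * float(np.exp(-d / decay)) * (island_boost if in_island else 1.0)
        b = max(0.0, a * (1.0 - min(eff, 0.95)) + rng.normal(0, noise_sd))
        ratio = (b + 1.0) / (a + 1.0)
        klass = "up" if ratio > 2 else "down" if ratio < 0.5 else "unchanged"
        subjects.append(
            DifferentialPeak(
                interval=GenomicInterval("chr1", s_start, s_start + width),
                signal_a=a,
                signal_b=b,
                fold=ratio,
                klass=klass,
            )
        )
        anchors.append(anchor)
        flags.append(in_island)
        pos = s_start + width + 100_000  # keep subject/anchor groups independent
    return subjects, anchors, flags


# --- file output -------------------------------------------------------------

def write_disp_simulation(sim: DispSimulation, outdir) -> dict[str, str]:
    """Write BEDPE read pairs, truth BEDs and chrom sizes; returns paths."""
    import os

    from .io import write_bed, write_bedpe

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    sizes_path = os.path.join(outdir, "genome.chrom.sizes")
    with open(sizes_path, "w") as fh:
        for chrom, length in sim.genome.items():
            fh.write(f"{chrom}\t{length}\n")
    paths["chrom_sizes"] = sizes_path
    for (cond, rep), fs in sim.fragments.items():
        p = os.path.join(outdir, f"reads_{cond}_rep{rep}.bedpe")
        write_bedpe(fragments_to_pairs(fs, sim.config.read_len), p)
        paths[f"bedpe_{cond}_rep{rep}"] = p
    for cond in ("A", "B"):
        p = os.path.join(outdir, f"truth_peaks_{cond}.bed")
        write_bed(sim.truth_peaks(cond), p)
        paths[f"truth_peaks_{cond}"] = p
        p = os.path.join(outdir, f"truth_islands_{cond}.bed")
        write_bed(sim.truth_islands[cond], p)
        paths[f"truth_islands_{cond}"] = p
    return paths


def write_proteome_simulation(sim: ProteomeSimulation, outdir) -> dict[str, str]:
    """Write proteome FASTA, disorder-region TSV and precipitated-set list."""
    import os

    os.makedirs(outdir, exist_ok=True)
    fasta = os.path.join(outdir, "proteome.fasta")
    with open(fasta, "w") as fh:
        for p in sim.background:
            if p.sequence is None:
                continue
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    tsv = os.path.join(outdir, "disorder_regions.tsv")
    with open(tsv, "w") as fh:
        for p in sim.background:
            for s, e in p.regions:  # back to 1-based inclusive at the boundary
                fh.write(f"{p.id}\t{s + 1}\t{e}\t{p.length}\n")
    sel = os.path.join(outdir, "precipitated_ids.txt")
    with open(sel, "w") as fh:
        for p in sim.precipitated:
            fh.write(p.id + "\n")
    return {"fasta": fasta, "regions_tsv": tsv, "precipitated_ids": sel}
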