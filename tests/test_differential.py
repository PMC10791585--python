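"""Two-condition comparison: union table, fold classes, island patterns."""
import numpy as np
import pandas as pd
import pytest

from dispkit.core import Genome, GenomicInterval, MergedRegion, Peak
from dispkit.coverage import CoverageTrack
from dispkit.differential import (
    DifferentialPeak,
    build_union_signal_table,
    classify_differential_peaks,
    classify_island_patterns,
    diff_island_sets,
    filter_differential_genes,
    link_islands_to_genes,
    stratify_changes_by_distance,
)
from dispkit.simulate import simulate_anchor_coupling


def _peak(chrom, start, end, signal=1.0):
    return Peak(interval=GenomicInterval(chrom, start, end), signal=signal)


def _region(chrom, start, end):
    iv = GenomicInterval(chrom, start, end)
    return MergedRegion(interval=iv, peaks=[Peak(interval=iv)], total_signal=1.0)


def _flat(genome, value):
    return CoverageTrack(
        genome=genome,
        values={c: np.full(genome.n_bins(c, 10), float(value)) for c in genome},
        resolution=10,
    )


class TestUnionTable:
    def test_identical_peak_sets_keep_size(self, small_genome):
        peaks = [_peak("chr1", 1000, 2000), _peak("chr1", 30_000, 31_000)]
        t = _flat(small_genome, 1.0)
        table = build_union_signal_table(peaks, peaks, [t], [t])
        assert len(table) == 2

    def test_disjoint_sets_concatenate(self, small_genome):
        a = [_peak("chr1", i * 5000, i * 5000 + 500) for i in range(10)]
        b = [_peak("chr2", i * 3000, i * 3000 + 500) for i in range(15)]
        t = _flat(small_genome, 1.0)
        assert len(build_union_signal_table(a, b, [t], [t])) == 25

    def test_replicates_average(self, small_genome):
        peaks = [_peak("chr1", 10_000, 11_000)]
        table = build_union_signal_table(
            peaks, peaks, [_flat(small_genome, 2.0), _flat(small_genome, 4.0)], [_flat(small_genome, 1.0)]
        )
        assert table["signal_a"].iloc[0] == pytest.approx(3.0)
        assert table["signal_b"].iloc[0] == pytest.approx(1.0)

    def test_mismatched_genomes_rejected(self, small_genome):
        other = Genome({"chrX": 1000})
        peaks = [_peak("chr1", 0, 100)]
        with pytest.raises(ValueError, match="different genomes"):
            build_union_signal_table(peaks, peaks, [_flat(small_genome, 1)], [_flat(other, 1)])


def _table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal_a", "signal_b"])


class TestFoldClassification:
    def test_exactly_twofold_is_unchanged(self):
        (d,) = classify_differential_peaks(_table([("chr1", 0, 100, 1.0, 2.0)]), pseudocount=0.0)
        assert d.klass == "unchanged"

    def test_up_and_down_are_symmetric(self):
        d = classify_differential_peaks(
            _table([("chr1", 0, 100, 1.0, 2.5), ("chr1", 200, 300, 2.5, 1.0)]),
            pseudocount=0.0,
        )
        assert [x.klass for x in d] == ["up", "down"]

    def test_pseudocount_bounds_empty_site_fold(self):
        (d,) = classify_differential_peaks(_table([("chr1", 0, 100, 0.0, 5.0)]), pseudocount=0.5)
        assert d.fold == pytest.approx(11.0)
        assert d.klass == "up"

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            classify_differential_peaks(_table([("chr1", 0, 100, -1.0, 2.0)]))

    def test_partition_and_antisymmetry_on_random_tables(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            n = int(rng.integers(1, 80))
            rows = [
                ("chr1", i * 1000, i * 1000 + 500, float(a), float(b))
                for i, (a, b) in enumerate(zip(rng.lognormal(0, 1, n), rng.lognormal(0, 1, n)))
            ]
            fwd = classify_differential_peaks(_table(rows))
            counts = {k: sum(d.klass == k for d in fwd) for k in ("up", "down", "unchanged")}
            assert sum(counts.values()) == n
            swapped = [(c, s, e, b, a) for c, s, e, a, b in rows]
            rev = classify_differential_peaks(_table(swapped))
            for f, r in zip(fwd, rev):
                assert {f.klass, r.klass} in ({"up", "down"}, {"unchanged"})


class TestIslandSets:
    def test_identical_sets_give_empty_diff(self):
        islands = [_region("chr1", 0, 10_000), _region("chr2", 0, 5_000)]
        lost, gained = diff_island_sets(islands, islands)
        assert lost == [] and gained == []

    def test_new_island_in_b_is_gained(self):
        a = [_region("chr1", 0, 10_000)]
        b = a + [_region("chr1", 100_000, 120_000)]
        lost, gained = diff_island_sets(a, b)
        assert lost == []
        assert [g.interval.start for g in gained] == [100_000]

    def test_matches_all_pairs_overlap_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = [
                _region("chr1", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 500_000, 25), rng.integers(1000, 40_000, 25))
            ]
            b = [
                _region("chr1", int(s), int(s) + int(w))
                for s, w in zip(rng.integers(0, 500_000, 25), rng.integers(1000, 40_000, 25))
            ]
            lost, gained = diff_island_sets(a, b)
            lost_expected = [
                r for r in a if not any(r.interval.overlaps(x.interval) for x in b)
            ]
            gained_expected = [
                r for r in b if not any(r.interval.overlaps(x.interval) for x in a)
            ]
            assert lost == lost_expected and gained == gained_expected
            # lost and gained can never overlap each other
            for l in lost:
                assert not any(l.interval.overlaps(g.interval) for g in gained)


def _dp(chrom, start, end, a, b, klass):
    return DifferentialPeak(
        interval=GenomicInterval(chrom, start, end), signal_a=a, signal_b=b,
        fold=(b + 1) / (a + 1), klass=klass,
    )


class TestPatterns:
    def test_lost_with_anchor_is_pattern_a(self):
        lost = [_region("chr1", 0, 20_000)]
        anchors = [_peak("chr1", 5_000, 5_500)]
        (p,) = classify_island_patterns(lost, [], anchors, [])
        assert (p.direction, p.pattern) == ("lost", "A")

    def test_gained_with_sub_twofold_partner_is_pattern_d(self):
        gained = [_region("chr1", 0, 20_000)]
        partner = [_dp("chr1", 5_000, 5_500, 10.0, 18.0, "unchanged")]  # 1.8-fold
        (p,) = classify_island_patterns([], gained, [], partner)
        assert (p.direction, p.pattern) == ("gained", "D")

    def test_no_anchors_no_partners_all_b_and_d(self):
        lost = [_region("chr1", 0, 20_000)]
        gained = [_region("chr2", 0, 20_000)]
        out = classify_island_patterns(lost, gained, [], [])
        assert [(p.direction, p.pattern) for p in out] == [("lost", "B"), ("gained", "D")]

    def test_every_island_gets_exactly_one_pattern(self):
        rng = np.random.default_rng(22)
        lost = [
            _region("chr1", int(s), int(s) + 20_000) for s in rng.integers(0, 2_000_000, 30)
        ]
        gained = [
            _region("chr1", int(s), int(s) + 20_000) for s in rng.integers(0, 2_000_000, 30)
        ]
        anchors = [_peak("chr1", int(s), int(s) + 400) for s in rng.integers(0, 2_000_000, 40)]
        partner = [
            _dp("chr1", int(s), int(s) + 400, 1.0, float(b), "up" if b > 3 else "unchanged")
            for s, b in zip(rng.integers(0, 2_000_000, 40), rng.uniform(0, 6, 40))
        ]
        out = classify_island_patterns(lost, gained, anchors, partner)
        assert len(out) == 60
        assert all(p.pattern in "AB" for p in out if p.direction == "lost")
        assert all(p.pattern in "CD" for p in out if p.direction == "gained")

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        lost = [
            _region("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 1_000_000, 20), rng.integers(5000, 50_000, 20))
        ]
        gained = [
            _region("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 1_000_000, 20), rng.integers(5000, 50_000, 20))
        ]
        anchors = [_peak("chr1", int(s), int(s) + 300) for s in rng.integers(0, 1_000_000, 25)]
        partner = [
            _dp("chr1", int(s), int(s) + 300, 1.0, float(b), "up" if (b + 1) / 2 > 2 else "unchanged")
            for s, b in zip(rng.integers(0, 1_000_000, 25), rng.uniform(0, 8, 25))
        ]
        out = classify_island_patterns(lost, gained, anchors, partner)
        by_iv = {(p.island.interval.start, p.direction): p.pattern for p in out}
        for r in lost:
            hit = any(r.interval.overlaps(a.interval) for a in anchors)
            assert by_iv[(r.interval.start, "lost")] == ("A" if hit else "B")
        ups = [d for d in partner if d.klass == "up"]
        for r in gained:
            hit = any(r.interval.overlaps(d.interval) for d in ups)
            assert by_iv[(r.interval.start, "gained")] == ("C" if hit else "D")


class TestDistanceStratification:
    def test_abutting_subject_lands_in_first_bin(self):
        anchors = [_peak("chr1", 1000, 1200)]
        subjects = [_dp("chr1", 1200, 1400, 5.0, 1.0, "down")]
        df = stratify_changes_by_distance(subjects, anchors, [False])
        row = df[(df["distance_bin"] == "0-150") & (~df["in_island"])].iloc[0]
        assert row["n"] == 1 and row["median_change"] == pytest.approx(-4.0)

    def test_boundary_150_goes_to_second_bin(self):
        anchors = [_peak("chr1", 1000, 1200)]
        subjects = [_dp("chr1", 1350, 1500, 2.0, 2.0, "unchanged")]
        df = stratify_changes_by_distance(subjects, anchors, [False])
        assert df[df["distance_bin"] == "150-1000"]["n"].sum() == 1
        assert df[df["distance_bin"] == "0-150"]["n"].sum() == 0

    def test_assignments_match_linear_scan_oracle(self):
        rng = np.random.default_rng(24)
        anchors = [_peak("chr1", int(s), int(s) + 200) for s in rng.integers(0, 1_000_000, 30)]
        subjects = [
            _dp("chr1", int(s), int(s) + 200, 1.0, float(b), "unchanged")
            for s, b in zip(rng.integers(0, 1_000_000, 100), rng.random(100))
        ]
        flags = [bool(x) for x in rng.integers(0, 2, 100)]
        df = stratify_changes_by_distance(subjects, anchors, flags)
        bins = [(0, 150), (150, 1000), (1000, 5000), (5000, None)]
        expected_n = {(f"{lo}-{hi}" if hi else f">={lo}", m): 0 for lo, hi in bins for m in (True, False)}
        for s, member in zip(subjects, flags):
            d = min(s.interval.distance(a.interval) for a in anchors)
            for lo, hi in bins:
                if d >= lo and (hi is None or d < hi):
                    label = f"{lo}-{hi}" if hi else f">={lo}"
                    expected_n[(label, member)] += 1
                    break
        for row in df.itertuples(index=False):
            assert row.n == expected_n[(row.distance_bin, row.in_island)]

    def test_anchor_coupled_loss_decays_with_distance(self):
        subjects, anchors, flags = simulate_anchor_coupling(seed=4)
        df = stratify_changes_by_distance(subjects, anchors, flags)
        medians = df.groupby("distance_bin")["median_change"].mean()
        assert medians["0-150"] < medians["150-1000"] < medians[">=5000"]
        # the near bin shows the largest loss of binding
        assert abs(medians["0-150"]) == max(abs(m) for m in medians)


class TestGeneLinking:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "expr_a", "expr_b"])

    def test_inclusive_thresholds_retained(self):
        islands = [_region("chr1", 1_000_000, 1_020_000)]
        genes = self._genes([("g1", "chr1", 1_119_000, 1_119_100, 2.5, 5.0)])  # 99 kb, fold 2.0
        out = link_islands_to_genes(islands, genes)
        assert list(out["gene"]) == ["g1"]

    def test_beyond_flank_not_linked(self):
        islands = [_region("chr1", 1_000_000, 1_020_000)]
        genes = self._genes([("g1", "chr1", 1_121_001, 1_121_101, 10.0, 100.0)])  # 101 kb
        assert link_islands_to_genes(islands, genes).empty

    def test_sub_threshold_fold_filtered(self):
        islands = [_region("chr1", 1_000_000, 1_020_000)]
        genes = self._genes([("g1", "chr1", 1_030_000, 1_030_100, 100.0, 190.0)])  # fold 1.9
        assert link_islands_to_genes(islands, genes).empty

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            link_islands_to_genes([], pd.DataFrame({"gene": []}))


class TestExpressionFilter:
    def test_thresholds(self):
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "fold": [1.6, 1.6, 1.5, 0.5],
                "p": [0.01, 0.06, 0.01, 0.001],
            }
        )
        out = filter_differential_genes(table)
        assert list(out["differential"]) == [True, False, True, True]
        assert list(out["direction"]) == ["up", "none", "up", "down"]

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="'p'"):
            filter_differential_genes(pd.DataFrame({"gene": [], "fold": []}))
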