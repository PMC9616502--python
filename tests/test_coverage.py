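"""Coverage tracks, signal matrices, profiles, occupancy and fractions
against naive per-base oracles."""

import numpy as np
import pytest

from satarray import (
    ConfigError,
    CoverageTrack,
    DataError,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    ddct_fold_change,
    extract_signal_matrix,
    fold_enrichment_track,
    merge_intervals,
    occupancy_subsets,
    per_feature_mean,
    repeat_fraction_of_subsets,
    top_k_peaks,
    tpm_normalize,
    trimmed_mean_profile,
)

from _oracles import (
    dense_track,
    oracle_mean,
    oracle_occupancy,
    oracle_repeat_fractions,
    oracle_trimmed_mean,
    per_base_masks,
)
from conftest import random_interval_set


def random_track(rng, layout, n_runs=60, max_val=20.0):
    runs = []
    for chrom, size in layout.entries:
        pos = 0
        for _ in range(n_runs):
            pos += int(rng.integers(0, 400))
            L = int(rng.integers(1, 500))
            if pos + L > size:
                break
            runs.append((chrom, pos, pos + L, float(np.round(rng.uniform(0, max_val), 3))))
            pos += L
    return CoverageTrack.from_run_list(runs, layout), runs


@pytest.fixture
def small_layout():
    return GenomeLayout([("c", 50_000)])


class TestCoverageTrack:
    def test_bedgraph_round_trip(self, small_layout, rng, tmp_path):
        track, _ = random_track(rng, small_layout)
        p = tmp_path / "t.bedGraph"
        track.write_bedgraph(p)
        back = CoverageTrack.read_bedgraph(p, small_layout)
        p2 = tmp_path / "t2.bedGraph"
        back.write_bedgraph(p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_library_scaling(self, small_layout, tmp_path):
        t = CoverageTrack.from_run_list([("c", 0, 100, 5.0)], small_layout)
        p = tmp_path / "t.bedGraph"
        t.write_bedgraph(p)
        scaled = CoverageTrack.read_bedgraph(p, small_layout, scale_to_library=True)
        assert scaled.total_signal() == pytest.approx(1e6)

    def test_mean_over_matches_per_base_oracle(self, small_layout, rng):
        track, runs = random_track(rng, small_layout)
        dense = dense_track(small_layout.entries, runs)["c"]
        for _ in range(50):
            a = float(rng.uniform(0, 49_000))
            b = a + float(rng.uniform(0.5, 900))
            assert track.mean_over("c", a, b) == pytest.approx(
                oracle_mean(dense, a, b), abs=1e-9)

    def test_uncovered_and_out_of_range_read_zero(self, small_layout):
        t = CoverageTrack.from_run_list([("c", 100, 200, 4.0)], small_layout)
        assert t.mean_over("c", 0, 100) == 0.0
        assert t.mean_over("c", 150, 250) == pytest.approx(2.0)


class TestFoldEnrichment:
    def test_equal_tracks_give_unit_ratio(self, small_layout, rng):
        track, _ = random_track(rng, small_layout)
        fe = fold_enrichment_track(track, track, pseudocount=1.0)
        for s, e, v in zip(*fe.runs["c"]):
            assert v == pytest.approx(1.0)

    def test_formula_at_zero_control(self, small_layout):
        sig = CoverageTrack.from_run_list([("c", 0, 100, 9.0)], small_layout)
        ctl = CoverageTrack.from_run_list([("c", 200, 300, 2.0)], small_layout)
        fe = fold_enrichment_track(sig, ctl, pseudocount=1.0)
        assert fe.mean_over("c", 0, 100) == pytest.approx(10.0)
        assert fe.mean_over("c", 200, 300) == pytest.approx(1.0 / 3.0)
        assert fe.mean_over("c", 400, 500) == pytest.approx(1.0)

    def test_mismatched_chromosomes_rejected(self):
        lay = GenomeLayout([("c", 1000), ("d", 1000)])
        sig = CoverageTrack.from_run_list([("c", 0, 10, 1.0)], lay)
        ctl = CoverageTrack.from_run_list([("d", 0, 10, 1.0)], lay)
        with pytest.raises(DataError):
            fold_enrichment_track(sig, ctl, pseudocount=1.0)

    def test_matches_per_base_oracle(self, small_layout, rng):
        sig, sruns = random_track(rng, small_layout)
        ctl, cruns = random_track(rng, small_layout)
        pc = 0.5
        fe = fold_enrichment_track(sig, ctl, pseudocount=pc)
        ds = dense_track(small_layout.entries, sruns)["c"]
        dc = dense_track(small_layout.entries, cruns)["c"]
        expected = (ds + pc) / (dc + pc)
        got = np.zeros(50_000)
        for s, e, v in zip(*fe.runs["c"]):
            got[s:e] = v
        np.testing.assert_allclose(got, expected, atol=1e-9)


class TestSignalMatrix:
    def test_constant_track_fills_matrix(self, small_layout):
        t = CoverageTrack.from_run_list([("c", 0, 50_000, 3.5)], small_layout)
        feats = IntervalSet([GenomicInterval("c", 10_000, 12_000),
                             GenomicInterval("c", 20_000, 20_777)], small_layout)
        m = extract_signal_matrix(t, feats, flank=1000, bin_size=100, body_bins=7)
        np.testing.assert_allclose(m.values, 3.5)
        assert m.values.shape == (2, 10 + 7 + 10)

    def test_minus_strand_row_is_reversed(self, small_layout, rng):
        track, _ = random_track(rng, small_layout)
        plus = IntervalSet([GenomicInterval("c", 20_000, 22_000, "+")], small_layout)
        minus = IntervalSet([GenomicInterval("c", 20_000, 22_000, "-")], small_layout)
        mp = extract_signal_matrix(track, plus, flank=500, body_bins=8)
        mm = extract_signal_matrix(track, minus, flank=500, body_bins=8)
        np.testing.assert_allclose(mm.values[0], mp.values[0][::-1])

    def test_cells_match_per_base_oracle(self, small_layout, rng):
        track, runs = random_track(rng, small_layout)
        dense = dense_track(small_layout.entries, runs)["c"]
        feats = IntervalSet([GenomicInterval("c", 5_000, 5_333),
                             GenomicInterval("c", 30_000, 31_003)], small_layout)
        flank, bs, nb = 400, 100, 5
        m = extract_signal_matrix(track, feats, flank=flank, bin_size=bs,
                                  body_bins=nb, strand_oriented=False)
        for fi, iv in enumerate(feats):
            edges = (
                [iv.start - flank + bs * k for k in range(flank // bs + 1)]
                + [iv.start + (iv.end - iv.start) * k / nb for k in range(1, nb + 1)]
                + [iv.end + bs * k for k in range(1, flank // bs + 1)]
            )
            for j, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
                assert m.values[fi, j] == pytest.approx(
                    oracle_mean(dense, a, b), abs=1e-9), (fi, j)

    def test_flank_must_divide_by_bin_size(self, small_layout):
        t = CoverageTrack.from_run_list([], small_layout)
        feats = IntervalSet([GenomicInterval("c", 100, 200)], small_layout)
        with pytest.raises(ConfigError):
            extract_signal_matrix(t, feats, flank=150, bin_size=100, body_bins=2)


class TestTrimmedMean:
    def _matrix(self, columns):
        vals = np.asarray(columns, dtype=float).T
        feats = tuple(GenomicInterval("c", i * 10, i * 10 + 5)
                      for i in range(vals.shape[0]))
        from satarray import SignalMatrix
        return SignalMatrix(vals, feats, bin_size=100, flank=0,
                            body_bins=vals.shape[1], strand_oriented=False)

    def test_identical_rows_pass_through(self):
        m = self._matrix([[7.0] * 10, [3.0] * 10])
        prof = trimmed_mean_profile(m, 0.5)
        np.testing.assert_allclose(prof.values, [7.0, 3.0])

    def test_symmetric_trim_of_1_to_1000(self):
        m = self._matrix([np.arange(1, 1001, dtype=float)])
        assert trimmed_mean_profile(m, 0.5).values[0] == pytest.approx(500.5)

    def test_outlier_removed(self):
        col = np.ones(100)
        col[13] = 1e6
        m = self._matrix([col])
        assert trimmed_mean_profile(m, 0.5).values[0] == pytest.approx(1.0)

    def test_zero_trim_equals_column_mean(self, rng):
        cols = rng.uniform(0, 50, size=(3, 40))
        m = self._matrix(cols)
        np.testing.assert_allclose(trimmed_mean_profile(m, 0.0).values,
                                   cols.mean(axis=1))

    def test_matches_sort_based_oracle(self, rng):
        for trim in (0.5, 2.0, 10.0):
            cols = rng.uniform(0, 100, size=(4, 321))
            m = self._matrix(cols)
            prof = trimmed_mean_profile(m, trim)
            for j in range(4):
                assert prof.values[j] == pytest.approx(
                    oracle_trimmed_mean(cols[j], trim), abs=1e-9)

    def test_out_of_range_trim_rejected(self):
        m = self._matrix([[1.0, 2.0]])
        with pytest.raises(ConfigError):
            trimmed_mean_profile(m, 60)


class TestPerFeatureMean:
    def test_body_only_average(self, small_layout):
        t = CoverageTrack.from_run_list([("c", 10_000, 12_000, 6.0)], small_layout)
        feats = IntervalSet([GenomicInterval("c", 10_000, 12_000)], small_layout)
        m = extract_signal_matrix(t, feats, flank=1000, body_bins=4)
        assert per_feature_mean(m)[0] == pytest.approx(6.0)  # flanks (0) excluded

    def test_matches_per_base_oracle(self, small_layout, rng):
        track, runs = random_track(rng, small_layout)
        dense = dense_track(small_layout.entries, runs)["c"]
        feats = IntervalSet([GenomicInterval("c", int(s), int(s) + int(l))
                             for s, l in zip(rng.integers(0, 40_000, 10),
                                             rng.integers(200, 2_000, 10))],
                            small_layout)
        nb = 6
        m = extract_signal_matrix(track, feats, flank=0, body_bins=nb,
                                  strand_oriented=False)
        means = per_feature_mean(m)
        for fi, iv in enumerate(feats):
            edges = [iv.start + (iv.end - iv.start) * k / nb for k in range(nb + 1)]
            cells = [oracle_mean(dense, a, b) for a, b in zip(edges[:-1], edges[1:])]
            assert means[fi] == pytest.approx(np.mean(cells), abs=1e-9)


class TestTopK:
    def test_k_at_least_n_is_identity(self, layout, rng):
        peaks = random_interval_set(rng, layout, 10, with_meta=True)
        assert len(top_k_peaks(peaks, 50)) == 10

    def test_selects_highest_scores(self, layout):
        peaks = IntervalSet([
            GenomicInterval("chr1", 0, 10, score=5.0),
            GenomicInterval("chr1", 20, 30, score=3.0),
            GenomicInterval("chr1", 40, 50, score=9.0)], layout)
        top = top_k_peaks(peaks, 2)
        assert sorted(iv.score for iv in top) == [5.0, 9.0]

    def test_missing_scores_rejected(self, layout):
        peaks = IntervalSet([GenomicInterval("chr1", 0, 10)], layout)
        with pytest.raises(DataError):
            top_k_peaks(peaks, 1)

    def test_matches_sort_oracle_with_ties(self, layout, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + 10,
                               score=float(rng.integers(0, 5)))
               for s in rng.choice(np.arange(0, 40_000, 10), 1000, replace=False)]
        peaks = IntervalSet(ivs, layout)
        top = top_k_peaks(peaks, 100)
        ref = sorted(ivs, key=lambda iv: (-iv.score, iv.chrom, iv.start))[:100]
        assert [(iv.chrom, iv.start, iv.score) for iv in top] == \
            [(iv.chrom, iv.start, iv.score) for iv in ref]


class TestOccupancy:
    def test_identical_single_replicates_all_shared(self, layout, rng):
        peaks = random_interval_set(rng, layout, 20)
        subs = occupancy_subsets([peaks], [peaks])
        assert len(subs.a_only) == 0 and len(subs.b_only) == 0
        assert merge_intervals(subs.shared).total_bp() == \
            merge_intervals(peaks).total_bp()

    def test_disjoint_conditions(self, layout):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)], layout)
        b = IntervalSet([GenomicInterval("chr1", 500, 600)], layout)
        subs = occupancy_subsets([a], [b])
        assert [(iv.start, iv.end) for iv in subs.a_only] == [(0, 100)]
        assert [(iv.start, iv.end) for iv in subs.b_only] == [(500, 600)]
        assert len(subs.shared) == 0

    def test_matches_per_base_three_way_oracle(self, layout, rng):
        for _ in range(10):
            a_reps = [random_interval_set(rng, layout, 25, max_len=1500)
                      for _ in range(2)]
            b_reps = [random_interval_set(rng, layout, 25, max_len=1500)
                      for _ in range(2)]
            subs = occupancy_subsets(a_reps, b_reps, min_replicate_support=2)
            ref = oracle_occupancy(layout.entries, a_reps, b_reps, 2)
            for name, sub in subs.as_dict().items():
                got = per_base_masks(layout.entries, sub)
                for chrom, _ in layout.entries:
                    np.testing.assert_array_equal(got[chrom], ref[name][chrom],
                                                  err_msg=f"{name}:{chrom}")

    def test_subsets_disjoint_and_cover_support_one_universe(self, layout, rng):
        a = [random_interval_set(rng, layout, 20) for _ in range(2)]
        b = [random_interval_set(rng, layout, 20) for _ in range(2)]
        subs = occupancy_subsets(a, b, min_replicate_support=1)
        masks = {n: per_base_masks(layout.entries, s)
                 for n, s in subs.as_dict().items()}
        universe = per_base_masks(layout.entries,
                                  IntervalSet([iv for s in a + b for iv in s],
                                              layout))
        for chrom, _ in layout.entries:
            trio = [masks[n][chrom] for n in ("a_only", "b_only", "shared")]
            assert not np.any(trio[0] & trio[1])
            assert not np.any(trio[0] & trio[2])
            assert not np.any(trio[1] & trio[2])
            np.testing.assert_array_equal(trio[0] | trio[1] | trio[2],
                                          universe[chrom])


class TestRepeatFractions:
    def _subsets(self, layout, intervals):
        empty = IntervalSet([], layout)
        from satarray import OccupancySubsets
        return OccupancySubsets(IntervalSet(intervals, layout), empty, empty, 1)

    def test_subset_inside_one_class(self, layout):
        subs = self._subsets(layout, [GenomicInterval("chr1", 100, 200)])
        ann = IntervalSet([GenomicInterval("chr1", 0, 1000, name="LINE")], layout)
        fr = repeat_fraction_of_subsets(subs, ann)
        assert fr["a_only"]["LINE"] == pytest.approx(1.0)
        assert fr["a_only"]["unannotated"] == pytest.approx(0.0)

    def test_no_overlap_all_unannotated(self, layout):
        subs = self._subsets(layout, [GenomicInterval("chr1", 100, 200)])
        ann = IntervalSet([GenomicInterval("chr2", 0, 1000, name="SINE")], layout)
        fr = repeat_fraction_of_subsets(subs, ann)
        assert fr["a_only"] == {"unannotated": 1.0}

    def test_fractions_sum_to_one(self, layout, rng):
        subs = self._subsets(layout, list(random_interval_set(rng, layout, 20)))
        ann_ivs = [GenomicInterval(iv.chrom, iv.start, iv.end,
                                   name=("LINE", "SINE", "SAT")[i % 3])
                   for i, iv in enumerate(random_interval_set(rng, layout, 30))]
        fr = repeat_fraction_of_subsets(subs, IntervalSet(ann_ivs, layout))
        assert sum(fr["a_only"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_base_precedence_oracle(self, layout, rng):
        for _ in range(8):
            subset_ivs = list(random_interval_set(rng, layout, 15, max_len=2000))
            subs = self._subsets(layout, subset_ivs)
            ann_ivs = [GenomicInterval(iv.chrom, iv.start, iv.end,
                                       name=("LINE", "SINE", "SAT")[i % 3])
                       for i, iv in enumerate(
                           random_interval_set(rng, layout, 25, max_len=3000))]
            ann = IntervalSet(ann_ivs, layout)
            fr = repeat_fraction_of_subsets(subs, ann)["a_only"]
            masks = per_base_masks(layout.entries,
                                   IntervalSet(subset_ivs, layout))
            ref = oracle_repeat_fractions(layout.entries, masks, ann)
            assert set(fr) == set(ref)
            for cls in ref:
                assert fr[cls] == pytest.approx(ref[cls], abs=1e-9), cls


class TestExpressionUtils:
    def test_single_gene_tpm(self):
        assert tpm_normalize([7], [100])[0] == pytest.approx(1e6)

    def test_equal_genes_split_evenly(self):
        np.testing.assert_allclose(tpm_normalize([5, 5, 5, 5], [200] * 4),
                                    [250_000.0] * 4)

    def test_hand_computed_example(self):
        tpm = tpm_normalize([10, 20], [1000, 4000])
        np.testing.assert_allclose(tpm, [666666.6667, 333333.3333], rtol=1e-6)

    def test_tpm_conserves_a_million(self, rng):
        counts = rng.integers(0, 500, 50)
        lengths = rng.integers(100, 5000, 50)
        assert tpm_normalize(counts, lengths).sum() == pytest.approx(1e6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DataError):
            tpm_normalize([0, 0], [100, 100])

    @pytest.mark.parametrize("cts,expected", [
        ((20, 15, 20, 15), 1.0),    # treated == control
        ((19, 15, 20, 15), 2.0),    # ddCt = -1
        ((20, 15, 22, 15), 4.0),    # worked example: ddCt = -2
    ])
    def test_ddct_fold_change(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(DataError):
            ddct_fold_change(float("nan"), 15, 20, 15)
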