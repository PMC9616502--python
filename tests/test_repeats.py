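"""Alignment, consensus, divergence and group comparison."""

import numpy as np
import pytest
from scipy import stats as sps

from satarray import (
    DataError,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    RepeatCopy,
    build_consensus,
    classify_copies,
    copy_divergence,
    group_summary,
    needleman_wunsch,
    percent_divergence,
    reverse_complement,
    two_sample_t_test,
)
from satarray.simulate import mutate_from_consensus, random_dna

from _oracles import oracle_nw_score


def _copy(layout, chrom, start, end, seq=None, bound=None, divergence=None):
    seq = seq if seq is not None else "A" * (end - start)
    return RepeatCopy(GenomicInterval(chrom, start, end), seq, bound, divergence)


@pytest.fixture
def small_layout():
    return GenomeLayout([("chr1", 10_000)])


class TestClassify:
    def test_single_base_overlap_binds(self, small_layout):
        copies = [_copy(small_layout, "chr1", 100, 200)]
        peaks = IntervalSet([GenomicInterval("chr1", 150, 160)], small_layout)
        assert classify_copies(copies, peaks)[0].bound is True

    def test_empty_peak_set_leaves_all_unbound(self, small_layout):
        copies = [_copy(small_layout, "chr1", 100, 200),
                  _copy(small_layout, "chr1", 300, 350)]
        labeled = classify_copies(copies, IntervalSet([], small_layout))
        assert all(c.bound is False for c in labeled)

    def test_touching_peak_does_not_bind(self, small_layout):
        copies = [_copy(small_layout, "chr1", 100, 200)]
        peaks = IntervalSet([GenomicInterval("chr1", 200, 250)], small_layout)
        assert classify_copies(copies, peaks)[0].bound is False

    def test_labels_partition_copies(self, small_layout, rng):
        copies = [_copy(small_layout, "chr1", int(s), int(s) + 50)
                  for s in rng.choice(np.arange(0, 9900, 60), 40, replace=False)]
        peaks = IntervalSet([GenomicInterval("chr1", 0, 3000)], small_layout)
        labeled = classify_copies(copies, peaks, min_overlap=10)
        n_bound = sum(c.bound for c in labeled)
        n_unbound = sum(not c.bound for c in labeled)
        assert n_bound + n_unbound == len(copies)


class TestNeedlemanWunsch:
    def test_identity_alignment(self):
        aln = needleman_wunsch("ACGT", "ACGT")
        assert (aln.score, aln.matches, aln.mismatches, aln.gap_columns) == (4, 4, 0, 0)

    def test_forced_single_deletion(self):
        aln = needleman_wunsch("AAAA", "AAA")
        assert aln.score == 1  # 3 matches + one gap
        assert aln.gap_columns == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(DataError):
            needleman_wunsch("", "ACGT")

    def test_alignment_column_counts_consistent(self, rng):
        for _ in range(20):
            a = random_dna(int(rng.integers(5, 40)), rng)
            b = random_dna(int(rng.integers(5, 40)), rng)
            aln = needleman_wunsch(a, b)
            assert aln.matches + aln.mismatches + aln.gap_columns == len(aln.aligned_a)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            # no column may be gap in both rows
            assert all(ca != "-" or cb != "-"
                       for ca, cb in zip(aln.aligned_a, aln.aligned_b))

    def test_score_equals_exhaustive_enumeration(self, rng):
        """DP score == brute-force maximum over all gapped alignments."""
        for _ in range(100):
            a = random_dna(int(rng.integers(1, 9)), rng)
            b = random_dna(int(rng.integers(1, 9)), rng)
            assert needleman_wunsch(a, b).score == \
                pytest.approx(oracle_nw_score(a, b, 1.0, -1.0, -2.0))

    def test_score_symmetric(self, rng):
        for _ in range(25):
            a = random_dna(int(rng.integers(3, 30)), rng)
            b = random_dna(int(rng.integers(3, 30)), rng)
            assert needleman_wunsch(a, b).score == needleman_wunsch(b, a).score


class TestPercentDivergence:
    def test_identical_sequences_zero(self):
        assert percent_divergence(needleman_wunsch("ACGTACGT", "ACGTACGT")) == 0.0

    def test_one_mismatch_in_ten(self):
        aln = needleman_wunsch("AAAAAAAAAA", "AAAAAAAAAC")
        assert percent_divergence(aln) == pytest.approx(10.0)

    def test_row_order_invariant(self, rng):
        for _ in range(10):
            a = random_dna(30, rng)
            b = random_dna(30, rng)
            assert percent_divergence(needleman_wunsch(a, b)) == \
                pytest.approx(percent_divergence(needleman_wunsch(b, a)))

    def test_divergence_recovers_substitution_rate(self, rng):
        """Unit-length copies at 5% substitution read back ~5% divergence."""
        unit = random_dna(300, rng)
        n = 60
        divs = [copy_divergence(
            mutate_from_consensus(unit, 0.05, 0.0, 300, rng).sequence, unit)
            for _ in range(n)]
        se = 100 * np.sqrt(0.05 * 0.95 / 300 / n)
        assert abs(np.mean(divs) - 5.0) < 3 * se

    def test_tandem_copy_divergence_close_to_rate(self, rng):
        """Windowed divergence of long tandem copies stays near the
        configured rate (slight register-sliding bias tolerated)."""
        unit = random_dna(300, rng)
        divs = [copy_divergence(
            mutate_from_consensus(unit, 0.10, 0.002, 1500, rng).sequence, unit)
            for _ in range(20)]
        assert abs(np.mean(divs) - 10.0) / 10.0 < 0.10


class TestConsensus:
    def test_identical_sequences_fixed_point(self):
        model = build_consensus(["ACGTACGT"] * 3)
        assert model.consensus == "ACGTACGT"
        assert model.rounds == 1

    def test_column_majority(self):
        assert build_consensus(["AAAA", "AAAA", "AATA"]).consensus == "AAAA"

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(DataError):
            build_consensus(["ACGT"])

    def test_column_frequencies_sum_to_contributors(self, rng):
        seqs = [mutate_from_consensus("ACGTACGTAC" * 3, 0.1, 0.0, 30, rng).sequence
                for _ in range(10)]
        model = build_consensus(seqs)
        for counts in model.column_frequencies:
            assert 0 < sum(counts.values()) <= len(seqs)

    def test_recovers_truth_consensus(self, rng):
        """50 copies at 5% substitution + 0.2% indels from a 200-bp truth:
        rebuilt majority consensus within Hamming distance 2 after
        alignment."""
        truth = random_dna(200, rng)
        seqs = [mutate_from_consensus(truth, 0.05, 0.002, 200, rng).sequence
                for _ in range(50)]
        model = build_consensus(seqs)
        aln = needleman_wunsch(model.consensus, truth)
        assert aln.mismatches + aln.gap_columns <= 2


class TestTTest:
    def test_identical_groups(self):
        r = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_computed_pooled_value(self):
        r = two_sample_t_test([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(3, 40)))
            y = rng.normal(0.3, 1.5, int(rng.integers(3, 40)))
            ours = two_sample_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert ours.t == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)
            welch = two_sample_t_test(x, y, welch=True)
            refw = sps.ttest_ind(x, y, equal_var=False)
            assert welch.t == pytest.approx(refw.statistic, rel=1e-10)
            assert welch.p == pytest.approx(refw.pvalue, rel=1e-10)

    def test_degenerate_zero_variance_convention(self):
        r = two_sample_t_test([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(DataError):
            two_sample_t_test([1.0], [1.0, 2.0])

    def test_null_p_values_uniform(self, rng):
        """Under H0 the p-value is ~Uniform(0,1) (KS at alpha=0.01)."""
        ps = []
        for _ in range(300):
            x = rng.normal(0, 1, 25)
            y = rng.normal(0, 1, 25)
            ps.append(two_sample_t_test(x, y).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestGroupSummary:
    def _labeled(self, layout, rng, nb=30, nu=30, shift=0.0):
        copies = []
        pos = 0
        for i in range(nb + nu):
            bound = i < nb
            L = int(rng.normal(120 + (80 + shift if bound else 0), 10))
            copies.append(_copy(layout, "chr1", pos, pos + L, "A" * L, bound,
                                divergence=float(np.clip(
                                    rng.normal(5 if bound else 15, 1), 0, 100))))
            pos += L + 5
        return copies

    def test_identical_groups_give_p_one(self, small_layout):
        copies = [_copy(small_layout, "chr1", i * 20, i * 20 + 10, "A" * 10,
                        bound=(i % 2 == 0), divergence=7.0)
                  for i in range(10)]
        gs = group_summary(copies)
        assert gs.length_test.p == 1.0
        assert gs.divergence_test.p == 1.0

    def test_separated_groups_detected(self, small_layout, rng):
        gs = group_summary(self._labeled(small_layout, rng))
        assert gs.length_test.p < 1e-10
        assert gs.divergence_test.p < 1e-10
        assert gs.bound.mean_length > gs.unbound.mean_length
        assert gs.bound.mean_divergence < gs.unbound.mean_divergence

    def test_histogram_counts_conserve_group_n(self, small_layout, rng):
        copies = self._labeled(small_layout, rng)
        gs = group_summary(copies)
        assert gs.length_histogram["bound"].sum() == gs.bound.n
        assert gs.length_histogram["unbound"].sum() == gs.unbound.n

    def test_empty_group_is_an_error(self, small_layout):
        copies = [_copy(small_layout, "chr1", 0, 10, "A" * 10, True, 1.0),
                  _copy(small_layout, "chr1", 20, 30, "A" * 10, True, 2.0)]
        with pytest.raises(DataError, match="classification"):
            group_summary(copies)


def test_reverse_complement():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AACG") == "CGTT"
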