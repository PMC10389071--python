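"""Randomness metrics: worked examples, oracle agreement, invariants."""

import math

import numpy as np
import pytest

import randgen as rg
from randgen.metrics import UndefinedMetricError

import oracles


class TestDigramCounts:
    def test_lag1_hand_count(self):
        counts = rg.digram_counts([1, 2, 1, 2], lag=1)
        assert counts[0, 1] == 2 and counts[1, 0] == 1
        assert counts.sum() == 3

    def test_lag2_hand_count(self):
        counts = rg.digram_counts([1, 2, 1, 2], lag=2)
        assert counts[0, 0] == 1 and counts[1, 1] == 1
        assert counts.sum() == 2

    def test_total_is_n_minus_lag(self, random_sequences):
        for seq in random_sequences[:50]:
            assert rg.digram_counts(seq, 1).sum() == len(seq) - 1

    def test_lag_too_large_raises(self):
        with pytest.raises(UndefinedMetricError):
            rg.digram_counts([1, 2], lag=2)


class TestRedundancy:
    def test_balanced_usage_is_zero(self):
        seq = list(range(1, 11)) * 3
        assert rg.redundancy(seq) == pytest.approx(0.0, abs=1e-12)

    def test_constant_sequence_is_hundred(self):
        assert rg.redundancy([7] * 20) == pytest.approx(100.0)

    def test_worked_example(self):
        # counts {2,1,1}: H = 1.5 bits, R = 100 (1 - 1.5/log2 10)
        assert rg.redundancy([1, 1, 2, 3]) == pytest.approx(
            100 * (1 - 1.5 / math.log2(10))
        )


class TestEvansRNG:
    def test_maximal_stereotypy(self):
        assert rg.evans_rng([5, 5, 5, 5], lag=1) == pytest.approx(100.0)

    def test_all_singleton_digrams_zero(self):
        assert rg.evans_rng([1, 1, 2, 1], lag=1) == pytest.approx(0.0)

    def test_degenerate_denominator_is_missing_not_zero(self):
        assert math.isnan(rg.evans_rng([1, 2], lag=1))

    def test_base_invariance(self, random_sequences):
        """The index is a ratio of entropy terms, so the log base cancels."""
        for seq in random_sequences[:40]:
            if len(seq) < 4:
                continue
            v2 = oracles.oracle_evans_rng(seq, 1, log=math.log2)
            v10 = oracles.oracle_evans_rng(seq, 1, log=math.log10)
            ours = rg.evans_rng(seq, lag=1)
            if math.isnan(ours):
                assert math.isnan(v2)
            else:
                assert ours == pytest.approx(v2, abs=1e-9)
                assert ours == pytest.approx(v10, abs=1e-9)


class TestNSQ:
    def test_single_digram_used(self):
        assert rg.null_score_quotient([5, 5, 5]) == pytest.approx(100.0)

    def test_hand_count(self):
        assert rg.null_score_quotient([1, 2, 3]) == pytest.approx(9800 / 99)

    def test_full_digram_coverage_gives_zero(self):
        cyc = oracles.de_bruijn_digits(10, 2)
        seq = cyc + [cyc[0]]  # 101 digits covering all 100 digrams
        assert len(seq) == 101
        assert rg.null_score_quotient(seq) == pytest.approx(0.0)


class TestAdjacency:
    def test_fully_ascending(self):
        assert rg.adjacency(list(range(1, 11)))[2] == pytest.approx(100.0)

    def test_repetitions_are_not_steps(self):
        assert rg.adjacency([4, 4, 4, 4])[2] == pytest.approx(0.0)

    def test_hand_count(self):
        asc, desc, comb = rg.adjacency([1, 2, 5, 6])
        assert comb == pytest.approx(200 / 3)
        assert desc == 0.0

    def test_no_wraparound(self):
        assert rg.adjacency([10, 1, 10, 1])[2] == pytest.approx(0.0)


class TestTurningPointIndex:
    def test_monotone_is_zero(self):
        assert rg.turning_point_index([1, 3, 5, 7, 9]) == pytest.approx(0.0)

    def test_alternating_hand_count(self):
        assert rg.turning_point_index([1, 2, 1, 2, 1]) == pytest.approx(150.0)

    def test_three_point_peak(self):
        assert rg.turning_point_index([1, 3, 2]) == pytest.approx(150.0)

    def test_equal_runs_collapsed(self):
        # collapses to [1,3,2]: one turn; n stays 5
        assert rg.turning_point_index([1, 3, 3, 3, 2]) == pytest.approx(50.0)


class TestDescriptors:
    def test_rf_constant(self):
        rf, r_rf = rg.response_frequencies([1, 1, 1])
        assert rf[0] == 3 and r_rf[0] == 1.0

    def test_rf_balanced(self):
        _, r_rf = rg.response_frequencies(list(range(1, 11)) * 3)
        assert np.allclose(r_rf, 0.1)

    def test_fod_ascending(self):
        fod, r_fod = rg.first_order_differences([1, 2, 3, 4])
        assert fod[9 + 1] == 3 and fod.sum() == 3
        assert r_fod[9 + 1] == pytest.approx(0.75)

    def test_fod_repetitions(self):
        fod, _ = rg.first_order_differences([5, 5, 5])
        assert fod[9] == 2

    def test_r_fod_sums_to_fraction(self, random_sequences):
        """Relative FOD divides by n, so the bins sum to (n-1)/n."""
        for seq in random_sequences[:50]:
            _, r_fod = rg.first_order_differences(seq)
            assert r_fod.sum() == pytest.approx((len(seq) - 1) / len(seq))

    def test_cf_constant_saturates(self):
        cf, r_cf = rg.correlation_function([1, 1, 1])
        assert cf == pytest.approx(1.5)
        assert r_cf == pytest.approx(1.0)

    def test_cf_hand_count(self):
        cf, r_cf = rg.correlation_function([1, 2, 1])
        assert cf == pytest.approx(0.5)
        assert r_cf == pytest.approx(1 / 3)


class TestMetricsProfile:
    def test_union_of_hand_counts(self):
        prof = rg.metrics_profile([1, 2, 1, 2, 1])
        assert prof.adjacency_combined == pytest.approx(100.0)
        assert prof.TPI == pytest.approx(150.0)
        assert prof.FOD[9 + 1] == 2 and prof.FOD[9 - 1] == 2

    def test_constant_sequence_extremes(self):
        prof = rg.metrics_profile([4] * 12)
        assert prof.R == pytest.approx(100.0)
        assert prof.NSQ == pytest.approx(100.0)
        assert prof.RNG == pytest.approx(100.0)
        assert prof.adjacency_combined == 0.0

    def test_metadata_independence(self):
        a = rg.ResponseSequence("P1", "ASD", (3, 1, 4, 1, 5, 9, 2, 6))
        b = rg.ResponseSequence("Q9", "CTRL", (3, 1, 4, 1, 5, 9, 2, 6))
        pa, pb = rg.metrics_profile(a), rg.metrics_profile(b)
        assert pa.to_dict() == pb.to_dict()

    def test_too_short_raises(self):
        with pytest.raises(UndefinedMetricError):
            rg.metrics_profile([1, 2])


def test_every_metric_matches_brute_force_oracle(random_sequences):
    """Two-route check of all metrics on random sequences (tol 1e-9)."""
    for seq in random_sequences:
        prof = rg.metrics_profile(seq)
        assert prof.R == pytest.approx(oracles.oracle_redundancy(seq), abs=1e-9)
        for ours, lag in ((prof.RNG, 1), (prof.RNG2, 2)):
            ref = oracles.oracle_evans_rng(seq, lag)
            if math.isnan(ref):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-9)
        assert prof.NSQ == pytest.approx(oracles.oracle_nsq(seq), abs=1e-9)
        assert prof.adjacency_combined == pytest.approx(
            oracles.oracle_adjacency(seq)[2], abs=1e-9
        )
        assert prof.TPI == pytest.approx(oracles.oracle_tpi(seq), abs=1e-9)
        rf, r_rf = oracles.oracle_rf(seq)
        assert np.array_equal(prof.RF, rf)
        assert np.allclose(prof.r_RF, r_rf, atol=1e-12)
        fod, r_fod = oracles.oracle_fod(seq)
        assert np.array_equal(prof.FOD, fod)
        assert np.allclose(prof.r_FOD, r_fod, atol=1e-12)
        cf, r_cf = oracles.oracle_cf(seq)
        assert prof.Cf == pytest.approx(cf, abs=1e-9)
        assert prof.r_Cf == pytest.approx(r_cf, abs=1e-9)


def test_exact_conservation_laws(random_sequences):
    """Sum RF = n, sum FOD = n-1, digram total = n - lag, as integers."""
    for seq in random_sequences[:80]:
        prof = rg.metrics_profile(seq)
        assert int(prof.RF.sum()) == len(seq)
        assert int(prof.FOD.sum()) == len(seq) - 1
        assert rg.digram_counts(seq, 1).sum() == len(seq) - 1
        if len(seq) > 2:
            assert rg.digram_counts(seq, 2).sum() == len(seq) - 2


def test_feature_table_layout(small_cohort):
    table = rg.feature_table(small_cohort.sequences)
    assert list(table.columns[:3]) == ["participant_id", "group", "n"]
    assert len(table) == 5
    assert set(rg.PROFILE_COLUMNS).issubset(table.columns)
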