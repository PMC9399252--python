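"""Rhythmic-gene caller: p-value calibration, the three criteria, phases."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rreclock.caller import (
    ExpressionTimecourse,
    call_matrix,
    call_rhythmic,
    peak_phase,
    phase_histogram,
    rhythm_pvalue,
    row_standardize,
)
from rreclock.synthetic import gen_expression_matrix

CT = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])


def _tc(means, sds=None, n_reps=3, rng=None, gene="g"):
    """Timecourse with the given per-time means, optionally jittered."""
    values = []
    for i, mu in enumerate(means):
        if sds is None:
            v = np.full(n_reps, float(mu))
        else:
            v = rng.normal(mu, sds[i], n_reps)
        values.append(np.clip(v, 0.0, None))
    return ExpressionTimecourse(gene, CT, tuple(values))


def _cosine_tc(amplitude=2.0, baseline=5.0, phase=8.0, period=24.0, n_reps=3):
    means = baseline + amplitude * np.cos(2 * np.pi * (CT - phase) / period)
    return _tc(means, n_reps=n_reps)


class TestRhythmPvalue:
    def test_null_pvalues_are_uniform(self):
        """Flat genes with seeded noise: KS against Uniform(0,1) holds."""
        rng = np.random.default_rng(100)
        pvals = [
            rhythm_pvalue(_tc(np.full(6, 10.0), sds=np.full(6, 1.5), rng=rng))
            for _ in range(1000)
        ]
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_noise_free_cosine_is_extreme(self):
        assert rhythm_pvalue(_cosine_tc(amplitude=2.0)) < 1e-4

    def test_constant_profile_has_p_one(self):
        tc = ExpressionTimecourse("g", CT, tuple(np.array([4.0]) for _ in CT))
        assert rhythm_pvalue(tc) == 1.0

    def test_deterministic_for_fixed_input(self):
        tc = _cosine_tc()
        assert rhythm_pvalue(tc) == rhythm_pvalue(tc)

    def test_too_few_observations_rejected(self):
        tc = ExpressionTimecourse(
            "g", CT[:4], tuple(np.array([1.0]) for _ in range(4))
        )
        with pytest.raises(ValueError):
            rhythm_pvalue(tc)


class TestThreeCriteria:
    def test_fold_and_sd_criteria_on_strong_rhythm(self):
        """Means {2,3,6,4,2,1}: peak 6 >= 1.5 x trough 1; tiny SDs pass c3."""
        rng = np.random.default_rng(0)
        tc = _tc([2, 3, 6, 4, 2, 1], sds=np.full(6, 0.05), rng=rng)
        call = call_rhythmic(tc)
        assert call.c2 and call.c3
        assert call.peak == pytest.approx(6.0, abs=0.1)
        assert call.trough == pytest.approx(1.0, abs=0.1)

    def test_low_fold_fails_regardless_of_p(self):
        tc = _tc([2.0, 2.2, 2.6, 2.4, 2.2, 2.0])
        call = call_rhythmic(tc)
        assert not call.c2  # 2.6 / 2.0 = 1.3 < 1.5
        assert not call.is_rhythmic

    def test_noisy_amplitude_fails_sd_criterion(self):
        means = np.array([4.0, 5.0, 8.0, 6.0, 5.0, 4.0])  # amplitude 4
        values = []
        rng = np.random.default_rng(1)
        for mu in means:
            v = rng.normal(mu, 7.0, 4)
            values.append(np.clip(v, 0.01, None))
        tc = ExpressionTimecourse("g", CT, tuple(values))
        call = call_rhythmic(tc)
        if call.sd_max > 1.5 * call.amplitude:
            assert not call.c3 and not call.is_rhythmic

    def test_zero_trough_counts_as_infinite_fold(self):
        means = [0.0, 1.0, 4.0, 5.0, 2.0, 0.5]
        tc = _tc(means)
        assert call_rhythmic(tc).c2

    def test_all_zero_profile_is_not_rhythmic(self):
        tc = ExpressionTimecourse(
            "g", CT, tuple(np.zeros(3) for _ in CT)
        )
        call = call_rhythmic(tc)
        assert not call.is_rhythmic

    def test_criteria_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(2)
        means = [2, 3, 6, 4, 2, 1]
        tc = _tc(means, sds=np.full(6, 0.3), rng=rng)
        call = call_rhythmic(tc)
        scaled = ExpressionTimecourse(
            "g", CT, tuple(v * 37.5 for v in tc.values)
        )
        call2 = call_rhythmic(scaled)
        assert (call.c1, call.c2, call.c3) == (call2.c1, call2.c2, call2.c3)
        assert call.p_value == pytest.approx(call2.p_value)

    def test_single_replicate_sd_excluded(self):
        tc = ExpressionTimecourse(
            "g", CT, tuple(np.array([m]) for m in [2.0, 3.0, 6.0, 4.0, 2.0, 1.0])
        )
        call = call_rhythmic(tc)
        assert np.isnan(call.sd_max)
        assert call.c3  # no usable SD -> criterion passes by exclusion


class TestPhase:
    def test_noise_free_cosine_phase_recovery(self):
        assert peak_phase(_cosine_tc(phase=8.0)) == pytest.approx(8.0, abs=0.5)

    def test_phase_equivariance_under_time_shift(self):
        p0 = peak_phase(_cosine_tc(phase=6.0))
        p1 = peak_phase(_cosine_tc(phase=10.0))
        assert (p1 - p0) % 24.0 == pytest.approx(4.0, abs=1.0)

    def test_flat_gene_has_no_phase(self):
        rng = np.random.default_rng(3)
        tc = _tc(np.full(6, 10.0), sds=np.full(6, 0.5), rng=rng)
        call = call_rhythmic(tc)
        if not call.is_rhythmic:
            assert call.peak_phase is None


class TestPhaseHistogram:
    def test_counts_sum_to_rhythmic_genes(self):
        matrix, _ = gen_expression_matrix(n_genes=120, seed=8)
        calls = call_matrix(matrix)
        hist = phase_histogram(calls)
        assert hist.sum() == int(calls["is_rhythmic"].sum())

    def test_no_rhythmic_genes_all_zero(self):
        calls = pd.DataFrame(
            {"is_rhythmic": [False, False], "peak_phase_ct": [np.nan, np.nan]}
        )
        hist = phase_histogram(calls)
        assert (hist == 0).all()

    def test_phase_cluster_lands_in_modal_bin(self):
        """Phases concentrated at CT8 put the mode at the CT6 or CT10 bin."""
        matrix, _ = gen_expression_matrix(
            n_genes=300,
            frac_rhythmic=0.5,
            phase_distribution=("vonmises", 8.0, 8.0),
            seed=9,
        )
        calls = call_matrix(matrix)
        hist = phase_histogram(calls)
        assert hist.idxmax() in (6.0, 10.0)


class TestRowStandardize:
    def test_small_row_exact(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]])
        out, flags = row_standardize(df)
        assert out.to_numpy().mean() == pytest.approx(0.0)
        assert out.to_numpy().std() == pytest.approx(1.0)
        assert not flags.iloc[0]

    def test_already_standardized_unchanged(self):
        row = np.array([[-1.0, 0.0, 1.0]]) / np.std([-1.0, 0.0, 1.0])
        out, _ = row_standardize(pd.DataFrame(row))
        assert np.allclose(out.to_numpy(), row)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.lognormal(1.0, 0.6, (20, 12)))
        out, _ = row_standardize(df)
        oracle = np.array(
            [(r - r.mean()) / r.std() for r in df.to_numpy()]
        )
        assert np.allclose(out.to_numpy(), oracle, atol=1e-12)

    def test_zero_variance_row_flagged_and_zeroed(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out, flags = row_standardize(df)
        assert flags.tolist() == [True, False]
        assert (out.iloc[0] == 0.0).all()
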