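"""Shift-and-sum predictions, split enumeration, cross-validated r, ceiling."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

from lamadd import (
    PredictionCondition,
    average_blocks,
    crossval_correlation,
    enumerate_splits,
    extract_blocks,
    linear_depth_model,
    noise_ceiling,
    shift_sum_predict,
    simulate_depth_session,
)
from lamadd.epochs import EpochSet

DT = 1.3


def _epochs_from(trials_by_dur, runs_by_dur):
    return EpochSet(
        trials={d: np.asarray(v) for d, v in trials_by_dur.items()},
        trial_runs={d: np.asarray(v) for d, v in runs_by_dur.items()},
        dt=DT,
        baseline_s=15.6,
    )


class TestShiftSumPredict:
    def test_impulse_two_copies(self):
        resp = np.zeros(14)
        resp[0] = 1.0
        pred = shift_sum_predict(resp, PredictionCondition(2.6, 5.2), DT)
        expected = np.zeros(16)
        expected[0] = expected[2] = 1.0
        np.testing.assert_array_equal(pred, expected)

    def test_short_to_medium_is_shift_plus_original(self, rng):
        resp = rng.standard_normal(14)
        pred = shift_sum_predict(resp, PredictionCondition(2.6, 5.2), DT)
        manual = np.zeros(16)
        manual[:14] += resp
        manual[2:16] += resp
        np.testing.assert_allclose(pred, manual, rtol=1e-15)

    def test_composition_identity(self, rng):
        """Predicting 10.4 s from 2.6 s directly equals composing
        2.6->5.2 with 5.2->10.4 (linearity of shift-and-sum)."""
        resp = rng.standard_normal(14)
        direct = shift_sum_predict(resp, PredictionCondition(2.6, 10.4), DT)
        via = shift_sum_predict(
            shift_sum_predict(resp, PredictionCondition(2.6, 5.2), DT),
            PredictionCondition(5.2, 10.4),
            DT,
        )
        np.testing.assert_allclose(direct, via, atol=1e-12)

    def test_non_multiple_condition_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            PredictionCondition(2.6, 6.5)

    def test_wrong_source_length_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            shift_sum_predict(np.zeros(10), PredictionCondition(2.6, 5.2), DT)


class TestEnumerateSplits:
    @pytest.mark.parametrize("n,k,expected", [(8, 4, 70), (2, 1, 2), (4, 2, 6)])
    def test_counts_match_bruteforce(self, n, k, expected):
        splits = enumerate_splits(n, k)
        brute = list(itertools.combinations(range(n), k))
        assert len(splits) == expected == len(brute)
        assert [s[0] for s in splits] == brute

    def test_test_set_is_complement(self):
        for train, test in enumerate_splits(8, 4):
            assert sorted(train + test) == list(range(8))

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            enumerate_splits(4, 4)

    def test_relabeling_invariance_up_to_permutation(self):
        splits = enumerate_splits(6, 3)
        relabel = {i: (i + 2) % 6 for i in range(6)}
        mapped = {
            tuple(sorted(relabel[i] for i in train)) for train, _ in splits
        }
        assert mapped == {tuple(sorted(t)) for t, _ in splits}


class TestCrossvalCorrelation:
    def test_noise_free_linear_r_is_one(self):
        design, H = simulate_depth_session(9, linear_depth_model())
        ep = extract_blocks(H, design, DT)
        splits = enumerate_splits(8, 4)
        for cond in [PredictionCondition(2.6, 5.2), PredictionCondition(2.6, 10.4),
                     PredictionCondition(5.2, 10.4)]:
            med, per = crossval_correlation(ep, cond, splits, 8)
            assert per.shape == (70, 5)
            np.testing.assert_allclose(per, 1.0, atol=1e-9)
            np.testing.assert_allclose(med, 1.0, atol=1e-9)

    def test_orthogonal_prediction_r_near_zero(self, rng):
        """Target responses constructed orthogonal to the shift-sum of the
        source over the window give r ~ 0."""
        n_runs = 4
        src = np.tile(np.sin(np.linspace(0, 3, 14)), (n_runs, 1, 1))
        pred = shift_sum_predict(src[0, 0], PredictionCondition(2.6, 5.2), DT)
        pred_c = pred - pred.mean()
        tgt_base = rng.standard_normal(16)
        tgt_c = tgt_base - tgt_base.mean()
        tgt_orth = tgt_c - (tgt_c @ pred_c) / (pred_c @ pred_c) * pred_c
        tgt = np.tile(tgt_orth, (n_runs, 1, 1))
        ep = _epochs_from({2.6: src, 5.2: tgt}, {2.6: range(n_runs), 5.2: range(n_runs)})
        med, _ = crossval_correlation(ep, PredictionCondition(2.6, 5.2), enumerate_splits(4, 2), 4)
        np.testing.assert_allclose(med, 0.0, atol=1e-9)

    def test_median_of_identical_splits(self, rng):
        n_runs = 4
        src = np.tile(rng.standard_normal(14), (n_runs, 1, 1))
        tgt = np.tile(rng.standard_normal(16), (n_runs, 1, 1))
        ep = _epochs_from({2.6: src, 5.2: tgt}, {2.6: range(n_runs), 5.2: range(n_runs)})
        med, per = crossval_correlation(ep, PredictionCondition(2.6, 5.2), enumerate_splits(4, 2), 4)
        assert np.all(per == per[0, 0])
        assert med[0] == per[0, 0]

    def test_scale_invariance(self, rng):
        """Scaling the source responses by any positive constant leaves
        every correlation unchanged (the statistic tests shape, not
        amplitude)."""
        design, H = simulate_depth_session(2, linear_depth_model(), noise_sigma=0.2)
        splits = enumerate_splits(8, 4)
        cond = PredictionCondition(2.6, 10.4)
        ep1 = extract_blocks(H, design, DT)
        med1, per1 = crossval_correlation(ep1, cond, splits, 8)
        ep2 = extract_blocks(H, design, DT)
        ep2.trials[2.6] = 37.5 * ep2.trials[2.6]
        med2, per2 = crossval_correlation(ep2, cond, splits, 8)
        np.testing.assert_allclose(per1, per2, atol=1e-12)

    def test_zero_variance_split_excluded_with_warning(self, rng):
        n_runs = 4
        src = rng.standard_normal((n_runs, 1, 14))
        tgt = rng.standard_normal((n_runs, 1, 16))
        tgt[2] = tgt[3] = 5.0  # test half {2,3} observed response is constant
        ep = _epochs_from({2.6: src, 5.2: tgt}, {2.6: range(n_runs), 5.2: range(n_runs)})
        with pytest.warns(UserWarning, match="excluded"):
            med, per = crossval_correlation(
                ep, PredictionCondition(2.6, 5.2), enumerate_splits(4, 2), 4
            )
        assert np.isnan(per[0]).all()  # the split whose test set is {2,3}
        assert np.isfinite(med).all()


class TestNoiseCeiling:
    def test_identical_halves_r_one(self, rng):
        tgt = np.tile(rng.standard_normal(20), (4, 1, 1))
        ep = _epochs_from({10.4: tgt}, {10.4: range(4)})
        med, _ = noise_ceiling(ep, 10.4, enumerate_splits(4, 2), 4)
        np.testing.assert_allclose(med, 1.0, atol=1e-12)

    def test_sign_flipped_halves_r_minus_one(self, rng):
        base = rng.standard_normal(20)
        tgt = np.stack([base, -base]).reshape(2, 1, 20)
        ep = _epochs_from({10.4: tgt}, {10.4: range(2)})
        med, _ = noise_ceiling(ep, 10.4, enumerate_splits(2, 1), 2)
        np.testing.assert_allclose(med, -1.0, atol=1e-12)

    def test_ceiling_bounds_prediction_on_noisy_data(self):
        """Paired over seeds, the noise ceiling is at least the
        cross-validated prediction r more often than chance (one-sided
        sign test)."""
        wins = 0
        n_seeds = 30
        splits = enumerate_splits(8, 4)
        cond = PredictionCondition(2.6, 10.4)
        for seed in range(n_seeds):
            design, H = simulate_depth_session(seed, linear_depth_model(), noise_sigma=0.25)
            ep = extract_blocks(H, design, DT)
            med, _ = crossval_correlation(ep, cond, splits, 8)
            ceil, _ = noise_ceiling(ep, 10.4, splits, 8)
            wins += ceil.mean() >= med.mean()
        p = stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
        assert p < 0.05


def test_adaptation_lowers_prediction_correlation():
    """Same seed, noise-free: the adapted pipeline correlates strictly
    worse than the linear one for the 2.6->10.4 prediction at every depth."""
    splits = enumerate_splits(8, 4)
    cond = PredictionCondition(2.6, 10.4)
    design, H_lin = simulate_depth_session(4, linear_depth_model())
    _, H_adapt = simulate_depth_session(4, linear_depth_model(), nonlinearity="adaptation", strength=0.12)
    med_lin, _ = crossval_correlation(extract_blocks(H_lin, design, DT), cond, splits, 8)
    med_ada, _ = crossval_correlation(extract_blocks(H_adapt, design, DT), cond, splits, 8)
    assert np.all(med_ada < med_lin)
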