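"""Pain-diary processing, growth-mixture EM and locked labelling."""

import numpy as np
import pandas as pd
import pytest

from corticomark.synthetic import (DEFAULT_LOW_TRAJECTORY, TrajectoryParams,
                                   generate_pain_diary)
from corticomark.trajectory import (HIGH, LOW, LabelRule,
                                    apply_locked_labels,
                                    assign_training_labels,
                                    build_trajectory_matrix,
                                    compute_pain_scores, fit_gmm,
                                    impute_trajectories, posterior_for)


def _diary_row(pid, day, time, activity, score):
    return {"participant": pid, "day": day, "time": time,
            "activity": activity, "score": score}


def _mini_diary():
    rows = []
    for act, score in (("chewing", 3.0), ("yawning", 2.0)):
        rows.append(_diary_row("P1", 1, "10:00", act, score))
    for act, score in (("chewing", 10.0), ("yawning", 10.0)):
        rows.append(_diary_row("P1", 1, "19:00", act, score))
    for act, score in (("chewing", 0.0), ("yawning", np.nan)):
        rows.append(_diary_row("P1", 2, "10:00", act, score))
    for act, score in (("chewing", 0.0), ("yawning", 0.0)):
        rows.append(_diary_row("P1", 2, "19:00", act, score))
    return pd.DataFrame(rows)


class TestPainScores:
    def test_sum_zero_and_maximum(self):
        scores = compute_pain_scores(_mini_diary()).set_index(
            ["day", "time"])["pain_score"]
        assert scores.loc[(1, "10:00")] == 5.0
        assert scores.loc[(1, "19:00")] == 20.0
        assert scores.loc[(2, "19:00")] == 0.0

    def test_missing_activity_makes_timepoint_missing(self):
        scores = compute_pain_scores(_mini_diary()).set_index(
            ["day", "time"])["pain_score"]
        assert np.isnan(scores.loc[(2, "10:00")])

    def test_unknown_activity_rejected(self):
        with pytest.raises(ValueError, match="grimacing"):
            compute_pain_scores(_mini_diary(),
                                activities=("chewing", "grimacing"))


class TestTrajectoryMatrix:
    def test_seven_day_matrix_shape_and_order(self):
        diary = generate_pain_diary("P1", HIGH, DEFAULT_LOW_TRAJECTORY,
                                    DEFAULT_LOW_TRAJECTORY, 0.0, seed=1)
        mat = build_trajectory_matrix(diary, span_days=7)
        assert mat.shape == (1, 14)
        assert list(mat.columns) == sorted(mat.columns)

    def test_interior_gap_linear_midpoint(self):
        mat = pd.DataFrame([[2.0, np.nan, 4.0]], index=["P1"],
                           columns=[1.0, 2.0, 3.0])
        out = impute_trajectories(mat)
        assert out.loc["P1", 2.0] == pytest.approx(3.0)

    def test_complete_rows_unchanged_under_both_modes(self):
        mat = pd.DataFrame([[2.0, 3.0, 4.0]], index=["P1"],
                           columns=[1.0, 2.0, 3.0])
        for mode in ("linear_interpolate", "none"):
            pd.testing.assert_frame_equal(impute_trajectories(mat, mode), mat)

    def test_leading_gap_carried_back(self):
        mat = pd.DataFrame([[np.nan, 3.0, 4.0]], index=["P1"],
                           columns=[1.0, 2.0, 3.0])
        out = impute_trajectories(mat)
        assert out.loc["P1", 1.0] == pytest.approx(3.0)

    def test_sparse_participants_excluded_with_warning(self):
        mat = pd.DataFrame([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]],
                           index=["P1", "P2"], columns=[1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="excluded 1"):
            out = impute_trajectories(mat)
        assert list(out.index) == ["P2"]


def _two_class_matrix(n=40, sep=6.0, noise=0.0, seed=0, T=10):
    """n participants with constant trajectories at 2 vs 2+sep."""
    rng = np.random.default_rng(seed)
    times = np.arange(1.0, 1.0 + T)
    truth = np.array([HIGH, LOW] * (n // 2))
    base = np.where(truth == HIGH, 2.0 + sep, 2.0)
    Y = base[:, None] + noise * rng.standard_normal((n, T))
    mat = pd.DataFrame(Y, index=[f"P{i:03d}" for i in range(n)],
                       columns=times)
    return mat, pd.Series(truth, index=mat.index)


class TestGrowthMixture:
    def test_noise_free_constant_classes_separate_perfectly(self):
        mat, truth = _two_class_matrix(noise=1e-3)
        fit = fit_gmm(mat, n_starts=5, seed=0)
        p = fit.posterior_high
        assert np.all(p[truth == HIGH].to_numpy() > 0.999)
        assert np.all(p[truth == LOW].to_numpy() < 0.001)
        # class mean trajectories recover the two constants
        assert fit.mean_trajectory(HIGH).mean() == pytest.approx(8.0, abs=0.05)
        assert fit.mean_trajectory(LOW).mean() == pytest.approx(2.0, abs=0.05)

    def test_loglik_nondecreasing_and_posteriors_normalized(self):
        mat, _ = _two_class_matrix(noise=1.5, sep=3.0, seed=3)
        fit = fit_gmm(mat, n_starts=5, seed=1)
        assert np.all(np.diff(fit.loglik_history) >= -1e-8)
        assert np.all((fit.posterior_high >= 0) & (fit.posterior_high <= 1))
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_recovery_at_three_sd_separation(self):
        from sklearn.metrics import adjusted_rand_score
        high = TrajectoryParams(intercept=7.0, slope=0.2, quadratic=-0.01,
                                within_noise_sd=1.5, between_sd=0.8)
        low = TrajectoryParams(intercept=2.5, slope=0.2, quadratic=-0.01,
                               within_noise_sd=1.5, between_sd=0.8)
        rng = np.random.default_rng(0)
        diaries, truth = [], []
        for i in range(60):
            cls = HIGH if i % 2 else LOW
            diaries.append(generate_pain_diary(f"P{i:02d}", cls, high, low,
                                               0.0, seed=int(rng.integers(2**31)),
                                               days=7))
            truth.append(cls)
        mat = build_trajectory_matrix(pd.concat(diaries), span_days=7)
        fit = fit_gmm(mat, n_starts=10, seed=0)
        pred = (fit.posterior_high > 0.5).astype(int)
        assert adjusted_rand_score([t == HIGH for t in truth], pred) >= 0.9

    def test_identical_trajectories_flag_degenerate_class(self):
        mat = pd.DataFrame(np.full((20, 8), 5.0) +
                           1e-6 * np.arange(8)[None, :],
                           index=[f"P{i}" for i in range(20)],
                           columns=np.arange(1.0, 9.0))
        with pytest.warns(UserWarning, match="near-empty"):
            fit = fit_gmm(mat, n_starts=3, seed=0)
        assert "degenerate_class" in fit.flags

    def test_label_assignment_invariant_to_participant_order(self):
        mat, _ = _two_class_matrix(n=30, noise=1.0, sep=4.0, seed=5)
        fit = fit_gmm(mat, n_starts=5, seed=2)
        labels, _ = assign_training_labels(fit, n_extreme=10)
        perm = np.random.default_rng(0).permutation(len(mat))
        fit2 = fit_gmm(mat.iloc[perm], n_starts=5, seed=2)
        labels2, _ = assign_training_labels(fit2, n_extreme=10)
        # posteriors may differ at EM tolerance; labels should not
        common = labels.dropna().index.intersection(labels2.dropna().index)
        assert len(common) >= 18
        assert (labels[common] == labels2[common]).all()


class TestLabelRules:
    def _fit(self, n=100):
        mat, truth = _two_class_matrix(n=n, noise=1.0, sep=5.0, seed=9)
        return fit_gmm(mat, n_starts=5, seed=4), truth, mat

    def test_extreme_rank_rule_labels_eighty_of_hundred(self):
        fit, truth, _ = self._fit(100)
        labels, rule = assign_training_labels(fit, n_extreme=40)
        assert labels.notna().sum() == 80
        assert (labels == HIGH).sum() == 40 and (labels == LOW).sum() == 40
        assert rule.tau_low <= rule.tau_high

    def test_separable_posteriors_give_unit_thresholds(self):
        mat, _ = _two_class_matrix(n=20, noise=1e-3)
        fit = fit_gmm(mat, n_starts=3, seed=0)
        _, rule = assign_training_labels(fit, n_extreme=10)
        assert rule.tau_high == pytest.approx(1.0, abs=1e-6)
        assert rule.tau_low == pytest.approx(0.0, abs=1e-6)

    def test_half_extreme_labels_everyone(self):
        fit, _, _ = self._fit(40)
        labels, _ = assign_training_labels(fit, n_extreme=20)
        assert labels.notna().all()

    def test_unlocked_rule_refused(self):
        rule = LabelRule(tau_high=0.9, tau_low=0.1, n_extreme=10)
        with pytest.raises(RuntimeError, match="not locked"):
            apply_locked_labels(pd.Series([0.5]), rule)

    def test_intermediate_posteriors_stay_unlabeled(self):
        rule = LabelRule(tau_high=0.9, tau_low=0.1, n_extreme=10).lock()
        p = pd.Series([0.95, 0.5, 0.05], index=list("abc"))
        labels = apply_locked_labels(p, rule)
        assert labels["a"] == HIGH and labels["c"] == LOW
        assert pd.isna(labels["b"])

    def test_locked_model_labels_subset_of_new_cohort(self):
        fit, _, mat = self._fit(100)
        _, rule = assign_training_labels(fit, n_extreme=40)
        rule.lock()
        new_mat, _ = _two_class_matrix(n=30, noise=1.5, sep=5.0, seed=77)
        posteriors = posterior_for(fit, new_mat)
        labels = apply_locked_labels(posteriors, rule)
        assert 0 < labels.notna().sum() <= 30


class TestNoiseFreeDiary:
    def test_diary_reproduces_class_polynomial_after_clipping(self):
        params = TrajectoryParams(intercept=1.0, slope=2.0, quadratic=-0.15,
                                  within_noise_sd=1e-9, between_sd=0.0)
        diary = generate_pain_diary("P1", HIGH, params, params, 0.0, seed=0)
        mat = build_trajectory_matrix(diary, span_days=30)
        t = mat.columns.to_numpy(float)
        expected = np.clip(params.mean(t), 0, 20)
        assert np.max(np.abs(mat.to_numpy()[0] - expected)) <= 0.5

    def test_zero_missing_rate_is_complete(self):
        diary = generate_pain_diary("P1", LOW, DEFAULT_LOW_TRAJECTORY,
                                    DEFAULT_LOW_TRAJECTORY, 0.0, seed=2)
        assert len(diary) == 30 * 2 * 2
        assert diary["score"].notna().all()
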