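"""ROC/AUC machinery, nested CV, locking discipline and cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from corticomark.models import (covariate_model,
                                covariate_feature_selection, internal_cv,
                                optimal_threshold, paf_cutoffs,
                                predict_blinded, roc_auc, select_and_lock)


def _pairwise_auc(scores, y):
    """O(n^2) concordant-pair oracle with half-credit ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def _feature_frame(n=80, paf_shift=-1.0, p_dep_high=0.8, seed=0,
                   covariates=False):
    """Planted-effect feature table: high-pain rows have slower alpha and
    more corticomotor depression."""
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    paf = 10.0 + paf_shift * y + rng.normal(0, 0.4, n)
    p_dep = np.where(y == 1, p_dep_high, 1 - p_dep_high)
    cme = (rng.random(n) >= p_dep).astype(float)  # 1 = facilitator
    df = pd.DataFrame({
        "participant": [f"P{i:03d}" for i in range(n)],
        "paf_hz": paf, "cme_class": cme,
        "label": np.where(y == 1, "high", "low")})
    if covariates:
        df["sex"] = rng.integers(0, 2, n).astype(float)
        df["pcs_total"] = rng.normal(14, 8, n).round()
        df["pcs_helplessness"] = rng.normal(5, 2, n).round()
    return df


class TestRocAuc:
    def test_separated_scores_give_unit_auc(self):
        r = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], ci=False)
        assert r.auc == 1.0
        assert r.band == "outstanding"

    def test_constant_scores_give_half(self):
        r = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0], ci=False)
        assert r.auc == 0.5

    @given(st.integers(0, 2**31 - 1), st.integers(4, 60))
    @settings(max_examples=100, deadline=None)
    def test_rank_formula_matches_pairwise_oracle_with_ties(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.3, 0.5, 0.9], size=n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        r = roc_auc(scores, y, ci=False)
        assert r.auc == pytest.approx(_pairwise_auc(scores, y), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        from sklearn.metrics import roc_auc_score
        assert roc_auc(scores, y, ci=False).auc == pytest.approx(
            roc_auc_score(y, scores))

    def test_bootstrap_ci_brackets_the_estimate(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        y = np.array([1] * 30 + [0] * 30)
        r = roc_auc(scores, y, n_boot=500, seed=1)
        assert r.ci_low <= r.auc <= r.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestOptimalThreshold:
    def test_perfect_separation_reports_smallest_achieving_tau(self):
        tau, sens, spec = optimal_threshold([0.9, 0.8, 0.2, 0.1],
                                            [1, 1, 0, 0])
        assert tau == pytest.approx(0.8)
        assert sens == 1.0 and spec == 1.0

    def test_four_point_hand_case(self):
        # J by threshold: 0.1 -> 0, 0.2 -> 0.5, 0.6 -> 0, 0.8 -> 0.5
        scores = [0.8, 0.6, 0.2, 0.1]
        y = [1, 0, 1, 0]
        tau, sens, spec = optimal_threshold(scores, y)
        assert sens + spec - 1 == pytest.approx(0.5)
        assert tau == pytest.approx(0.2)  # smallest among the J ties

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 7), size=20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        tau, sens, spec = optimal_threshold(scores, y)
        best_j = max(
            ((scores >= t) & (y == 1)).sum() / (y == 1).sum()
            + ((scores < t) & (y == 0)).sum() / (y == 0).sum() - 1
            for t in np.unique(scores))
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_random_scores_have_small_j(self, rng):
        js = []
        for _ in range(20):
            scores = rng.random(200)
            y = rng.integers(0, 2, 200)
            y[:2] = [0, 1]
            _, sens, spec = optimal_threshold(scores, y)
            js.append(sens + spec - 1)
        assert np.mean(js) < 0.25


class TestInternalCV:
    def test_partition_sizes_are_64_16_with_four_folds_of_16(self):
        res = internal_cv(_feature_frame(80), families=("logistic_regression",),
                          seed=0)[0]
        assert res.n_internal_train == 64
        assert res.n_validation == 16
        assert res.internal_fold_sizes == [16, 16, 16, 16]

    def test_separable_features_reach_unit_validation_auc(self):
        df = _feature_frame(80, paf_shift=-6.0, p_dep_high=1.0, seed=1)
        df["paf_hz"] = np.where(df["label"] == "high", 8.0, 11.9)
        for res in internal_cv(df, seed=0):
            assert res.validation_auc == pytest.approx(1.0)

    def test_label_permutation_null_is_centered(self):
        aucs = []
        for seed in range(20):
            df = _feature_frame(80, paf_shift=0.0, p_dep_high=0.5, seed=seed)
            res = internal_cv(df, families=("logistic_regression",),
                              seed=seed)[0]
            aucs.append(res.validation_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestLocking:
    def _locked(self, **kw):
        df = _feature_frame(80, **kw)
        cv = internal_cv(df, families=("logistic_regression",), seed=0)
        return select_and_lock(cv, df, seed=0), df

    def test_single_family_is_locked(self):
        model, _ = self._locked()
        assert model.family == "logistic_regression"
        assert model.locked

    def test_tie_goes_to_simplest_family(self):
        df = _feature_frame(80)
        cv = internal_cv(df, families=("random_forest",
                                       "logistic_regression"), seed=0)
        for r in cv:
            r.validation_auc = 0.9
        model = select_and_lock(cv, df, seed=0)
        assert model.family == "logistic_regression"

    def test_planted_effect_recovers_negative_signs(self):
        # slower alpha and depression in the high-pain class must appear as
        # negative standardized coefficients for both features
        model, _ = self._locked(paf_shift=-1.0, p_dep_high=0.8)
        names = model.feature_names
        assert model.coefficients[names.index("paf_hz")] < 0
        assert model.coefficients[names.index("cme_class")] < 0

    def test_tampering_is_detected(self):
        model, df = self._locked()
        model.scaler_mean = model.scaler_mean + 0.1
        with pytest.raises(RuntimeError, match="integrity"):
            predict_blinded(model, df, df["label"].to_numpy(),
                            np.arange(len(df)))

    def test_unlocked_model_refused(self):
        model, df = self._locked()
        model.locked = False
        with pytest.raises(RuntimeError, match="not locked"):
            predict_blinded(model, df, df["label"].to_numpy(),
                            np.arange(len(df)))


class TestBlindedPrediction:
    def test_scores_invariant_to_row_permutation(self):
        model_df = _feature_frame(80)
        cv = internal_cv(model_df, families=("logistic_regression",), seed=0)
        model = select_and_lock(cv, model_df, seed=0)
        test = _feature_frame(30, seed=5)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(test))
        base = model.scores(test)
        shuffled_rows = test.iloc[perm].reset_index(drop=True)
        assert np.allclose(model.scores(shuffled_rows), base[perm])

    def test_unshuffling_restores_alignment(self):
        model_df = _feature_frame(80)
        cv = internal_cv(model_df, families=("logistic_regression",), seed=0)
        model = select_and_lock(cv, model_df, seed=0)
        test = _feature_frame(30, seed=6)
        perm = np.random.default_rng(3).permutation(len(test))
        shuffled_truth = test["label"].to_numpy()[perm]
        blinded = predict_blinded(model, test, shuffled_truth, perm, seed=0)
        direct = roc_auc(model.scores(test), test["label"].to_numpy(),
                         ci=False)
        assert blinded.roc.auc == pytest.approx(direct.auc)

    def test_coin_flip_scores_sit_in_the_binomial_null_band(self):
        model_df = _feature_frame(80)
        cv = internal_cv(model_df, families=("logistic_regression",), seed=0)
        model = select_and_lock(cv, model_df, seed=0)
        aucs = []
        rng = np.random.default_rng(0)
        for _ in range(50):
            test = _feature_frame(38, paf_shift=0.0, p_dep_high=0.5,
                                  seed=int(rng.integers(2**31)))
            blinded = predict_blinded(model, test,
                                      test["label"].to_numpy(),
                                      np.arange(len(test)), seed=0)
            aucs.append(blinded.roc.auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestPafCutoffs:
    def _model(self, seed=0):
        df = _feature_frame(80, seed=seed)
        cv = internal_cv(df, families=("logistic_regression",), seed=seed)
        return select_and_lock(cv, df, seed=seed)

    def test_cutoff_participant_sits_on_decision_boundary(self):
        model = self._model()
        cuts = paf_cutoffs(model)
        for cme_value, key in ((1.0, "facilitator"), (0.0, "depressor")):
            probe = pd.DataFrame({"paf_hz": [cuts[key]],
                                  "cme_class": [cme_value]})
            p = model.scores(probe)[0]
            assert p == pytest.approx(model.probability_threshold, abs=1e-6)

    def test_cutoff_gap_matches_closed_form(self):
        model = self._model(seed=3)
        cuts = paf_cutoffs(model)
        i_paf = model.feature_names.index("paf_hz")
        i_cme = model.feature_names.index("cme_class")
        b = model.coefficients
        expected_gap = (- b[i_cme] / model.scaler_scale[i_cme]
                        / (b[i_paf] / model.scaler_scale[i_paf]))
        assert cuts["facilitator"] - cuts["depressor"] == pytest.approx(
            expected_gap, abs=1e-9)

    def test_facilitators_need_slower_alpha_when_both_signs_negative(self):
        for seed in range(3):
            model = self._model(seed=seed)
            assert all(c < 0 for c in model.coefficients)
            cuts = paf_cutoffs(model)
            assert cuts["facilitator"] < cuts["depressor"]

    def test_zero_paf_coefficient_reported_as_no_cutoff(self):
        model = self._model()
        model.coefficients[model.feature_names.index("paf_hz")] = 0.0
        model.intercept = float(model.intercept)
        assert paf_cutoffs(model)["facilitator"] is None

    def test_non_logistic_model_rejected(self):
        df = _feature_frame(80)
        cv = internal_cv(df, families=("random_forest",), seed=0)
        model = select_and_lock(cv, df, seed=0)
        with pytest.raises(ValueError, match="logistic"):
            paf_cutoffs(model)


class TestCovariateModel:
    def test_independent_covariates_rarely_selected(self):
        picked = []
        for seed in range(5):
            df = _feature_frame(80, covariates=True, seed=seed)
            table = covariate_feature_selection(
                df, ["paf_hz", "cme_class", "sex", "pcs_total",
                     "pcs_helplessness"])
            sel = set(table.loc[table.selected, "feature"])
            picked.append(sel)
            assert "paf_hz" in sel          # the planted effect survives
        covariate_hits = sum(bool(s & {"sex", "pcs_total",
                                       "pcs_helplessness"}) for s in picked)
        assert covariate_hits <= 2          # ~5% false-positive rate each

    def test_duplicated_feature_selected_once(self):
        df = _feature_frame(80)
        table = covariate_feature_selection(
            df, ["paf_hz", "paf_hz", "cme_class"])
        assert table["feature"].tolist() == ["paf_hz", "cme_class"]

    def test_fallback_when_nothing_survives(self):
        df = _feature_frame(80, paf_shift=0.0, p_dep_high=0.5,
                            covariates=True, seed=9)
        with pytest.warns(UserWarning, match="falling back"):
            model, _ = covariate_model(df, seed=0, p_threshold=1e-12)
        assert model.feature_names == ["paf_hz", "cme_class"]
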