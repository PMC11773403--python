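"""Locked-model biomarker classification and ROC utilities.

The feature table carries two biomarkers per participant — sensorimotor
peak alpha frequency (Hz) and the facilitator/depressor corticomotor class
— plus optional covariates. Five candidate classifier families are tuned
and compared on the labelled training set with a nested internal split
(64 train / 16 validation out of 80, hyperparameters by 4-fold CV over the
64); the family with the best validation AUC is refit on all labelled
training rows, its standardisation constants and probability threshold are
frozen, and the locked model is applied exactly once to a blinded,
permuted test set.

Sign conventions: high pain sensitivity is the positive class and the
corticomotor class is coded facilitator = 1 / depressor = 0, so slower
alpha and corticomotor depression predicting higher pain appear as
negative logistic coefficients for both features.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .trajectory import HIGH, LOW

BIOMARKER_FEATURES = ["paf_hz", "cme_class"]
COVARIATE_FEATURES = ["sex", "pcs_total", "pcs_helplessness"]
BINARY_FEATURES = {"cme_class", "sex"}

#: candidate families in tie-break order (fewest parameters first)
FAMILIES = ("logistic_regression", "svm", "neural_network",
            "random_forest", "gradient_boosting")

AUC_BANDS = ((0.9, "outstanding"), (0.8, "excellent"), (0.7, "acceptable"))


def auc_band(auc: float) -> str:
    for lo, name in AUC_BANDS:
        if auc >= lo:
            return name
    return "below"


# ---------------------------------------------------------------------------
# ROC / AUC

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def band(self) -> str:
        return auc_band(self.auc)


def _auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the probability that a random positive outscores a random
    negative, ties counting one half (midrank Mann-Whitney form)."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores, labels, ci: bool = True, n_boot: int = 2000,
            seed: int = 0) -> ROCResult:
    """ROC AUC with a stratified percentile-bootstrap 95% CI.

    ``labels`` may be 0/1 or the high/low strings; high is positive.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    y = _binarize(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute an AUC")
    auc = _auc_rank(scores, y)
    fpr, tpr, thr = roc_curve(y, scores)
    lo = hi = auc
    if ci:
        rng = np.random.default_rng(seed)
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate([rng.choice(pos, pos.size, replace=True),
                                   rng.choice(neg, neg.size, replace=True)])
            boots[b] = _auc_rank(scores[take], y[take])
        lo, hi = np.percentile(boots, [2.5, 97.5])
    return ROCResult(auc=auc, ci_low=float(lo), ci_high=float(hi),
                     fpr=fpr, tpr=tpr, thresholds=thr)


def optimal_threshold(scores, labels) -> tuple[float, float, float]:
    """Probability threshold maximising Youden's J = sens + spec - 1.

    Classification rule: score >= tau is positive. Candidate thresholds are
    the observed scores; among ties on J the smallest tau is returned.
    Returns ``(tau, sensitivity, specificity)`` at that threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binarize(labels)
    n_pos, n_neg = y.sum(), (1 - y).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best = None
    for tau in np.unique(scores):
        pred = scores >= tau
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(tau), float(sens), float(spec))
    return best[1], best[2], best[3]


def _binarize(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        known = {HIGH: 1, LOW: 0}
        bad = [v for v in np.unique(arr) if v not in known]
        if bad:
            raise ValueError(f"unknown labels: {bad}")
        return np.array([known[v] for v in arr], dtype=int)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# model families

def _make_estimator(family: str, seed: int):
    """Pipeline of training-fitted standardisation + one classifier family,
    with its (deliberately small, published) hyperparameter grid."""
    from sklearn.ensemble import (GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if family == "logistic_regression":
        clf = LogisticRegression(max_iter=2000)
        grid = {"clf__C": [0.1, 1.0, 10.0]}
    elif family == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
        grid = {"clf__max_depth": [2, 4]}
    elif family == "gradient_boosting":
        clf = GradientBoostingClassifier(n_estimators=50, random_state=seed)
        grid = {"clf__max_depth": [1, 2]}
    elif family == "svm":
        clf = SVC(probability=True, random_state=seed)
        grid = {"clf__C": [0.5, 2.0]}
    elif family == "neural_network":
        clf = MLPClassifier(hidden_layer_sizes=(8,), max_iter=1000,
                            random_state=seed)
        grid = {"clf__alpha": [1e-3, 1e-1]}
    else:
        raise ValueError(f"unknown model family {family!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return pipe, grid


@dataclass
class CVResult:
    family: str
    validation_auc: float
    best_params: dict
    estimator: object            # tuned pipeline refit on the internal 64
    internal_fold_sizes: list[int]
    n_internal_train: int
    n_validation: int


def _labeled_xy(features: pd.DataFrame, feature_names: list[str]
                ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    lab = features.dropna(subset=["label"])
    lab = lab[lab["label"].isin([HIGH, LOW])]
    X = lab[feature_names].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("labelled rows must have complete features")
    y = _binarize(lab["label"].to_numpy())
    return X, y, lab


def internal_cv(features: pd.DataFrame,
                families: tuple[str, ...] = FAMILIES,
                feature_names: list[str] | None = None,
                seed: int = 0) -> list[CVResult]:
    """Tune and compare candidate families on the labelled training set.

    The labelled rows (80 by design) are split 64/16: the held-out 16 form
    the validation set and the 64 are divided into four stratified folds of
    16 for hyperparameter tuning. Each family's tuned model is scored by
    validation-set AUC.
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold

    feature_names = feature_names or BIOMARKER_FEATURES
    X, y, _ = _labeled_xy(features, feature_names)
    n = y.size
    if min((y == 1).sum(), (y == 0).sum()) < 5:
        raise ValueError("need >= 5 labelled rows per class to stratify "
                         "the 5 internal partitions")
    outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    val_idx = next(iter(outer.split(X, y)))[1]
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]
    inner = StratifiedKFold(n_splits=4, shuffle=True, random_state=seed)
    folds = list(inner.split(Xtr, ytr))

    results = []
    for family in families:
        pipe, grid = _make_estimator(family, seed)
        search = GridSearchCV(pipe, grid, cv=folds, scoring="roc_auc",
                              refit=True, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(Xtr, ytr)
        scores = search.best_estimator_.predict_proba(Xval)[:, 1]
        val_auc = roc_auc(scores, yval, ci=False).auc
        results.append(CVResult(
            family=family, validation_auc=val_auc,
            best_params=search.best_params_,
            estimator=search.best_estimator_,
            internal_fold_sizes=[len(te) for _, te in folds],
            n_internal_train=len(train_idx), n_validation=len(val_idx)))
    return results


# ---------------------------------------------------------------------------
# locking

@dataclass
class LockedModel:
    """A frozen classifier: parameters, standardisation constants and
    probability threshold fixed before the test set is seen.

    ``params_hash`` fingerprints the frozen state; prediction refuses to
    run if the stored hash no longer matches (tamper detection).
    """

    family: str
    feature_names: list[str]
    estimator: object
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    probability_threshold: float
    validation_auc: float
    best_params: dict
    lock_timestamp: float = 0.0
    params_hash: str = ""
    coefficients: np.ndarray | None = None   # logistic only, standardized
    intercept: float | None = None
    locked: bool = field(default=False)

    def _state_digest(self) -> str:
        parts = [self.family, json.dumps(self.feature_names),
                 np.asarray(self.scaler_mean).tobytes(),
                 np.asarray(self.scaler_scale).tobytes(),
                 f"{self.probability_threshold:.12g}"]
        if self.coefficients is not None:
            parts.append(np.asarray(self.coefficients).tobytes())
            parts.append(f"{self.intercept:.12g}")
        h = hashlib.sha256()
        for p in parts:
            h.update(p if isinstance(p, bytes) else p.encode())
        return h.hexdigest()

    def lock(self) -> "LockedModel":
        self.lock_timestamp = time.time()
        self.params_hash = self._state_digest()
        self.locked = True
        return self

    def verify(self) -> None:
        if not self.locked:
            raise RuntimeError("model is not locked; lock() before "
                               "predicting the test set")
        if self._state_digest() != self.params_hash:
            raise RuntimeError("locked-model integrity check failed: "
                               "parameters changed after locking")

    def scores(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]

    def to_json(self) -> str:
        payload = {
            "family": self.family,
            "feature_names": self.feature_names,
            "scaler_mean": np.asarray(self.scaler_mean).tolist(),
            "scaler_scale": np.asarray(self.scaler_scale).tolist(),
            "probability_threshold": self.probability_threshold,
            "validation_auc": self.validation_auc,
            "best_params": self.best_params,
            "lock_timestamp": self.lock_timestamp,
            "params_hash": self.params_hash,
            "coefficients": (None if self.coefficients is None
                             else np.asarray(self.coefficients).tolist()),
            "intercept": self.intercept,
        }
        return json.dumps(payload, indent=2)


def select_and_lock(cv_results: list[CVResult], features: pd.DataFrame,
                    feature_names: list[str] | None = None,
                    seed: int = 0,
                    threshold_scores: str = "refit") -> LockedModel:
    """Pick the best family by validation AUC, refit on all labelled rows,
    freeze standardisation constants and the Youden probability threshold.

    Ties on validation AUC go to the family with the fewest parameters
    (the ``FAMILIES`` order).
    """
    if not cv_results:
        raise ValueError("no candidate families evaluated")
    feature_names = feature_names or BIOMARKER_FEATURES
    rank = {f: i for i, f in enumerate(FAMILIES)}
    best = max(cv_results,
               key=lambda r: (r.validation_auc, -rank.get(r.family, 99)))
    X, y, _ = _labeled_xy(features, feature_names)
    pipe, _ = _make_estimator(best.family, seed)
    pipe.set_params(**best.best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pipe.fit(X, y)
    scaler = pipe.named_steps["scale"]
    clf = pipe.named_steps["clf"]
    coef = inter = None
    if best.family == "logistic_regression":
        coef = clf.coef_[0].copy()
        inter = float(clf.intercept_[0])
    train_scores = pipe.predict_proba(X)[:, 1]
    tau, _, _ = optimal_threshold(train_scores, y)
    model = LockedModel(
        family=best.family, feature_names=list(feature_names),
        estimator=pipe, scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(), probability_threshold=float(tau),
        validation_auc=best.validation_auc, best_params=best.best_params,
        coefficients=coef, intercept=inter)
    return model.lock()


# ---------------------------------------------------------------------------
# blinded test prediction

@dataclass
class BlindedResult:
    roc: ROCResult
    sensitivity: float
    specificity: float
    threshold: float
    confusion: dict
    n_test: int


def predict_blinded(model: LockedModel, test_features: pd.DataFrame,
                    shuffled_labels, permutation,
                    seed: int = 0) -> BlindedResult:
    """Score the blinded test set and evaluate against shuffled truth.

    ``shuffled_labels[j]`` is the true label of the participant in row
    ``permutation[j]`` of ``test_features``; the permutation (recorded
    before prediction) is inverted only at scoring time, so predictions are
    computed without access to aligned truth. Per-participant scores are a
    pure function of that participant's features, hence invariant to row
    order.
    """
    model.verify()
    perm = np.asarray(permutation, dtype=int)
    n = len(test_features)
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("permutation must be a permutation of the test rows")
    scores = model.scores(test_features)
    y = np.empty(n, dtype=int)
    y[perm] = _binarize(shuffled_labels)      # un-shuffle the truth
    roc = roc_auc(scores, y, seed=seed)
    tau = model.probability_threshold
    pred = scores >= tau
    tp = int((pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    return BlindedResult(roc=roc, sensitivity=sens, specificity=spec,
                         threshold=tau,
                         confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
                         n_test=n)


# ---------------------------------------------------------------------------
# raw-Hz cutoffs from a locked logistic model

def paf_cutoffs(model: LockedModel, tau: float | None = None
                ) -> dict[str, float | None]:
    """Raw-Hz PAF value below which a participant is classified high pain
    sensitive, separately per corticomotor class.

    For a logistic model on standardised PAF and the binary corticomotor
    code c, the decision boundary at probability tau solves
    ``b0 + b_paf * z(paf) + b_cme * c = logit(tau)``; inverting the
    training standardisation gives one raw-Hz cutoff per class (two
    parallel boundaries). Returns None per class when ``b_paf`` is 0.
    """
    if model.family != "logistic_regression" or model.coefficients is None:
        raise ValueError("raw-Hz cutoffs require a locked logistic model")
    names = model.feature_names
    if "paf_hz" not in names or "cme_class" not in names:
        raise ValueError("model must use paf_hz and cme_class features")
    tau = model.probability_threshold if tau is None else tau
    i_paf, i_cme = names.index("paf_hz"), names.index("cme_class")
    b0, b = model.intercept, model.coefficients
    out: dict[str, float | None] = {}
    for label, c in (("facilitator", 1.0), ("depressor", 0.0)):
        if b[i_paf] == 0:
            out[label] = None
            continue
        # contribution of any further (covariate) features is taken at the
        # training mean, i.e. standardised 0
        z = (logit(tau) - b0 - b[i_cme] * (c - model.scaler_mean[i_cme])
             / model.scaler_scale[i_cme]) / b[i_paf]
        out[label] = float(model.scaler_mean[i_paf]
                           + model.scaler_scale[i_paf] * z)
    return out


# ---------------------------------------------------------------------------
# covariate-augmented variant

def covariate_feature_selection(features: pd.DataFrame,
                                candidates: list[str],
                                p_threshold: float = 0.05) -> pd.DataFrame:
    """Univariate label association per candidate feature.

    Continuous features use a two-sample t test across labels, binary
    features a Fisher exact test. Returns a frame of p-values with a
    ``selected`` column (p < threshold).
    """
    _, y, lab = _labeled_xy(features, list(dict.fromkeys(candidates)))
    rows = []
    for name in dict.fromkeys(candidates):
        x = lab[name].to_numpy(dtype=float)
        if name in BINARY_FEATURES or set(np.unique(x)) <= {0.0, 1.0}:
            table = [[(x[y == g] == v).sum() for v in (0, 1)] for g in (0, 1)]
            p = stats.fisher_exact(table)[1]
            kind = "binary"
        else:
            p = stats.ttest_ind(x[y == 1], x[y == 0]).pvalue
            kind = "continuous"
        rows.append({"feature": name, "kind": kind, "p_value": float(p),
                     "selected": bool(p < p_threshold)})
    return pd.DataFrame(rows)


def covariate_model(features: pd.DataFrame, seed: int = 0,
                    p_threshold: float = 0.05,
                    candidates: list[str] | None = None
                    ) -> tuple[LockedModel, pd.DataFrame]:
    """Fit the covariate-augmented logistic variant after p-value feature
    filtering; falls back to the biomarkers when nothing survives."""
    candidates = candidates or (BIOMARKER_FEATURES + COVARIATE_FEATURES)
    table = covariate_feature_selection(features, candidates, p_threshold)
    selected = table.loc[table["selected"], "feature"].tolist()
    if not selected:
        warnings.warn("no feature passed the p-value filter; falling back "
                      "to the biomarker-only feature set", stacklevel=2)
        selected = list(BIOMARKER_FEATURES)
    cv = internal_cv(features, families=("logistic_regression",),
                     feature_names=selected, seed=seed)
    model = select_and_lock(cv, features, feature_names=selected, seed=seed)
    return model, table


def robustness_grid(*args, **kwargs):
    """Re-run the full pipeline over a grid of methodological choices; see
    :func:`corticomark.pipeline.robustness_grid` (re-exported here)."""
    from .pipeline import robustness_grid as _grid
    return _grid(*args, **kwargs)
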