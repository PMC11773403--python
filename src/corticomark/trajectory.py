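"""Growth mixture modelling of longitudinal pain diaries.

Participants rate pain (0-10) during jaw activities twice daily for 30
days; the analysed outcome is the summed chewing + yawning score (0-20).
A two-class growth mixture model (GMM) — a finite mixture of class-specific
polynomial mean trajectories with a participant random intercept and
homoscedastic Gaussian residuals — is fitted by EM to the first seven diary
days (where pain is most prominent) and yields a posterior probability of
belonging to the *high pain sensitive* class for every participant.

Training-set labels are assigned by posterior rank: the ``n_extreme`` most
and least probable participants are labelled high/low pain sensitive and
the posterior values at those ranks become locked thresholds. The locked
model and thresholds then label a test set, typically leaving participants
with intermediate posteriors unlabelled.

Model, for participant *i* in latent class *k* with observation times
:math:`t_1..t_{T_i}`:

.. math::

    y_{it} = \\beta_{k0} + \\beta_{k1} t + \\beta_{k2} t^2 + b_i +
             \\varepsilon_{it},\\qquad
    b_i \\sim N(0, \\tau^2),\\;
    \\varepsilon_{it} \\sim N(0, \\sigma^2)

so the marginal covariance within a participant is compound-symmetric,
:math:`\\sigma^2 I + \\tau^2 \\mathbf{1}\\mathbf{1}^\\top`, which the EM
exploits in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

REQUIRED_ACTIVITIES = ("chewing", "yawning")

#: within-day encoding of the two diary prompts: 10 am at the day mark,
#: 7 pm at +0.375 day (9 h / 24 h)
TIME_OFFSETS = {"10:00": 0.0, "19:00": 0.375}

HIGH, LOW = "high", "low"

_VAR_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# diary -> trajectory matrix

def compute_pain_scores(diary: pd.DataFrame,
                        activities: tuple[str, ...] = REQUIRED_ACTIVITIES
                        ) -> pd.DataFrame:
    """Sum the per-activity scores into one pain score per timepoint.

    Expects long-format columns ``participant, day, time, activity, score``
    (score NaN when missing). The summed score is missing whenever any
    requested activity is missing at that timepoint (imputation, if any,
    happens later on the trajectory matrix).
    """
    present = set(diary["activity"].unique())
    unknown = [a for a in activities if a not in present]
    if unknown:
        raise ValueError(f"activities not present in diary: {unknown}")
    sub = diary[diary["activity"].isin(activities)]
    wide = sub.pivot_table(index=["participant", "day", "time"],
                           columns="activity", values="score",
                           aggfunc="first", dropna=False)
    total = wide[list(activities)].sum(axis=1, min_count=len(activities))
    return total.rename("pain_score").reset_index()


def build_trajectory_matrix(diary: pd.DataFrame,
                            span_days: int = 7,
                            activities: tuple[str, ...] = REQUIRED_ACTIVITIES
                            ) -> pd.DataFrame:
    """Participant x timepoint matrix of summed pain scores.

    Columns are chronological fractional days (``day + 0`` for 10 am,
    ``day + 0.375`` for 7 pm) over diary days ``1..span_days``; values are
    0-20 or NaN.
    """
    scores = compute_pain_scores(diary, activities)
    scores = scores[scores["day"] <= span_days]
    t = scores["day"].astype(float) + scores["time"].map(TIME_OFFSETS)
    if t.isna().any():
        bad = scores.loc[t.isna(), "time"].unique()
        raise ValueError(f"unknown diary times: {list(bad)}")
    scores = scores.assign(t=t)
    mat = scores.pivot_table(index="participant", columns="t",
                             values="pain_score", dropna=False)
    # preserve enrollment order of participants
    order = diary["participant"].drop_duplicates().tolist()
    return mat.reindex([p for p in order if p in mat.index])


def impute_trajectories(matrix: pd.DataFrame,
                        mode: str = "linear_interpolate") -> pd.DataFrame:
    """Fill diary gaps, or leave them (``mode='none'``).

    Linear interpolation fills interior gaps along time; leading/trailing
    gaps take the nearest observed value. Participants with fewer than two
    observed timepoints cannot be interpolated and are dropped with a
    warning.
    """
    if mode == "none":
        return matrix.copy()
    if mode != "linear_interpolate":
        raise ValueError(f"unknown imputation mode {mode!r}")
    n_obs = matrix.notna().sum(axis=1)
    thin = matrix.index[n_obs < 2]
    if len(thin):
        warnings.warn(
            f"excluded {len(thin)} participant(s) with < 2 observed "
            f"diary timepoints: {list(thin)}", stacklevel=2)
    out = matrix.drop(index=thin)
    cols = out.columns.to_numpy(dtype=float)
    filled = out.T.set_axis(cols).interpolate(
        method="index", limit_direction="both").T
    filled.columns = out.columns
    return filled


# ---------------------------------------------------------------------------
# growth mixture EM

@dataclass
class GrowthMixtureFit:
    """A fitted two-class growth mixture model."""

    coefficients: np.ndarray      # (2, degree+1); row 0 = low, row 1 = high
    sigma2: float                 # residual variance
    tau2: float                   # random-intercept variance
    weights: np.ndarray           # mixing proportions, row order as above
    times: np.ndarray             # timepoints the model was fitted on
    degree: int
    posterior_high: pd.Series     # participant -> P(high class)
    loglik: float
    loglik_history: np.ndarray    # of the winning start
    n_starts_converged: int
    flags: list[str] = field(default_factory=list)

    def mean_trajectory(self, cls: str, t: np.ndarray | None = None
                        ) -> np.ndarray:
        t = self.times if t is None else np.asarray(t, dtype=float)
        beta = self.coefficients[1 if cls == HIGH else 0]
        return _design(t, self.degree) @ beta


@dataclass
class LabelRule:
    """Locked posterior-probability thresholds for labelling a test set."""

    tau_high: float
    tau_low: float
    n_extreme: int
    locked: bool = False

    def __post_init__(self) -> None:
        if self.tau_low > self.tau_high + 1e-12:
            raise ValueError("tau_low must not exceed tau_high")

    def lock(self) -> "LabelRule":
        self.locked = True
        return self


def _design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(np.asarray(t, dtype=float), degree + 1,
                     increasing=True)


def _loglik_terms(Y0, mask, Ti, mu, sigma2, tau2):
    """Per-participant, per-class Gaussian log-likelihood (K x n) plus the
    sufficient statistics S (sum of residuals) under compound symmetry."""
    # residuals with missing entries zeroed; mu is (K, T)
    R = (Y0[None, :, :] - mu[:, None, :]) * mask[None, :, :]   # (K, n, T)
    S = R.sum(axis=2)                                          # (K, n)
    sq = (R**2).sum(axis=2)                                    # (K, n)
    denom = sigma2 + Ti * tau2                                 # (n,)
    quad = (sq - (tau2 / denom)[None, :] * S**2) / sigma2
    logdet = (Ti - 1) * np.log(sigma2) + np.log(denom)
    ll = -0.5 * (Ti * np.log(2 * np.pi) + logdet)[None, :] - 0.5 * quad
    return ll, S


def _m_step(Y0, mask, Ti, resp, sigma2, tau2, X, degree):
    """Multicycle ECM update: class polynomials by responsibility-weighted
    least squares on the raw outcomes (the exact marginal maximizer here,
    because the intercept column spans the compound-symmetry direction),
    then the random-intercept posterior is refreshed before the closed-form
    variance updates."""
    n, T = Y0.shape
    K = resp.shape[0]
    beta = np.empty((K, degree + 1))
    for k in range(K):
        w_t = (resp[k][:, None] * mask)                        # (n, T)
        XtWX = X.T @ (w_t.sum(axis=0)[:, None] * X)
        XtWy = X.T @ (w_t * Y0).sum(axis=0)
        beta[k] = np.linalg.solve(XtWX, XtWy)
    mu = beta @ X.T                                            # (K, T)
    # posterior of the random intercept given the fresh class means
    _, S = _loglik_terms(Y0, mask, Ti, mu, sigma2, tau2)
    denom = sigma2 + Ti * tau2
    m = (tau2 / denom)[None, :] * S                            # E[b_i | k]
    v = tau2 * sigma2 / denom                                  # Var[b_i | k]
    R = (Y0[None, :, :] - mu[:, None, :] - m[:, :, None]) * mask[None, :, :]
    sigma2 = float((resp * ((R**2).sum(axis=2) + Ti[None, :] * v)).sum()
                   / (resp * Ti[None, :]).sum())
    tau2 = float((resp * (m**2 + v)).sum() / n)
    weights = resp.mean(axis=1)
    return beta, max(sigma2, _VAR_FLOOR), max(tau2, _VAR_FLOOR), weights


def _run_em(Y0, mask, Ti, X, degree, beta, sigma2, tau2, weights,
            max_iter, tol):
    history = []
    prev = -np.inf
    for _ in range(max_iter):
        mu = beta @ X.T
        ll, _ = _loglik_terms(Y0, mask, Ti, mu, sigma2, tau2)
        logw = np.log(np.maximum(weights, 1e-300))[:, None] + ll
        norm = logsumexp(logw, axis=0)
        loglik = float(norm.sum())
        history.append(loglik)
        resp = np.exp(logw - norm[None, :])
        beta, sigma2, tau2, weights = _m_step(
            Y0, mask, Ti, resp, sigma2, tau2, X, degree)
        # relative criterion: variance-component ridges improve the
        # log-likelihood by slowly decaying slivers forever
        if loglik - prev < tol * max(1.0, abs(loglik)) and np.isfinite(prev):
            return beta, sigma2, tau2, weights, resp, np.array(history), True
        prev = loglik
    return beta, sigma2, tau2, weights, resp, np.array(history), False


def _init_from_assignment(Y0, mask, Ti, X, hard, K, degree):
    resp = np.zeros((K, Y0.shape[0]))
    resp[hard, np.arange(Y0.shape[0])] = 1.0
    resp = 0.9 * resp + 0.1 / K                     # soften hard labels
    subj_mean = (Y0 * mask).sum(axis=1) / np.maximum(Ti, 1)
    tau2_seed = max(float(np.var(subj_mean)) * 0.5, 1e-3)
    beta, sigma2, tau2, weights = _m_step(Y0, mask, Ti, resp,
                                          1.0, tau2_seed, X, degree)
    return beta, sigma2, max(tau2, 1e-4), weights


def fit_gmm(matrix: pd.DataFrame,
            n_classes: int = 2,
            degree: int = 2,
            n_starts: int = 50,
            seed: int = 0,
            max_iter: int = 1000,
            tol: float = 1e-6) -> GrowthMixtureFit:
    """Fit the growth mixture model by multi-start EM.

    The first start uses k-means responsibilities; the remaining starts use
    random soft assignments. The best converged start by log-likelihood
    wins. Classes are anchored so that class "high" has the larger mean
    trajectory integral, making posteriors comparable across fits.
    """
    if n_classes != 2:
        raise NotImplementedError("two trajectory classes are supported")
    work = matrix.dropna(how="all")
    times = work.columns.to_numpy(dtype=float)
    n, T = work.shape
    if T < degree + 2:
        raise ValueError(f"need >= {degree + 2} timepoints for a degree-"
                         f"{degree} polynomial, got {T}")
    if n < 4 * n_classes:
        raise ValueError(f"need >= {4 * n_classes} participants, got {n}")
    Y = work.to_numpy(dtype=float)
    mask = np.isfinite(Y).astype(float)
    Y0 = np.nan_to_num(Y)
    Ti = mask.sum(axis=1)
    X = _design(times, degree)
    rng = np.random.default_rng(seed)

    best = None
    n_converged = 0
    for start in range(n_starts):
        if start == 0:
            from sklearn.cluster import KMeans
            col_means = Y0.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
            filled = np.where(mask > 0, Y0, col_means[None, :])
            hard = KMeans(n_clusters=n_classes, n_init=5,
                          random_state=seed).fit_predict(filled)
        else:
            hard = rng.integers(0, n_classes, size=n)
            if len(np.unique(hard)) < n_classes:  # pragma: no cover
                hard[: n_classes] = np.arange(n_classes)
        init = _init_from_assignment(Y0, mask, Ti, X, hard, n_classes, degree)
        beta, sigma2, tau2, weights, resp, history, ok = _run_em(
            Y0, mask, Ti, X, degree, *init, max_iter=max_iter, tol=tol)
        n_converged += ok
        if ok and (best is None or history[-1] > best[-1]):
            best = (beta, sigma2, tau2, weights, resp, history, history[-1])
    if best is None:
        raise RuntimeError(
            f"EM failed to converge in any of {n_starts} starts "
            f"(n={n}, T={T}, max_iter={max_iter}); increase max_iter or "
            "check the trajectory matrix for degenerate structure")
    beta, sigma2, tau2, weights, resp, history, loglik = best

    # anchor: "high" = larger area under the mean trajectory
    integrals = (beta @ X.T).mean(axis=1)
    order = np.argsort(integrals)          # [low, high]
    beta, weights, resp = beta[order], weights[order], resp[order]

    flags = []
    if weights.min() < 2.0 / n:
        flags.append("degenerate_class")
        warnings.warn("growth mixture fit has a near-empty class",
                      stacklevel=2)
    posterior = pd.Series(resp[1], index=work.index, name="p_high")
    return GrowthMixtureFit(
        coefficients=beta, sigma2=sigma2, tau2=tau2, weights=weights,
        times=times, degree=degree, posterior_high=posterior,
        loglik=loglik, loglik_history=history,
        n_starts_converged=n_converged, flags=flags)


def posterior_for(fit: GrowthMixtureFit, matrix: pd.DataFrame) -> pd.Series:
    """Posterior P(high) for new participants under a frozen fit (E-step
    only; used to label a test set with the locked training model)."""
    work = matrix.dropna(how="all")
    missing_cols = [c for c in work.columns
                    if not np.isclose(fit.times, float(c)).any()]
    if missing_cols:
        raise ValueError(f"matrix timepoints {missing_cols} not in the fit")
    Y = work.to_numpy(dtype=float)
    mask = np.isfinite(Y).astype(float)
    Y0 = np.nan_to_num(Y)
    Ti = mask.sum(axis=1)
    X = _design(work.columns.to_numpy(dtype=float), fit.degree)
    mu = fit.coefficients @ X.T
    ll, _ = _loglik_terms(Y0, mask, Ti, mu, fit.sigma2, fit.tau2)
    logw = np.log(np.maximum(fit.weights, 1e-300))[:, None] + ll
    resp = np.exp(logw - logsumexp(logw, axis=0)[None, :])
    return pd.Series(resp[1], index=work.index, name="p_high")


# ---------------------------------------------------------------------------
# labelling

def assign_training_labels(fit: GrowthMixtureFit, n_extreme: int = 40
                           ) -> tuple[pd.Series, LabelRule]:
    """Label the posterior-rank extremes of the training set.

    The ``n_extreme`` participants with the highest P(high) are labelled
    high, the ``n_extreme`` lowest are labelled low, and the middle stays
    unlabelled. The posteriors at the boundary ranks become the locked
    thresholds for test-set labelling. Ties at a rank boundary are broken
    by enrollment order (stable sort on the matrix row order).
    """
    p = fit.posterior_high
    n = len(p)
    if n < 2 * n_extreme:
        raise ValueError(f"training set of {n} cannot label 2 x {n_extreme}")
    order_desc = np.argsort(-p.to_numpy(), kind="stable")
    labels = pd.Series(pd.NA, index=p.index, dtype="object", name="label")
    hi_idx = p.index[order_desc[:n_extreme]]
    lo_idx = p.index[order_desc[n - n_extreme:]]
    labels.loc[hi_idx] = HIGH
    labels.loc[lo_idx] = LOW
    tau_high = float(p.iloc[order_desc[n_extreme - 1]])
    tau_low = float(p.iloc[order_desc[n - n_extreme]])
    rule = LabelRule(tau_high=tau_high, tau_low=tau_low, n_extreme=n_extreme)
    return labels, rule


def apply_locked_labels(posteriors: pd.Series, rule: LabelRule) -> pd.Series:
    """Label a test set with a locked rule; intermediate posteriors stay
    unlabelled. Refuses to run on an unlocked rule (audit discipline)."""
    if not rule.locked:
        raise RuntimeError(
            "label rule is not locked; lock() it on the training set "
            "before labelling a test set")
    labels = pd.Series(pd.NA, index=posteriors.index, dtype="object",
                       name="label")
    labels[posteriors >= rule.tau_high] = HIGH
    labels[(posteriors <= rule.tau_low) & labels.isna()] = LOW
    return labels
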