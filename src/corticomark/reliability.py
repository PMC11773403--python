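"""Test-retest reliability: ICC across sessions and class agreement.

The intraclass correlation is the two-way random-effects, absolute-
agreement, single-measure form ICC(2,1), computed from the two-way ANOVA
mean squares with the conventional F-distribution confidence bounds — the
standard choice for test-retest designs where sessions are a random
sample of possible measurement occasions. Session-to-session agreement of
the binary facilitator/depressor classification uses Cohen's kappa plus
raw percent agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

ICC_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def icc_band(value: float) -> str:
    for lo, name in ICC_BANDS:
        if value >= lo:
            return name
    return "poor"


@dataclass
class ReliabilityReport:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_sessions: int
    band: str
    flags: list[str]


def icc(measurements: np.ndarray, alpha: float = 0.05) -> ReliabilityReport:
    """ICC(2,1) from a subjects x sessions matrix.

    Rows with missing cells are dropped listwise with a warning. With zero
    between-subject variance the ICC is undefined and flagged.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurements must be subjects x sessions")
    flags: list[str] = []
    keep = np.isfinite(m).all(axis=1)
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} subject(s) with "
                      "missing sessions (listwise deletion)", stacklevel=2)
        flags.append("listwise_deletion")
        m = m[keep]
    n, k = m.shape
    if k < 2:
        raise ValueError("need >= 2 sessions")
    if n < 5:
        raise ValueError("need >= 5 subjects")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)     # rows (subjects)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)     # columns (sessions)
    sse = np.sum((m - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    between_var = np.var(row_means)
    if np.isclose(between_var, 0.0):
        flags.append("zero_between_subject_variance")
        return ReliabilityReport(np.nan, np.nan, np.nan, n, k,
                                 "undefined", flags)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom

    # F-based confidence bounds for single-measure absolute agreement
    if mse <= 0 or value >= 1.0 - 1e-12:   # perfect agreement
        lo = hi = 1.0
    else:
        fj = msc / mse
        term = n * (1 + (k - 1) * value) - k * value
        v = ((k - 1) * (n - 1) * (k * value * fj + term) ** 2 /
             ((n - 1) * k**2 * value**2 * fj**2 + term**2))
        f_up = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_lo = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_up * mse) / (
            f_up * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_lo * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_lo * msr)
    return ReliabilityReport(float(value), float(lo), float(hi), n, k,
                             icc_band(float(value)), flags)


@dataclass
class AgreementReport:
    kappa: float
    percent_agreement: float
    n: int
    flags: list[str]


def class_agreement(classes_a, classes_b) -> AgreementReport:
    """Cohen's kappa and raw agreement between two paired classifications
    (e.g. facilitator/depressor on day 2 vs day 5)."""
    from sklearn.metrics import cohen_kappa_score

    a = np.asarray(classes_a)
    b = np.asarray(classes_b)
    if a.shape != b.shape:
        raise ValueError("paired classifications must align")
    agree = float(np.mean(a == b))
    flags: list[str] = []
    if len(np.unique(np.concatenate([a, b]))) < 2:
        flags.append("single_category")
        return AgreementReport(np.nan, agree, a.size, flags)
    kappa = float(cohen_kappa_score(a, b))
    return AgreementReport(kappa, agree, a.size, flags)
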