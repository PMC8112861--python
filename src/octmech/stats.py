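"""Statistical layer: group tests, ROC analysis, DeLong, ICC, logistic fit.

The conventions deliberately mirror common clinical-statistics software:
Student pooled-variance t by default (Welch by flag), two-sided Fisher
exact by the minimum-likelihood-sum definition, ROC thresholds at
midpoints between consecutive unique scores, Youden-index cutoffs with
ties broken toward higher sensitivity, DeLong's structural-component test
for correlated AUCs, and ICC(1,1) from the one-way random-effects ANOVA.
t-tests accept either raw samples or (mean, sd, n) summaries, so printed
group summaries can be re-tested directly.  All operations are pure:
identical inputs give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["RocCurve", "DiagnosticResult", "LogisticFit",
           "two_sample_t", "paired_t", "fisher_exact_2x2", "chi_square_2x2",
           "roc_auc", "youden_cutoff", "delong_test", "icc_oneway",
           "logistic_combination", "auc_band", "diagnostic_result"]


# --------------------------------------------------------------------------
# group comparison tests

def _summary(x) -> tuple:
    if isinstance(x, tuple) and len(x) == 3:
        m, sd, n = x
        if n < 2 or sd < 0:
            raise ValueError("need n >= 2 and sd >= 0")
        return float(m), float(sd), int(n)
    arr = np.asarray(x, float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def two_sample_t(a, b, pooled: bool = True) -> tuple:
    """Two-sided two-sample t-test from raw samples or (mean, sd, n) summaries.

    Returns ``(t, df, p)``.  Student pooled-variance by default; Welch with
    ``pooled=False``.  Zero variance with equal means yields p = 1.
    """
    m1, s1, n1 = _summary(a)
    m2, s2, n2 = _summary(b)
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero variance with unequal means")
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def paired_t(differences) -> tuple:
    """Two-sided paired t-test on a vector of pair differences."""
    d = np.asarray(differences, float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, float(d.size - 1), 1.0
        raise ValueError("zero-variance differences with nonzero mean")
    t = d.mean() / (sd / np.sqrt(d.size))
    df = d.size - 1
    return float(t), float(df), float(2.0 * sps.t.sf(abs(t), df))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]],
                                  alternative="two-sided")[1])


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Pearson chi-square (no continuity correction) for [[a, b], [c, d]].

    Returns ``(chi2, p)`` with 1 degree of freedom.  Kept alongside the
    Fisher test because published 2x2 p-values are often the uncorrected
    Pearson statistic even when a Fisher test is stated.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined with a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), float(sps.chi2.sf(chi2, 1))


# --------------------------------------------------------------------------
# ROC analysis

@dataclass
class RocCurve:
    """Empirical ROC curve with midpoint thresholds.

    ``orientation`` is +1 when higher scores indicate the positive class,
    -1 when lower scores do (e.g. fibrous cap thickness).  Thresholds are
    in the original score units; a case is called positive when
    ``orientation * score >= orientation * threshold``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: int


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r1 = ranks[:pos.size].sum()
    u = r1 - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_auc(scores, labels, orientation: str = "auto") -> RocCurve:
    """Empirical ROC curve and tie-corrected Mann-Whitney AUC.

    ``orientation``: 'higher' (higher score = positive), 'lower', or
    'auto' which flips so that the reported AUC is >= 0.5.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present")

    auc_hi = _auc_mann_whitney(scores, labels)
    if orientation == "auto":
        sign = 1 if auc_hi >= 0.5 else -1
    elif orientation == "higher":
        sign = 1
    elif orientation == "lower":
        sign = -1
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    auc = auc_hi if sign == 1 else 1.0 - auc_hi

    s = sign * scores
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2
    thr = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    pos, neg = s[labels == 1], s[labels == 0]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    return RocCurve(thresholds=sign * thr, sensitivity=sens,
                    specificity=spec, auc=auc, orientation=sign)


def youden_cutoff(curve: RocCurve) -> tuple:
    """Cutoff maximizing sensitivity + specificity - 1.

    Ties resolve to the highest-sensitivity threshold (a fixed,
    deterministic stand-in for 'clinical judgment').  Returns
    ``(cutoff, sensitivity, specificity)``.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    i = best[np.argmax(curve.sensitivity[best])]
    return (float(curve.thresholds[i]), float(curve.sensitivity[i]),
            float(curve.specificity[i]))


def auc_band(auc: float) -> str:
    """Qualitative diagnostic-efficiency label for an AUC value."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must be in [0, 1]")
    if auc >= 0.9:
        return "excellent"
    if auc >= 0.8:
        return "very good"
    if auc >= 0.7:
        return "good"
    if auc >= 0.6:
        return "sufficient"
    return "not sufficient"


@dataclass
class DiagnosticResult:
    """Per-feature diagnostic summary: curve, Youden cutoff, AUC band."""

    feature: str
    curve: RocCurve
    cutoff: float
    sensitivity: float
    specificity: float
    band: str


def diagnostic_result(feature: str, scores, labels,
                      orientation: str = "auto") -> DiagnosticResult:
    curve = roc_auc(scores, labels, orientation)
    cutoff, sens, spec = youden_cutoff(curve)
    return DiagnosticResult(feature=feature, curve=curve, cutoff=cutoff,
                            sensitivity=sens, specificity=spec,
                            band=auc_band(curve.auc))


# --------------------------------------------------------------------------
# DeLong test for two correlated AUCs

def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)        # V10 (per pos), V01


def delong_test(scores_a, scores_b, labels,
                orientation: str = "auto") -> tuple:
    """DeLong comparison of two correlated AUCs on the same cases.

    Returns ``(auc_a, auc_b, z, p)``; ``p`` is the two-sided normal
    p-value on the AUC difference.  Each score set is oriented
    independently when ``orientation='auto'``.
    """
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if sa.shape != labels.shape or sb.shape != labels.shape:
        raise ValueError("scores and labels must be paired on the same cases")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present")

    def orient(s):
        if orientation == "auto" and _auc_mann_whitney(s, labels) < 0.5:
            return -s
        if orientation == "lower":
            return -s
        return s

    sa, sb = orient(sa), orient(sb)
    v10a, v01a = _delong_placements(sa, labels)
    v10b, v01b = _delong_placements(sb, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n1, n0 = v10a.size, v01a.size
    if n1 < 2 or n0 < 2:
        raise ValueError("DeLong test needs >= 2 cases per class")
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0:
        if auc_a == auc_b:
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("degenerate DeLong variance with unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# --------------------------------------------------------------------------
# intraclass correlation, one-way random effects

def icc_oneway(ratings) -> float:
    """ICC(1,1) from a complete n-subjects x k-raters matrix.

    ICC = (MSB - MSW) / (MSB + (k - 1) MSW) with the one-way random
    effects mean squares.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) ratings matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssw = np.sum((x - row_means[:, None]) ** 2)
    if ssb + ssw == 0:
        raise ValueError("zero total variance")
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


# --------------------------------------------------------------------------
# multivariable logistic combination

@dataclass
class LogisticFit:
    """IRLS logistic fit; probabilities feed downstream ROC analysis."""

    coefficients: np.ndarray      # intercept first
    probabilities: np.ndarray
    converged: bool
    separated: bool
    kept_columns: list = field(default_factory=list)


def logistic_combination(features, labels, max_iter: int = 100,
                         tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Constant feature columns are dropped with a warning.  Under perfect
    separation the likelihood is unbounded; the fit is flagged and the
    probabilities of the last stable iterate are returned.
    """
    x = np.atleast_2d(np.asarray(features, float))
    if x.shape[0] == 1 and np.asarray(labels).size > 1:
        x = x.T
    y = np.asarray(labels, float)
    n, p = x.shape
    if y.size != n:
        raise ValueError("labels must match the number of rows")
    if n <= p:
        raise ValueError("need more cases than features")
    keep = [j for j in range(p) if np.ptp(x[:, j]) > 0]
    if len(keep) < p:
        warnings.warn("dropping constant feature column(s)", stacklevel=2)
    xm = np.column_stack([np.ones(n)] + [x[:, j] for j in keep])

    beta = np.zeros(xm.shape[1])
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = np.clip(xm @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        xtw = xm.T * w
        try:
            new = np.linalg.solve(xtw @ xm, xtw @ z)
        except np.linalg.LinAlgError:
            separated = True
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > 50:
            separated = True
            break
        if step < tol:
            converged = True
            break
    eta = np.clip(xm @ beta, -30, 30)
    probs = 1.0 / (1.0 + np.exp(-eta))
    if separated:
        warnings.warn("possible perfect separation; returning last stable "
                      "iterate", stacklevel=2)
    return LogisticFit(coefficients=beta, probabilities=probs,
                       converged=converged, separated=separated,
                       kept_columns=keep)
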