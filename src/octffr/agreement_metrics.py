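"""Agreement and diagnostic-performance statistics.

Implements the evaluation toolkit for comparing a simulated FFR against the
wire-measured reference: Bland-Altman limits of agreement, thresholded
diagnostic performance with exact (Clopper-Pearson) binomial confidence
intervals, Pearson correlation with a Fisher-z interval, and ROC AUC with
DeLong's paired test. The clinical positivity threshold is FFR <= 0.80
(closed: exactly 0.80 is positive).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError

FFR_THRESHOLD = 0.80


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive = measured FFR <= threshold."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidParameterError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_scores(cls, measured: Sequence[float], simulated: Sequence[float],
                    threshold: float = FFR_THRESHOLD) -> "ConfusionMatrix":
        m = np.asarray(measured, dtype=float)
        s = np.asarray(simulated, dtype=float)
        if m.shape != s.shape:
            raise InvalidParameterError("paired vectors must have equal length")
        truth = m <= threshold
        pred = s <= threshold
        return cls(tp=int(np.sum(truth & pred)), fn=int(np.sum(truth & ~pred)),
                   fp=int(np.sum(~truth & pred)), tn=int(np.sum(~truth & ~pred)))


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman summary of simulated - measured differences."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    r_ci: tuple[float, float]
    n: int


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not (0 <= x <= n) or n < 1:
        raise InvalidParameterError("need 0 <= x <= n and n >= 1")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class RatioWithCI:
    value: float
    ci: tuple[float, float]
    numerator: int
    denominator: int


def _ratio(x: int, n: int, level: float) -> Optional[RatioWithCI]:
    if n == 0:
        return None  # undefined, not zero
    return RatioWithCI(x / n, clopper_pearson(x, n, level), x, n)


def diagnostic_summary(m: ConfusionMatrix, level: float = 0.95) -> dict:
    """Accuracy, sensitivity, specificity, PPV and NPV with exact CIs.

    Metrics with a zero denominator are reported as None (undefined).
    """
    if m.n < 1:
        raise InvalidParameterError("empty confusion matrix")
    return {
        "accuracy": _ratio(m.tp + m.tn, m.n, level),
        "sensitivity": _ratio(m.tp, m.tp + m.fn, level),
        "specificity": _ratio(m.tn, m.tn + m.fp, level),
        "ppv": _ratio(m.tp, m.tp + m.fp, level),
        "npv": _ratio(m.tn, m.tn + m.fn, level),
    }


def pearson_r(x: Sequence[float], y: Sequence[float],
              level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Product-moment correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need >= 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidParameterError("zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        return r, (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(x.size - 3)
    zc = stats.norm.ppf(0.5 + level / 2)
    return r, (math.tanh(z - zc * se), math.tanh(z + zc * se))


def bland_altman(pairs: Sequence[tuple[float, float]],
                 level: float = 0.95) -> AgreementSummary:
    """Limits of agreement for (measured, simulated) pairs.

    Differences are simulated - measured; limits are mean +/- 1.96 * SD with
    the sample (n-1) standard deviation.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise InvalidParameterError("need >= 2 (measured, simulated) pairs")
    measured, simulated = arr[:, 0], arr[:, 1]
    diff = simulated - measured
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    if arr.shape[0] >= 3 and np.std(measured) > 0 and np.std(simulated) > 0:
        r, ci = pearson_r(measured, simulated, level)
    else:
        r, ci = float("nan"), (float("nan"), float("nan"))
    return AgreementSummary(mean_diff=mean, sd_diff=sd,
                            loa_low=mean - 1.96 * sd, loa_high=mean + 1.96 * sd,
                            pearson_r=r, r_ci=ci, n=arr.shape[0])


def _prep_roc(truth, score, direction: str):
    t = np.asarray(truth, dtype=bool)
    s = np.asarray(score, dtype=float)
    if t.shape != s.shape:
        raise InvalidParameterError("truth/score length mismatch")
    if t.all() or not t.any():
        raise InvalidParameterError("both classes must be present")
    if direction not in (">", "<"):
        raise InvalidParameterError("direction must be '>' or '<'")
    return t, (s if direction == ">" else -s)


def roc_auc(truth: Sequence[bool], score: Sequence[float],
            direction: str = ">") -> float:
    """AUC by the Mann-Whitney pair-counting identity; ties count 0.5.

    direction '>' means larger scores indicate the positive class ('<' for
    markers like simFFR where smaller values predict significance).
    """
    t, s = _prep_roc(truth, score, direction)
    ranks = stats.rankdata(s)
    n1 = int(t.sum())
    n0 = t.size - n1
    u = float(ranks[t].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _placements(t: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values for positives and negatives."""
    pos = s[t]
    neg = s[~t]
    # V10[i]: fraction of negatives below positive i (ties half)
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / neg.size
                    for x in pos])
    v01 = np.array([(np.sum(pos > x) + 0.5 * np.sum(pos == x)) / pos.size
                    for x in neg])
    return v10, v01, float(v10.mean())


def delong_test(truth: Sequence[bool], score_a: Sequence[float],
                score_b: Sequence[float], direction_a: str = ">",
                direction_b: str = ">") -> dict:
    """Paired DeLong comparison of two AUCs on the same cases.

    Returns auc_a, auc_b, z and the two-sided p; z and p are None when the
    paired variance is degenerate (e.g. identical scores).
    """
    t, sa = _prep_roc(truth, score_a, direction_a)
    _, sb = _prep_roc(truth, score_b, direction_b)
    v10a, v01a, auc_a = _placements(t, sa)
    v10b, v01b, auc_b = _placements(t, sb)
    n1, n0 = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    out = {"auc_a": auc_a, "auc_b": auc_b, "delta": auc_a - auc_b}
    if var <= 0:
        out["z"] = None
        out["p"] = None
        out["note"] = "degenerate paired variance"
        return out
    z = (auc_a - auc_b) / math.sqrt(var)
    out["z"] = float(z)
    out["p"] = float(2.0 * stats.norm.sf(abs(z)))
    return out
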