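"""Model evaluation: Kaplan-Meier curves, weighted log-rank tests, ROC/AUC
from the prognostic index, and chi-square association helpers.

The two-sample survival comparison defaults to the Gehan-Breslow-Wilcoxon
weighted log-rank test (weight = number at risk, emphasizing early
differences); the unweighted log-rank is available via ``weighting``.
ROC treats relapse as the positive class; AUC equals the Mann-Whitney
concordance probability with ties counted one half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import SurvivalOutcome

__all__ = ["KMCurve", "LogRankResult", "ROCResult", "km_estimate", "weighted_logrank_test", "roc_auc", "chi_square_association"]


def _unpack(survival) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(survival, SurvivalOutcome):
        return survival.time, survival.event
    time, event = survival
    return np.asarray(time, dtype=float), np.asarray(event).astype(int)


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # number at risk at each event time
    censor_times: np.ndarray    # times of censored observations (plot ticks)

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival estimates must be non-increasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t): 1 before the first event, stepping down at each event time."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    weighting: str
    n_a: int
    n_b: int


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray   # sensitivity
    fpr: np.ndarray   # 1 - specificity
    auc: float


def km_estimate(survival) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    A censoring tied with an event counts the censored subject as still at
    risk at that event time (censored-after-events convention).
    """
    time, event = _unpack(survival)
    if len(time) == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    ev = np.unique(time[event == 1])
    surv = np.array([float(kmf.survival_function_at_times(t).iloc[0]) for t in ev])
    tbl = kmf.event_table
    at_risk = np.array([int(tbl.loc[t, "at_risk"]) for t in ev]) if len(ev) else np.array([], int)
    return KMCurve(event_times=ev, survival=surv, at_risk=at_risk, censor_times=np.sort(time[event == 0]))


def weighted_logrank_test(survival_a, survival_b, weighting: str = "gehan_wilcoxon") -> LogRankResult:
    """Two-sample weighted log-rank test.

    ``gehan_wilcoxon`` (default) weights each event time by the number at
    risk; ``logrank`` uses unit weights.  The statistic is chi-square with 1
    degree of freedom.  With no events at all, p = 1 with a warning.
    """
    ta, ea = _unpack(survival_a)
    tb, eb = _unpack(survival_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return LogRankResult(0.0, 1.0, weighting, len(ta), len(tb))
    kwargs = {"weightings": "wilcoxon"} if weighting == "gehan_wilcoxon" else {}
    if weighting not in ("gehan_wilcoxon", "logrank"):
        raise ValueError(f"unknown weighting {weighting!r}")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb, **kwargs)
    return LogRankResult(float(res.test_statistic), float(res.p_value), weighting, len(ta), len(tb))


def roc_auc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> ROCResult:
    """ROC over all score thresholds; AUC by trapezoid rule.

    Equals the Mann-Whitney concordance probability P(score_pos > score_neg)
    with ties counted 1/2.  Relapse (label 1) is the positive class.  Both
    classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    # Mann-Whitney form (identical to the trapezoid area, exact under ties)
    pos = s[y == 1]
    neg = s[y == 0]
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = float((greater + 0.5 * ties) / (len(pos) * len(neg)))
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def chi_square_association(group_labels, binary_outcome, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the groups x outcome contingency table.

    No Yates continuity correction by default.  All marginals must be
    positive.
    """
    table = pd.crosstab(pd.Series(group_labels), pd.Series(binary_outcome)).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table needs positive marginals in >= 2x2 cells")
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)
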