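"""Survival and classification evaluation.

Kaplan–Meier curves, the log-rank test, univariate Cox hazard ratios on a
continuous risk score, Harrell's concordance index, rank-based ROC AUC, and
the train-AND-test significance rule used to call a model "successful".

Tie conventions, stated once:

* KM / log-rank: at tied times events are processed before censorings
  (standard product-limit convention).
* Harrell's C: a pair (i, j) is comparable iff t_i < t_j and sample i had
  the event; it is concordant when score_i > score_j; tied scores count 1/2.
* AUC: Mann–Whitney with the usual 1/2 credit for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    """Raised when an evaluation cannot be computed on the given data."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Product-limit estimate for one group."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "greenwood_se": self.greenwood_se,
            }
        )


def km_curve(time, event, group_labels=None) -> dict:
    """Kaplan–Meier estimates, one per group (single group ``"all"`` if none)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if group_labels is None:
        group_labels = np.repeat("all", len(time))
    group_labels = np.asarray(group_labels)
    out = {}
    for g in pd.unique(group_labels):
        sel = group_labels == g
        if sel.sum() == 0:
            raise EvaluationError(f"empty group {g!r}")
        t, e = time[sel], event[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        ev_times = np.unique(t[e == 1])
        at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=float)
        d = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=float)
        surv = np.cumprod(1.0 - d / at_risk) if len(ev_times) else np.array([])
        with np.errstate(divide="ignore", invalid="ignore"):
            gw = np.cumsum(d / (at_risk * (at_risk - d)))
            se = surv * np.sqrt(gw)
        out[g] = KMEstimate(
            times=ev_times,
            at_risk=at_risk,
            events=d,
            survival=surv,
            censor_times=np.sort(t[e == 0]),
            greenwood_se=np.nan_to_num(se, nan=0.0, posinf=0.0),
        )
    return out


# ---------------------------------------------------------------------------
# Log-rank


def log_rank_test(time, event, group_labels):
    """k-group log-rank chi-square test (df = k - 1)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(group_labels)
    levels = pd.unique(groups)
    k = len(levels)
    if k < 2:
        raise EvaluationError("log-rank test needs >= 2 groups")
    if event.sum() < 1:
        raise EvaluationError("log-rank test needs >= 1 event")
    ev_times = np.unique(time[event == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for u in ev_times:
        at_risk = time >= u
        n_t = at_risk.sum()
        d_t = ((time == u) & (event == 1)).sum()
        for a, ga in enumerate(levels):
            n_a = (at_risk & (groups == ga)).sum()
            d_a = ((time == u) & (event == 1) & (groups == ga)).sum()
            obs[a] += d_a
            exp[a] += d_t * n_a / n_t
        if n_t > 1:
            for a, ga in enumerate(levels):
                n_a = (at_risk & (groups == ga)).sum()
                for b, gb in enumerate(levels):
                    n_b = (at_risk & (groups == gb)).sum()
                    delta = 1.0 if a == b else 0.0
                    var[a, b] += (
                        d_t * (n_a / n_t) * (delta - n_b / n_t) * (n_t - d_t) / (n_t - 1)
                    )
    diff = (obs - exp)[:-1]
    v = var[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(v) @ diff)
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# Univariate Cox on a risk score


@dataclass
class CoxScoreResult:
    hr: float  # hazard ratio per unit score
    p: float  # Wald p-value
    beta: float
    se: float
    monotone_likelihood: bool = False


def cox_score_test(time, event, scores, method: str = "wald") -> CoxScoreResult:
    """Univariate Cox PH fit on a continuous risk score.

    Returns the hazard ratio per unit of score and its Wald p-value
    (likelihood-ratio p with ``method="lr"``). Monotone likelihood (perfectly
    separating score) is flagged rather than fatal.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if event.sum() < 2:
        raise EvaluationError("need >= 2 events for the Cox score test")
    if np.ptp(scores) == 0:
        raise EvaluationError("risk score is constant")
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.DataFrame({"time": time, "event": event, "score": scores})
    cph = CoxPHFitter()
    monotone = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as exc:
            raise EvaluationError(f"Cox fit did not converge: {exc}") from exc
        for w in caught:
            if "convergence" in str(w.message).lower() or "complete separation" in str(w.message).lower():
                monotone = True
    beta = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    if abs(beta) > 50:
        monotone = True
    if method == "lr":
        p = float(cph.log_likelihood_ratio_test().p_value)
    else:
        p = float(cph.summary.loc["score", "p"])
    return CoxScoreResult(hr=float(np.exp(beta)), p=p, beta=beta, se=se,
                          monotone_likelihood=monotone)


# ---------------------------------------------------------------------------
# Harrell's concordance index


def concordance_index(scores, time, event) -> float:
    """Harrell's C for right-censored data.

    Comparable pairs are (i, j) with t_i < t_j and event_i = 1 (the
    earlier-failing patient's outcome is known to be worse). A pair is
    concordant when the earlier failure has the higher score; tied scores
    score 1/2. C = 0.5 is chance, 1 perfect.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    ev = np.flatnonzero(e == 1)
    if len(ev) == 0:
        raise EvaluationError("no comparable pairs (no events)")
    comparable = t[ev][:, None] < t[None, :]  # i (event) fails before j
    n_comp = comparable.sum()
    if n_comp == 0:
        raise EvaluationError("no comparable pairs")
    higher = s[ev][:, None] > s[None, :]
    tied = s[ev][:, None] == s[None, :]
    concordant = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(concordant / n_comp)


def roc_auc(predicted, labels) -> float:
    """Mann–Whitney ROC AUC with tie correction."""
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=float)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("AUC needs both classes present")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, predicted))


# ---------------------------------------------------------------------------
# Reports and the success rule


@dataclass
class EvaluationReport:
    """Train/test evaluation of one fitted risk model family."""

    family: str
    train_hr: float
    train_p: float
    test_hr: float
    test_p: float
    test_cindex: float
    n_selected: int
    train_logrank_p: Optional[float] = None
    test_logrank_p: Optional[float] = None
    train_auc: Optional[float] = None
    test_auc: Optional[float] = None

    @property
    def success(self) -> bool:
        return model_success(self.train_p, self.test_p, self.n_selected)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["success"] = self.success
        return d


def model_success(train_p: float, test_p: float, n_selected: int,
                  alpha: float = 0.05) -> bool:
    """A model succeeds iff it is non-empty and prognostic (p < alpha) on
    both the training and the testing set."""
    if n_selected < 1:
        return False
    return bool(train_p < alpha and test_p < alpha)
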