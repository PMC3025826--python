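"""Sparse penalized risk models, statsmodels-style.

Two model classes form the core of the package:

:class:`LassoCox`
    L1-penalized Cox proportional-hazards model. ``fit()`` maximises the
    penalized partial likelihood along a descending lambda grid and picks
    lambda by seeded k-fold cross-validated partial-likelihood deviance
    (Verweij & van Houwelingen), minimum rule by default; the 1-SE rule is
    available. Returns :class:`LassoCoxResults`.

:class:`LassoLogit`
    L1-penalized logistic regression for binary response (e.g. pathological
    complete response), lambda by seeded CV on held-out deviance. Returns
    :class:`LassoLogitResults`.

Design matrices are standardized internally; the training means/SDs are
stored on the results object so held-out samples are encoded with training
constants. The *risk score* of a Cox model is the linear predictor centered
at the training means — the natural log of the hazard ratio relative to the
training-average patient — so the conventional high/low cut-off of zero is
meaningful on test data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ModelError(RuntimeError):
    """Raised when a model cannot be fitted on the given data."""


# ---------------------------------------------------------------------------
# Feature encoding


CLINICAL_VARIABLES = ("er", "size", "grade", "her2")


def encode_clinical(table: pd.DataFrame, variables=CLINICAL_VARIABLES) -> pd.DataFrame:
    """Numeric encoding of the clinical covariates.

    ER/HER2 positive -> 1, size >= 2 cm -> 1, grade ordinal 1-3. Rows with a
    missing value in a requested variable raise, since models require
    complete cases.
    """
    cols = {}
    for v in variables:
        s = table[v]
        if v in ("er", "her2"):
            enc = s.map({"pos": 1.0, "neg": 0.0})
        elif v == "size":
            enc = s.map({"ge2cm": 1.0, "lt2cm": 0.0})
        elif v == "grade":
            enc = pd.to_numeric(s, errors="coerce")
        else:
            enc = pd.to_numeric(s, errors="coerce")
        if enc.isna().any():
            bad = table.index[enc.isna()].tolist()
            raise ModelError(f"missing/invalid {v!r} for sample(s) {bad[:5]}")
        cols[v] = enc.astype(float)
    return pd.DataFrame(cols, index=table.index)


@dataclass
class FeatureSet:
    """Design matrix for one model family.

    family is one of {"clinical", "genomic", "combined"}; clinical variables
    are encoded per :func:`encode_clinical`, module scores enter as-is.
    """

    family: str
    design: pd.DataFrame  # samples x variables

    @property
    def variables(self) -> list:
        return list(self.design.columns)

    @classmethod
    def build(cls, family: str, cohort: pd.DataFrame, scores=None,
              clinical_variables=CLINICAL_VARIABLES) -> "FeatureSet":
        parts = []
        if family in ("clinical", "combined"):
            parts.append(encode_clinical(cohort, clinical_variables))
        if family in ("genomic", "combined"):
            if scores is None:
                raise ModelError(f"family {family!r} requires module scores")
            score_df = scores.scores if hasattr(scores, "scores") else scores
            parts.append(score_df.T.loc[cohort.index])
        if not parts:
            raise ModelError(f"unknown family {family!r}")
        design = pd.concat(parts, axis=1)
        if design.isna().any().any():
            bad = design.columns[design.isna().any()].tolist()
            raise ModelError(f"missing values in design columns {bad[:5]}")
        return cls(family=family, design=design)


def _standardize(design: pd.DataFrame):
    mean = design.mean(axis=0)
    sd = design.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = design.columns[~keep].tolist()
        warnings.warn(f"dropping constant variable(s): {dropped[:5]}", stacklevel=3)
    cols = design.columns[keep]
    z = design[cols].sub(mean[keep], axis=1).div(sd[keep], axis=1)
    return z, mean[keep], sd[keep]


# ---------------------------------------------------------------------------
# Cox partial likelihood utilities (Breslow ties)


def cox_partial_loglik(beta: np.ndarray, x: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Breslow partial log-likelihood at beta (used for CV deviance)."""
    eta = x @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o = eta[order]
    t_o = time[order]
    e_o = event[order]
    m = np.max(eta)
    cum = np.logaddexp.accumulate(eta_o - m) + m  # log sum exp over risk set
    # risk set of t is everyone with time >= t; with decreasing order the
    # cumulative sum at the end of a tie group covers the whole group
    log_risk = cum.copy()
    j = 0
    n = len(t_o)
    while j < n:
        k = j
        while k + 1 < n and t_o[k + 1] == t_o[j]:
            k += 1
        log_risk[j:k + 1] = cum[k]
        j = k + 1
    return float(np.sum(e_o * (eta_o - log_risk)))


def cox_lambda_max(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Smallest lambda at which all L1-penalized Cox coefficients are zero.

    From the score equations at beta = 0 (glmnet scaling: penalty lambda *
    n * sum |beta| on the partial likelihood, i.e. gradient / n bound).
    """
    n = len(time)
    order = np.argsort(-time, kind="stable")
    x_o = x[order]
    t_o = time[order]
    e_o = event[order]
    csum = np.cumsum(x_o, axis=0)
    counts = np.arange(1, n + 1, dtype=float)
    # extend over tie groups as in the likelihood
    j = 0
    risk_mean = np.empty_like(x_o)
    while j < n:
        k = j
        while k + 1 < n and t_o[k + 1] == t_o[j]:
            k += 1
        risk_mean[j:k + 1] = csum[k] / counts[k]
        j = k + 1
    grad = (x_o - risk_mean)[e_o == 1].sum(axis=0)
    return float(np.max(np.abs(grad)) / n)


def _cv_folds(n: int, k: int, seed: int, strata: Optional[np.ndarray] = None):
    """Seeded fold assignment; if strata given, each level spread over folds."""
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    for level in np.unique(strata):
        idx = np.flatnonzero(strata == level)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % k
    return assign


# ---------------------------------------------------------------------------
# LASSO Cox


@dataclass
class LassoCoxResults:
    """Fitted L1-penalized Cox model.

    ``params`` holds coefficients on the standardized scale, indexed by
    variable; ``selected`` is the nonzero subset. ``alpha`` is the chosen
    penalty; ``cv_deviance`` the CV partial-likelihood deviance per grid
    point.
    """

    model: "LassoCox"
    params: pd.Series
    alpha: float
    alphas: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    seed: int
    rule: str
    train_mean: pd.Series
    train_sd: pd.Series
    training_ids: list = field(default_factory=list)

    @property
    def selected(self) -> dict:
        nz = self.params[self.params != 0]
        return dict(nz)

    @property
    def n_selected(self) -> int:
        return int((self.params != 0).sum())

    def predict_risk_score(self, design: pd.DataFrame) -> pd.Series:
        """Risk score = linear predictor centered at the training means.

        Zero corresponds to the training-average hazard (log hazard ratio
        vs. the average training patient).
        """
        missing = [v for v in self.params.index if v not in design.columns]
        if missing:
            raise ModelError(f"design lacks selected variable(s) {missing[:5]}")
        z = design[self.params.index].sub(self.train_mean, axis=1).div(self.train_sd, axis=1)
        return z @ self.params

    def summary(self) -> str:
        lines = [
            "L1-penalized Cox proportional hazards",
            f"  n train = {len(self.training_ids)}, p = {len(self.params)}",
            f"  lambda = {self.alpha:.6g} ({self.rule} rule, seed {self.seed})",
            f"  nonzero coefficients: {self.n_selected}",
            "",
            f"  {'variable':<30s} {'coef (std)':>12s}",
        ]
        for name, b in sorted(self.selected.items(), key=lambda kv: -abs(kv[1])):
            lines.append(f"  {name:<30s} {b:>12.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": getattr(self.model, "family", None),
            "alpha": self.alpha,
            "rule": self.rule,
            "seed": self.seed,
            "coefficients": {k: float(v) for k, v in self.selected.items()},
            "train_mean": {k: float(v) for k, v in self.train_mean.items()},
            "train_sd": {k: float(v) for k, v in self.train_sd.items()},
            "training_ids": list(map(str, self.training_ids)),
        }


class LassoCox:
    """L1-penalized Cox proportional-hazards model.

    Parameters
    ----------
    design : DataFrame
        Samples x variables, complete cases; standardized internally.
    time, event : array-like
        Follow-up in years and 0/1 event indicator, aligned with the design
        index.
    family : str, optional
        Label carried through to results ("clinical", "genomic", ...).
    """

    def __init__(self, design: pd.DataFrame, time, event, family: str = ""):
        self.design = design
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.family = family
        if len(self.time) != len(design) or len(self.event) != len(design):
            raise ModelError("time/event length does not match design")
        if self.event.sum() < 2:
            raise ModelError("need >= 2 events to fit a Cox model")

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, scores=None, family: str = "combined",
                    clinical_variables=CLINICAL_VARIABLES) -> "LassoCox":
        fs = FeatureSet.build(family, cohort, scores, clinical_variables)
        return cls(fs.design, cohort["time"], cohort["event"], family=family)

    def fit(self, cv_folds: int = 10, seed: int = 0, rule: str = "min",
            alphas=None, n_alphas: int = 50, alpha_min_ratio: float = 0.01,
            ) -> LassoCoxResults:
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        z, mean, sd = _standardize(self.design)
        x = z.to_numpy()
        n, p = x.shape
        if p == 0:
            raise ModelError("no non-constant variables to fit")
        lam_max = cox_lambda_max(x, self.time, self.event)

        if alphas is not None:
            alphas = np.sort(np.asarray(alphas, dtype=float))[::-1]
        else:
            alphas = lam_max * 1.001 * np.logspace(
                0, np.log10(alpha_min_ratio), n_alphas
            )

        def path_coefs(x_fit, t_fit, e_fit, grid):
            """Coefficient path; grid points >= lambda_max are exactly zero."""
            lm = cox_lambda_max(x_fit, t_fit, e_fit)
            coefs = np.zeros((x_fit.shape[1], len(grid)))
            active = grid < lm
            if active.any():
                y_fit = Surv.from_arrays(e_fit.astype(bool), t_fit)
                est = CoxnetSurvivalAnalysis(
                    l1_ratio=1.0, alphas=grid[active], tol=1e-7, max_iter=100000
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(x_fit, y_fit)
                fitted = np.asarray(est.coef_)
                n_got = fitted.shape[1]
                where = np.flatnonzero(active)
                coefs[:, where[:n_got]] = fitted
                if n_got < len(where):  # path terminated early: carry last fit
                    coefs[:, where[n_got:]] = fitted[:, [-1]]
            return coefs

        coefs_full = path_coefs(x, self.time, self.event, alphas)

        # CV partial-likelihood deviance (Verweij & van Houwelingen)
        folds = _cv_folds(n, min(cv_folds, n), seed, strata=self.event)
        cv = np.zeros((cv_folds, len(alphas)))
        valid = np.zeros(cv_folds, dtype=bool)
        for k in range(min(cv_folds, n)):
            tr = folds != k
            if self.event[tr].sum() < 2 or self.event[~tr].sum() < 1:
                continue
            try:
                ck = path_coefs(x[tr], self.time[tr], self.event[tr], alphas)
            except Exception as exc:  # degenerate fold
                logger.warning("CV fold %d failed: %s", k, exc)
                continue
            for j in range(len(alphas)):
                pl_all = cox_partial_loglik(ck[:, j], x, self.time, self.event)
                pl_tr = cox_partial_loglik(ck[:, j], x[tr], self.time[tr], self.event[tr])
                cv[k, j] = -2.0 * (pl_all - pl_tr)
            valid[k] = True
        if not valid.any():
            raise ModelError("all CV folds degenerate (too few events)")
        dev = cv[valid].mean(axis=0)
        dev_se = cv[valid].std(axis=0, ddof=1) / np.sqrt(valid.sum()) if valid.sum() > 1 else np.zeros_like(dev)

        j_min = int(np.argmin(dev))
        if rule == "1se":
            cutoff = dev[j_min] + dev_se[j_min]
            ok = np.flatnonzero(dev <= cutoff)
            j_sel = int(ok[0])  # grid descends: first point = sparsest
        elif rule == "min":
            j_sel = j_min
        else:
            raise ValueError(f"unknown lambda rule {rule!r}")

        params = pd.Series(coefs_full[:, j_sel], index=z.columns)
        return LassoCoxResults(
            model=self,
            params=params,
            alpha=float(alphas[j_sel]),
            alphas=alphas,
            cv_deviance=dev,
            cv_deviance_se=dev_se,
            seed=seed,
            rule=rule,
            train_mean=mean,
            train_sd=sd,
            training_ids=list(self.design.index),
        )


# ---------------------------------------------------------------------------
# LASSO logistic


@dataclass
class LassoLogitResults:
    """Fitted L1-penalized logistic model (standardized coefficients)."""

    model: "LassoLogit"
    params: pd.Series
    intercept: float
    alpha: float
    alphas: np.ndarray
    cv_deviance: np.ndarray
    seed: int
    rule: str
    train_mean: pd.Series
    train_sd: pd.Series
    training_ids: list = field(default_factory=list)

    @property
    def selected(self) -> dict:
        nz = self.params[self.params != 0]
        return dict(nz)

    @property
    def n_selected(self) -> int:
        return int((self.params != 0).sum())

    def predict_linear(self, design: pd.DataFrame) -> pd.Series:
        missing = [v for v in self.params.index if v not in design.columns]
        if missing:
            raise ModelError(f"design lacks selected variable(s) {missing[:5]}")
        z = design[self.params.index].sub(self.train_mean, axis=1).div(self.train_sd, axis=1)
        return self.intercept + z @ self.params

    def predict_proba(self, design: pd.DataFrame) -> pd.Series:
        eta = self.predict_linear(design)
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            "L1-penalized logistic regression",
            f"  n train = {len(self.training_ids)}, p = {len(self.params)}",
            f"  lambda = {self.alpha:.6g} ({self.rule} rule, seed {self.seed})",
            f"  intercept = {self.intercept:.4f}",
            f"  nonzero coefficients: {self.n_selected}",
            "",
            f"  {'variable':<30s} {'coef (std)':>12s}",
        ]
        for name, b in sorted(self.selected.items(), key=lambda kv: -abs(kv[1])):
            lines.append(f"  {name:<30s} {b:>12.4f}")
        return "\n".join(lines)


class LassoLogit:
    """L1-penalized logistic regression for a binary response."""

    def __init__(self, design: pd.DataFrame, response, family: str = ""):
        self.design = design
        self.response = np.asarray(response, dtype=int)
        self.family = family
        if len(self.response) != len(design):
            raise ModelError("response length does not match design")
        if len(np.unique(self.response)) < 2:
            raise ModelError("both response classes must be present in training data")

    def fit(self, cv_folds: int = 10, seed: int = 0, rule: str = "min",
            alphas=None, n_alphas: int = 50, alpha_min_ratio: float = 0.001,
            ) -> LassoLogitResults:
        from sklearn.linear_model import LogisticRegression

        z, mean, sd = _standardize(self.design)
        x = z.to_numpy()
        y = self.response
        n, p = x.shape
        prev = y.mean()
        lam_max = float(np.max(np.abs(x.T @ (y - prev))) / n)

        if alphas is not None:
            alphas = np.sort(np.asarray(alphas, dtype=float))[::-1]
        else:
            alphas = lam_max * 1.001 * np.logspace(0, np.log10(alpha_min_ratio), n_alphas)

        def fit_one(x_fit, y_fit, lam):
            p_fit = y_fit.mean()
            lm = float(np.max(np.abs(x_fit.T @ (y_fit - p_fit))) / len(y_fit))
            if lam >= lm:
                b0 = float(np.log(p_fit / (1 - p_fit))) if 0 < p_fit < 1 else 0.0
                return np.zeros(x_fit.shape[1]), b0
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (len(y_fit) * lam), solver="saga",
                max_iter=20000, tol=1e-7,
            )
            clf.fit(x_fit, y_fit)
            return clf.coef_[0], float(clf.intercept_[0])

        folds = _cv_folds(n, min(cv_folds, n), seed, strata=y)
        cv = np.zeros((cv_folds, len(alphas)))
        valid = np.zeros(cv_folds, dtype=bool)
        eps = 1e-12
        for k in range(min(cv_folds, n)):
            tr = folds != k
            if len(np.unique(y[tr])) < 2 or (~tr).sum() == 0:
                continue
            for j, lam in enumerate(alphas):
                b, b0 = fit_one(x[tr], y[tr], lam)
                eta = x[~tr] @ b + b0
                prob = np.clip(1 / (1 + np.exp(-eta)), eps, 1 - eps)
                cv[k, j] = -2 * np.sum(y[~tr] * np.log(prob) + (1 - y[~tr]) * np.log(1 - prob))
            valid[k] = True
        if not valid.any():
            raise ModelError("all CV folds degenerate (single-class)")
        dev = cv[valid].sum(axis=0)
        dev_per = cv[valid]
        dev_se = dev_per.std(axis=0, ddof=1) * np.sqrt(valid.sum()) if valid.sum() > 1 else np.zeros_like(dev)

        j_min = int(np.argmin(dev))
        if rule == "1se":
            ok = np.flatnonzero(dev <= dev[j_min] + dev_se[j_min])
            j_sel = int(ok[0])
        elif rule == "min":
            j_sel = j_min
        else:
            raise ValueError(f"unknown lambda rule {rule!r}")

        b, b0 = fit_one(x, y, float(alphas[j_sel]))
        params = pd.Series(b, index=z.columns)
        return LassoLogitResults(
            model=self,
            params=params,
            intercept=b0,
            alpha=float(alphas[j_sel]),
            alphas=alphas,
            cv_deviance=dev,
            seed=seed,
            rule=rule,
            train_mean=mean,
            train_sd=sd,
            training_ids=list(self.design.index),
        )


# ---------------------------------------------------------------------------
# Functional conveniences


def fit_lasso_cox(design, time, event, cv_folds=10, seed=0, **kwargs) -> LassoCoxResults:
    return LassoCox(design, time, event).fit(cv_folds=cv_folds, seed=seed, **kwargs)


def fit_lasso_logistic(design, response, cv_folds=10, seed=0, **kwargs) -> LassoLogitResults:
    return LassoLogit(design, response).fit(cv_folds=cv_folds, seed=seed, **kwargs)


def predict_risk_score(results: LassoCoxResults, design: pd.DataFrame) -> pd.Series:
    return results.predict_risk_score(design)


def stratify_risk(scores, threshold: float = 0.0) -> pd.Series:
    """High/low risk labels: high iff score > threshold; ties go to low."""
    s = pd.Series(scores)
    return pd.Series(np.where(s > threshold, "high", "low"), index=s.index)
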