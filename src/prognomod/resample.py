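"""Resampling experiment designs.

Stratified 2/3 - 1/3 train/test splits, repeated model building with the
train-AND-test significance rule, per-variable selection frequencies among
successful rounds, mean test-set concordance per model family and pairwise
superiority fractions, and the parallel binary-response (pCR) experiment.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .evaluate import (
    EvaluationError,
    EvaluationReport,
    concordance_index,
    cox_score_test,
    log_rank_test,
    roc_auc,
)
from .modules import ModuleRegistry, compute_all_scores
from .risk import FeatureSet, LassoCox, LassoLogit, ModelError, stratify_risk

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("source", "platform", "er", "grade", "size", "her2")
FAMILIES = ("clinical", "genomic", "combined")


# ---------------------------------------------------------------------------
# Stratified splitting


@dataclass
class SplitPlan:
    """Exact train/test partition, reproducible from its seed."""

    assignment: pd.Series  # sample id -> "train" / "test"
    ratio: float
    strata_fields: tuple
    seed: int

    @property
    def train_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "train"]

    @property
    def test_ids(self) -> pd.Index:
        return self.assignment.index[self.assignment == "test"]


def stratified_split(cohort: pd.DataFrame, strata_fields=DEFAULT_STRATA,
                     ratio: float = 2 / 3, seed: int = 0) -> SplitPlan:
    """Seeded stratified partition into train (~ratio) and test.

    Within each cross-classified stratum the sample ids are shuffled and
    allocated floor or ceil of ratio * cell size, whichever keeps the
    running global train count closest to the target; every cell is within
    one sample of the target fraction and singleton cells go to train.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    strata_fields = tuple(f for f in strata_fields if f in cohort.columns)
    rng = np.random.default_rng(seed)
    if strata_fields:
        key = cohort[list(strata_fields)].astype(str).agg("|".join, axis=1)
    else:
        key = pd.Series("all", index=cohort.index)
    assignment = pd.Series("test", index=cohort.index, dtype=object)
    running_train = 0
    running_total = 0
    for cell in sorted(key.unique()):
        ids = list(cohort.index[key == cell])
        rng.shuffle(ids)
        n = len(ids)
        if n == 1:
            n_train = 1
        else:
            lo = int(np.floor(ratio * n))
            hi = int(np.ceil(ratio * n))
            target = ratio * (running_total + n)
            n_train = lo if abs(running_train + lo - target) <= abs(running_train + hi - target) else hi
        assignment[ids[:n_train]] = "train"
        running_train += n_train
        running_total += n
    return SplitPlan(assignment=assignment, ratio=ratio,
                     strata_fields=strata_fields, seed=seed)


# ---------------------------------------------------------------------------
# One round of model building


@dataclass
class FamilyResult:
    family: str
    fitted: Optional[object]
    report: Optional[EvaluationReport]
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class RoundResult:
    index: int
    seed: int
    plan: SplitPlan
    families: dict  # family name -> FamilyResult

    def success(self, family: str) -> bool:
        fr = self.families.get(family)
        return bool(fr and fr.ok and fr.report.success)


def _evaluate_cox_family(fitted, design, cohort, train_ids, test_ids) -> EvaluationReport:
    def _one(ids):
        sub = cohort.loc[ids]
        score = fitted.predict_risk_score(design.loc[ids])
        if fitted.n_selected == 0 or np.ptp(score.to_numpy()) == 0:
            return 1.0, 1.0, None, score
        res = cox_score_test(sub["time"], sub["event"], score)
        labels = stratify_risk(score)
        lr_p = None
        if labels.nunique() > 1 and sub["event"].sum() >= 1:
            _, lr_p = log_rank_test(sub["time"], sub["event"], labels)
        return res.hr, res.p, lr_p, score

    tr_hr, tr_p, tr_lr, _ = _one(train_ids)
    te_hr, te_p, te_lr, te_score = _one(test_ids)
    te_sub = cohort.loc[test_ids]
    try:
        cindex = concordance_index(te_score, te_sub["time"], te_sub["event"])
    except EvaluationError:
        cindex = 0.5
    return EvaluationReport(
        family=fitted.model.family, train_hr=tr_hr, train_p=tr_p,
        test_hr=te_hr, test_p=te_p, test_cindex=cindex,
        n_selected=fitted.n_selected,
        train_logrank_p=tr_lr, test_logrank_p=te_lr,
    )


def run_round(cohort: pd.DataFrame, scores=None, families=FAMILIES, seed: int = 0,
              strata_fields=DEFAULT_STRATA, ratio: float = 2 / 3,
              cv_folds: int = 10, expr=None, registry: Optional[ModuleRegistry] = None,
              rederive: bool = False, lambda_rule: str = "min") -> RoundResult:
    """Split, fit each family on train, evaluate on train and test.

    With ``rederive=True`` (requires ``expr`` and ``registry``) the module
    scoring constants are derived from the training samples only and applied
    to the test samples — the leakage-free protocol. Otherwise the
    precomputed global ``scores`` are used. A family whose fit fails is
    marked failed; the round continues.
    """
    plan = stratified_split(cohort, strata_fields, ratio, seed)
    train_ids, test_ids = plan.train_ids, plan.test_ids

    if rederive:
        if expr is None or registry is None:
            raise ValueError("rederive=True requires expr and registry")
        ref = expr.subset_samples(train_ids)
        scores = compute_all_scores(expr, registry, reference=ref)

    results = {}
    for family in families:
        try:
            fs = FeatureSet.build(family, cohort, scores)
            model = LassoCox(fs.design.loc[train_ids],
                             cohort.loc[train_ids, "time"],
                             cohort.loc[train_ids, "event"], family=family)
            fitted = model.fit(cv_folds=cv_folds, seed=seed, rule=lambda_rule)
            report = _evaluate_cox_family(fitted, fs.design, cohort, train_ids, test_ids)
            results[family] = FamilyResult(family, fitted, report)
        except (ModelError, EvaluationError, ValueError) as exc:
            logger.warning("round %d: family %s failed: %s", seed, family, exc)
            results[family] = FamilyResult(family, None, None, error=str(exc))
    return RoundResult(index=seed, seed=seed, plan=plan, families=results)


# ---------------------------------------------------------------------------
# The repeated-rounds procedure


@dataclass
class ResampleSummary:
    """Aggregate over resampling rounds.

    Selection counts are tabulated over *successful* rounds only (per
    family); C-index means and the superiority matrix use every round where
    the families evaluated.
    """

    n_attempted: int
    n_target: int
    n_successful: dict  # family -> count
    selection_counts: dict  # family -> {variable: count among successes}
    selection_direction: dict  # family -> {variable: "poor" | "good"}
    cindex_rounds: pd.DataFrame  # rounds x families, NaN where failed
    primary_family: str
    complete: bool
    base_seed: int
    round_seconds: list = field(default_factory=list)

    @property
    def mean_test_cindex(self) -> dict:
        return {f: float(v) for f, v in self.cindex_rounds.mean(axis=0).items()}

    @property
    def superiority_matrix(self) -> pd.DataFrame:
        """M[f1][f2] = fraction of mutually evaluated rounds with C(f1) > C(f2)."""
        fams = list(self.cindex_rounds.columns)
        m = pd.DataFrame(np.nan, index=fams, columns=fams)
        for f1 in fams:
            for f2 in fams:
                if f1 == f2:
                    m.loc[f1, f2] = 0.0
                    continue
                both = self.cindex_rounds[[f1, f2]].dropna()
                if len(both) == 0:
                    continue
                m.loc[f1, f2] = float((both[f1] > both[f2]).mean())
        return m

    def selection_frequency(self, family: Optional[str] = None) -> pd.DataFrame:
        """Figure-style table: variable, frequency among successes, direction."""
        family = family or self.primary_family
        n = max(self.n_successful.get(family, 0), 1)
        counts = self.selection_counts.get(family, {})
        rows = [
            {
                "variable": var,
                "count": c,
                "frequency": c / n,
                "direction": self.selection_direction[family].get(var, ""),
            }
            for var, c in counts.items()
        ]
        df = pd.DataFrame(rows, columns=["variable", "count", "frequency", "direction"])
        return df.sort_values(["frequency", "variable"], ascending=[False, True]).reset_index(drop=True)

    def to_json(self, path) -> None:
        d = {
            "n_attempted": self.n_attempted,
            "n_target": self.n_target,
            "n_successful": self.n_successful,
            "complete": self.complete,
            "base_seed": self.base_seed,
            "primary_family": self.primary_family,
            "mean_test_cindex": self.mean_test_cindex,
            "selection_counts": self.selection_counts,
            "selection_direction": self.selection_direction,
            "superiority_matrix": json.loads(self.superiority_matrix.to_json()),
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def run_resampling(cohort: pd.DataFrame, scores=None, families=FAMILIES,
                   n_target: int = 200, max_attempts: int = 1000,
                   base_seed: int = 0, **round_kwargs) -> ResampleSummary:
    """Repeat the round procedure until ``n_target`` successful models.

    Rounds run with derived seeds ``base_seed + i`` so any round can be
    reproduced in isolation. Success is judged on the *primary* family
    ("combined" when present). If the attempt cap is hit first, the summary
    is returned partial with ``complete=False``.
    """
    families = tuple(families)
    primary = "combined" if "combined" in families else families[0]
    n_successful = {f: 0 for f in families}
    counts: dict = {f: {} for f in families}
    signs: dict = {f: {} for f in families}
    cindex_rows = []
    timings = []
    attempts = 0
    while n_successful[primary] < n_target and attempts < max_attempts:
        t0 = _time.perf_counter()
        rr = run_round(cohort, scores, families, seed=base_seed + attempts, **round_kwargs)
        attempts += 1
        row = {}
        for f in families:
            fr = rr.families[f]
            row[f] = fr.report.test_cindex if fr.ok else np.nan
            if fr.ok and fr.report.success:
                n_successful[f] += 1
                for var, beta in fr.fitted.selected.items():
                    counts[f][var] = counts[f].get(var, 0) + 1
                    signs[f][var] = signs[f].get(var, 0.0) + np.sign(beta)
        cindex_rows.append(row)
        timings.append(_time.perf_counter() - t0)
        logger.info("round %d done in %.2fs (successes: %d/%d)",
                    attempts, timings[-1], n_successful[primary], n_target)
    direction = {
        f: {var: ("poor" if s > 0 else "good") for var, s in signs[f].items()}
        for f in families
    }
    return ResampleSummary(
        n_attempted=attempts,
        n_target=n_target,
        n_successful=n_successful,
        selection_counts=counts,
        selection_direction=direction,
        cindex_rounds=pd.DataFrame(cindex_rows, columns=list(families)),
        primary_family=primary,
        complete=n_successful[primary] >= n_target,
        base_seed=base_seed,
        round_seconds=timings,
    )


def exclude_modules(registry: ModuleRegistry, names) -> ModuleRegistry:
    """Registry minus the named signatures (for the exclusion re-analyses)."""
    return registry.exclude(names)


# ---------------------------------------------------------------------------
# pCR (binary response) experiment


@dataclass
class PCRFamilyResult:
    family: str
    fitted: Optional[object]
    train_auc: Optional[float]
    test_auc: Optional[float]
    selected: dict  # variable -> "pCR" / "no-pCR" association
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class PCRReport:
    seed: int
    plan: SplitPlan
    families: dict  # family -> PCRFamilyResult

    def auc_table(self) -> pd.DataFrame:
        rows = [
            {"family": f, "train_auc": r.train_auc, "test_auc": r.test_auc}
            for f, r in self.families.items() if r.ok
        ]
        return pd.DataFrame(rows, columns=["family", "train_auc", "test_auc"])


def run_pcr_experiment(cohort: pd.DataFrame, scores=None, families=FAMILIES,
                       seed: int = 0, strata_fields=("response", "er", "her2"),
                       ratio: float = 2 / 3, cv_folds: int = 10,
                       max_retries: int = 10) -> PCRReport:
    """Split stratified by response and clinical factors, fit an L1 logistic
    model per family, report train/test ROC AUC and the selected variables
    with their direction of association (positive coefficient -> pCR)."""
    if cohort["response"].nunique() < 2:
        raise ModelError("both response classes required")
    plan = None
    for retry in range(max_retries):
        cand = stratified_split(cohort, strata_fields, ratio, seed + retry)
        tr = cohort.loc[cand.train_ids, "response"]
        te = cohort.loc[cand.test_ids, "response"]
        if tr.nunique() == 2 and te.nunique() == 2:
            plan = cand
            break
        logger.warning("seed %d: a split side is single-class, redrawing", seed + retry)
    if plan is None:
        raise ModelError("could not find a split with both classes on both sides")

    results = {}
    for family in families:
        try:
            fs = FeatureSet.build(family, cohort, scores)
            model = LassoLogit(fs.design.loc[plan.train_ids],
                               cohort.loc[plan.train_ids, "response"], family=family)
            fitted = model.fit(cv_folds=cv_folds, seed=seed)
            p_tr = fitted.predict_proba(fs.design.loc[plan.train_ids])
            p_te = fitted.predict_proba(fs.design.loc[plan.test_ids])
            train_auc = roc_auc(p_tr, cohort.loc[plan.train_ids, "response"])
            test_auc = roc_auc(p_te, cohort.loc[plan.test_ids, "response"])
            selected = {
                var: ("pCR" if b > 0 else "no-pCR") for var, b in fitted.selected.items()
            }
            results[family] = PCRFamilyResult(family, fitted, train_auc, test_auc, selected)
        except (ModelError, EvaluationError, ValueError) as exc:
            logger.warning("pCR family %s failed: %s", family, exc)
            results[family] = PCRFamilyResult(family, None, None, None, {}, error=str(exc))
    return PCRReport(seed=seed, plan=plan, families=results)
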