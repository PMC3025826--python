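"""Gene-expression module definitions and scoring.

A *module* is a named set of co-expressed genes summarised into one variable
per sample. Four scoring routes are supported, mirroring the four ways such
signatures are constructed in the breast-cancer literature:

``median``
    Median across member genes of median-centered expression.
``first_pc``
    Sample projections on the first principal axis of the z-scored member
    genes, sign-oriented and standardised to unit variance.
``centroid_corr``
    Rank correlation (default) of each sample's member-gene profile with one
    or more published class centroids; one score row per centroid.
``published_model``
    A fixed linear model: offset + sum of per-gene weights times expression.

Scoring constants (gene medians, z-score parameters, principal axes) can be
derived from a *reference* sample set and applied to other samples, so that
train/test protocols stay leakage-free.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

MODES = ("median", "first_pc", "centroid_corr", "published_model")


class RegistryFormatError(ValueError):
    """Raised for malformed GMT / sidecar registry files."""


@dataclass
class ModuleDefinition:
    """A named gene set plus its scoring mode and mode-specific payload."""

    name: str
    genes: list
    mode: str = "median"
    centroids: Optional[dict] = None  # centroid name -> {gene: value}
    weights: Optional[dict] = None  # gene -> weight
    offset: float = 0.0
    direction_hint: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise RegistryFormatError(
                f"module {self.name!r}: unknown mode {self.mode!r}; expected one of {MODES}"
            )
        if not self.genes:
            raise RegistryFormatError(f"module {self.name!r}: empty gene list")
        self.genes = [str(g).upper() for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise RegistryFormatError(f"module {self.name!r}: duplicate gene symbols")
        if self.mode == "centroid_corr":
            if not self.centroids:
                raise RegistryFormatError(
                    f"module {self.name!r}: centroid_corr mode requires centroids"
                )
            self.centroids = {
                str(c): {str(g).upper(): float(v) for g, v in cvals.items()}
                for c, cvals in self.centroids.items()
            }
            for c, cvals in self.centroids.items():
                if not np.all(np.isfinite(list(cvals.values()))):
                    raise RegistryFormatError(
                        f"module {self.name!r}: non-finite centroid values for {c!r}"
                    )
        elif self.centroids is not None:
            raise RegistryFormatError(
                f"module {self.name!r}: centroids only valid for centroid_corr mode"
            )
        if self.mode == "published_model":
            if self.weights is None:
                raise RegistryFormatError(
                    f"module {self.name!r}: published_model mode requires weights"
                )
            self.weights = {str(g).upper(): float(w) for g, w in self.weights.items()}
            if not np.all(np.isfinite(list(self.weights.values()) + [self.offset])):
                raise RegistryFormatError(f"module {self.name!r}: non-finite weights")
        elif self.weights is not None:
            raise RegistryFormatError(
                f"module {self.name!r}: weights only valid for published_model mode"
            )


class ModuleRegistry:
    """Ordered collection of :class:`ModuleDefinition`, keyed by name."""

    def __init__(self, modules=()):
        self._modules: dict = {}
        for m in modules:
            self.add(m)

    def add(self, module: ModuleDefinition) -> None:
        if module.name in self._modules:
            raise RegistryFormatError(f"duplicate module name {module.name!r}")
        self._modules[module.name] = module

    def __len__(self) -> int:
        return len(self._modules)

    def __iter__(self):
        return iter(self._modules.values())

    def __contains__(self, name) -> bool:
        return name in self._modules

    def __getitem__(self, name) -> ModuleDefinition:
        return self._modules[name]

    @property
    def names(self) -> list:
        return list(self._modules)

    def counts_by_mode(self) -> dict:
        counts: dict = {}
        for m in self:
            counts[m.mode] = counts.get(m.mode, 0) + 1
        return counts

    def exclude(self, names) -> "ModuleRegistry":
        """Registry minus the named modules; unknown names are an error."""
        names = list(names)
        unknown = [n for n in names if n not in self._modules]
        if unknown:
            raise KeyError(
                f"unknown module name(s) {unknown}; valid names include "
                f"{self.names[:10]}..."
            )
        drop = set(names)
        out = ModuleRegistry(m for m in self if m.name not in drop)
        logger.info("excluded %d modules, %d remain", len(drop), len(out))
        return out


def read_module_registry(gmt_path, sidecar_json_path=None) -> ModuleRegistry:
    """Read a registry from a GMT gene-set file plus optional JSON sidecar.

    GMT lines are ``name<TAB>description<TAB>gene1<TAB>gene2...``. Modules
    absent from the sidecar default to median scoring. The sidecar schema is
    ``{module: {mode, centroids?, weights?, offset?, direction_hint?}}``.
    """
    sidecar = {}
    if sidecar_json_path is not None:
        with open(sidecar_json_path) as fh:
            sidecar = json.load(fh)

    registry = ModuleRegistry()
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RegistryFormatError(
                    f"{gmt_path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            params = sidecar.get(name, {})
            try:
                registry.add(
                    ModuleDefinition(
                        name=name,
                        description=description,
                        genes=genes,
                        mode=params.get("mode", "median"),
                        centroids=params.get("centroids"),
                        weights=params.get("weights"),
                        offset=float(params.get("offset", 0.0)),
                        direction_hint=params.get("direction_hint"),
                    )
                )
            except RegistryFormatError as exc:
                raise RegistryFormatError(f"{gmt_path}:{lineno}: {exc}") from exc
    unknown = set(sidecar) - set(registry.names)
    if unknown:
        raise RegistryFormatError(
            f"sidecar references unknown module(s): {sorted(unknown)}"
        )
    logger.info("read %d modules, counts by mode: %s", len(registry), registry.counts_by_mode())
    return registry


def write_module_registry(registry: ModuleRegistry, gmt_path, sidecar_json_path=None) -> None:
    sidecar = {}
    with open(gmt_path, "w") as fh:
        for m in registry:
            fh.write("\t".join([m.name, m.description or "na"] + list(m.genes)) + "\n")
            entry: dict = {"mode": m.mode}
            if m.centroids is not None:
                entry["centroids"] = m.centroids
            if m.weights is not None:
                entry["weights"] = m.weights
                entry["offset"] = m.offset
            if m.direction_hint is not None:
                entry["direction_hint"] = m.direction_hint
            sidecar[m.name] = entry
    if sidecar_json_path is not None:
        with open(sidecar_json_path, "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)


@dataclass
class MatchReport:
    """Outcome of intersecting a module's gene list with an expression matrix."""

    module: str
    matched: list
    n_total: int
    scoreable: bool

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def fraction(self) -> float:
        return self.n_matched / self.n_total if self.n_total else 0.0


def match_genes(expr: ExpressionMatrix, module: ModuleDefinition, min_fraction: float = 0.5) -> MatchReport:
    """Case-insensitive intersection of module genes with the matrix rows.

    A module is scoreable iff matched/total >= ``min_fraction``. Zero matches
    mark the module unscoreable with a warning rather than failing.
    """
    present = set(expr.gene_ids)
    matched = [g for g in module.genes if g in present]
    fraction = len(matched) / len(module.genes)
    scoreable = fraction >= min_fraction and len(matched) >= 1
    if not matched:
        warnings.warn(f"module {module.name!r}: no genes matched", stacklevel=2)
    return MatchReport(module.name, matched, len(module.genes), scoreable)


@dataclass
class ModuleScoreMatrix:
    """Module x sample scores plus the per-module gene-match report."""

    scores: pd.DataFrame  # modules (rows) x samples (columns)
    report: pd.DataFrame  # per requested module: mode, n_genes, n_matched, fraction, scoreable

    @property
    def module_names(self) -> pd.Index:
        return self.scores.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.columns

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "module"
        out.to_csv(path, sep="\t")


def score_median(expr, module, min_fraction=0.5, reference=None):
    """Median-of-centered-genes score.

    Each matched gene is centered by its median across the reference samples
    (the cohort itself by default); the score is the per-sample median of
    those centered values. Centering makes the score location-free across
    platforms.
    """
    match = match_genes(expr, module, min_fraction)
    if not match.scoreable:
        return None, match
    sub = expr.values.loc[match.matched]
    ref = sub if reference is None else reference.values.loc[match.matched]
    centered = sub.sub(ref.median(axis=1), axis=0)
    return centered.median(axis=0), match


def score_first_pc(expr, module, min_fraction=0.5, reference=None):
    """First-principal-component score of the z-scored member genes.

    Genes are z-scored with reference-sample mean/SD; the score is each
    sample's projection on the first principal axis of the reference
    submatrix, sign-oriented so it correlates non-negatively with the mean
    member-gene profile (or per ``direction_hint``), then scaled to unit
    reference variance.
    """
    match = match_genes(expr, module, min_fraction)
    if not match.scoreable or len(match.matched) < 2:
        if match.scoreable:
            warnings.warn(
                f"module {module.name!r}: first_pc needs >= 2 matched genes", stacklevel=2
            )
            match.scoreable = False
        return None, match
    ref_expr = expr if reference is None else reference
    ref = ref_expr.values.loc[match.matched]
    if ref.shape[1] < 3:
        raise ValueError(f"module {module.name!r}: first_pc needs >= 3 samples")
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() == 0:
        warnings.warn(f"module {module.name!r}: all genes zero-variance", stacklevel=2)
        match.scoreable = False
        return None, match
    if not keep.all():
        warnings.warn(
            f"module {module.name!r}: dropped {(~keep).sum()} zero-variance gene(s)",
            stacklevel=2,
        )
    genes = ref.index[keep]
    z_ref = ref.loc[genes].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    # first left singular vector = first principal axis in gene space
    u, s, _ = np.linalg.svd(z_ref.to_numpy(), full_matrices=False)
    axis = u[:, 0]
    ref_score = axis @ z_ref.to_numpy()
    mean_profile = z_ref.mean(axis=0).to_numpy()
    orient = np.sign(np.dot(ref_score - ref_score.mean(), mean_profile - mean_profile.mean()))
    if orient == 0:
        orient = 1.0
    if module.direction_hint is not None:
        orient = float(module.direction_hint)
    axis = axis * orient
    ref_score = ref_score * orient
    scale = ref_score.std(ddof=1)
    if scale == 0:
        scale = 1.0
    center = ref_score.mean()
    z = expr.values.loc[genes].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    score = (axis @ z.to_numpy() - center) / scale
    return pd.Series(score, index=expr.sample_ids), match


def score_centroid_correlation(expr, module, min_fraction=0.5, method="spearman"):
    """Correlation of each sample's member-gene profile with class centroids.

    Returns one row per centroid, named ``module.centroid``. Rank correlation
    is the default; ``method="pearson"`` switches to product-moment. Samples
    with a constant profile get a missing score (undefined correlation).
    """
    match = match_genes(expr, module, min_fraction)
    if not match.scoreable:
        return None, match
    rows = {}
    for cname, cvals in module.centroids.items():
        genes = [g for g in match.matched if g in cvals]
        if len(genes) / len(module.genes) < min_fraction:
            warnings.warn(
                f"module {module.name!r}: centroid {cname!r} overlap below threshold",
                stacklevel=2,
            )
            continue
        centroid = np.array([cvals[g] for g in genes])
        sub = expr.values.loc[genes].to_numpy()
        scores = np.full(sub.shape[1], np.nan)
        for j in range(sub.shape[1]):
            profile = sub[:, j]
            if np.ptp(profile) == 0 or np.ptp(centroid) == 0:
                logger.warning(
                    "module %s: constant profile, correlation undefined for sample %s",
                    module.name,
                    expr.sample_ids[j],
                )
                continue
            if method == "spearman":
                scores[j] = stats.spearmanr(profile, centroid).statistic
            else:
                scores[j] = stats.pearsonr(profile, centroid).statistic
        rows[f"{module.name}.{cname}"] = pd.Series(scores, index=expr.sample_ids)
    if not rows:
        match.scoreable = False
        return None, match
    return pd.DataFrame(rows).T, match


def score_published_model(expr, module, min_fraction=0.5):
    """Fixed linear-model score: offset + sum of weights x expression.

    Genes missing from the matrix contribute zero and are reported via the
    match report.
    """
    match = match_genes(expr, module, min_fraction)
    if not match.scoreable:
        return None, match
    genes = [g for g in match.matched if g in (module.weights or {})]
    w = np.array([module.weights[g] for g in genes])
    if genes:
        vals = expr.values.loc[genes].to_numpy()
        score = module.offset + w @ vals
    else:
        score = np.full(expr.n_samples, module.offset)
    return pd.Series(score, index=expr.sample_ids), match


_SCORERS = {
    "median": score_median,
    "first_pc": score_first_pc,
    "centroid_corr": score_centroid_correlation,
    "published_model": score_published_model,
}


def compute_all_scores(
    expr: ExpressionMatrix,
    registry: ModuleRegistry,
    min_fraction: float = 0.5,
    method: str = "spearman",
    reference: Optional[ExpressionMatrix] = None,
) -> ModuleScoreMatrix:
    """Score every registry module against the matrix, in registry order.

    ``reference`` (default: the matrix itself) supplies the samples from
    which scoring constants — gene medians, z-score parameters, principal
    axes — are derived; pass the training subset to score held-out samples
    without leakage. Unscoreable modules are dropped from the score matrix
    and flagged in the report. Fails only if no module is scoreable.
    """
    rows = []
    report_rows = []
    for module in registry:
        scorer = _SCORERS[module.mode]
        if module.mode == "centroid_corr":
            result, match = scorer(expr, module, min_fraction, method=method)
        elif module.mode == "published_model":
            result, match = scorer(expr, module, min_fraction)
        else:
            result, match = scorer(expr, module, min_fraction, reference=reference)
        report_rows.append(
            {
                "module": module.name,
                "mode": module.mode,
                "n_genes": match.n_total,
                "n_matched": match.n_matched,
                "fraction": match.fraction,
                "scoreable": match.scoreable,
            }
        )
        if result is None:
            logger.warning("module %s not scoreable (matched %d/%d)",
                           module.name, match.n_matched, match.n_total)
            continue
        if isinstance(result, pd.DataFrame):
            rows.append(result)
        else:
            rows.append(result.to_frame(module.name).T)
    if not rows:
        raise ValueError("no module was scoreable against this expression matrix")
    scores = pd.concat(rows, axis=0)
    report = pd.DataFrame(report_rows).set_index("module")
    return ModuleScoreMatrix(scores=scores, report=report)
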