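"""Synthetic expression cohorts with the structure the analysis assumes.

The generator emulates a multi-batch, clinically annotated breast-cancer
expression cohort: blocks of co-expressed genes form modules driven by
latent per-sample scores, batches add per-gene location shifts, clinical
covariates (ER, tumor size, grade, a HER2 latent) are thresholded Gaussians
correlated with designated module scores, relapse times follow an
exponential-baseline Cox model on a sparse set of true predictors with
independent exponential censoring, and binary response (pCR) follows a
logistic model on the same kind of linear predictor.

Everything is driven by :class:`SimulationConfig`; a fixed seed reproduces
every matrix and table exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import ExpressionMatrix


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def _default_coefficients() -> dict:
    # two prognostic modules (one adverse, one protective) plus grade/size,
    # magnitudes typical of standardized log-hazard effects in breast cancer
    return {"MOD_001": 0.8, "MOD_002": -0.6, "grade": 0.4, "size": 0.3}


def _default_dependence() -> dict:
    # clinical variable -> (driving module index, latent correlation)
    return {"er": (0, -0.6), "size": (1, 0.4), "grade": (1, 0.5), "her2": (3, 0.7)}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Rates are per year; coefficients are per standard deviation of the
    (standardized) covariate. Defaults mirror the combined node-negative
    cohort the package targets: ~550 samples, two platforms/batches, ER+
    fraction 0.72, 7-year administrative follow-up, event hazard giving
    roughly a quarter of patients a relapse within the window.
    """

    n_samples: int = 550
    n_genes: int = 2000
    n_modules: int = 20
    genes_per_module: int = 15
    module_correlation: float = 0.7
    n_batches: int = 2
    batch_shift_sd: float = 0.5
    true_coefficients: dict = field(default_factory=_default_coefficients)
    baseline_hazard_rate: float = 0.05
    censoring_rate: float = 0.10
    followup_cutpoint_years: float = 7.0
    pcr_intercept: float = -1.1
    er_pos_rate: float = 0.718
    size_lt2_rate: float = 0.562
    grade_rates: tuple = (0.178, 0.331, 0.491)
    her2_pos_rate: float = 0.20
    clinical_dependence: dict = field(default_factory=_default_dependence)
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.genes_per_module > self.n_genes:
            raise SimulationConfigError(
                "n_modules * genes_per_module exceeds n_genes "
                f"({self.n_modules} * {self.genes_per_module} > {self.n_genes})"
            )
        if not 0.0 <= self.module_correlation <= 1.0:
            raise SimulationConfigError("module_correlation must lie in [0, 1]")
        for name in ("baseline_hazard_rate", "censoring_rate", "followup_cutpoint_years"):
            if getattr(self, name) <= 0:
                raise SimulationConfigError(f"{name} must be strictly positive")
        if self.batch_shift_sd < 0:
            raise SimulationConfigError("batch_shift_sd must be >= 0")
        if self.n_batches < 1:
            raise SimulationConfigError("n_batches must be >= 1")
        for clin, (mod_idx, rho) in self.clinical_dependence.items():
            if not -1.0 <= rho <= 1.0:
                raise SimulationConfigError(
                    f"clinical_dependence[{clin!r}] correlation must lie in [-1, 1]"
                )
            if not 0 <= mod_idx < self.n_modules:
                raise SimulationConfigError(
                    f"clinical_dependence[{clin!r}] references module index {mod_idx} "
                    f"but n_modules={self.n_modules}"
                )

    def module_name(self, idx: int) -> str:
        return f"MOD_{idx + 1:03d}"

    def to_json(self, path) -> None:
        d = asdict(self)
        d["grade_rates"] = list(d["grade_rates"])
        d["clinical_dependence"] = {k: list(v) for k, v in d["clinical_dependence"].items()}
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        d["grade_rates"] = tuple(d["grade_rates"])
        d["clinical_dependence"] = {k: tuple(v) for k, v in d["clinical_dependence"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth saved alongside a generated cohort (JSON-serialisable)."""

    module_memberships: dict  # module name -> gene list
    true_coefficients: dict
    batch_shifts: dict  # batch label -> per-gene shift list (gene order)
    latent_module_scores: pd.DataFrame  # modules x samples
    seed: int

    def to_json(self, path) -> None:
        d = {
            "module_memberships": self.module_memberships,
            "true_coefficients": self.true_coefficients,
            "batch_shifts": self.batch_shifts,
            "latent_module_scores": {
                "index": list(self.latent_module_scores.index),
                "columns": list(self.latent_module_scores.columns),
                "values": self.latent_module_scores.to_numpy().tolist(),
            },
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        lms = pd.DataFrame(
            np.asarray(d["latent_module_scores"]["values"], dtype=float),
            index=d["latent_module_scores"]["index"],
            columns=d["latent_module_scores"]["columns"],
        )
        return cls(
            module_memberships=d["module_memberships"],
            true_coefficients=d["true_coefficients"],
            batch_shifts=d["batch_shifts"],
            latent_module_scores=lms,
            seed=d["seed"],
        )

    def to_registry(self):
        """Median-mode module registry over the true memberships."""
        from .modules import ModuleDefinition, ModuleRegistry

        return ModuleRegistry(
            ModuleDefinition(name=name, genes=genes, mode="median",
                             description="synthetic module")
            for name, genes in self.module_memberships.items()
        )


def generate_expression_cohort(config: SimulationConfig):
    """Generate (ExpressionMatrix, clinical table, SyntheticTruth).

    Member genes of module m are sqrt(rho) * Z_m + sqrt(1-rho) * noise, so
    the average within-module pairwise correlation is rho; remaining genes
    are independent noise. Per-(batch, gene) additive shifts are drawn
    N(0, batch_shift_sd). Clinical categories come from latent Gaussians
    correlated with their designated module's score, thresholded at the
    normal quantiles of the configured prevalences.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n, g = config.n_samples, config.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    her2_module = config.clinical_dependence.get("her2", (None, 0.0))[0]
    gene_ids = []
    memberships = {}
    k = 0
    for m in range(config.n_modules):
        name = config.module_name(m)
        members = []
        for j in range(config.genes_per_module):
            if m == her2_module and j == 0:
                gid = "ERBB2"
            else:
                gid = f"G{k + 1:05d}"
            members.append(gid)
            gene_ids.append(gid)
            k += 1
        memberships[name] = members
    while k < g:
        gene_ids.append(f"G{k + 1:05d}")
        k += 1

    latent = rng.standard_normal((config.n_modules, n))
    rho = config.module_correlation
    values = np.empty((g, n))
    idx = 0
    for m in range(config.n_modules):
        noise = rng.standard_normal((config.genes_per_module, n))
        values[idx: idx + config.genes_per_module] = (
            np.sqrt(rho) * latent[m] + np.sqrt(1.0 - rho) * noise
        )
        idx += config.genes_per_module
    values[idx:] = rng.standard_normal((g - idx, n))

    batch = rng.integers(0, config.n_batches, size=n)
    batch_labels = [f"batch{b}" for b in batch]
    shifts = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, g))
    if config.batch_shift_sd == 0:
        shifts[:] = 0.0
    values = values + shifts[batch].T

    ann = pd.DataFrame(
        {
            "batch": batch_labels,
            "platform": ["Affymetrix" if b % 2 == 0 else "Agilent" for b in batch],
            "source": [f"STUDY{b + 1}" for b in batch],
        },
        index=sample_ids,
    )
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), ann
    )

    def latent_for(clin):
        mod_idx, r = config.clinical_dependence.get(clin, (None, 0.0))
        eps = rng.standard_normal(n)
        if mod_idx is None or r == 0:
            return eps
        return r * latent[mod_idx] + np.sqrt(1.0 - r**2) * eps

    er_l = latent_for("er")
    size_l = latent_for("size")
    grade_l = latent_for("grade")
    her2_l = latent_for("her2")
    g1, g2, _ = config.grade_rates
    clinical = pd.DataFrame(
        {
            "er": np.where(er_l <= norm.ppf(config.er_pos_rate), "pos", "neg"),
            "size": np.where(size_l <= norm.ppf(config.size_lt2_rate), "lt2cm", "ge2cm"),
            "grade": np.select(
                [grade_l <= norm.ppf(g1), grade_l <= norm.ppf(g1 + g2)], ["1", "2"], "3"
            ),
            "her2": np.where(her2_l >= norm.ppf(1.0 - config.her2_pos_rate), "pos", "neg"),
            "source": ann["source"].to_numpy(),
            "platform": ann["platform"].to_numpy(),
        },
        index=sample_ids,
    )

    truth = SyntheticTruth(
        module_memberships=memberships,
        true_coefficients=dict(config.true_coefficients),
        batch_shifts={f"batch{b}": shifts[b].tolist() for b in range(config.n_batches)},
        latent_module_scores=pd.DataFrame(
            latent, index=[config.module_name(m) for m in range(config.n_modules)],
            columns=sample_ids,
        ),
        seed=config.seed,
    )
    return expr, clinical, truth


def _linear_predictor(scores, clinical, coefficients):
    """Standardized linear predictor over named module/clinical variables."""
    from .risk import encode_clinical

    score_df = scores.scores if hasattr(scores, "scores") else scores
    parts = {}
    clin_enc = None
    for name in coefficients:
        if name in score_df.index:
            parts[name] = score_df.loc[name].to_numpy(dtype=float)
        else:
            if clin_enc is None:
                present = [v for v in ("er", "size", "grade", "her2") if v in clinical.columns]
                clin_enc = encode_clinical(clinical, present)
            if name not in clin_enc.columns:
                raise SimulationConfigError(
                    f"coefficient name {name!r} matches no module score or clinical variable"
                )
            parts[name] = clin_enc[name].to_numpy(dtype=float)
    eta = np.zeros(len(clinical))
    for name, beta in coefficients.items():
        x = parts[name]
        sd = x.std(ddof=0)
        if sd == 0:
            continue
        eta += beta * (x - x.mean()) / sd
    return eta


def generate_survival_outcomes(scores, clinical, truth: SyntheticTruth,
                               config: SimulationConfig) -> pd.DataFrame:
    """Right-censored relapse outcomes from an exponential-baseline Cox model.

    Event times are exponential with hazard ``baseline_hazard_rate *
    exp(eta)`` on standardized covariates; censoring is independent
    exponential at ``censoring_rate``; observed time is the minimum. The
    follow-up cut-point is *not* applied here (see
    :func:`prognomod.cohort.apply_followup_cutpoint`).
    """
    config.validate()
    eta = _linear_predictor(scores, clinical, truth.true_coefficients)
    rng = np.random.default_rng([config.seed, 1])
    hazard = config.baseline_hazard_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / config.censoring_rate, size=len(eta))
    out = clinical.copy()
    out["time"] = np.minimum(t_event, t_cens)
    out["event"] = (t_event <= t_cens).astype(int)
    return out


def generate_pcr_outcomes(scores, clinical, truth: SyntheticTruth,
                          config: SimulationConfig) -> pd.DataFrame:
    """Binary pCR outcomes: response ~ Bernoulli(logistic(intercept + eta))."""
    config.validate()
    eta = _linear_predictor(scores, clinical, truth.true_coefficients)
    rng = np.random.default_rng([config.seed, 2])
    prob = 1.0 / (1.0 + np.exp(-(config.pcr_intercept + eta)))
    out = clinical.copy()
    out["response"] = (rng.random(len(eta)) < prob).astype(int)
    return out


def simulate_cohort(config: SimulationConfig, outcome: str = "survival"):
    """One-call convenience: expression + scored modules + outcomes.

    Returns (expr, cohort, scores, truth) where scores are median-mode
    module scores over the true memberships and cohort carries survival or
    response columns.
    """
    from .modules import compute_all_scores

    expr, clinical, truth = generate_expression_cohort(config)
    scores = compute_all_scores(expr, truth.to_registry())
    if outcome == "survival":
        cohort = generate_survival_outcomes(scores, clinical, truth, config)
    elif outcome == "pcr":
        cohort = generate_pcr_outcomes(scores, clinical, truth, config)
    else:
        raise ValueError(f"unknown outcome type {outcome!r}")
    return expr, cohort, scores, truth
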