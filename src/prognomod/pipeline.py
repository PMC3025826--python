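"""End-to-end pipeline orchestration and report rendering.

All numerics land in machine-readable JSON/TSV first; the markdown report is
a derived view. Every output directory carries the fully resolved config so
any artifact is regenerable from it alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cohort import apply_followup_cutpoint, complete_case_filter, define_subgroup
from .containers import ExpressionMatrix, read_table_tsv, validate_clinical
from .modules import compute_all_scores, read_module_registry
from .resample import (
    PCRReport,
    ResampleSummary,
    run_pcr_experiment,
    run_resampling,
)

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Raised before any computation when a config is invalid."""


@dataclasses.dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    expression_path: str
    cohort_path: str
    registry_gmt: str
    registry_sidecar: str = ""
    annotation_path: str = ""
    analysis: str = "resample"  # "resample" or "pcr"
    subgroup: str = "all"
    families: tuple = ("clinical", "genomic", "combined")
    exclude: tuple = ()
    n_target: int = 200
    max_attempts: int = 1000
    cv_folds: int = 10
    cutpoint_years: float = 7.0
    min_fraction: float = 0.5
    seed: int = 0
    out_dir: str = "pipeline_out"

    def validate(self) -> None:
        from .cohort import BUILTIN_SUBGROUPS

        for p in (self.expression_path, self.cohort_path, self.registry_gmt):
            if not Path(p).exists():
                raise PipelineConfigError(f"input not found: {p}")
        if self.subgroup not in BUILTIN_SUBGROUPS:
            raise PipelineConfigError(
                f"unknown subgroup {self.subgroup!r}; valid: {sorted(BUILTIN_SUBGROUPS)}"
            )
        bad = set(self.families) - {"clinical", "genomic", "combined"}
        if bad:
            raise PipelineConfigError(f"unknown families {sorted(bad)}")
        if self.analysis not in ("resample", "pcr"):
            raise PipelineConfigError(f"unknown analysis {self.analysis!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("families", "exclude"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["families"] = list(d["families"])
        d["exclude"] = list(d["exclude"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> Path:
    """assemble -> score -> resample (or pcr) -> reports.

    Returns the output directory; the resolved config is serialized there
    for provenance.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    expr = ExpressionMatrix.from_tsv(
        config.expression_path, config.annotation_path or None
    )
    cohort = validate_clinical(read_table_tsv(config.cohort_path))
    registry = read_module_registry(
        config.registry_gmt, config.registry_sidecar or None
    )
    if config.exclude:
        registry = registry.exclude(config.exclude)

    required = ["er", "size", "grade"]
    required += ["time", "event"] if config.analysis == "resample" else ["response"]
    cohort = complete_case_filter(cohort, [f for f in required if f in cohort.columns])
    if config.analysis == "resample" and "time" in cohort.columns:
        cohort = apply_followup_cutpoint(cohort, config.cutpoint_years)
    ids = define_subgroup(cohort, config.subgroup)
    cohort = cohort.loc[ids]
    expr = expr.subset_samples([s for s in expr.sample_ids if s in set(ids)])

    scores = compute_all_scores(expr, registry, min_fraction=config.min_fraction)
    scores.to_tsv(out / "module_scores.tsv")
    scores.report.to_csv(out / "match_report.tsv", sep="\t")

    if config.analysis == "resample":
        summary = run_resampling(
            cohort, scores, config.families, n_target=config.n_target,
            max_attempts=config.max_attempts, base_seed=config.seed,
            cv_folds=config.cv_folds,
        )
        summary.to_json(out / "summary.json")
        summary.selection_frequency().to_csv(out / "selection_frequency.tsv", sep="\t", index=False)
        summary.cindex_rounds.to_csv(out / "cindex_rounds.tsv", sep="\t")
        summary.superiority_matrix.to_csv(out / "superiority_matrix.tsv", sep="\t")
        (out / "report.md").write_text(render_report(summary))
    else:
        report = run_pcr_experiment(
            cohort, scores, config.families, seed=config.seed, cv_folds=config.cv_folds
        )
        report.auc_table().to_csv(out / "auc.tsv", sep="\t", index=False)
        (out / "report.md").write_text(render_report(report))
    logger.info("pipeline outputs written to %s", out)
    return out


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: floatfmt.format(v) if pd.notna(v) else "")
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + rows)


def render_report(summary) -> str:
    """Human-readable markdown view of a resampling or pCR summary.

    Tables are deterministically ordered (frequency descending, then name).
    """
    lines = ["# prognomod report", ""]
    if isinstance(summary, ResampleSummary):
        lines += [
            f"Rounds attempted: {summary.n_attempted}; target successes: "
            f"{summary.n_target}; complete: {summary.complete}",
            "",
            "## Successful models per family",
            "",
            _md_table(pd.DataFrame([summary.n_successful])),
            "",
            "## Mean test-set concordance index",
            "",
            _md_table(pd.DataFrame([summary.mean_test_cindex])),
            "",
            "## Superiority fractions (row beats column)",
            "",
            _md_table(summary.superiority_matrix.reset_index(names="model")),
            "",
            f"## Selection frequency among successful {summary.primary_family} models",
            "",
        ]
        freq = summary.selection_frequency()
        if len(freq):
            lines.append(_md_table(freq))
        else:
            lines.append("*No successful models — nothing was selected.*")
    elif isinstance(summary, PCRReport):
        lines += ["## ROC AUC per family", "", _md_table(summary.auc_table()), ""]
        for fam, res in summary.families.items():
            if not res.ok:
                lines += [f"### {fam}: failed ({res.error})", ""]
                continue
            lines.append(f"### Variables selected by the {fam} model")
            lines.append("")
            if res.selected:
                tab = pd.DataFrame(
                    sorted(res.selected.items()), columns=["variable", "associated_with"]
                )
                lines.append(_md_table(tab))
            else:
                lines.append("*Empty model.*")
            lines.append("")
    else:
        lines.append("*Empty or unknown summary — nothing to report.*")
    return "\n".join(lines) + "\n"
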