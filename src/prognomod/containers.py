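"""Core data containers: expression matrices, clinical/cohort tables.

Expression data are stored log-scale, genes x samples, with per-sample
annotations (batch, platform, source). Clinical and cohort tables are plain
pandas DataFrames indexed by sample id with a documented column vocabulary:

``er``      {"pos", "neg", "missing"}
``size``    {"lt2cm", "ge2cm", "missing"}
``grade``   {1, 2, 3} or "missing"
``her2``    {"pos", "neg", "missing"}
``source``, ``platform``  free strings
``time``    follow-up in years (> 0)
``event``   {0, 1} relapse indicator
``response``{0, 1} pathological complete response indicator
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = "missing"

CLINICAL_CATEGORIES = {
    "er": {"pos", "neg", MISSING},
    "size": {"lt2cm", "ge2cm", MISSING},
    "her2": {"pos", "neg", MISSING},
}


class DataError(ValueError):
    """Raised when input data violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, plus per-sample annotations.

    Parameters
    ----------
    values : DataFrame
        Genes (index, uppercase symbols) by samples (columns).
    sample_annotations : DataFrame, optional
        Indexed by sample id; columns typically include ``batch``,
        ``platform`` and ``source``. Missing annotations default to a
        single-batch table.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 1 or v.shape[1] < 1:
            raise DataError("expression matrix needs >= 1 gene and >= 1 sample")
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dupes[:5]}")
        self.values = v.astype(float)
        self.values.index = self.values.index.astype(str).str.upper()
        if self.sample_annotations is None:
            self.sample_annotations = pd.DataFrame(
                {"batch": "batch0", "platform": "unknown", "source": "unknown"},
                index=self.values.columns,
            )
        else:
            self.sample_annotations = self.sample_annotations.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)],
            self.sample_annotations.loc[list(sample_ids)],
        )

    def to_tsv(self, path, annotation_path=None) -> None:
        """Write the matrix as TSV (first column ``gene_id``)."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        if annotation_path is not None:
            ann = self.sample_annotations.copy()
            ann.index.name = "sample_id"
            ann.to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, annotation_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        ann = None
        if annotation_path is not None and Path(annotation_path).exists():
            ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        return cls(values, ann)


def validate_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-column vocabulary; returns the table unchanged."""
    if table.index.duplicated().any():
        raise DataError("duplicate sample ids in clinical table")
    for col, allowed in CLINICAL_CATEGORIES.items():
        if col in table.columns:
            bad = set(table[col].astype(str)) - allowed
            if bad:
                raise DataError(f"invalid values in column {col!r}: {sorted(bad)}")
    if "grade" in table.columns:
        ok = {"1", "2", "3", MISSING}
        bad = set(table["grade"].astype(str)) - ok
        if bad:
            raise DataError(f"invalid values in column 'grade': {sorted(bad)}")
    if "event" in table.columns:
        if not set(np.unique(table["event"])) <= {0, 1}:
            raise DataError("event indicator must be 0/1")
    if "time" in table.columns:
        t = np.asarray(table["time"], dtype=float)
        if (t <= 0).any():
            bad_ids = table.index[t <= 0].tolist()
            raise DataError(f"nonpositive follow-up time for samples {bad_ids[:5]}")
    return table


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")
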