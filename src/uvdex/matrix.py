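"""Expression-matrix container and TSV I/O.

The central in-memory object is :class:`ExpressionMatrix`: a genes x samples
log2 expression table (pandas DataFrame) paired with a sample-annotation
table holding, per sample, the experimental group, zeitgeber time (hours
since lights-on) and batch/day label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, MatrixParseError

ANNOTATION_COLUMNS = ("group", "zt", "batch")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with sample annotations.

    Parameters
    ----------
    values
        DataFrame of finite floats; index = gene ids, columns = sample ids.
    samples
        DataFrame indexed by sample id with columns ``group`` (condition
        label), ``zt`` (zeitgeber time, hours in [0, 24)) and ``batch``.
        Row order must match the column order of ``values``.
    zero_variance_genes
        Gene ids flagged as zero-variance by :func:`uvdex.normalize.standardize_genes`.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    zero_variance_genes: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        if list(self.samples.index) != list(self.values.columns):
            raise DataError(
                "sample annotation rows do not match matrix columns"
            )
        for col in ANNOTATION_COLUMNS:
            if col not in self.samples.columns:
                raise DataError(f"sample annotation missing column {col!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise DataError("expression values must all be finite numbers")
        zt = self.samples["zt"].to_numpy(dtype=float)
        if ((zt < 0) | (zt >= 24)).any():
            raise DataError("zeitgeber times must lie in [0, 24)")

    # -- convenience accessors -------------------------------------------------

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

    @property
    def groups(self) -> list:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["group"]))

    def group_samples(self, group: str) -> list:
        """Sample ids belonging to one condition."""
        ids = self.samples.index[self.samples["group"] == group]
        return list(ids)

    def with_values(self, values: pd.DataFrame, **kw) -> "ExpressionMatrix":
        """New matrix sharing this one's annotations."""
        return ExpressionMatrix(values, self.samples.copy(), **kw)


def read_matrix(path, annotations=None) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id, header = sample ids).

    ``annotations`` may be a path to a sample-annotation TSV; when omitted,
    minimal annotations are fabricated (group = sample id prefix before the
    last ``_``, zt = 0, batch = "NA") so matrices can be inspected standalone.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise MatrixParseError(f"{path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixParseError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            where = f"gene {bad[0]!r}, sample {col!r}" if len(bad) else f"sample {col!r}"
            raise MatrixParseError(f"{path}: non-numeric value at {where}")
    if annotations is not None:
        ann = read_annotations(annotations)
    else:
        ann = pd.DataFrame(
            {
                "group": [c.rsplit("_", 1)[0] for c in df.columns],
                "zt": 0.0,
                "batch": "NA",
            },
            index=df.columns,
        )
    return ExpressionMatrix(df.astype(float), ann.loc[df.columns])


def write_matrix(X: ExpressionMatrix, path) -> None:
    """Write the expression table as TSV, 6 decimal places."""
    X.values.to_csv(path, sep="\t", float_format="%.6f", index_label="gene")


def read_annotations(path) -> pd.DataFrame:
    """Read a sample-annotation TSV (sample, group, zt, batch)."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise MatrixParseError(f"{path}: annotation columns missing: {missing}")
    ann["zt"] = ann["zt"].astype(float)
    return ann


def write_annotations(X: ExpressionMatrix, path) -> None:
    X.samples.to_csv(path, sep="\t", index_label="sample")
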