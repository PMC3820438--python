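"""Reading and writing the package's plain-text formats.

Expression matrices travel as TSV (first column gene id, header row sample
ids) with a companion two-column sample-to-group file; study results as
tidy CSV with a fixed, documented header.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .evaluation import RESULT_COLUMNS
from .stats_core import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_groups_tsv",
    "write_results_csv",
    "read_results_csv",
]


class SchemaError(ValueError):
    """Raised when a file does not match the documented schema."""


def read_expression_tsv(
    path, groups=None, group_sizes: tuple[int, int] | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    ``groups`` maps sample id -> group label (e.g. from
    :func:`read_groups_tsv`); alternatively ``group_sizes`` assigns the
    first n1 columns to group "1" and the rest to group "2".
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)]
        raise SchemaError(
            f"missing value(s) in expression matrix, first affected gene: {bad[0]!r}"
        )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"duplicate gene id {dup!r}")
    samples = df.columns.to_numpy()
    if groups is not None:
        unresolved = [s for s in samples if s not in groups]
        if unresolved:
            raise SchemaError(f"samples without a group assignment: {unresolved[:5]}")
        group = np.array([groups[s] for s in samples])
    elif group_sizes is not None:
        n1, n2 = group_sizes
        if n1 + n2 != len(samples):
            raise SchemaError(
                f"group sizes {n1}+{n2} do not match {len(samples)} samples"
            )
        group = np.array(["1"] * n1 + ["2"] * n2)
    else:
        raise ValueError("provide either a groups mapping or group_sizes")
    return ExpressionMatrix(
        values=df.to_numpy(float), gene_ids=df.index.to_numpy(), group=group
    )


def write_expression_tsv(data: ExpressionMatrix, path, float_format=None) -> None:
    """Write an expression matrix as TSV at full precision (round-trip safe)."""
    df = pd.DataFrame(
        data.values,
        index=pd.Index(data.gene_ids, name="gene_id"),
        columns=[f"s{i:03d}" for i in range(data.values.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format=float_format)


def read_groups_tsv(path) -> dict:
    """Two-column sample-id / group-label file (no header) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise SchemaError(f"group file must have 2 columns, found {df.shape[1]}")
    return dict(zip(df[0], df[1]))


def write_results_csv(rows: pd.DataFrame, path) -> None:
    """Write a study result table with the fixed column order."""
    missing = [c for c in RESULT_COLUMNS if c not in rows.columns]
    if missing:
        raise SchemaError(f"result table missing columns: {missing}")
    extra = [c for c in rows.columns if c not in RESULT_COLUMNS]
    rows[RESULT_COLUMNS + extra].to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    """Read a study result table, validating the documented header."""
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"result file missing columns: {missing}")
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    if extra:
        warnings.warn(
            f"unknown extra column(s) preserved: {extra}", RuntimeWarning, stacklevel=2
        )
    if "note" in df.columns:
        df["note"] = df["note"].fillna("")
    return df
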