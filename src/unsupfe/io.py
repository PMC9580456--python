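"""Readers and writers for the pipeline's tabular formats.

Count matrices arrive as TSV/CSV (feature IDs in the first column, sample
IDs in the header) or as MatrixMarket triplets with ``.rows`` / ``.cols``
name sidecars; tensors arrive as long-format tables with columns
(feature, sample, condition, value).  All outputs are TSV with a one-line
``#`` header embedding the configuration hash and seed so a run can be
replayed from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .decomposition import (
    ExpressionMatrix,
    ExpressionTensor,
    MatrixDecomposition,
    TensorDecomposition,
)
from .pvalues import PValueAssignment

__all__ = [
    "FilterReport",
    "read_count_matrix",
    "read_tensor_long",
    "read_design",
    "write_tsv_with_header",
    "write_results",
    "write_sd_curve",
    "write_decomposition",
]

FILTER_MODES = ("drop_all_zero", "require_all_nonzero", "none")

# htseq-count appends bookkeeping rows ("__no_feature", "__ambiguous", ...)
# that must never be treated as genes
_SPECIAL_PREFIX = "__"


@dataclass
class FilterReport:
    """Counts of rows dropped per filtering rule."""

    n_input: int
    n_special: int = 0
    n_filtered: int = 0
    n_kept: int = 0
    filter_mode: str = "none"


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, comment="#")


def _read_mtx(path: Path) -> pd.DataFrame:
    raw = mmread(path)
    mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
    rows = Path(str(path) + ".rows")
    cols = Path(str(path) + ".cols")
    if not rows.exists() or not cols.exists():
        rows = path.with_suffix(".rows")
        cols = path.with_suffix(".cols")
    feature_ids = rows.read_text().split()
    sample_ids = cols.read_text().split()
    return pd.DataFrame(mat, index=feature_ids, columns=sample_ids)


def read_count_matrix(
    path: str | Path, filter_mode: str = "drop_all_zero"
) -> tuple[ExpressionMatrix, FilterReport]:
    """Read a gene-by-sample matrix and apply row filtering.

    Rows whose ID starts with ``__`` are always dropped.  ``filter_mode``
    then removes genes with zero counts in every sample (``drop_all_zero``),
    keeps only genes positive in every sample (``require_all_nonzero``), or
    leaves the rest untouched (``none``).
    """
    if filter_mode not in FILTER_MODES:
        raise ValueError(f"unknown filter_mode {filter_mode!r}; choose from {FILTER_MODES}")
    path = Path(path)
    df = _read_mtx(path) if path.suffix.lower() == ".mtx" else _read_table(path)
    report = FilterReport(n_input=len(df), filter_mode=filter_mode)

    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature ID {dup!r}")
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric value at feature {row!r}, sample {col!r}")

    special = df.index.astype(str).str.startswith(_SPECIAL_PREFIX)
    report.n_special = int(special.sum())
    df = df.loc[~special]

    values = df.to_numpy(dtype=float)
    if filter_mode == "drop_all_zero":
        keep = ~(values == 0).all(axis=1)
    elif filter_mode == "require_all_nonzero":
        keep = (values > 0).all(axis=1)
    else:
        keep = np.ones(len(df), bool)
    report.n_filtered = int((~keep).sum())
    df = df.loc[keep]
    report.n_kept = len(df)
    if report.n_kept < 2:
        raise ValueError("fewer than 2 features remain after filtering")
    return (
        ExpressionMatrix(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns]),
        report,
    )


def read_tensor_long(path: str | Path) -> ExpressionTensor:
    """Read a complete 3-mode tensor from a long-format table.

    Expects columns (feature, sample, condition, value); every cell of the
    feature x sample x condition grid must be present exactly once.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = ["feature", "sample", "condition", "value"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"long-format tensor needs columns {required}, got {list(df.columns)}")
    features = list(dict.fromkeys(df["feature"].astype(str)))
    samples = list(dict.fromkeys(df["sample"].astype(str)))
    conditions = list(dict.fromkeys(df["condition"].astype(str)))
    expected = len(features) * len(samples) * len(conditions)
    if len(df) != expected:
        raise ValueError(
            f"tensor is incomplete: {len(df)} rows for a "
            f"{len(features)}x{len(samples)}x{len(conditions)} grid ({expected} cells)"
        )
    pivot = df.set_index(["feature", "sample", "condition"])["value"]
    if pivot.index.duplicated().any():
        raise ValueError("duplicate (feature, sample, condition) cells")
    values = np.empty((len(features), len(samples), len(conditions)))
    fi = {f: i for i, f in enumerate(features)}
    si = {s: j for j, s in enumerate(samples)}
    ci = {c: k for k, c in enumerate(conditions)}
    for (f, s, c), v in pivot.items():
        values[fi[str(f)], si[str(s)], ci[str(c)]] = v
    return ExpressionTensor(values, features, samples, conditions)


def read_design(path: str | Path, column: str) -> pd.Series:
    """Read one numeric column of a sample design table (index = sample IDs)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if column not in df.columns:
        raise ValueError(f"design file has no column {column!r}; available: {list(df.columns)}")
    return df[column].astype(float)


def write_tsv_with_header(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    """Write a TSV preceded by a single ``#`` metadata line (key=value pairs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "# " + " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_results(
    assignment: PValueAssignment,
    feature_ids: list[str],
    scores: np.ndarray,
    path: str | Path,
    meta: dict,
) -> None:
    df = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "score_u": scores,
            "raw_p": assignment.raw_p,
            "adjusted_p": assignment.adjusted_p,
            "selected": assignment.selected.astype(int),
        }
    )
    write_tsv_with_header(df, path, meta)


def write_sd_curve(result, path: str | Path, meta: dict) -> None:
    sigmas = [s for s, _ in result.objective_curve]
    sigma_h = [h for _, h in result.objective_curve]
    n_sel = result.n_selected_curve or [np.nan] * len(sigmas)
    df = pd.DataFrame({"sigma": sigmas, "sigma_h": sigma_h, "n_selected": n_sel})
    write_tsv_with_header(df, path, meta)


def write_decomposition(
    decomp: MatrixDecomposition | TensorDecomposition,
    feature_ids: list[str],
    sample_ids: list[str],
    out_dir: str | Path,
    meta: dict,
    condition_ids: list[str] | None = None,
) -> None:
    """Write factor matrices as TSV, one file per factor."""
    out_dir = Path(out_dir)
    if isinstance(decomp, MatrixDecomposition):
        pairs = [
            ("scores", decomp.scores, feature_ids, "PC"),
            ("loadings", decomp.loadings, sample_ids, "PC"),
        ]
    else:
        pairs = [
            ("factor_feature", decomp.factor_feature, feature_ids, "L"),
            ("factor_sample", decomp.factor_sample, sample_ids, "L"),
            ("factor_condition", decomp.factor_condition, condition_ids or [], "L"),
        ]
    for name, mat, ids, prefix in pairs:
        df = pd.DataFrame(mat, columns=[f"{prefix}{l + 1}" for l in range(mat.shape[1])])
        df.insert(0, "id", ids)
        write_tsv_with_header(df, out_dir / f"{name}.tsv", meta)
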