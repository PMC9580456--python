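"""Standardization and matrix/tensor factorization.

The feature-extraction pipeline works on a gene-by-sample expression matrix
``x_ij`` (N features, M samples) or a gene-by-sample-by-condition tensor
``x_ijk``.  Each sample column (or each (sample, condition) fiber) is
standardized over features to mean 0 and sum of squares N, after which the
matrix is decomposed by PCA and the tensor by higher-order SVD (HOSVD, the
standard way to compute an all-orthogonal Tucker decomposition).  The
feature-side singular/principal vectors ``u`` produced here are what the
P-value attribution step consumes.

PCA is defined through the N x N feature-side gram matrix
``sum_j x_ij x_i'j`` but is computed via a thin SVD of the N x M matrix,
which yields mathematically identical scores and eigenvalues without ever
materializing an N x N array (N can be ~1e5 for a genome-wide matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "ExpressionTensor",
    "MatrixDecomposition",
    "TensorDecomposition",
    "AxisSelection",
    "standardize_matrix",
    "standardize_tensor",
    "pca",
    "hosvd",
    "select_axes",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with identifiers.

    ``values[i, j]`` is the expression of feature ``feature_ids[i]`` in
    sample ``sample_ids[j]``.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise ValueError(f"need at least 2 features and 2 samples, got {n} x {m}")
        if len(self.feature_ids) != n or len(self.sample_ids) != m:
            raise ValueError("identifier lengths do not match the value array")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ExpressionTensor:
    """Three-mode expression array: features x samples x conditions."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        n, m, k = self.values.shape
        if n < 2 or m < 1 or k < 1:
            raise ValueError(f"invalid tensor shape {n} x {m} x {k}")
        for ids, size, what in (
            (self.feature_ids, n, "feature"),
            (self.sample_ids, m, "sample"),
            (self.condition_ids, k, "condition"),
        ):
            if len(ids) != size:
                raise ValueError(f"{what} identifiers do not match the value array")
            _check_unique(ids, what)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")


@dataclass
class MatrixDecomposition:
    """PCA of a standardized expression matrix.

    ``scores[:, l]`` is the l-th principal-component score over features
    (orthonormal columns, the eigenvectors of the feature-side gram matrix);
    ``loadings[:, l]`` is the matching sample-side loading
    ``v_lj = sum_i x_ij u_li`` with squared norm ``eigenvalues[l]``.
    """

    scores: np.ndarray  # N x L, orthonormal columns
    loadings: np.ndarray  # M x L
    eigenvalues: np.ndarray  # L, descending
    contributions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        total = float(np.sum(self.eigenvalues))
        self.contributions = np.asarray(self.eigenvalues, dtype=float) / total

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class TensorDecomposition:
    """All-orthogonal Tucker decomposition computed by HOSVD.

    ``core[l1, l2, l3]`` weights the rank-1 term
    ``factor_feature[:, l1] o factor_sample[:, l2] o factor_condition[:, l3]``.
    """

    factor_feature: np.ndarray  # N x L1
    factor_sample: np.ndarray  # M x L2
    factor_condition: np.ndarray  # K x L3
    core: np.ndarray  # L1 x L2 x L3

    def reconstruct(self) -> np.ndarray:
        out = np.tensordot(self.factor_feature, self.core, axes=(1, 0))
        out = np.tensordot(out, self.factor_sample.T, axes=(1, 0))
        # axes now (feature, condition-core, sample); contract condition last
        out = np.tensordot(out, self.factor_condition.T, axes=(1, 0))
        return out  # feature x sample x condition


@dataclass
class AxisSelection:
    """Indices (0-based) of the decomposition axes chosen for P-value attribution."""

    feature_axis: int
    sample_axis: int | None = None
    condition_axis: int | None = None


def _standardize_columns(cols: np.ndarray, labels: list[str], what: str) -> np.ndarray:
    """Center each column to mean 0 and scale to sum of squares N (rows)."""
    n = cols.shape[0]
    centered = cols - cols.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", centered, centered)
    bad = np.flatnonzero(ss <= 0)
    if bad.size:
        raise ValueError(f"constant {what} {labels[bad[0]]}: cannot standardize")
    return centered * np.sqrt(n / ss)


def standardize_matrix(
    x: ExpressionMatrix,
    log_transform: bool = False,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Standardize every sample column to mean 0 / sum of squares N over features.

    With ``log_transform`` the values are first mapped to
    ``log2(x + pseudocount)``; count matrices are otherwise used as-is.
    """
    values = np.asarray(x.values, dtype=float)
    if log_transform:
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if np.any(values + pseudocount <= 0):
            raise ValueError("log transform requires x + pseudocount > 0")
        values = np.log2(values + pseudocount)
    std = _standardize_columns(values, x.sample_ids, "sample column")
    return ExpressionMatrix(std, list(x.feature_ids), list(x.sample_ids))


def standardize_tensor(x: ExpressionTensor) -> ExpressionTensor:
    """Standardize every (sample, condition) fiber over features."""
    n, m, k = x.values.shape
    flat = x.values.reshape(n, m * k)
    # C-order reshape of (n, m, k): flat column index is j*k + c
    labels = [f"({s}, {c})" for s in x.sample_ids for c in x.condition_ids]
    std = _standardize_columns(flat, labels, "(sample, condition) fiber")
    return ExpressionTensor(
        std.reshape(n, m, k),
        list(x.feature_ids),
        list(x.sample_ids),
        list(x.condition_ids),
    )


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Sign vector making each column's largest-magnitude entry positive."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def pca(x: ExpressionMatrix) -> MatrixDecomposition:
    """Principal-component decomposition of a standardized matrix.

    Equivalent to diagonalizing the N x N feature-side gram matrix: the score
    columns are its eigenvectors, the eigenvalues its spectrum, and the
    sample-side loadings are ``v_lj = sum_i x_ij u_li``.  Computed by thin
    SVD so memory stays O(N*M).
    """
    u, s, vt = np.linalg.svd(x.values, full_matrices=False)
    signs = _fix_signs(u)
    u = u * signs
    loadings = (vt.T * s) * signs  # v_l = X^T u_l, column l scaled by s_l
    return MatrixDecomposition(scores=u, loadings=loadings, eigenvalues=s**2)


def _unfold(t: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)


def hosvd(
    x: ExpressionTensor, ranks: tuple[int, int, int] | None = None
) -> TensorDecomposition:
    """Higher-order SVD of a 3-mode tensor.

    Each factor matrix holds the left singular vectors of the corresponding
    mode unfolding; the core is the tensor contracted with the factor
    transposes.  By default full unfolding ranks are kept, so the
    decomposition reconstructs the input exactly (up to round-off); ``ranks``
    optionally truncates each mode.
    """
    t = x.values
    factors = []
    for mode in range(3):
        um, _, _ = np.linalg.svd(_unfold(t, mode), full_matrices=False)
        if ranks is not None:
            r = int(ranks[mode])
            if not 1 <= r <= um.shape[1]:
                raise ValueError(f"rank {r} out of range for mode {mode}")
            um = um[:, :r]
        um = um * _fix_signs(um)
        factors.append(um)
    core = np.einsum(
        "ijk,ia,jb,kc->abc", t, factors[0], factors[1], factors[2], optimize=True
    )
    return TensorDecomposition(
        factor_feature=factors[0],
        factor_sample=factors[1],
        factor_condition=factors[2],
        core=core,
    )


def _argmax_abs_corr(columns: np.ndarray, target: np.ndarray, what: str) -> int:
    target = np.asarray(target, dtype=float)
    if target.shape[0] != columns.shape[0]:
        raise ValueError(f"{what} target length {target.shape[0]} does not match mode size {columns.shape[0]}")
    tc = target - target.mean()
    norm_t = np.linalg.norm(tc)
    if norm_t == 0:
        raise ValueError(f"{what} target has zero variance")
    cc = columns - columns.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(cc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(norms > 0, (cc.T @ tc) / (norms * norm_t), 0.0)
    return int(np.argmax(np.abs(corr)))


def select_axes(
    decomp: MatrixDecomposition | TensorDecomposition,
    target_sample: np.ndarray | None = None,
    target_condition: np.ndarray | None = None,
    mode: Literal["correlation", "explicit"] = "correlation",
    explicit_indices: Sequence[int] | None = None,
) -> AxisSelection:
    """Choose the decomposition axes tied to the biological contrast of interest.

    In ``correlation`` mode the sample axis (and, for a tensor, the condition
    axis) is the factor column with the largest absolute Pearson correlation
    to the supplied target vector; the tensor feature axis is then the one
    whose core entry ``G(l1, l2, l3)`` has the largest absolute value (ties
    broken toward the smallest index).  ``explicit`` mode takes 0-based
    indices verbatim after bounds checking.
    """
    is_tensor = isinstance(decomp, TensorDecomposition)

    if mode == "explicit":
        if explicit_indices is None:
            raise ValueError("explicit mode requires explicit_indices")
        idx = list(explicit_indices)
        if is_tensor:
            if len(idx) != 3:
                raise ValueError("tensor selection needs (l1, l2, l3)")
            sizes = decomp.core.shape
            for i, size in zip(idx, sizes):
                if not 0 <= i < size:
                    raise IndexError(f"component index {i} out of range [0, {size})")
            return AxisSelection(idx[0], idx[1], idx[2])
        if len(idx) != 1:
            raise ValueError("matrix selection needs a single component index")
        if not 0 <= idx[0] < decomp.n_components:
            raise IndexError(f"component index {idx[0]} out of range [0, {decomp.n_components})")
        return AxisSelection(idx[0])

    if mode != "correlation":
        raise ValueError(f"unknown selection mode {mode!r}")
    if target_sample is None:
        raise ValueError("correlation mode requires target_sample")

    if not is_tensor:
        l = _argmax_abs_corr(decomp.loadings, target_sample, "sample")
        return AxisSelection(l)

    l2 = _argmax_abs_corr(decomp.factor_sample, target_sample, "sample")
    if target_condition is not None:
        l3 = _argmax_abs_corr(decomp.factor_condition, target_condition, "condition")
        g = np.abs(decomp.core[:, l2, l3])
        l1 = int(np.argmax(g))
        return AxisSelection(l1, l2, l3)
    if decomp.core.shape[2] == 1:
        l3 = 0
        l1 = int(np.argmax(np.abs(decomp.core[:, l2, l3])))
        return AxisSelection(l1, l2, l3)
    # no condition target: pick (l1, l3) jointly from the core slab at l2
    slab = np.abs(decomp.core[:, l2, :])
    l1, l3 = np.unravel_index(int(np.argmax(slab)), slab.shape)
    return AxisSelection(int(l1), l2, int(l3))
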