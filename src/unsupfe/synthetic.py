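"""Synthetic data generators for end-to-end testing of the pipeline.

Four generators cover the statistical designs the method is meant to handle:

* ``gaussian_with_outliers`` — a score vector that is a standard-normal null
  contaminated by a block of identical outliers.  This is the canonical
  failure case for the pooled SD: the outliers inflate it, the P-values grow,
  and nothing survives BH at 0.01 until the SD is recalibrated.
* ``two_class_counts`` — a two-class count matrix (reference-vs-brain style
  benchmark design) with log-normal per-gene baselines, a planted DEG
  fraction with signed log2 fold changes applied to one class, and Poisson
  counting noise (negative-binomial optional).  The method under test makes
  no negative-binomial assumption, so Poisson is the deliberate default.
* ``planted_tensor`` — a gene x sample x condition Gaussian tensor with a
  control-vs-treated mean shift planted in a gene subset under one condition.
* ``uniform_ma_demo`` — two independent uniform variables mapped to MA-plot
  coordinates, illustrating why, at a fixed threshold on the raw difference,
  points with small mean expression need a larger fold change to be flagged.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import ExpressionMatrix, ExpressionTensor

__all__ = [
    "SyntheticMixture",
    "SyntheticCounts",
    "PlantedTensor",
    "gaussian_with_outliers",
    "two_class_counts",
    "planted_tensor",
    "uniform_ma_demo",
]


@dataclass
class SyntheticMixture:
    """Standard-normal null values pooled with constant outliers."""

    values: np.ndarray
    is_outlier: np.ndarray
    n_null: int
    n_out: int
    out_value: float
    seed: int


@dataclass
class SyntheticCounts:
    """Two-class count matrix with planted DEGs and ground-truth labels."""

    matrix: ExpressionMatrix
    class_labels: np.ndarray  # True = class A
    is_deg: np.ndarray
    lfc: np.ndarray  # signed log2 fold change, 0 for non-DEGs
    params: dict


@dataclass
class PlantedTensor:
    """Gaussian tensor with a condition-specific treated-vs-control signal."""

    tensor: ExpressionTensor
    is_signal: np.ndarray  # over genes
    contrast: np.ndarray  # over samples: -1 control, +1 treated
    signal_condition: int
    params: dict


def gaussian_with_outliers(
    n_null: int = 1000,
    n_out: int = 100,
    out_value: float = 5.0,
    seed: int = 0,
) -> SyntheticMixture:
    """Draw ``n_null`` standard-normal values and append ``n_out`` copies of
    ``out_value``."""
    if n_null < 0 or n_out < 0:
        raise ValueError("counts must be nonnegative")
    if n_null + n_out < 2:
        raise ValueError("need at least 2 values in total")
    rng = np.random.default_rng(seed)
    values = np.concatenate([rng.standard_normal(n_null), np.full(n_out, float(out_value))])
    is_outlier = np.concatenate([np.zeros(n_null, bool), np.ones(n_out, bool)])
    return SyntheticMixture(values, is_outlier, n_null, n_out, float(out_value), seed)


def two_class_counts(
    n_genes: int = 2000,
    n_per_class: int = 7,
    deg_fraction: float = 0.1,
    lfc_scale: float = 2.0,
    baseline_log_mean: float = 5.0,
    baseline_log_sd: float = 2.0,
    seed: int = 0,
    nb_dispersion: float | None = None,
    libsize_scale: float = 0.0,
) -> SyntheticCounts:
    """Simulate a two-class RNA-seq count matrix with a planted DEG fraction.

    Per-gene baseline means are ``2**Normal(baseline_log_mean,
    baseline_log_sd)`` (log2-normal).  A ``deg_fraction`` share of genes gets
    a signed log2 fold change with magnitude ``|Normal(0, lfc_scale)|``
    applied multiplicatively to class B only.  Counts are Poisson around the
    class mean; passing ``nb_dispersion`` > 0 switches to gamma-Poisson
    (negative binomial) noise with that dispersion.  ``libsize_scale`` > 0
    adds a per-sample log-normal library-size factor.
    """
    if n_genes < 100:
        raise ValueError("need at least 100 genes")
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per class")
    if not 0 <= deg_fraction <= 1:
        raise ValueError("deg_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    baseline = 2.0 ** rng.normal(baseline_log_mean, baseline_log_sd, n_genes)
    n_deg = int(round(deg_fraction * n_genes))
    is_deg = np.zeros(n_genes, bool)
    is_deg[rng.choice(n_genes, size=n_deg, replace=False)] = True
    lfc = np.zeros(n_genes)
    if n_deg:
        signs = rng.choice([-1.0, 1.0], size=n_deg)
        lfc[is_deg] = signs * np.abs(rng.normal(0.0, lfc_scale, n_deg))

    m = 2 * n_per_class
    class_labels = np.array([True] * n_per_class + [False] * n_per_class)
    mean = np.tile(baseline[:, None], (1, m))
    mean[:, ~class_labels] *= 2.0 ** lfc[:, None]
    if libsize_scale > 0:
        mean = mean * 2.0 ** rng.normal(0.0, libsize_scale, m)[None, :]

    if nb_dispersion is not None:
        if nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        shape = 1.0 / nb_dispersion
        mean = rng.gamma(shape, mean / shape)
    counts = rng.poisson(mean).astype(float)

    matrix = ExpressionMatrix(
        counts,
        [f"gene_{i}" for i in range(n_genes)],
        [f"A_{j}" for j in range(n_per_class)] + [f"B_{j}" for j in range(n_per_class)],
    )
    params = dict(
        n_genes=n_genes,
        n_per_class=n_per_class,
        deg_fraction=deg_fraction,
        lfc_scale=lfc_scale,
        baseline_log_mean=baseline_log_mean,
        baseline_log_sd=baseline_log_sd,
        nb_dispersion=nb_dispersion,
        libsize_scale=libsize_scale,
        seed=seed,
    )
    return SyntheticCounts(matrix, class_labels, is_deg, lfc, params)


def planted_tensor(
    n_genes: int = 1000,
    n_samples: int = 6,
    n_conditions: int = 3,
    signal_genes: int = 50,
    signal_condition: int = 0,
    effect: float = 3.0,
    seed: int = 0,
) -> PlantedTensor:
    """Gaussian background tensor with a planted condition-specific contrast.

    Samples split into a control half and a treated half; the first
    ``signal_genes`` genes receive a mean shift of ``effect`` on treated
    samples under ``signal_condition`` only.
    """
    if signal_genes > n_genes:
        raise ValueError("signal_genes exceeds n_genes")
    if not 0 <= signal_condition < n_conditions:
        raise ValueError("signal_condition out of range")
    if n_samples < 2 or n_samples % 2:
        raise ValueError("n_samples must be even and at least 2")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_genes, n_samples, n_conditions))
    half = n_samples // 2
    is_signal = np.zeros(n_genes, bool)
    is_signal[:signal_genes] = True
    values[np.ix_(is_signal, np.arange(half, n_samples), [signal_condition])] += effect
    contrast = np.array([-1.0] * half + [1.0] * half)
    tensor = ExpressionTensor(
        values,
        [f"gene_{i}" for i in range(n_genes)],
        [f"ctrl_{j}" for j in range(half)] + [f"trt_{j}" for j in range(half)],
        [f"cond_{k}" for k in range(n_conditions)],
    )
    params = dict(
        n_genes=n_genes,
        n_samples=n_samples,
        n_conditions=n_conditions,
        signal_genes=signal_genes,
        signal_condition=signal_condition,
        effect=effect,
        seed=seed,
    )
    return PlantedTensor(tensor, is_signal, contrast, signal_condition, params)


def uniform_ma_demo(
    n: int, delta_threshold: float = 0.5, seed: int = 0
) -> pd.DataFrame:
    """MA coordinates of independent uniform pairs, flagged by raw difference.

    Columns: x, y (uniform on [0, 1]), A = (log2 x + log2 y) / 2,
    M = log2(x / y), flagged = |x - y| > delta_threshold.  The flagged region
    shows that at fixed M the raw difference shrinks with the smaller
    variable: Delta = y * (2**M - 1).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if delta_threshold < 0:
        raise ValueError("delta_threshold must be nonnegative")
    rng = np.random.default_rng(seed)
    x = rng.uniform(size=n)
    y = rng.uniform(size=n)
    with np.errstate(divide="ignore"):
        a = 0.5 * (np.log2(x) + np.log2(y))
        m = np.log2(x) - np.log2(y)
    return pd.DataFrame(
        {"x": x, "y": y, "A": a, "M": m, "flagged": np.abs(x - y) > delta_threshold}
    )
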