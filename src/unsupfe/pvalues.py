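"""Chi-squared P-value attribution, BH adjustment, and feature selection.

A selected score column ``u`` is assumed to follow a centered Gaussian null
with standard deviation sigma; each feature's statistic ``(u_i / sigma)^2``
is then chi-squared with 1 degree of freedom, and
``P_i = P[chi2_1 > (u_i/sigma)^2]``.  Raw P-values are corrected by the
Benjamini-Hochberg step-up procedure and features with adjusted P at or
below a threshold (conventionally 0.01, or 0.1 for the tensor analyses) are
selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PValueAssignment",
    "chi2_pvalues",
    "bh_adjust",
    "naive_sd",
    "select_features",
    "assign_pvalues",
]

# smallest positive normal double: raw P is clamped here instead of
# underflowing to 0 so log-scale diagnostics stay finite
_P_FLOOR = np.finfo(float).tiny


@dataclass
class PValueAssignment:
    """Per-feature raw/adjusted P-values and selection flags at one sigma."""

    sigma: float
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    selected: np.ndarray
    threshold: float

    n_selected: int = field(init=False)
    n_unselected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_selected = int(np.count_nonzero(self.selected))
        self.n_unselected = int(self.selected.size - self.n_selected)


def chi2_pvalues(u: np.ndarray, sigma: float) -> np.ndarray:
    """Two-sided Gaussian-null P-values via the chi-squared(1) survival function."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("scores must be finite")
    p = stats.chi2.sf(np.square(u / sigma), df=1)
    return np.maximum(p, _P_FLOOR)


def bh_adjust(raw_p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (capped at 1, original order)."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        raise ValueError("cannot adjust an empty P-value vector")
    if np.any(raw_p <= 0) or np.any(raw_p > 1):
        raise ValueError("raw P-values must lie in (0, 1]")
    return multipletests(raw_p, method="fdr_bh")[1]


def naive_sd(u: np.ndarray) -> float:
    """Population SD (divisor N, mean-centered) pooled over all features."""
    u = np.asarray(u, dtype=float)
    if u.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(u))
    if sd == 0 or not math.isfinite(sd):
        raise ValueError("scores are constant; SD is undefined as a null scale")
    return sd


def select_features(
    raw_p: np.ndarray, threshold: float = 0.01, sigma: float = float("nan")
) -> PValueAssignment:
    """BH-adjust raw P-values and flag features with adjusted P <= threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    adjusted = bh_adjust(raw_p)
    selected = adjusted <= threshold
    return PValueAssignment(
        sigma=float(sigma),
        raw_p=np.asarray(raw_p, dtype=float),
        adjusted_p=adjusted,
        selected=selected,
        threshold=float(threshold),
    )


def assign_pvalues(
    u: np.ndarray, sigma: float, threshold: float = 0.01
) -> PValueAssignment:
    """Full attribution for one score column: chi-squared P, BH, selection."""
    return select_features(chi2_pvalues(u, sigma), threshold=threshold, sigma=sigma)
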