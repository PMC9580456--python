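"""Empirical-null SD calibration by histogram flatness.

The pooled SD of a score column overestimates the null scale whenever
outliers (true differentially expressed features) inflate it, which makes
every P-value too large and can empty the selected set entirely.  The
calibration implemented here scans candidate SDs and, for each, recomputes
the P-values, the BH adjustment, and the selection cutoff; the histogram of
1 - P below the selection boundary is then scored by the population SD of
its bin counts, sigma_h.  Under a correctly scaled null the unselected
P-values are uniform, so the histogram is flat up to the boundary bin and
sigma_h is minimal — the calibrated SD is the minimizer of sigma_h.

The objective is self-referential (the bin set depends on the candidate SD
through selection), cheap, and piecewise-noisy, so it is minimized by a
deterministic log-spaced grid scan followed by bounded scalar refinement.
A degenerate trivial minimum exists as sigma -> 0, where nearly everything
is flagged and hardly any bins remain; such candidates are excluded by an
admissibility guard (at least half of the features must stay unselected and
at least 10 bins must be included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .pvalues import assign_pvalues, naive_sd

__all__ = [
    "HistogramObjective",
    "SDOptimizationResult",
    "histogram_objective",
    "optimize_sd",
    "recompute_sd",
]

_MIN_INCLUDED_BINS = 10


@dataclass(frozen=True)
class HistogramObjective:
    """One evaluation of the flatness objective at a candidate sigma."""

    sigma_h: float
    n_bins_included: int
    n_selected: int


@dataclass
class SDOptimizationResult:
    """Outcome of the SD calibration.

    ``sigma_recomputed`` is the pooled SD restricted to the features left
    unselected at the optimum — a diagnostic that should sit near the true
    null SD when the calibration succeeded.
    """

    sigma_naive: float
    sigma_opt: float
    sigma_recomputed: float
    objective_curve: list[tuple[float, float]]
    p0: float
    n_bins: int
    n_selected_at_opt: int
    n_selected_curve: list[int] = field(default_factory=list)


def histogram_objective(
    sigma: float, u: np.ndarray, p0: float = 0.01, n_bins: int = 100
) -> HistogramObjective:
    """Flatness of the 1-P histogram over the unselected region at one sigma.

    P-values are computed at ``sigma`` and BH-adjusted; features with
    adjusted P <= ``p0`` count as selected.  The histogram of ``1 - P`` is
    formed on ``n_bins`` equal-width bins spanning [0, 1], and the bins
    whose left edge lies below ``t = min(1 - P_i over selected)`` (``t = 1``
    when nothing is selected) enter the objective.  The bin containing the
    selection boundary itself is therefore included: when the calibration
    succeeds, the selected features pile into that single bin while the rest
    of the histogram is uniform, and any candidate sigma that lets null
    features leak into the boundary region is penalized.  Returns the
    population SD of the included bin counts; fewer than 2 included bins is
    inadmissible and reported as +inf.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 histogram bins")
    u = np.asarray(u, dtype=float)
    if u.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} scores, got {u.size}")
    assignment = assign_pvalues(u, sigma, threshold=p0)
    one_minus_p = 1.0 - assignment.raw_p
    if assignment.n_selected:
        t = float(np.min(one_minus_p[assignment.selected]))
    else:
        t = 1.0
    counts, edges = np.histogram(one_minus_p, bins=n_bins, range=(0.0, 1.0))
    included = counts[edges[:-1] < t]
    if included.size < 2:
        return HistogramObjective(np.inf, int(included.size), assignment.n_selected)
    return HistogramObjective(
        float(np.std(included)), int(included.size), assignment.n_selected
    )


def _admissible(obj: HistogramObjective, n: int) -> bool:
    return (
        np.isfinite(obj.sigma_h)
        and obj.n_bins_included >= _MIN_INCLUDED_BINS
        and (n - obj.n_selected) >= n / 2
    )


def optimize_sd(
    u: np.ndarray,
    p0: float = 0.01,
    n_bins: int = 100,
    grid: np.ndarray | None = None,
    n_grid: int = 200,
) -> SDOptimizationResult:
    """Calibrate the null SD by minimizing the histogram-flatness objective.

    The objective is evaluated on a log-spaced grid (by default ``n_grid``
    points spanning ``[sigma_naive / 50, 2 * sigma_naive]``); inadmissible
    candidates — those flagging at least half of the features or leaving
    fewer than 10 histogram bins — are discarded, and the grid minimum is
    refined by bounded scalar minimization between its neighbors.
    """
    u = np.asarray(u, dtype=float)
    sigma_naive = naive_sd(u)
    if grid is None:
        grid = np.geomspace(sigma_naive / 50.0, 2.0 * sigma_naive, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
            raise ValueError("grid must be a positive, strictly increasing vector")

    n = u.size
    evals = [histogram_objective(s, u, p0=p0, n_bins=n_bins) for s in grid]
    curve = [(float(s), e.sigma_h) for s, e in zip(grid, evals)]
    admissible = [i for i, e in enumerate(evals) if _admissible(e, n)]
    if not admissible:
        raise ValueError(
            "no admissible sigma on the grid; widen the grid or raise p0"
        )

    best = min(admissible, key=lambda i: (evals[i].sigma_h, i))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    sigma_opt = float(grid[best])
    best_val = evals[best].sigma_h
    if hi > lo:

        # finite penalty: Brent's parabolic step cannot handle inf arithmetic
        penalty = 1e30

        def penalized(s: float) -> float:
            e = histogram_objective(s, u, p0=p0, n_bins=n_bins)
            return e.sigma_h if _admissible(e, n) else penalty

        res = optimize.minimize_scalar(
            penalized, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4 * sigma_naive}
        )
        if res.fun < penalty and res.fun <= best_val:
            sigma_opt = float(res.x)

    final = assign_pvalues(u, sigma_opt, threshold=p0)
    return SDOptimizationResult(
        sigma_naive=sigma_naive,
        sigma_opt=sigma_opt,
        sigma_recomputed=recompute_sd(u, sigma_opt, p0),
        objective_curve=curve,
        p0=p0,
        n_bins=n_bins,
        n_selected_at_opt=final.n_selected,
        n_selected_curve=[e.n_selected for e in evals],
    )


def recompute_sd(u: np.ndarray, sigma: float, p0: float = 0.01) -> float:
    """Pooled SD over the features NOT selected at (sigma, p0).

    The unselected set is the presumed Gaussian part of the score
    distribution; its pooled SD should approach the true null SD when the
    calibrated sigma separates signal from null correctly.
    """
    u = np.asarray(u, dtype=float)
    assignment = assign_pvalues(u, sigma, threshold=p0)
    rest = u[~assignment.selected]
    if rest.size < 2:
        raise ValueError("fewer than 2 unselected features; cannot recompute SD")
    return naive_sd(rest)
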