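"""Optional diagnostic plots (objective curve, 1-P histogram, MA plot)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pvalues import chi2_pvalues
from .sd_optimization import SDOptimizationResult

__all__ = ["plot_objective_curve", "plot_pvalue_histogram", "plot_maplot"]


def plot_objective_curve(result: SDOptimizationResult, path: str | Path) -> None:
    sigmas = np.array([s for s, _ in result.objective_curve])
    values = np.array([h for _, h in result.objective_curve])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    finite = np.isfinite(values)
    ax.plot(sigmas[finite], values[finite], ".", ms=3)
    ax.axvline(result.sigma_opt, color="red", lw=1, label=f"optimum {result.sigma_opt:.3g}")
    ax.axvline(result.sigma_naive, color="gray", lw=1, ls="--", label=f"pooled {result.sigma_naive:.3g}")
    ax.set_xlabel("candidate SD")
    ax.set_ylabel(r"$\sigma_h$ (bin-count SD)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pvalue_histogram(u: np.ndarray, sigma: float, path: str | Path, n_bins: int = 100) -> None:
    p = chi2_pvalues(u, sigma)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(1.0 - p, bins=n_bins, range=(0, 1), color="steelblue")
    ax.set_xlabel("1 - P")
    ax.set_ylabel("count")
    ax.set_title(f"sigma = {sigma:.4g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_maplot(ma: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"not_selected": "0.7", "selected_0.1": "blue", "selected_0.01": "red"}
    for cat, color in colors.items():
        sub = ma[ma["category"] == cat]
        ax.scatter(sub["A"], sub["M"], s=4, c=color, label=cat, alpha=0.6, lw=0)
    ax.set_xlabel("A (mean log2 expression)")
    ax.set_ylabel("M (log2 fold change)")
    ax.legend(frameon=False, fontsize=8, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
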