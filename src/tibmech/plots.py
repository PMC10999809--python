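"""Figure helpers: regression scatter with 95 % band, mid-slice map pairs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .comparison import RegressionReport

__all__ = ["plot_regression", "plot_midplane_pair"]


def plot_regression(
    x: np.ndarray,
    y: np.ndarray,
    report: RegressionReport,
    xlabel: str = "x",
    ylabel: str = "y",
    path: str | Path | None = None,
    identity_line: bool = False,
):
    """Scatter with the OLS fit and its 95 % confidence band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x, y, s=25, color="k", zorder=3)
    if len(report.outliers):
        ax.scatter(x[report.outliers], y[report.outliers], s=60, facecolors="none",
                   edgecolors="tab:orange", label="outlier (1.5 IQR)", zorder=4)
    xs = np.linspace(x.min(), x.max(), 100)
    fit = report.slope * xs + report.intercept
    n = report.n
    t_crit = stats.t.ppf(0.975, n - 2)
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    half = t_crit * report.see * np.sqrt(1.0 / n + (xs - xbar) ** 2 / sxx)
    ax.plot(xs, fit, color="tab:red", lw=1.5,
            label=f"$R^2$ = {report.r_squared:.2f}")
    ax.fill_between(xs, fit - half, fit + half, color="0.8", alpha=0.7, zorder=1)
    if identity_line:
        lim = [min(x.min(), y.min()), max(x.max(), y.max())]
        ax.plot(lim, lim, "k--", lw=0.8, label="1:1")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_midplane_pair(
    hfe_map: np.ndarray,
    dvc_map: np.ndarray,
    title_left: str = "hFE",
    title_right: str = "DVC",
    label: str = r"$\|\tilde{F}\|$",
    path: str | Path | None = None,
):
    """Side-by-side mid-slice maps on a common color scale (original config)."""
    both = np.concatenate([np.ravel(hfe_map), np.ravel(dvc_map)])
    vmin, vmax = np.nanmin(both), np.nanmax(both)
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    for ax, m, title in zip(axes, (hfe_map, dvc_map), (title_left, title_right)):
        im = ax.imshow(m, origin="lower", vmin=vmin, vmax=vmax, cmap="viridis")
        ax.set_title(title, fontsize=10)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.85, label=label)
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
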