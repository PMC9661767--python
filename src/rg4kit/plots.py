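"""Optional figures: saturation curves, coverage regression, bias bars.

Each function takes the plain-text tables the pipeline writes and renders a
matplotlib figure; nothing here affects the numeric outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_saturation", "plot_coverage_regression", "plot_nt_bias"]


def plot_saturation(sat: pd.DataFrame, path: str | Path) -> None:
    """Deduplicated molecules vs subsampled depth, one line per library."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for lib, grp in sat.groupby("library"):
        ax.plot(grp["depth"], grp["deduplicated"], marker="o", label=lib)
    ax.set_xlabel("subsampled read pairs")
    ax.set_ylabel("deduplicated molecules")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_coverage_regression(
    cov_a: np.ndarray, cov_b: np.ndarray, slope: float, intercept: float, path: str | Path
) -> None:
    """log10-log10 scatter of agreed-site coverages with the OLS line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lx, ly = np.log10(cov_a), np.log10(cov_b)
    ax.scatter(lx, ly, s=8, alpha=0.6)
    xs = np.linspace(lx.min(), lx.max(), 50)
    ax.plot(xs, slope * xs + intercept, color="crimson",
            label=f"slope={slope:.2f}, b={intercept:.3f}")
    ax.set_xlabel("log10 coverage (library A)")
    ax.set_ylabel("log10 coverage (library B)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_nt_bias(bias: pd.DataFrame, path: str | Path) -> None:
    """Stacked bars of the 5'-nucleotide composition views."""
    fig, ax = plt.subplots(figsize=(5, 4))
    views = [v for v in bias["view"].unique() if v != "stalled_positions"]
    bottom = {v: 0.0 for v in views}
    colors = {"A": "#4daf4a", "C": "#377eb8", "G": "#ff7f00", "T": "#e41a1c"}
    for base in "ACGT":
        vals = []
        for v in views:
            row = bias[(bias["view"] == v) & (bias["key"] == base)]
            vals.append(float(row["value"].iloc[0]) if len(row) else 0.0)
        ax.bar(views, vals, bottom=[bottom[v] for v in views],
               color=colors[base], label=base)
        for v, val in zip(views, vals):
            bottom[v] += val
    ax.set_ylabel("fraction of read 5' nucleotides")
    ax.legend(ncols=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
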