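"""Plot helpers: correlogram envelopes and coefficient (forest) plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_correlogram", "plot_coefficients"]


def plot_correlogram(correlogram, path: str | Path, title: str = ""):
    """Observed LOESS curve with the permutation null envelope."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(correlogram.grid, correlogram.lower, correlogram.upper,
                    color="0.85", label="null envelope (95%)")
    ax.plot(correlogram.grid, correlogram.observed, "k-", lw=1.5,
            label="observed")
    sig = correlogram.significant()
    if sig.any():
        ax.plot(correlogram.grid[sig], correlogram.observed[sig], "r.",
                ms=6, label="outside envelope")
    ax.set_xlabel("pairwise distance")
    ax.set_ylabel("relatedness (LOESS)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_coefficients(coef_table, path: str | Path, title: str = ""):
    """Forest plot of (averaged) coefficients with 95% CIs.

    ``coef_table`` is a DataFrame indexed by term with columns ``coef``,
    ``ci_lower`` and ``ci_upper`` (as produced by FitResult.coef_table or
    model averaging).
    """
    terms = [t for t in coef_table.index if t != "(Intercept)"]
    tbl = coef_table.loc[terms]
    fig, ax = plt.subplots(figsize=(5, 0.5 + 0.4 * max(len(terms), 1)))
    y = range(len(tbl))
    ax.hlines(y, tbl["ci_lower"], tbl["ci_upper"], color="0.3")
    ax.plot(tbl["coef"], y, "ko", ms=5)
    ax.axvline(0.0, color="0.7", ls="--", lw=1)
    ax.set_yticks(list(y))
    ax.set_yticklabels(tbl.index)
    ax.set_xlabel("coefficient (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
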