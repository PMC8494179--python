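"""Plot rendering for tornado, PSA scatter and CEAC outputs.

All functions take the exported DataFrames (not live model objects) so any
result CSV can be re-plotted without re-running the analysis.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["tornado_plot", "scatter_plot", "ceac_plot"]


def tornado_plot(df: pd.DataFrame, path: str | Path, base_metric: float = 0.0) -> Path:
    """Horizontal-bar tornado of incremental NMB at the threshold."""
    df = df.iloc[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(8, 0.35 * len(df) + 1.5))
    left = df[["metric_low", "metric_high"]].min(axis=1)
    width = (df["metric_low"] - df["metric_high"]).abs()
    colors = ["#c0392b" if flip else "#2980b9" for flip in df["flip"]]
    ax.barh(df["parameter"], width, left=left, color=colors, alpha=0.85)
    ax.axvline(base_metric, color="k", lw=0.8)
    ax.set_xlabel("incremental net monetary benefit of screening (USD)")
    ax.set_title("One-way sensitivity analysis (red bars flip the decision)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def scatter_plot(df: pd.DataFrame, path: str | Path, wtp: float = 50_000.0) -> Path:
    """Incremental cost-effectiveness plane with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(df["inc_qaly"], df["inc_cost"], s=6, alpha=0.4, color="#2980b9")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    lim = max(abs(df["inc_qaly"]).max(), 1e-6)
    xs = [-lim, lim]
    ax.plot(xs, [wtp * x for x in xs], "r--", lw=1,
            label=f"WTP = ${wtp:,.0f}/QALY")
    ax.set_xlabel("incremental QALYs (screening - non-screening)")
    ax.set_ylabel("incremental cost, USD")
    ax.set_title("PSA incremental cost-effectiveness plane")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ceac_plot(df: pd.DataFrame, path: str | Path) -> Path:
    """Acceptability curves for both strategies."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.plot(df["wtp"], df["p_screening"], label="screening", color="#2980b9")
    ax.plot(df["wtp"], df["p_non_screening"], label="non-screening",
            color="#c0392b")
    ax.axhline(0.5, color="k", lw=0.6, ls=":")
    ax.set_xlabel("willingness to pay, USD/QALY")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.set_title("Cost-effectiveness acceptability curve")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
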