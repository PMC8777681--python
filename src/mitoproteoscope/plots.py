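"""Figure helpers for the report: volcano, RCA bars, growth curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

CLASS_COLORS = {"down": "#4c72b0", "up": "#c44e52", "ns": "#bbbbbb"}


def volcano_plot(volcano: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    plotted = volcano.dropna(subset=["y"])
    for cls, sub in plotted.groupby("class"):
        ax.scatter(sub["x"], sub["y"], s=6, alpha=0.6,
                   color=CLASS_COLORS.get(cls, "#bbbbbb"), label=cls)
    for x in volcano.attrs.get("x_lines", (-1, 1)):
        ax.axvline(x, color="k", ls="--", lw=0.7)
    ax.axhline(volcano.attrs.get("y_line", 1.301), color="k", ls="--", lw=0.7)
    ax.set_xlabel("log2 difference (patient - control)")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def rca_plot(rca_table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = range(len(rca_table))
    vals = rca_table["ratio_percent"]
    err_low = vals - rca_table["ci_low_percent"]
    err_high = rca_table["ci_high_percent"] - vals
    ax.bar(x, vals, color="#55a868", width=0.6)
    ax.errorbar(x, vals, yerr=[err_low.fillna(0), err_high.fillna(0)],
                fmt="none", ecolor="k", capsize=3, lw=1)
    for i, (pct, star) in enumerate(zip(vals, rca_table["stars"])):
        if star not in ("na",):
            ax.text(i, (pct if pd.notna(pct) else 0) + 6, star,
                    ha="center", fontsize=8)
    ax.axhline(100, color="k", ls=":", lw=0.8)
    ax.set_xticks(list(x))
    ax.set_xticklabels(rca_table.index, rotation=0)
    ax.set_ylabel("relative complex abundance (% of control)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def growth_plot(growth: pd.DataFrame, path: str | Path) -> None:
    conditions = sorted(growth.loc[~growth["is_blank"], "condition"].unique())
    fig, axes = plt.subplots(1, len(conditions),
                             figsize=(3.2 * len(conditions), 3), sharey=True)
    if len(conditions) == 1:
        axes = [axes]
    for ax, condition in zip(axes, conditions):
        sub = growth[(growth["condition"] == condition) & (~growth["is_blank"])]
        means = sub.groupby(["cell_line", "day"])["growth_norm"].mean().unstack(0)
        means.plot(ax=ax, marker="o", ms=3)
        ax.set_title(condition, fontsize=9)
        ax.set_xlabel("day")
    axes[0].set_ylabel("growth (relative to day 0)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
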