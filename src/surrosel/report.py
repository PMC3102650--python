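"""Tabular and graphical report generation.

Writes the analysis outputs in the shapes practitioners expect from a
surrogacy study: a sites-required table, per-bar mean +/- SD data for
the two effectiveness figures, the ANOVA and Tukey tables, the
effectiveness/consistency classification, and bar charts with error
bars.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .pipeline import ALL_SPECIES_ROW, TARGET_ALL
from .stats import AnovaResult, Classification, TukeyResult

__all__ = ["render_report"]


def _bar_data(eval_table: pd.DataFrame, target: str | None = None) -> pd.DataFrame:
    df = eval_table
    if target is not None:
        df = df[df["target"] == target]
    out = (
        df.groupby(["region", "group", "target"], sort=False)["representation_pct"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    return out


def render_report(
    sites_table: pd.DataFrame,
    eval_table: pd.DataFrame,
    anova: AnovaResult,
    tukey: TukeyResult,
    classification: Classification,
    out_dir,
) -> dict[str, Path]:
    """Write all report files under ``out_dir`` and return their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    regions = list(dict.fromkeys(sites_table["region"]))
    wide = sites_table.pivot(index="group", columns="region", values=["n_species", "n_sites"])
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    order = [g for g in dict.fromkeys(sites_table["group"]) if g != ALL_SPECIES_ROW]
    order.append(ALL_SPECIES_ROW)
    wide = wide.loc[[g for g in order if g in wide.index]]
    paths["table1"] = out / "table1.csv"
    wide.to_csv(paths["table1"])

    fig1 = _bar_data(eval_table, TARGET_ALL)
    paths["fig1_data"] = out / "fig1_data.csv"
    fig1.to_csv(paths["fig1_data"], index=False)

    fig2 = _bar_data(eval_table[eval_table["target"] != TARGET_ALL])
    paths["fig2_data"] = out / "fig2_data.csv"
    fig2.to_csv(paths["fig2_data"], index=False)

    anova_out = anova.factors.copy()
    anova_out.loc["model"] = {
        "ss": float("nan"),
        "df": anova.model_df[0],
        "ms": float("nan"),
        "F": anova.model_f,
        "p": anova.model_p,
    }
    paths["anova"] = out / "anova.csv"
    anova_out.to_csv(paths["anova"], index_label="source")

    paths["tukey"] = out / "tukey.csv"
    tukey.table.to_csv(paths["tukey"], index=False)

    eff = classification.effectiveness.pivot(index="group", columns="region", values="effective")
    eff.columns = [f"effective_{r}" for r in eff.columns]
    cls = eff.merge(
        classification.consistency.set_index("group")[["consistent"]],
        left_index=True,
        right_index=True,
        how="left",
    )
    paths["classification"] = out / "classification.csv"
    cls.to_csv(paths["classification"])

    paths["fig1"] = out / "fig1.png"
    _plot_grouped_bars(fig1, regions, "Representation of all target species (%)", paths["fig1"])

    paths["fig2"] = out / "fig2.png"
    _plot_target_panels(fig2, regions, paths["fig2"])
    return paths


def _plot_grouped_bars(data: pd.DataFrame, regions, ylabel: str, path: Path) -> None:
    groups = list(dict.fromkeys(data["group"]))
    x = range(len(groups))
    width = 0.8 / max(1, len(regions))
    fig, ax = plt.subplots(figsize=(max(6, len(groups)), 4))
    for i, region in enumerate(regions):
        sub = data[data["region"] == region].set_index("group").reindex(groups)
        ax.bar(
            [xi + i * width for xi in x],
            sub["mean"],
            width=width,
            yerr=sub["sd"],
            capsize=2,
            label=str(region),
        )
    ax.set_xticks([xi + width * (len(regions) - 1) / 2 for xi in x])
    ax.set_xticklabels(groups, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_target_panels(data: pd.DataFrame, regions, path: Path) -> None:
    targets = list(dict.fromkeys(data["target"]))
    ncols = 3
    nrows = -(-len(targets) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.8 * nrows), squeeze=False, sharey=True
    )
    groups = list(dict.fromkeys(data["group"]))
    width = 0.8 / max(1, len(regions))
    for ax, target in zip(axes.flat, targets):
        sub_t = data[data["target"] == target]
        x = range(len(groups))
        for i, region in enumerate(regions):
            sub = sub_t[sub_t["region"] == region].set_index("group").reindex(groups)
            ax.bar(
                [xi + i * width for xi in x],
                sub["mean"],
                width=width,
                yerr=sub["sd"],
                capsize=1.5,
                label=str(region),
            )
        ax.set_title(f"target: {target}", fontsize=9)
        ax.set_xticks([xi + width * (len(regions) - 1) / 2 for xi in x])
        ax.set_xticklabels(groups, rotation=90, fontsize=6)
    for ax in axes.flat[len(targets):]:
        ax.set_visible(False)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
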