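"""Inferential layer: two-way ANOVA, Tukey HSD, and classification.

Representation percentages from the evaluation table are analysed with
a fixed-effects two-way ANOVA (region x group, with interaction) over a
balanced design, followed by Tukey's honestly-significant-difference
test on all region x group cell pairs at a conservative alpha (default
1%, lowered to blunt the spatial non-independence of overlapping
solutions). Two labels are then derived per indicator group:

* **effective** (per region): its mean target representation exceeds
  the null model's in that region *and* the group-vs-null Tukey
  comparison is significant;
* **consistent**: the group's performance in the two regions is *not*
  significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .pipeline import IDEAL_MODEL, NULL_MODEL, TARGET_ALL

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "Classification",
    "two_way_anova",
    "tukey_hsd",
    "classify",
]


@dataclass
class AnovaResult:
    """Factorial decomposition plus overall-model (cell-means) test.

    ``factors`` has rows region/group/interaction/residual with columns
    ss, df, ms, F, p. ``model_df`` is (cells - 1, N - cells): with 11
    groups, 2 regions and 20 runs per cell that is (21, 418).
    ``zero_variance`` flags a degenerate table (all observations equal),
    in which case every F is undefined (NaN).
    """

    factors: pd.DataFrame
    model_f: float
    model_df: tuple[int, int]
    model_p: float
    cell_stats: pd.DataFrame  # columns: region, group, n, mean, sd
    n_per_cell: int
    zero_variance: bool

    @property
    def ms_resid(self) -> float:
        return float(self.factors.loc["residual", "ms"])

    @property
    def df_resid(self) -> int:
        return int(self.factors.loc["residual", "df"])

    @property
    def n_cells(self) -> int:
        return len(self.cell_stats)


@dataclass
class TukeyResult:
    """All pairwise region x group cell comparisons.

    ``table`` columns: region_i, group_i, region_j, group_j, mean_diff
    (absolute), q, p, significant. ``alpha`` is the level the
    significance flags were computed at.
    """

    table: pd.DataFrame
    alpha: float
    k: int
    df_resid: int

    def lookup(self, cell_i: tuple[str, str], cell_j: tuple[str, str]) -> pd.Series:
        t = self.table
        m = (
            ((t["region_i"] == cell_i[0]) & (t["group_i"] == cell_i[1])
             & (t["region_j"] == cell_j[0]) & (t["group_j"] == cell_j[1]))
            | ((t["region_i"] == cell_j[0]) & (t["group_i"] == cell_j[1])
               & (t["region_j"] == cell_i[0]) & (t["group_j"] == cell_i[1]))
        )
        rows = t[m]
        if rows.empty:
            raise KeyError(f"no comparison between {cell_i} and {cell_j}")
        return rows.iloc[0]


@dataclass
class Classification:
    """Effectiveness per (region, group) and consistency per group."""

    effectiveness: pd.DataFrame  # region, group, mean, null_mean, p_vs_null, effective
    consistency: pd.DataFrame  # group, p_between_regions, consistent
    alpha: float


def _check_balance(df: pd.DataFrame) -> int:
    counts = df.groupby(["region", "group"], sort=False).size()
    if counts.nunique() != 1:
        deficient = counts.idxmin()
        raise ValueError(
            f"unbalanced design: cell (region={deficient[0]!r}, group={deficient[1]!r}) "
            f"has {counts.min()} observations, others up to {counts.max()}"
        )
    return int(counts.iloc[0])


def two_way_anova(
    table: pd.DataFrame, target: str = TARGET_ALL, response: str = "representation_pct"
) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction on the evaluation table.

    Requires a balanced design (equal runs per region x group cell),
    at least two groups and two regions. The overall-model F treats
    every region x group combination as one cell of a one-way layout,
    giving df ``(cells - 1, N - cells)``.
    """
    df = table[table["target"] == target].copy()
    if df.empty:
        raise ValueError(f"no records with target {target!r}")
    regions = df["region"].unique()
    groups = df["group"].unique()
    if len(regions) < 2:
        raise ValueError("two-way ANOVA requires at least 2 regions")
    if len(groups) < 2:
        raise ValueError("two-way ANOVA requires at least 2 groups")
    n = _check_balance(df)
    if n < 2:
        raise ValueError("need at least 2 observations per cell")

    cell_stats = (
        df.groupby(["region", "group"], sort=False)[response]
        .agg(n="size", mean="mean", sd=lambda x: x.std(ddof=1))
        .reset_index()
    )
    k = len(cell_stats)
    n_obs = len(df)
    y = df[response].to_numpy(dtype=float)
    ss_total = float(((y - y.mean()) ** 2).sum())

    idx = ["region", "group", "interaction", "residual"]
    if ss_total == 0.0:
        factors = pd.DataFrame(
            {
                "ss": [0.0, 0.0, 0.0, 0.0],
                "df": [len(regions) - 1, len(groups) - 1,
                       (len(regions) - 1) * (len(groups) - 1), n_obs - k],
                "ms": [0.0] * 4,
                "F": [np.nan] * 4,
                "p": [np.nan] * 4,
            },
            index=idx,
        )
        return AnovaResult(
            factors=factors,
            model_f=np.nan,
            model_df=(k - 1, n_obs - k),
            model_p=np.nan,
            cell_stats=cell_stats,
            n_per_cell=n,
            zero_variance=True,
        )

    model = ols(f"{response} ~ C(region) * C(group)", data=df).fit()
    aov = anova_lm(model, typ=2)
    rows = {
        "region": aov.loc["C(region)"],
        "group": aov.loc["C(group)"],
        "interaction": aov.loc["C(region):C(group)"],
        "residual": aov.loc["Residual"],
    }
    factors = pd.DataFrame(
        {
            "ss": [rows[r]["sum_sq"] for r in rows],
            "df": [int(rows[r]["df"]) for r in rows],
            "F": [rows[r]["F"] for r in rows],
            "p": [rows[r]["PR(>F)"] for r in rows],
        },
        index=list(rows),
    )
    factors.insert(2, "ms", factors["ss"] / factors["df"])
    return AnovaResult(
        factors=factors,
        model_f=float(model.fvalue),
        model_df=(int(model.df_model), int(model.df_resid)),
        model_p=float(model.f_pvalue),
        cell_stats=cell_stats,
        n_per_cell=n,
        zero_variance=False,
    )


def tukey_hsd(anova: AnovaResult, alpha: float = 0.01) -> TukeyResult:
    """Tukey HSD over all region x group cell pairs.

    ``q = |mean_i - mean_j| / sqrt(MS_resid / n)`` with the p-value from
    the studentized-range distribution with (k cells, residual df).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if anova.n_per_cell < 2:
        raise ValueError("Tukey HSD needs at least 2 observations per cell")
    cells = anova.cell_stats
    k = anova.n_cells
    se = np.sqrt(anova.ms_resid / anova.n_per_cell)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ci = cells.iloc[i]
            cj = cells.iloc[j]
            diff = abs(float(ci["mean"]) - float(cj["mean"]))
            if se > 0:
                q = diff / se
                p = float(studentized_range.sf(q, k, anova.df_resid))
            else:
                q = np.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            rows.append(
                (ci["region"], ci["group"], cj["region"], cj["group"],
                 diff, q, p, p < alpha)
            )
    table = pd.DataFrame(
        rows,
        columns=["region_i", "group_i", "region_j", "group_j",
                 "mean_diff", "q", "p", "significant"],
    )
    return TukeyResult(table=table, alpha=alpha, k=k, df_resid=anova.df_resid)


def classify(
    table: pd.DataFrame,
    tukey: TukeyResult,
    alpha: float = 0.01,
    target: str = TARGET_ALL,
) -> Classification:
    """Label indicator groups effective (per region) and consistent.

    Effective: mean representation above the same-region null model's
    *and* significantly so. Consistent: the between-region comparison
    of the group not significant. Order of records in the table does
    not matter.
    """
    df = table[table["target"] == target]
    if df.empty:
        raise ValueError(f"no records with target {target!r}")
    means = df.groupby(["region", "group"], sort=False)["representation_pct"].mean()
    regions = sorted(df["region"].unique())
    groups = [g for g in df["group"].unique() if g not in (NULL_MODEL, IDEAL_MODEL)]
    for r in regions:
        if (r, NULL_MODEL) not in means.index:
            raise ValueError(f"missing null-model cell for region {r!r}")

    eff_rows = []
    for r in regions:
        null_mean = float(means[(r, NULL_MODEL)])
        for g in sorted(groups):
            m = float(means[(r, g)])
            comp = tukey.lookup((r, g), (r, NULL_MODEL))
            effective = m > null_mean and bool(comp["p"] < alpha)
            eff_rows.append((r, g, m, null_mean, float(comp["p"]), effective))
    effectiveness = pd.DataFrame(
        eff_rows, columns=["region", "group", "mean", "null_mean", "p_vs_null", "effective"]
    )

    cons_rows = []
    if len(regions) == 2:
        ra, rb = regions
        for g in sorted(groups):
            comp = tukey.lookup((ra, g), (rb, g))
            cons_rows.append((g, float(comp["p"]), bool(comp["p"] >= alpha)))
    consistency = pd.DataFrame(cons_rows, columns=["group", "p_between_regions", "consistent"])
    return Classification(effectiveness=effectiveness, consistency=consistency, alpha=alpha)
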