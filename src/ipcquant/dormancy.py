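"""Replicate-level dormancy proportion analysis and qPCR expression ratios.

Dormancy assays score each female fly as arrested (no yolk deposition in the
ovarian follicles) or not, and summarize each replicate vial as the
proportion of arrested females among those dissected.  Inference is done on
the variance-stabilizing arcsine transform

    y = arcsin(sqrt(p)),   y in [0, pi/2] radians,

of the replicate proportions: a one-way ANOVA across genotypes with post-hoc
Tukey HSD, or a two-factor (genotype x photoperiod) ANOVA with interaction
for factorial designs.  Displayed group summaries stay on the untransformed
percent scale.

qPCR threshold cycles are converted to relative expression via 2^-ddCt with
a reference gene and a calibrator group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import FormatError, ValidationError
from .io import DormancyTable


@dataclass
class DormancyAnalysis:
    """Per-replicate proportions, group summaries and the ANOVA/Tukey tables."""

    proportions: pd.DataFrame   # replicate-level: group cols, proportion, arcsine
    group_summary: pd.DataFrame # mean / sem on the proportion scale, n_replicates
    anova: pd.DataFrame         # factor, df, sum_sq, F, p
    tukey: pd.DataFrame | None  # pair, difference (transformed scale), p_adj

    def __post_init__(self) -> None:
        p = self.proportions["proportion"].to_numpy()
        if np.any(p < 0) or np.any(p > 1):
            raise ValidationError("proportions must lie in [0, 1]")
        y = self.proportions["arcsine"].to_numpy()
        if np.any(y < -1e-12) or np.any(y > np.pi / 2 + 1e-12):
            raise ValidationError("arcsine values must lie in [0, pi/2]")


@dataclass
class DdCtResult:
    """2^-ddCt relative expression ratios against a calibrator group."""

    per_sample: pd.DataFrame    # sample, group, delta_ct, ddct, ratio
    group_summary: pd.DataFrame # group, mean_ratio, sem_ratio, n
    calibrator: str
    target: str
    reference: str

    def __post_init__(self) -> None:
        if (self.per_sample["ratio"] <= 0).any():
            raise ValidationError("expression ratios must be positive")


# ---------------------------------------------------------------------------
# proportions and the arcsine transform
# ---------------------------------------------------------------------------

def arcsine_transform(p):
    """Variance-stabilizing ``arcsin(sqrt(p))`` in radians, for p in [0, 1]."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def dormancy_proportions(table: DormancyTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate arrest proportions plus group mean +/- SEM.

    Returns ``(replicates, group_summary)``; the replicate frame carries both
    the raw proportion and its arcsine transform, the summary stays on the
    proportion scale (what figures display).
    """
    df = table.rows.copy()
    df["proportion"] = df["n_arrested"] / df["n_dissected"]
    df["arcsine"] = arcsine_transform(df["proportion"].to_numpy())
    group_cols = ["genotype"] + (["photoperiod"] if table.has_photoperiod else [])
    summary = (
        df.groupby(group_cols, sort=True)["proportion"]
        .agg(mean_proportion="mean",
             sem_proportion=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
             n_replicates="count")
        .reset_index()
    )
    return df, summary


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _anova_table_from_lm(model_fit, order: Sequence[str], typ: int = 2) -> pd.DataFrame:
    table = sm.stats.anova_lm(model_fit, typ=typ)
    table = table.rename_axis("factor").reset_index()
    table = table.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p", "F": "F", "df": "df"})
    # stable factor order
    key = {name: i for i, name in enumerate(order)}
    table["__k"] = table["factor"].map(lambda f: key.get(f, len(key)))
    table = table.sort_values("__k").drop(columns="__k").reset_index(drop=True)
    return table[["factor", "df", "sum_sq", "F", "p"]]


def anova_oneway_tukey(
    groups: Mapping[str, Sequence[float]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA with post-hoc Tukey HSD on (transformed) values.

    Returns ``(anova_table, tukey_table)``.  Identical data in every group
    carries no information: F = 0, p = 1, all Tukey p = 1.
    """
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValidationError("one-way ANOVA needs at least 2 groups")
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 replicates")

    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if np.ptp(pooled) == 0:
        anova = pd.DataFrame({
            "factor": ["group", "Residual"],
            "df": [float(df_between), float(df_within)],
            "sum_sq": [0.0, 0.0],
            "F": [0.0, np.nan],
            "p": [1.0, np.nan],
        })
        tukey = pd.DataFrame([
            {"group_a": a, "group_b": b, "difference": 0.0, "p_adj": 1.0}
            for i, a in enumerate(names) for b in names[i + 1:]
        ])
        return anova, tukey

    f_stat, p = sps.f_oneway(*arrays)
    grand = pooled.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    anova = pd.DataFrame({
        "factor": ["group", "Residual"],
        "df": [float(df_between), float(df_within)],
        "sum_sq": [ss_between, ss_within],
        "F": [float(f_stat), np.nan],
        "p": [float(p), np.nan],
    })

    hsd = sps.tukey_hsd(*arrays)
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": a,
                "group_b": names[j],
                "difference": float(arrays[i].mean() - arrays[j].mean()),
                "p_adj": float(hsd.pvalue[i, j]),
            })
    return anova, pd.DataFrame(rows)


def anova_twofactor(
    data: pd.DataFrame,
    value: str = "arcsine",
    factor_a: str = "genotype",
    factor_b: str = "photoperiod",
) -> pd.DataFrame:
    """Two-factor ANOVA with interaction on a (near-)balanced factorial design.

    Requires >= 2 levels per factor and >= 2 replicates in every design cell;
    uses Type-II sums of squares, which coincide with Type-I on balanced
    designs and remain interpretable under mild imbalance.
    """
    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise FormatError(f"two-factor ANOVA input is missing column {col!r}")
    if data[factor_a].nunique() < 2 or data[factor_b].nunique() < 2:
        raise ValidationError("both factors need at least 2 levels")
    cells = data.groupby([factor_a, factor_b], observed=True).size()
    expected = data[factor_a].nunique() * data[factor_b].nunique()
    if len(cells) < expected:
        raise ValidationError("factorial design has empty cells; a full design is required")
    if (cells < 2).any():
        raise ValidationError("every design cell needs at least 2 replicates")

    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    if np.ptp(df["_y"].to_numpy(dtype=float)) == 0:
        # no variation at all: all effects are exactly zero
        n = len(df)
        a_levels, b_levels = df["_a"].nunique(), df["_b"].nunique()
        dfs = [a_levels - 1, b_levels - 1, (a_levels - 1) * (b_levels - 1)]
        resid = n - 1 - sum(dfs)
        return pd.DataFrame({
            "factor": [factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"],
            "df": [float(d) for d in dfs] + [float(resid)],
            "sum_sq": [0.0] * 4,
            "F": [0.0, 0.0, 0.0, np.nan],
            "p": [1.0, 1.0, 1.0, np.nan],
        })
    fit = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    table = _anova_table_from_lm(
        fit, order=["C(_a)", "C(_b)", "C(_a):C(_b)", "Residual"], typ=2
    )
    table["factor"] = table["factor"].map({
        "C(_a)": factor_a,
        "C(_b)": factor_b,
        "C(_a):C(_b)": f"{factor_a}:{factor_b}",
        "Residual": "Residual",
    })
    return table


def analyze_dormancy(table: DormancyTable, two_factor: bool | None = None) -> DormancyAnalysis:
    """Full dormancy analysis: proportions -> arcsine -> ANOVA (+ Tukey).

    ``two_factor`` defaults to automatic: a genotype x photoperiod ANOVA when
    the table carries a photoperiod column, one-way across genotypes
    otherwise.  Tukey HSD is reported for the one-way path.
    """
    if two_factor is None:
        two_factor = table.has_photoperiod
    replicates, summary = dormancy_proportions(table)
    if two_factor:
        if not table.has_photoperiod:
            raise ValidationError("two-factor analysis requires a photoperiod column")
        anova = anova_twofactor(replicates, value="arcsine")
        tukey = None
    else:
        groups = {
            str(g): grp["arcsine"].to_numpy()
            for g, grp in replicates.groupby("genotype", sort=True)
        }
        anova, tukey = anova_oneway_tukey(groups)
    return DormancyAnalysis(
        proportions=replicates, group_summary=summary, anova=anova, tukey=tukey
    )


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def ddct_ratios(
    ct_table: pd.DataFrame,
    calibrator: str,
    target: str,
    reference: str = "rp49",
) -> DdCtResult:
    """Relative expression via the 2^-ddCt method.

    ``ct_table`` is tidy with columns ``sample, group, gene, ct``.  Per
    sample: dCt = Ct(target) - Ct(reference); ddCt = dCt - mean dCt of the
    calibrator group; ratio = 2^-ddCt.  The calibrator group has geometric
    mean ratio 1 by construction.
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise FormatError(f"Ct table is missing column(s): {', '.join(sorted(missing))}")
    wide = ct_table.pivot_table(index=["sample", "group"], columns="gene",
                                values="ct", aggfunc="mean")
    for gene in (target, reference):
        if gene not in wide.columns:
            raise FormatError(f"Ct table has no rows for gene {gene!r}")
    if wide[reference].isna().any():
        bad = wide.index[wide[reference].isna()].get_level_values("sample").tolist()
        raise ValidationError(f"missing reference Ct for sample(s): {bad}")
    if wide[target].isna().any():
        bad = wide.index[wide[target].isna()].get_level_values("sample").tolist()
        raise ValidationError(f"missing target Ct for sample(s): {bad}")

    per_sample = wide.reset_index()[["sample", "group"]].copy()
    per_sample["delta_ct"] = (wide[target] - wide[reference]).to_numpy()
    cal_mask = per_sample["group"].astype(str) == str(calibrator)
    if not cal_mask.any():
        raise ValidationError(f"calibrator group {calibrator!r} not present in Ct table")
    cal_mean = float(per_sample.loc[cal_mask, "delta_ct"].mean())
    per_sample["ddct"] = per_sample["delta_ct"] - cal_mean
    per_sample["ratio"] = np.power(2.0, -per_sample["ddct"])
    summary = (
        per_sample.groupby("group", sort=True)["ratio"]
        .agg(mean_ratio="mean",
             sem_ratio=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    return DdCtResult(per_sample=per_sample, group_summary=summary,
                      calibrator=str(calibrator), target=target, reference=reference)
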