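"""Group comparison of per-neuron response scores.

The imaging analysis follows the field's standard decision rule: when every
group passes Shapiro-Wilk normality (p > 0.05) a parametric path (one-way
ANOVA + Tukey HSD) is available, otherwise scores are compared with a
Kruskal-Wallis omnibus test followed by Bonferroni-corrected two-sided
Wilcoxon rank-sum pairwise comparisons.  Rank-sum p-values are exact
(enumeration) when both groups have n <= 8 and no ties, and use the
tie-corrected normal approximation otherwise; the method actually used is
always recorded in the result.

``synergy_excess`` formalizes the co-application question — is the response
to two peptides applied together larger than the sum of the single-peptide
responses? — as a percentile bootstrap on

    excess = central(combined) - [central(A) + central(B)]

with a one-sided bootstrap p-value for excess > 0.  The central tendency is
the median by default (matching the nonparametric treatment of the scores); a
mean-based variant is available via ``statistic="mean"``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

ALPHA_TIERS = (0.05, 0.01, 0.001)


def significance_tier(p: float, tiers: Sequence[float] = ALPHA_TIERS) -> str:
    """Map an (adjusted) p-value to the conventional star notation."""
    tiers = sorted(tiers, reverse=True)  # e.g. 0.05, 0.01, 0.001
    stars = 0
    for alpha in tiers:
        if p < alpha:
            stars += 1
    return "*" * stars if stars else "n.s."


@dataclass
class ComparisonResult:
    """Omnibus statistic plus the Bonferroni-adjusted pairwise table."""

    method: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, stat, p_raw, p_adj, significance, method

    def __post_init__(self) -> None:
        if len(self.pairwise):
            if (self.pairwise["p_adj"] + 1e-15 < self.pairwise["p_raw"]).any():
                raise ValidationError("adjusted p must be >= raw p")
            if (self.pairwise["p_adj"] > 1).any():
                raise ValidationError("adjusted p must be <= 1")


@dataclass
class SynergyResult:
    """Bootstrap estimate of the co-application excess over additivity."""

    excess: float
    ci_low: float
    ci_high: float
    p_value: float
    n_combined: int
    n_a: int
    n_b: int
    n_boot: int
    seed: int
    statistic: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.excess):
            raise ValidationError("synergy excess is not finite")
        if not (self.ci_low - 1e-12 <= self.excess <= self.ci_high + 1e-12):
            raise ValidationError("bootstrap CI does not contain the point estimate")


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValidationError(f"group {name!r} must be a 1-D score vector")
        out[str(name)] = arr
    return out


# ---------------------------------------------------------------------------
# test-path selection
# ---------------------------------------------------------------------------

def select_test_path(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> str:
    """Return ``"parametric"`` iff every group passes Shapiro-Wilk (p > alpha).

    Groups with fewer than 3 observations make normality untestable and raise.
    Constant groups are treated as non-normal.
    """
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups to select a test path")
    for name, values in groups.items():
        if len(values) < 3:
            raise ValidationError(
                f"group {name!r} has n={len(values)} < 3; normality untestable"
            )
        if np.ptp(values) == 0:
            return "nonparametric"
        if sps.shapiro(values).pvalue <= alpha:
            return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# rank-based tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df.

    All-identical observations carry no rank information: (H, p) = (0, 1).
    """
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups for Kruskal-Wallis")
    arrays = list(groups.values())
    total_n = sum(len(a) for a in arrays)
    if total_n < 5:
        raise ValidationError("Kruskal-Wallis needs a total sample size of at least 5")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 8
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U statistic of the first group, p, method)`` where method is
    ``"exact"`` (full enumeration; used when both n <= ``exact_max_n`` and
    there are no ties) or ``"normal_approx"`` (tie-corrected, with continuity
    correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs n >= 3 for the rank-sum test")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # no rank information at all
        return float(len(a) * len(b) / 2.0), 1.0, "degenerate"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(a) <= exact_max_n and len(b) <= exact_max_n:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "exact"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "normal_approx"


def bonferroni(p_values: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` with m the family size."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if family_size is None else int(family_size)
    if m < 1:
        raise ValidationError("Bonferroni family must contain at least one comparison")
    return np.minimum(1.0, p * m)


def pairwise_wilcoxon_bonferroni(
    groups: Mapping[str, Sequence[float]],
    family: Sequence[tuple[str, str]] | None = None,
    alpha_tiers: Sequence[float] = ALPHA_TIERS,
) -> ComparisonResult:
    """Kruskal-Wallis omnibus + Bonferroni-corrected rank-sum pairwise table.

    ``family`` lists the unordered treatment pairs making up the comparison
    family (default: all pairs); the Bonferroni multiplier is the family size.
    """
    groups = _as_groups(groups)
    if family is None:
        family = list(combinations(sorted(groups), 2))
    family = [tuple(pair) for pair in family]
    if not family:
        raise ValidationError("comparison family is empty")
    for pair in family:
        for name in pair:
            if name not in groups:
                raise ValidationError(f"family references unknown group {name!r}")

    h, p_omnibus = kruskal_wallis(groups)
    rows = []
    for g_a, g_b in family:
        stat, p_raw, method = rank_sum_test(groups[g_a], groups[g_b])
        rows.append({"group_a": g_a, "group_b": g_b, "stat": stat,
                     "p_raw": p_raw, "method": method})
    table = pd.DataFrame(rows)
    table["p_adj"] = bonferroni(table["p_raw"].to_numpy(), family_size=len(family))
    table["significance"] = [significance_tier(p, alpha_tiers) for p in table["p_adj"]]
    table = table[["group_a", "group_b", "stat", "p_raw", "p_adj", "significance", "method"]]
    return ComparisonResult(
        method="kruskal_wallis + bonferroni_wilcoxon",
        omnibus_stat=h,
        omnibus_p=p_omnibus,
        pairwise=table,
    )


# ---------------------------------------------------------------------------
# synergy bootstrap
# ---------------------------------------------------------------------------

def _group_rng(seed: int, values: np.ndarray) -> np.random.Generator:
    # substream keyed by the group's own (sorted) content so that the result
    # is exactly invariant under relabeling of the two single-peptide groups
    digest = zlib.crc32(np.sort(values).tobytes()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), digest]))


def synergy_excess(
    combined: Sequence[float],
    single_a: Sequence[float],
    single_b: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    statistic: str = "median",
    ci_level: float = 0.95,
) -> SynergyResult:
    """Bootstrap test of super-additivity of a peptide co-application.

    excess = central(combined) - [central(A) + central(B)]; each group is
    resampled independently ``n_boot`` times; the CI is the percentile
    interval and the p-value is one-sided for excess > 0 (fraction of
    bootstrap excesses <= 0, with the +1 small-sample correction).
    """
    if statistic not in ("median", "mean"):
        raise ValidationError("statistic must be 'median' or 'mean'")
    if n_boot < 1000:
        raise ValidationError("n_boot < 1000 gives unstable bootstrap estimates")
    central = np.median if statistic == "median" else np.mean
    arrays = [np.asarray(g, dtype=float) for g in (combined, single_a, single_b)]
    for arr in arrays:
        if len(arr) < 3:
            raise ValidationError("each group needs n >= 3 for the synergy bootstrap")
    # grouped as c - (a + b): addition commutes, so relabeling A<->B is exact
    point = float(central(arrays[0]) - (central(arrays[1]) + central(arrays[2])))

    boot_centrals = []
    for arr in arrays:
        rng = _group_rng(seed, arr)
        idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
        boot_centrals.append(central(arr[idx], axis=1))
    boot_excess = boot_centrals[0] - (boot_centrals[1] + boot_centrals[2])

    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(boot_excess, [alpha / 2, 1 - alpha / 2])
    # include the point estimate in the percentile interval by construction
    ci_low = min(float(ci_low), point)
    ci_high = max(float(ci_high), point)
    p_value = (1 + int(np.sum(boot_excess <= 0))) / (n_boot + 1)
    return SynergyResult(
        excess=point, ci_low=ci_low, ci_high=ci_high, p_value=float(p_value),
        n_combined=len(arrays[0]), n_a=len(arrays[1]), n_b=len(arrays[2]),
        n_boot=n_boot, seed=int(seed), statistic=statistic,
    )
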