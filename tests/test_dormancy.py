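"""Dormancy proportions, arcsine ANOVA, Tukey HSD and ddCt ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ipcquant import (
    DormancyTable,
    ValidationError,
    analyze_dormancy,
    anova_oneway_tukey,
    anova_twofactor,
    arcsine_transform,
    ddct_ratios,
    dormancy_proportions,
    simulate_dormancy_counts,
)
from ipcquant.errors import FormatError


def _table(rows):
    return DormancyTable(rows=pd.DataFrame(rows))


class TestProportions:
    def test_basic_and_bounds(self):
        table = _table([
            {"genotype": "A", "replicate": "v1", "n_dissected": 60, "n_arrested": 30},
            {"genotype": "A", "replicate": "v2", "n_dissected": 60, "n_arrested": 0},
            {"genotype": "A", "replicate": "v3", "n_dissected": 60, "n_arrested": 60},
        ])
        reps, _ = dormancy_proportions(table)
        np.testing.assert_allclose(reps["proportion"], [0.5, 0.0, 1.0])

    def test_group_mean_and_sem(self):
        table = _table([
            {"genotype": "A", "replicate": f"v{i}", "n_dissected": 10, "n_arrested": n}
            for i, n in enumerate([4, 5, 6])
        ])
        _, summary = dormancy_proportions(table)
        assert summary["mean_proportion"].iloc[0] == pytest.approx(0.5)
        assert summary["sem_proportion"].iloc[0] == pytest.approx(0.1 / np.sqrt(3))


class TestArcsine:
    def test_bounds_and_midpoint(self):
        assert arcsine_transform(0.0) == 0.0
        assert arcsine_transform(1.0) == pytest.approx(np.pi / 2)
        assert arcsine_transform(0.5) == pytest.approx(np.pi / 4)

    @settings(derandomize=True, max_examples=50)
    @given(p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0))
    def test_monotone(self, p1, p2):
        if p1 < p2:
            assert arcsine_transform(p1) < arcsine_transform(p2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            arcsine_transform(1.5)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        anova, tukey = anova_oneway_tukey({"a": [0.3] * 4, "b": [0.3] * 4})
        assert anova.loc[0, "F"] == 0.0 and anova.loc[0, "p"] == 1.0
        assert (tukey["p_adj"] == 1.0).all()

    def test_t_squared_equals_f_on_balanced_two_groups(self, rng):
        a = rng.normal(0.5, 0.1, 8)
        b = rng.normal(0.7, 0.1, 8)
        anova, _ = anova_oneway_tukey({"a": a, "b": b})
        t = sps.ttest_ind(a, b).statistic
        assert anova.loc[0, "F"] == pytest.approx(t**2, rel=1e-10)

    def test_tukey_not_less_conservative_than_unadjusted_t(self, rng):
        groups = {k: rng.normal(loc, 0.1, 6)
                  for k, loc in [("a", 0.4), ("b", 0.5), ("c", 0.65)]}
        _, tukey = anova_oneway_tukey(groups)
        for _, row in tukey.iterrows():
            p_t = sps.ttest_ind(groups[row["group_a"]], groups[row["group_b"]]).pvalue
            assert row["p_adj"] >= p_t - 1e-12

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            anova_oneway_tukey({"a": [0.1], "b": [0.2, 0.3]})

    def test_anova_df_sum_to_n_minus_one(self, rng):
        groups = {k: rng.normal(size=n) for k, n in [("a", 4), ("b", 6), ("c", 5)]}
        anova, _ = anova_oneway_tukey(groups)
        assert anova["df"].sum() == 15 - 1


class TestTwoFactorAnova:
    @staticmethod
    def _frame(effect_a=0.0, effect_b=0.0, interaction=0.0, noise=0.0, n=5, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, a in enumerate(["g1", "g2"]):
            for j, b in enumerate(["short", "long"]):
                mu = 0.5 + effect_a * i + effect_b * j + interaction * i * j
                for _ in range(n):
                    rows.append({"genotype": a, "photoperiod": b,
                                 "arcsine": mu + rng.normal(0, noise) if noise else mu})
        return pd.DataFrame(rows)

    def test_pure_additive_zero_noise_has_no_interaction_ss(self):
        table = anova_twofactor(self._frame(effect_a=0.2, effect_b=0.3))
        inter = table[table["factor"] == "genotype:photoperiod"].iloc[0]
        total_ss = table["sum_sq"].sum()
        assert inter["sum_sq"] <= 1e-12 * total_ss

    def test_constant_data_all_f_zero(self):
        table = anova_twofactor(self._frame())
        assert (table["F"].iloc[:3] == 0.0).all()
        assert (table["p"].iloc[:3] == 1.0).all()

    def test_df_sum_to_n_minus_one(self):
        table = anova_twofactor(self._frame(0.1, 0.2, 0.05, noise=0.05, n=4))
        assert table["df"].sum() == pytest.approx(16 - 1)

    def test_ss_decomposition_on_balanced_design(self):
        df = self._frame(0.1, 0.2, 0.05, noise=0.08, n=6, seed=3)
        table = anova_twofactor(df)
        total = ((df["arcsine"] - df["arcsine"].mean()) ** 2).sum()
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_empty_cell_rejected(self):
        df = self._frame(noise=0.1)
        df = df[~((df["genotype"] == "g2") & (df["photoperiod"] == "long"))]
        with pytest.raises(ValidationError, match="empty cells"):
            anova_twofactor(df)

    def test_genotype_effect_power(self):
        """A 0.3 rad genotype shift with sd 0.1 and 5 replicates/cell is
        detected at alpha = 0.05 in > 90% of simulations."""
        rng = np.random.default_rng(11)
        detected = 0
        n_sim = 200
        for _ in range(n_sim):
            df = self._frame(effect_a=0.3, effect_b=0.1, noise=0.1, n=5,
                             seed=int(rng.integers(2**31)))
            table = anova_twofactor(df)
            p = table.loc[table["factor"] == "genotype", "p"].iloc[0]
            detected += p < 0.05
        assert detected / n_sim > 0.90


class TestAnalyzeDormancy:
    def test_one_way_path(self):
        table = simulate_dormancy_counts({"wt": 0.3, "mut": 0.7},
                                         n_replicates=5, n_per_replicate=60, seed=5)
        analysis = analyze_dormancy(table)
        assert analysis.tukey is not None
        assert analysis.anova.loc[0, "p"] < 0.01
        assert analysis.proportions["arcsine"].between(0, np.pi / 2).all()

    def test_two_factor_auto_detection(self):
        table = simulate_dormancy_counts(
            {"wt": 0.3, "mut": 0.6},
            photoperiod_effects={"LD16:8": -0.8, "LD8:16": 0.8},
            n_replicates=4, n_per_replicate=60, seed=6,
        )
        analysis = analyze_dormancy(table)
        assert analysis.tukey is None
        factors = set(analysis.anova["factor"])
        assert {"genotype", "photoperiod", "genotype:photoperiod"} <= factors


class TestDdct:
    @staticmethod
    def _ct_table():
        # target Ct chosen so control ddCt = 0 and treated ddCt = +1 / -2
        rows = []
        for sample, group, tgt in [("s1", "ctrl", 25.0), ("s2", "ctrl", 25.0),
                                   ("s3", "low", 26.0), ("s4", "high", 23.0)]:
            rows.append({"sample": sample, "group": group, "gene": "snpfr", "ct": tgt})
            rows.append({"sample": sample, "group": group, "gene": "rp49", "ct": 20.0})
        return pd.DataFrame(rows)

    def test_closed_form_ratios(self):
        res = ddct_ratios(self._ct_table(), calibrator="ctrl", target="snpfr",
                          reference="rp49")
        ratios = res.per_sample.set_index("sample")["ratio"]
        assert ratios["s1"] == pytest.approx(1.0)       # ddCt = 0
        assert ratios["s3"] == pytest.approx(0.5)       # ddCt = +1
        assert ratios["s4"] == pytest.approx(4.0)       # ddCt = -2

    def test_calibrator_geometric_mean_is_one(self, rng):
        rows = []
        for i in range(6):
            rows.append({"sample": f"s{i}", "group": "ctrl", "gene": "snpfr",
                         "ct": 25.0 + rng.normal(0, 0.5)})
            rows.append({"sample": f"s{i}", "group": "ctrl", "gene": "rp49",
                         "ct": 20.0 + rng.normal(0, 0.5)})
        res = ddct_ratios(pd.DataFrame(rows), calibrator="ctrl", target="snpfr",
                          reference="rp49")
        geo = np.exp(np.mean(np.log(res.per_sample["ratio"])))
        assert geo == pytest.approx(1.0, abs=1e-12)

    def test_missing_reference_ct_rejected(self):
        table = self._ct_table()
        table = table[~((table["sample"] == "s3") & (table["gene"] == "rp49"))]
        with pytest.raises(ValidationError, match="reference"):
            ddct_ratios(table, calibrator="ctrl", target="snpfr", reference="rp49")

    def test_missing_columns_rejected(self):
        with pytest.raises(FormatError):
            ddct_ratios(pd.DataFrame({"sample": [], "ct": []}),
                        calibrator="c", target="t")
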