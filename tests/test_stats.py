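import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surrosel.pipeline import TARGET_ALL
from surrosel.stats import classify, tukey_hsd, two_way_anova


def long_table(cells: dict, target=TARGET_ALL) -> pd.DataFrame:
    rows = []
    for (region, group), vals in cells.items():
        for run, v in enumerate(vals, 1):
            rows.append((region, group, run, target, float(v)))
    return pd.DataFrame(
        rows, columns=["region", "group", "run", "target", "representation_pct"]
    )


FIXTURE = {
    ("A", "g1"): [10, 12, 11, 9, 13],
    ("A", "g2"): [20, 19, 21, 22, 18],
    ("B", "g1"): [15, 14, 16, 15, 15],
    ("B", "g2"): [25, 27, 26, 24, 28],
}


class TestTwoWayAnova:
    def test_unbalanced_table_rejected_naming_cell(self):
        cells = dict(FIXTURE)
        cells[("B", "g2")] = cells[("B", "g2")][:-1]
        with pytest.raises(ValueError, match="g2"):
            two_way_anova(long_table(cells))

    def test_zero_variance_flagged(self):
        cells = {k: [7.0] * 5 for k in FIXTURE}
        res = two_way_anova(long_table(cells))
        assert res.zero_variance
        assert np.isnan(res.model_f)

    def test_cell_stats_match_direct_computation(self):
        res = two_way_anova(long_table(FIXTURE))
        stats = res.cell_stats.set_index(["region", "group"])
        for key, vals in FIXTURE.items():
            assert stats.loc[key, "mean"] == pytest.approx(np.mean(vals))
            assert stats.loc[key, "sd"] == pytest.approx(np.std(vals, ddof=1))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_ss_decomposition_identity_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, n = rng.integers(2, 4), rng.integers(2, 5), rng.integers(2, 7)
        cells = {
            (f"r{i}", f"g{j}"): rng.normal(50, 10, size=n)
            for i in range(a)
            for j in range(b)
        }
        res = two_way_anova(long_table(cells))
        y = np.concatenate(list(cells.values()))
        ss_total = ((y - y.mean()) ** 2).sum()
        assert res.factors["ss"].sum() == pytest.approx(ss_total, rel=1e-9)


class TestTukey:
    def test_identical_means_give_zero_q(self):
        cells = {
            ("A", "g1"): [5, 6, 7, 8],
            ("A", "g2"): [5, 6, 7, 8],
            ("B", "g1"): [9, 10, 11, 12],
            ("B", "g2"): [9, 10, 11, 12],
        }
        res = tukey_hsd(two_way_anova(long_table(cells)))
        comp = res.lookup(("A", "g1"), ("A", "g2"))
        assert comp["q"] == 0.0 and not comp["significant"]

    def test_q_formula_on_known_quantities(self):
        anova = two_way_anova(long_table(FIXTURE))
        res = tukey_hsd(anova)
        comp = res.lookup(("A", "g1"), ("A", "g2"))
        # q = |11 - 20| / sqrt(MS_resid / 5) with MS_resid = 2
        assert comp["q"] == pytest.approx(9 / np.sqrt(2 / 5))

    def test_p_decreases_with_mean_difference(self):
        base = {
            ("A", "g1"): [10.0, 11, 9, 10],
            ("B", "g1"): [10.0, 9, 11, 10],
            ("B", "g2"): [10.0, 11, 9, 10],
        }
        ps = []
        for shift in (1.0, 3.0, 6.0):
            cells = dict(base)
            cells[("A", "g2")] = [v + shift for v in [10.0, 11, 9, 10]]
            res = tukey_hsd(two_way_anova(long_table(cells)))
            ps.append(res.lookup(("A", "g1"), ("A", "g2"))["p"])
        assert ps[0] > ps[1] > ps[2]

    def test_matches_statsmodels_tukeyhsd_on_cell_layout(self):
        # independent route: statsmodels' Tukey HSD over the same cells
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        table = long_table(FIXTURE)
        anova = two_way_anova(table)
        mine = tukey_hsd(anova, alpha=0.01)
        labels = table["region"] + ":" + table["group"]
        sm = pairwise_tukeyhsd(table["representation_pct"], labels, alpha=0.01)
        pairs = [(str(r[0]), str(r[1])) for r in sm.summary().data[1:]]
        sm_p = {frozenset(pair): p for pair, p in zip(pairs, sm.pvalues)}
        for _, row in mine.table.iterrows():
            key = frozenset(
                (f"{row.region_i}:{row.group_i}", f"{row.region_j}:{row.group_j}")
            )
            assert row["p"] == pytest.approx(sm_p[key], abs=5e-3)


class TestClassify:
    def _table(self, g_a=70, g_b=70, null_a=60, null_b=60, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        cells = {
            ("A", "g"): g_a + rng.normal(0, noise, 8),
            ("B", "g"): g_b + rng.normal(0, noise, 8),
            ("A", "null"): null_a + rng.normal(0, noise, 8),
            ("B", "null"): null_b + rng.normal(0, noise, 8),
            ("A", "ideal"): 90 + rng.normal(0, noise, 8),
            ("B", "ideal"): 90 + rng.normal(0, noise, 8),
        }
        return long_table(cells)

    def test_group_above_null_and_significant_is_effective(self):
        t = self._table()
        cls = classify(t, tukey_hsd(two_way_anova(t)))
        eff = cls.effectiveness.set_index(["region", "group"])["effective"]
        assert eff[("A", "g")] and eff[("B", "g")]

    def test_group_below_null_never_effective(self):
        t = self._table(g_a=40, g_b=40)
        cls = classify(t, tukey_hsd(two_way_anova(t)))
        assert not cls.effectiveness["effective"].any()

    def test_equal_performance_across_regions_is_consistent(self):
        t = self._table(g_a=70, g_b=70)
        cls = classify(t, tukey_hsd(two_way_anova(t)))
        assert cls.consistency.set_index("group").loc["g", "consistent"]

    def test_divergent_regions_inconsistent(self):
        t = self._table(g_a=80, g_b=55)
        cls = classify(t, tukey_hsd(two_way_anova(t)))
        assert not cls.consistency.set_index("group").loc["g", "consistent"]

    def test_missing_null_cell_rejected(self):
        cells = {
            ("A", "g"): [1.0, 2, 3],
            ("B", "g"): [1.0, 2, 3],
            ("A", "ideal"): [4.0, 5, 6],
            ("B", "ideal"): [4.0, 5, 6],
        }
        t = long_table(cells)
        with pytest.raises(ValueError, match="null"):
            classify(t, tukey_hsd(two_way_anova(t)))

    def test_invariant_to_record_order(self):
        t = self._table()
        tk = tukey_hsd(two_way_anova(t))
        shuffled = t.sample(frac=1.0, random_state=7).reset_index(drop=True)
        c1 = classify(t, tk)
        c2 = classify(shuffled, tk)
        pd.testing.assert_frame_equal(c1.effectiveness, c2.effectiveness)
        pd.testing.assert_frame_equal(c1.consistency, c2.consistency)
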