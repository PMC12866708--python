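"""Group statistics: ANOVA partitions, Holm-Sidak, ddCT, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiofunc import stats


def make_2x2(cells: dict) -> pd.DataFrame:
    rows = []
    for (a, b), vals in cells.items():
        for i, v in enumerate(vals):
            rows.append(dict(unit_id=f"{a}{b}{i}", factor_a=a, factor_b=b,
                             measurement="m", value=float(v)))
    return pd.DataFrame(rows)


FIXTURE = make_2x2({
    ("A1", "B1"): [1, 2], ("A1", "B2"): [1, 2],
    ("A2", "B1"): [3, 4], ("A2", "B2"): [3, 4],
})


class TestTwoWayAnova:
    def test_hand_computed_partition(self):
        res = stats.two_way_anova(FIXTURE)
        t = res.table
        assert t.loc["factor_a", "sum_sq"] == pytest.approx(8.0, abs=1e-9)
        assert t.loc["factor_b", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert t.loc["factor_a:factor_b", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert t.loc["Residual", "sum_sq"] == pytest.approx(2.0, abs=1e-9)
        assert t.loc["factor_a", "F"] == pytest.approx(16.0, abs=1e-9)

    def test_degenerate_constant_table(self):
        df = FIXTURE.copy()
        df["value"] = 5.0
        res = stats.two_way_anova(df)
        assert math.isnan(res.table.loc["factor_a", "F"])
        assert res.table.loc["factor_a", "p"] == 1.0
        assert (res.comparisons["p_raw"] == 1.0).all()

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        df = make_2x2({
            ("A1", "B1"): rng.normal(size=5), ("A1", "B2"): rng.normal(size=5),
            ("A2", "B1"): rng.normal(size=5), ("A2", "B2"): rng.normal(size=5),
        })
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1, r2 = stats.two_way_anova(df), stats.two_way_anova(shuffled)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        pd.testing.assert_frame_equal(r1.comparisons, r2.comparisons)

    def test_balanced_partition_identity_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            df = make_2x2({
                (a, b): rng.normal(size=6)
                for a in ("A1", "A2") for b in ("B1", "B2")
            })
            t = stats.two_way_anova(df).table
            total = float(((df["value"] - df["value"].mean()) ** 2).sum())
            assert t["sum_sq"].sum() == pytest.approx(total, rel=1e-8)

    def test_balanced_matches_statsmodels_type2(self):
        # classical partition (ours) vs statsmodels Type-II OLS route
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(11)
        df = make_2x2({
            (a, b): rng.normal(loc=hash((a, b)) % 3, size=8)
            for a in ("A1", "A2") for b in ("B1", "B2")
        })
        ours = stats.two_way_anova(df).table
        sm_tab = anova_lm(
            smf.ols("value ~ C(factor_a) * C(factor_b)", data=df).fit(), typ=2
        )
        assert ours.loc["factor_a", "F"] == pytest.approx(
            float(sm_tab.loc["C(factor_a)", "F"]), rel=1e-9)
        assert ours.loc["factor_a:factor_b", "p"] == pytest.approx(
            float(sm_tab.loc["C(factor_a):C(factor_b)", "PR(>F)"]), rel=1e-9)

    def test_unbalanced_uses_type2(self):
        rng = np.random.default_rng(5)
        df = make_2x2({
            ("A1", "B1"): rng.normal(size=18), ("A1", "B2"): rng.normal(size=13),
            ("A2", "B1"): rng.normal(size=24), ("A2", "B2"): rng.normal(size=10),
        })
        res = stats.two_way_anova(df)
        assert res.ss_type == "type-II"
        assert not res.balanced
        assert np.isfinite(res.table.loc["factor_a", "F"])

    def test_missing_cell_named(self):
        df = FIXTURE[~((FIXTURE.factor_a == "A2") & (FIXTURE.factor_b == "B2"))]
        with pytest.raises(ValueError, match="A2"):
            stats.two_way_anova(df)


class TestHolmSidak:
    def test_worked_example(self):
        adj, rej = stats.holm_sidak([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.029701, 0.059095, 0.059095], atol=5e-5)
        assert list(rej) == [True, False, False]

    def test_single_p_unchanged(self):
        adj, _ = stats.holm_sidak([0.2])
        assert adj[0] == pytest.approx(0.2, abs=1e-12)

    def test_all_zero(self):
        adj, rej = stats.holm_sidak([0.0, 0.0, 0.0])
        np.testing.assert_array_equal(adj, 0.0)
        assert rej.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.holm_sidak([0.1, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_properties_and_statsmodels_agreement(self, pvals):
        adj, _ = stats.holm_sidak(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # never exceeds Bonferroni
        assert np.all(adj <= np.minimum(p * len(p), 1.0) + 1e-9)
        # sorted monotonicity
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # independent library route
        from statsmodels.stats.multitest import multipletests

        _, adj_sm, _, _ = multipletests(p, method="holm-sidak")
        np.testing.assert_allclose(adj, adj_sm, atol=1e-10)


class TestOneWayAndTTest:
    def test_identical_groups(self):
        res = stats.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_example(self):
        res = stats.t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.674234614, abs=1e-6)
        assert res.p == pytest.approx(0.021311641, abs=1e-6)
        assert res.df == 4

    def test_one_way_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(loc=0.5, size=10)
        rows = [dict(unit_id=i, factor_a="g1", measurement="m", value=v)
                for i, v in enumerate(x)]
        rows += [dict(unit_id=20 + i, factor_a="g2", measurement="m", value=v)
                 for i, v in enumerate(y)]
        res = stats.one_way_anova(pd.DataFrame(rows))
        t = stats.t_test(x, y)
        assert res.table.loc["factor_a", "F"] == pytest.approx(t.t**2, rel=1e-9)
        assert res.table.loc["factor_a", "p"] == pytest.approx(t.p, rel=1e-9)


class TestSummarize:
    def test_mean_sem_n(self):
        df = pd.DataFrame([
            dict(factor_a="g", measurement="m", value=2.0),
            dict(factor_a="g", measurement="m", value=4.0),
        ])
        out = stats.summarize(df)
        assert out.loc[0, "mean"] == 3.0
        assert out.loc[0, "sem"] == pytest.approx(1.0)
        assert out.loc[0, "n"] == 2

    def test_single_value_sem_missing(self):
        df = pd.DataFrame([dict(factor_a="g", measurement="m", value=2.0)])
        out = stats.summarize(df)
        assert math.isnan(out.loc[0, "sem"])


class TestDdct:
    TABLE = pd.DataFrame([
        dict(sample="s1", group="treated", gene="T", ct=20.0),
        dict(sample="s1", group="treated", gene="R", ct=15.0),
        dict(sample="s2", group="cal", gene="T", ct=22.0),
        dict(sample="s2", group="cal", gene="R", ct=15.0),
    ])

    def test_fold_four(self):
        res = stats.ddct(self.TABLE, "T", "R", "cal")
        treated = res.samples.set_index("sample").loc["s1"]
        assert treated["fold"] == pytest.approx(4.0)

    def test_calibrator_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            rows.append(dict(sample=f"c{i}", group="cal", gene="T",
                             ct=22 + rng.normal(0, 0.5)))
            rows.append(dict(sample=f"c{i}", group="cal", gene="R", ct=15.0))
        res = stats.ddct(pd.DataFrame(rows), "T", "R", "cal")
        gm = float(np.exp(np.mean(np.log(res.samples["fold"]))))
        assert gm == pytest.approx(1.0, rel=1e-9)

    def test_constant_ct_shift_invariant(self):
        shifted = self.TABLE.copy()
        shifted.loc[shifted["sample"] == "s1", "ct"] += 3.0
        r0 = stats.ddct(self.TABLE, "T", "R", "cal")
        r1 = stats.ddct(shifted, "T", "R", "cal")
        pd.testing.assert_frame_equal(r0.samples, r1.samples)

    def test_replicates_averaged(self):
        reps = pd.concat([self.TABLE, self.TABLE], ignore_index=True)
        res = stats.ddct(reps, "T", "R", "cal")
        assert len(res.samples) == 2

    def test_missing_gene_rejected(self):
        broken = self.TABLE[~((self.TABLE["sample"] == "s1")
                              & (self.TABLE["gene"] == "R"))]
        with pytest.raises(ValueError, match="missing CT"):
            stats.ddct(broken, "T", "R", "cal")
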