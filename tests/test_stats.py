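import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliaquant.stats import lsd_posthoc, one_way_anova, two_way_mixed_anova


def mixed_table(values: np.ndarray, groups: list[str],
                markers: list[str]) -> pd.DataFrame:
    """Long-format table from a subjects x markers matrix."""
    rows = []
    for s, (g, row) in enumerate(zip(groups, values)):
        for m, v in zip(markers, row):
            rows.append({"subject": f"s{s}", "genotype": g, "marker": m,
                         "value": v})
    return pd.DataFrame(rows)


class TestOneWay:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.effect("group")["F"] == pytest.approx(0.0)

    def test_hand_computed_sums_of_squares(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        row = res.effect("group")
        assert row["ss"] == pytest.approx(13.5)
        assert row["ms_error"] * row["df_den"] == pytest.approx(4.0)
        assert (row["df_num"], row["df_den"]) == (1, 4)
        assert row["F"] == pytest.approx(13.5)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        f1 = one_way_anova([a, b]).effect("group")["F"]
        f2 = one_way_anova([a + 100, b + 100]).effect("group")["F"]
        assert f1 == pytest.approx(f2)

    def test_two_groups_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 11)
        row = one_way_anova([a, b]).effect("group")
        t, p = sps.ttest_ind(a, b)
        assert row["F"] == pytest.approx(t**2)
        assert row["p"] == pytest.approx(p)

    def test_agrees_with_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 9) for m in (0, 0.3, 1.0)]
        row = one_way_anova(groups).effect("group")
        f, p = sps.f_oneway(*groups)
        assert row["F"] == pytest.approx(f)
        assert row["p"] == pytest.approx(p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1], [2, 3]])


class TestTwoWayMixed:
    def test_all_equal_cells_f_zero(self):
        df = mixed_table(np.full((4, 3), 5.0), ["AD"] * 2 + ["NTG"] * 2,
                         ["NeuN", "CD68", "GFAP"])
        res = two_way_mixed_anova(df)
        for row in res.rows:
            assert row["F"] == pytest.approx(0.0)

    def test_matches_brute_force_ss_partition(self):
        # 2 genotypes x 2 markers x 2 subjects, hand-checkable numbers
        vals = np.array([[1.0, 2.0], [2.0, 4.0], [5.0, 5.0], [7.0, 6.0]])
        df = mixed_table(vals, ["AD", "AD", "NTG", "NTG"], ["m1", "m2"])
        res = two_way_mixed_anova(df)
        grand = vals.mean()
        ss_total = ((vals - grand) ** 2).sum()
        # brute-force partition
        subj = vals.mean(axis=1)
        ss_bs = 2 * ((subj - grand) ** 2).sum()
        ss_g = 4 * ((vals[:2].mean() - grand) ** 2 + (vals[2:].mean() - grand) ** 2)
        ss_sw = ss_bs - ss_g
        mk = vals.mean(axis=0)
        ss_m = 4 * ((mk - grand) ** 2).sum()
        cells = np.array([vals[:2].mean(axis=0), vals[2:].mean(axis=0)])
        gm = np.array([vals[:2].mean(), vals[2:].mean()])
        ss_i = 2 * ((cells - gm[:, None] - mk[None] + grand) ** 2).sum()
        ss_err = ss_total - ss_g - ss_sw - ss_m - ss_i
        g = res.effect("genotype")
        assert g["ss"] == pytest.approx(ss_g)
        assert g["ms_error"] * g["df_den"] == pytest.approx(ss_sw)
        m = res.effect("marker")
        assert m["ss"] == pytest.approx(ss_m)
        assert m["ms_error"] * m["df_den"] == pytest.approx(ss_err)
        assert res.effect("genotype*marker")["ss"] == pytest.approx(ss_i)

    def test_ss_conservation(self, rng):
        vals = rng.normal(0, 1, (10, 4))
        df = mixed_table(vals, ["AD"] * 6 + ["NTG"] * 4, list("abcd"))
        res = two_way_mixed_anova(df)
        g = res.effect("genotype")
        m = res.effect("marker")
        i = res.effect("genotype*marker")
        total = ((vals - vals.mean()) ** 2).sum()
        parts = (g["ss"] + g["ms_error"] * g["df_den"] + m["ss"] + i["ss"]
                 + m["ms_error"] * m["df_den"])
        assert parts == pytest.approx(total)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = rng.normal(0, 1, (9, 3)) + np.array([0.0, 0.5, 1.0])
        df = mixed_table(vals, ["AD"] * 5 + ["NTG"] * 4, list("xyz"))
        res = two_way_mixed_anova(df)
        pg = pingouin.mixed_anova(df, dv="value", within="marker",
                                  between="genotype", subject="subject")
        pg = pg.set_index("Source")
        assert res.effect("genotype")["F"] == pytest.approx(
            pg.loc["genotype", "F"], rel=1e-6)
        assert res.effect("marker")["F"] == pytest.approx(
            pg.loc["marker", "F"], rel=1e-6)
        assert res.effect("genotype*marker")["F"] == pytest.approx(
            pg.loc["Interaction", "F"], rel=1e-6)

    def test_pure_marker_effect(self, rng):
        base = rng.normal(0, 0.05, (8, 1))
        vals = base + np.array([0.0, 3.0, 6.0]) + rng.normal(0, 0.05, (8, 3))
        df = mixed_table(vals, ["AD"] * 4 + ["NTG"] * 4, list("abc"))
        res = two_way_mixed_anova(df)
        assert res.effect("genotype")["p"] > 0.05     # no genotype signal
        assert res.effect("marker")["F"] > 100.0

    def test_missing_within_level_rejected(self):
        df = mixed_table(np.ones((4, 2)), ["AD"] * 2 + ["NTG"] * 2, ["a", "b"])
        with pytest.raises(ValueError, match="within"):
            two_way_mixed_anova(df.iloc[:-1])


class TestLsdPosthoc:
    def _anova(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0, 10)]
        res = one_way_anova(groups)
        means = {f"g{i}": float(np.mean(g)) for i, g in enumerate(groups)}
        ns = {f"g{i}": len(g) for i, g in enumerate(groups)}
        return res, means, ns

    def test_identical_means_p_one(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        table = lsd_posthoc(res, {"a": 2.0, "b": 2.0}, {"a": 3, "b": 3})
        assert table.loc[0, "t"] == pytest.approx(0.0)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_separated_means_tiny_p(self, rng):
        res, means, ns = self._anova(rng)
        table = lsd_posthoc(res, means, ns).set_index(["a", "b"])
        assert table.loc[("g0", "g2"), "p"] < 1e-6

    def test_symmetric_in_pair_order(self, rng):
        res, means, ns = self._anova(rng)
        t1 = lsd_posthoc(res, means, ns)
        rev_means = dict(reversed(list(means.items())))
        t2 = lsd_posthoc(res, rev_means, ns)
        p1 = {frozenset((r.a, r.b)): r.p for r in t1.itertuples()}
        p2 = {frozenset((r.a, r.b)): r.p for r in t2.itertuples()}
        assert p1.keys() == p2.keys()
        for k in p1:
            assert p1[k] == pytest.approx(p2[k])
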