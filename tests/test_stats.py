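"""Routing, omnibus tests, Fisher LSD and annotation semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oxidiet.stats import (
    GroupComparison,
    check_assumptions,
    compare_variables,
    fisher_lsd,
    omnibus_test,
    render_group_table,
)


class TestRouting:
    def test_null_normal_routes_parametric_most_of_the_time(self, rng):
        # four α=0.05 assumption screens => parametric frequency ≈ 0.95^4
        routes = []
        for _ in range(300):
            data = {g: rng.normal(10, 2, 9) for g in ("STD", "HFHS", "HFHS+ω3")}
            routes.append(check_assumptions(data)[0])
        freq = np.mean([r == "parametric" for r in routes])
        assert 0.72 <= freq <= 0.92

    def test_variance_inflation_routes_nonparametric(self, rng):
        hits = 0
        for _ in range(100):
            data = {
                "a": rng.normal(10, 1, 9),
                "b": rng.normal(10, 1, 9),
                "c": rng.normal(10, 10, 9),
            }
            hits += check_assumptions(data)[0] == "nonparametric"
        assert hits >= 95

    def test_constant_group_routes_nonparametric_with_warning(self):
        route, warns = check_assumptions({"a": [1.0] * 5, "b": [1.0, 2.0, 3.0, 4.0, 5.0]})
        assert route == "nonparametric"
        assert any("constant" in w for w in warns)

    def test_tiny_group_untestable_normality(self):
        route, warns = check_assumptions({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})
        assert route == "nonparametric"
        assert any("untestable" in w for w in warns)


class TestOmnibus:
    def test_null_type_one_error_calibrated(self, rng):
        rejections = 0
        n_rep = 600
        for _ in range(n_rep):
            data = {g: rng.normal(0, 1, 9) for g in "abc"}
            _, p = omnibus_test(data, "parametric")
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_all_ties_kruskal_wallis_p_is_one(self):
        data = {"a": [5.0] * 9, "b": [5.0] * 9, "c": [5.0] * 9}
        stat, p = omnibus_test(data, "nonparametric")
        assert p == 1.0

    def test_two_group_anova_f_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(0.7, 1, 9)
        f_stat, f_p = omnibus_test({"a": a, "b": b}, "parametric")
        t = sps.ttest_ind(a, b, equal_var=True)
        assert f_stat == pytest.approx(t.statistic**2, rel=1e-10)
        assert f_p == pytest.approx(t.pvalue, rel=1e-10)

    def test_too_few_groups_is_error(self):
        with pytest.raises(ValueError):
            omnibus_test({"a": [1.0, 2.0], "b": [np.nan, np.nan, np.nan]}, "parametric")


class TestFisherLSD:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        # oracle equivalence on 100 random small instances
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            lsd_p = fisher_lsd({"a": a, "b": b}).p.iloc[0]
            t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
            assert abs(lsd_p - t_p) < 1e-10

    def test_identical_groups_direction_none_p_one(self):
        out = fisher_lsd({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert out.direction.iloc[0] == "none"
        assert out.p.iloc[0] == pytest.approx(1.0)

    def test_zero_mse_p_undefined(self):
        out = fisher_lsd({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        assert np.isnan(out.p.iloc[0])
        assert out.direction.iloc[0] == "up"

    def test_pooled_error_shared_across_pairs(self, rng):
        # all pairs use the full-model MSE: residual df is N - k for each
        data = {g: rng.normal(i, 1, 9) for i, g in enumerate("abc")}
        out = fisher_lsd(data)
        assert len(out) == 3
        # reconstruct each t from the common MSE
        mse = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in data.values()) / 24
        for _, row in out.iterrows():
            t_expect = (row.mean_a - row.mean_b) / np.sqrt(mse * (2 / 9))
            assert row.statistic == pytest.approx(t_expect, rel=1e-10)

    def test_missing_values_do_not_alter_other_groups(self, rng):
        a, b, c = rng.normal(0, 1, 9), rng.normal(0, 1, 9), rng.normal(0, 1, 9)
        full = fisher_lsd({"a": a, "b": b, "c": c}, pairs=[("a", "b")])
        c_with_nan = np.concatenate([c, [np.nan, np.nan]])
        with_nan = fisher_lsd({"a": a, "b": b, "c": c_with_nan}, pairs=[("a", "b")])
        assert with_nan.p.iloc[0] == pytest.approx(full.p.iloc[0], rel=1e-12)


class TestModelResults:
    def test_fit_and_summary(self, rng):
        data = {
            "STD": rng.normal(1.0, 0.16, 9),
            "HFHS": rng.normal(1.87, 0.03, 9),
            "HFHS+ω3": rng.normal(0.90, 0.11, 9),
        }
        res = GroupComparison(data, name="spot_21").fit()
        assert res.route in ("parametric", "nonparametric")
        assert 0 <= res.omnibus_p <= 1
        text = res.summary()
        assert "spot_21" in text and "pairwise" in text

    def test_from_dataframe_roundtrip(self, rng):
        df = pd.DataFrame(
            {
                "group": ["a"] * 5 + ["b"] * 5,
                "value": np.r_[rng.normal(0, 1, 5), rng.normal(3, 1, 5)],
            }
        )
        res = GroupComparison.from_dataframe(df).fit()
        assert set(res.model.groups) == {"a", "b"}
        assert res.pairwise.p.iloc[0] < 0.05

    def test_too_few_usable_groups_is_error(self):
        with pytest.raises(ValueError):
            GroupComparison({"a": [1.0, 2.0], "b": [np.nan] * 5})


class TestAnnotation:
    @staticmethod
    def _results_with_p(p, increase=True):
        """Parametric results with a fixed pairwise p, direction up/down."""
        res = GroupComparison(
            {"STD": [0.0, 1.0, 2.0], "HFHS": [10.0, 11.0, 12.0]}
        ).fit()
        res.pairwise.loc[:, "p"] = p
        if not increase:
            res.pairwise.loc[:, "direction"] = "down"
        return res

    def test_star_thresholds_strict(self):
        assert self._results_with_p(0.049).flags("STD") == {"HFHS": "*"}
        assert self._results_with_p(0.05).flags("STD") == {"HFHS": ""}
        assert self._results_with_p(0.009).flags("STD") == {"HFHS": "**"}
        assert self._results_with_p(0.01).flags("STD") == {"HFHS": "*"}
        assert self._results_with_p(0.2).flags("STD") == {"HFHS": ""}

    def test_arrows_only_for_significant_pairs(self):
        assert self._results_with_p(0.049).arrows("STD") == {"HFHS": "+"}
        assert self._results_with_p(0.049, increase=False).arrows("STD") == {"HFHS": "−"}
        assert self._results_with_p(0.2).arrows("STD") == {"HFHS": ""}

    def test_arrow_direction_matches_mean_difference(self, rng):
        for _ in range(50):
            data = {g: rng.normal(rng.uniform(0, 3), 1, 9) for g in "ab"}
            res = GroupComparison(data).fit()
            row = res.pairwise.iloc[0]
            if row.mean_b > row.mean_a:
                assert row.direction == "up"
            elif row.mean_b < row.mean_a:
                assert row.direction == "down"


class TestTidyInterfaces:
    def test_compare_variables_shapes(self, rng):
        df = pd.DataFrame(
            {
                "variable": ["v1"] * 18 + ["v2"] * 18,
                "animal_id": [f"x{i}" for i in range(36)],
                "group": (["a"] * 9 + ["b"] * 9) * 2,
                "value": rng.normal(0, 1, 36),
            }
        )
        out = compare_variables(df)
        assert set(out.variable) == {"v1", "v2"}
        assert {"route", "omnibus_p", "p", "direction", "stars"} <= set(out.columns)

    def test_render_group_table_cells(self, rng):
        df = pd.DataFrame(
            {
                "variable": ["v"] * 18,
                "animal_id": [f"x{i}" for i in range(18)],
                "group": ["STD"] * 9 + ["HFHS"] * 9,
                "value": np.r_[rng.normal(1, 0.1, 9), rng.normal(3, 0.1, 9)],
            }
        )
        out = render_group_table(df)
        row = out.iloc[0]
        assert "(" in row["STD"] and "(" in row["HFHS"]
        assert "**" in row["HFHS"]  # huge separation
        assert row["HFHS/STD"].startswith("+")
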