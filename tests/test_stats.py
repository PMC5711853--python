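"""Treatment ANOVA, Pearson tables, forward stepwise regression, variance
portions and the isotope delta utility, each against arithmetic oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from canopyvi import (delta_notation, forward_stepwise, pearson_table,
                      treatment_anova, variance_portions)


def frame(**cols):
    return pd.DataFrame(cols)


class TestTreatmentAnova:
    def test_identical_groups_give_zero_f(self):
        df = frame(treatment=["NPF"] * 3 + ["OP"] * 3, y=[1.0, 2.0, 3.0] * 2)
        res = treatment_anova(df, "y")
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(1)
        df = frame(treatment=["NPF"] * 10 + ["OP"] * 10,
                   y=np.concatenate([rng.normal(0, 0.01, 10), rng.normal(1, 0.01, 10)]))
        assert treatment_anova(df, "y").p_value < 0.001

    def test_hand_worked_sum_of_squares(self):
        # groups {1,2,3} and {2,4,6}: between-SS = 3*(2-3)^2+3*(4-3)^2 = 6,
        # within-SS = 2 + 8 = 10; F = (6/1)/(10/4) = 2.4
        df = frame(treatment=["NPF"] * 3 + ["OP"] * 3, y=[1, 2, 3, 2, 4, 6])
        res = treatment_anova(df, "y")
        assert res.f_stat == pytest.approx(2.4, abs=1e-12)
        assert res.p_value == pytest.approx(float(sps.f.sf(2.4, 1, 4)), abs=1e-12)
        assert res.groups["NPF"].mean == pytest.approx(2.0)
        assert res.groups["OP"].se == pytest.approx(2.0 / math.sqrt(3))

    def test_f_equals_t_squared_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        df = frame(treatment=["NPF"] * 12 + ["OP"] * 15, y=np.concatenate([a, b]))
        res = treatment_anova(df, "y")
        t, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)

    def test_underfilled_level_rejected(self):
        df = frame(treatment=["NPF", "NPF", "OP"], y=[1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            treatment_anova(df, "y")


class TestPearsonTable:
    def base_frame(self):
        x = np.arange(10, dtype=float)
        return frame(treatment=["NPF"] * 5 + ["OP"] * 5, x=x, y=2 * x)

    def test_exact_linear_relation(self):
        table = pearson_table(self.base_frame(), ["x"], "y")
        assert table.loc["x", ("Combined", "r")] == pytest.approx(1.0)
        assert table.loc["x", ("Combined", "p")] < 1e-9
        assert table.loc["x", ("Combined", "n")] == 10

    def test_constructed_orthogonality(self):
        df = frame(treatment=["NPF"] * 4, x=[-1.0, -1.0, 1.0, 1.0],
                   y=[-1.0, 1.0, -1.0, 1.0])
        table = pearson_table(df, ["x"], "y", groups=("NPF",))
        assert table.loc["x", ("NPF", "r")] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_hand_computed_covariance_ratio(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / math.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        df = frame(treatment=["NPF"] * 5, x=x, y=y)
        table = pearson_table(df, ["x"], "y", groups=("NPF",))
        assert table.loc["x", ("NPF", "r")] == pytest.approx(r_hand, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        df = frame(treatment=["NPF"] * 20, x=x, y=y)
        df2 = frame(treatment=["NPF"] * 20, x=3.0 * x + 7.0, y=y)
        df3 = frame(treatment=["NPF"] * 20, x=-x, y=y)
        r = pearson_table(df, ["x"], "y", groups=("NPF",)).loc["x", ("NPF", "r")]
        r2 = pearson_table(df2, ["x"], "y", groups=("NPF",)).loc["x", ("NPF", "r")]
        r3 = pearson_table(df3, ["x"], "y", groups=("NPF",)).loc["x", ("NPF", "r")]
        assert r2 == pytest.approx(r, abs=1e-12)
        assert r3 == pytest.approx(-r, abs=1e-12)

    def test_small_cells_flagged_not_fabricated(self):
        df = frame(treatment=["NPF", "NPF", "OP"], x=[1.0, 2.0, 3.0], y=[1.0, 2.0, 3.0])
        table = pearson_table(df, ["x"], "y")
        assert math.isnan(table.loc["x", ("NPF", "r")])
        assert table.loc["x", ("NPF", "n")] == 2

    def test_pairwise_dropping_records_n(self):
        df = frame(treatment=["NPF"] * 6, x=[1, 2, 3, 4, np.nan, 6],
                   y=[2.0, 4, 6, 8, 10, np.nan])
        table = pearson_table(df, ["x"], "y", groups=("NPF",))
        assert table.loc["x", ("NPF", "n")] == 4
        assert table.loc["x", ("NPF", "r")] == pytest.approx(1.0)


class TestForwardStepwise:
    def test_exact_single_predictor_model(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)  # pure noise
        df = frame(y=3.0 * x1, x1=x1, x2=x2)
        res = forward_stepwise(df, "y", ["x1", "x2"])
        assert res.terms == ("x1",)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["x1"] == pytest.approx(3.0, abs=1e-9)
        assert res.portions == {"x1": pytest.approx(1.0)}

    def test_null_design_stays_intercept_only(self):
        rng = np.random.default_rng(404)
        df = frame(y=rng.normal(size=50), x1=rng.normal(size=50),
                   x2=rng.normal(size=50))
        res = forward_stepwise(df, "y", ["x1", "x2"], alpha_enter=0.05)
        assert res.intercept_only
        assert res.terms == ()
        assert res.intercept == pytest.approx(df["y"].mean())

    def test_planted_two_predictor_recovery(self):
        rng = np.random.default_rng(7)
        n = 52
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1.5 + 3.0 * x1 - 2.0 * x2 + rng.normal(0, 0.5, n)
        df = frame(y=y, x1=x1, x2=x2)
        res = forward_stepwise(df, "y", ["x1", "x2"])
        assert set(res.terms) == {"x1", "x2"}
        assert abs(res.coefficients["x1"] - 3.0) < 3 * res.coefficient_se["x1"]
        assert abs(res.coefficients["x2"] + 2.0) < 3 * res.coefficient_se["x2"]
        # RSE estimates the planted residual scale
        assert res.rse == pytest.approx(0.5, rel=0.35)
        assert sum(res.portions.values()) == pytest.approx(1.0, abs=0.01)

    def test_alpha_one_enters_at_most_all_candidates_with_growing_r2(self, rng):
        n, k = 40, 4
        X = rng.normal(size=(n, k))
        y = X @ rng.normal(size=k) + rng.normal(0, 1, n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(k)])
        df["y"] = y
        res = forward_stepwise(df, "y", list(df.columns[:-1]), alpha_enter=1.0)
        assert len(res.terms) <= k
        # R2 of nested prefixes is non-decreasing
        r2_prev = -1.0
        for j in range(1, len(res.terms) + 1):
            sub = forward_stepwise(df, "y", list(res.terms[:j]), alpha_enter=1.0)
            assert sub.r_squared >= r2_prev - 1e-12
            r2_prev = sub.r_squared

    def test_listwise_missing_dropped(self):
        df = frame(y=[1.0, 2, 3, 4, 5, 6], x1=[1.0, 2, 3, 4, np.nan, 6])
        res = forward_stepwise(df, "y", ["x1"])
        assert res.n_obs == 5


class TestVariancePortions:
    def test_single_term_gets_everything(self, rng):
        x = rng.normal(size=20)
        df = frame(y=2 * x + rng.normal(0, 0.1, 20), x=x)
        assert variance_portions(df, "y", ["x"]) == {"x": pytest.approx(1.0)}

    def test_orthogonal_equal_coefficients_split_evenly(self):
        x1 = np.array([1.0, 1.0, -1.0, -1.0] * 5)
        x2 = np.array([1.0, -1.0, 1.0, -1.0] * 5)
        rng = np.random.default_rng(3)
        y = x1 + x2 + rng.normal(0, 0.05, 20)
        df = frame(y=y, x1=x1, x2=x2)
        portions = variance_portions(df, "y", ["x1", "x2"])
        assert portions["x1"] == pytest.approx(0.5, abs=0.02)
        assert portions["x2"] == pytest.approx(0.5, abs=0.02)

    def test_orthogonal_design_matches_incremental_r2_closed_form(self):
        # under orthogonality the LMG share is each term's own R2 / total R2
        x1 = np.array([1.0, 1.0, -1.0, -1.0] * 6)
        x2 = np.array([1.0, -1.0, 1.0, -1.0] * 6)
        y = 3.0 * x1 + 1.0 * x2
        df = frame(y=y, x1=x1, x2=x2)
        portions = variance_portions(df, "y", ["x1", "x2"])
        assert portions["x1"] == pytest.approx(9.0 / 10.0, abs=1e-9)
        assert portions["x2"] == pytest.approx(1.0 / 10.0, abs=1e-9)

    def test_portions_sum_to_one_on_random_fits(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 1, 30)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        portions = variance_portions(df, "y", ["a", "b", "c"])
        assert sum(portions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in portions.values())

    def test_beta_squared_method(self):
        x1 = np.array([1.0, 1.0, -1.0, -1.0] * 6)
        x2 = np.array([1.0, -1.0, 1.0, -1.0] * 6)
        y = 3.0 * x1 + 1.0 * x2
        df = frame(y=y, x1=x1, x2=x2)
        portions = variance_portions(df, "y", ["x1", "x2"], method="beta_sq")
        assert portions["x1"] == pytest.approx(0.9, abs=1e-9)

    def test_collinear_design_names_terms(self, rng):
        x = rng.normal(size=20)
        df = frame(y=x + rng.normal(0, 0.1, 20), x1=x, x2=2.0 * x)
        with pytest.raises(ValueError, match="x1"):
            variance_portions(df, "y", ["x1", "x2"])


class TestDeltaNotation:
    def test_standard_ratio_is_zero(self):
        assert delta_notation(0.0112372, 0.0112372) == 0.0

    def test_per_mil_scaling(self):
        assert delta_notation(1.001 * 0.0112372, 0.0112372) == pytest.approx(1.0)
        assert delta_notation(0.5 * 0.0112372, 0.0112372) == pytest.approx(-500.0)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(ValueError):
            delta_notation(0.01, 0.0)
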