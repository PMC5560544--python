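"""Odds ratios, logistic fitting, backward elimination, HL, Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calfsid.errors import SeparationError, ValidationError
from calfsid.regression import (
    ContingencyTable,
    MortalityLogit,
    Term,
    backward_eliminate,
    fit_logistic,
    hosmer_lemeshow,
    mann_whitney,
    odds_ratio,
)

counts = st.integers(1, 500)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "a,b,c,d,expected",
        [
            (171, 401, 142, 686, 2.06),  # hypothermia vs normothermia
            (98, 100, 103, 582, 5.54),  # cachectic vs good-moderate condition
            (10, 90, 10, 90, 1.00),
        ],
    )
    def test_cohort_tables(self, a, b, c, d, expected):
        est = odds_ratio(ContingencyTable(a, b, c, d))
        assert est.or_point == pytest.approx(expected, abs=0.005)
        assert est.ci_low <= est.or_point <= est.ci_high

    @given(counts, counts, counts, counts)
    def test_row_swap_antisymmetry(self, a, b, c, d):
        fwd = odds_ratio(ContingencyTable(a, b, c, d))
        rev = odds_ratio(ContingencyTable(c, d, a, b))
        assert rev.or_point == pytest.approx(1 / fwd.or_point, rel=1e-9)
        assert rev.ci_low == pytest.approx(1 / fwd.ci_high, rel=1e-9)
        assert rev.ci_high == pytest.approx(1 / fwd.ci_low, rel=1e-9)

    def test_zero_row_total_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(0, 0, 5, 5)

    def test_zero_cell_haldane_correction(self):
        with pytest.warns(UserWarning, match="Haldane"):
            est = odds_ratio(ContingencyTable(0, 10, 5, 5))
        assert est.or_point == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-9)


def two_by_two_frame(a, b, c, d):
    """Rows for a 2x2 design: exposure x, outcome y with the given counts."""
    rows = (
        [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d
    )
    return pd.DataFrame(rows, columns=["x", "y"])


class TestFitLogistic:
    def test_single_binary_predictor_equals_log_or(self):
        df = two_by_two_frame(171, 401, 142, 686)
        model = fit_logistic(df, "y", ["x"])
        expected = math.log(171 * 686 / (401 * 142))
        assert model.terms[0].coefficient == pytest.approx(expected, abs=1e-6)
        # Wald SE matches the 2x2 closed form too
        se = math.sqrt(1 / 171 + 1 / 401 + 1 / 142 + 1 / 686)
        assert model.terms[0].se == pytest.approx(se, abs=1e-6)

    def test_intercept_only_is_log_odds(self):
        df = pd.DataFrame({"y": [1] * 40 + [0] * 160})
        model = fit_logistic(df, "y", [])
        assert model.intercept == pytest.approx(math.log(40 / 160), abs=1e-8)

    def test_mean_fitted_probability_equals_event_rate(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=500)})
        df["y"] = (rng.random(500) < 1 / (1 + np.exp(-(-1 + 0.8 * df["x"])))).astype(int)
        res = MortalityLogit(df, "y", ["x"]).fit()
        assert res.predict().mean() == pytest.approx(df["y"].mean(), abs=1e-8)

    def test_perfect_separation_raises_naming_term(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)], "y": np.r_[np.zeros(50), np.ones(50)]})
        with pytest.raises(SeparationError, match="x"):
            fit_logistic(df, "y", ["x"])

    def test_thresholded_term_complete_case_n(self):
        df = two_by_two_frame(20, 30, 10, 40).astype(float)
        df.loc[:4, "x"] = np.nan
        model = fit_logistic(df, "y", [Term("hi", "x", op="ge", threshold=0.5)])
        assert model.n == 95

    def test_summary_contains_or_column(self, small_cohort):
        res = MortalityLogit(
            small_cohort, "died_observed", ["cns_involvement", "bronchopneumonia"]
        ).fit()
        text = res.summary()
        assert "OR" in text and "(intercept)" in text


class TestBackwardElimination:
    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(11)
        n = 3000
        x1, x2 = rng.integers(0, 2, (2, n))
        lp = -1.5 + 1.2 * x1 + 1.0 * x2
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        model = backward_eliminate(df, "y", ["x1", "x2"], alpha=0.01)
        assert {t.name for t in model.terms} == {"x1", "x2"}
        assert model.metadata["elimination_order"] == []

    def test_strong_effect_retained_null_terms_dropped(self):
        rng = np.random.default_rng(12)
        n = 5000
        strong = rng.integers(0, 2, n)
        nulls = rng.integers(0, 2, (3, n))
        lp = -1.5 + 2.0 * strong
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        df = pd.DataFrame({"strong": strong, "n1": nulls[0], "n2": nulls[1], "n3": nulls[2], "y": y})
        model = backward_eliminate(df, "y", ["strong", "n1", "n2", "n3"], alpha=0.01)
        assert "strong" in {t.name for t in model.terms}

    def test_never_removes_significant_term_at_removal_step(self):
        rng = np.random.default_rng(13)
        n = 4000
        x = rng.integers(0, 2, (4, n))
        lp = -1.0 + 1.5 * x[0] + 0.9 * x[1]
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        df = pd.DataFrame({f"x{i}": x[i] for i in range(4)} | {"y": y})
        model = backward_eliminate(df, "y", [f"x{i}" for i in range(4)], alpha=0.01)
        for step in model.metadata["elimination_order"]:
            assert step["p_value"] > 0.01


class TestHosmerLemeshow:
    def test_three_distinct_values_collapse(self):
        rng = np.random.default_rng(2)
        p = np.repeat([0.1, 0.3, 0.6], 100)
        y = (rng.random(300) < p).astype(int)
        res = hosmer_lemeshow(p, y, groups=10)
        assert res.groups == 3
        assert res.degrees_of_freedom == 1

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValidationError):
            hosmer_lemeshow(np.linspace(0.1, 0.9, 100), np.zeros(100), groups=2)

    def test_well_calibrated_model_not_rejected(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.05, 0.95, 2000)
        y = (rng.random(2000) < p).astype(int)
        res = hosmer_lemeshow(p, y)
        assert res.groups == 10 and res.degrees_of_freedom == 8
        assert res.p_value > 0.001


class TestMannWhitney:
    def test_identical_constant_groups(self):
        u, p = mann_whitney([5.0] * 4, [5.0] * 6)
        assert u == 12.0 and p == 1.0

    def test_full_separation_u_zero(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_exact_p_matches_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = mann_whitney(a, b)
        # exhaustive oracle: all C(6,3) assignments of the pooled values
        pooled = a + b
        observed_u = sum(x > y for x in a for y in b)
        count = total = 0
        for idx in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(6) if i not in idx]
            u = sum(x > y for x in ga for y in gb)
            total += 1
            if min(u, 9 - u) <= min(observed_u, 9 - observed_u):
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        _, p = mann_whitney(a, b)
        assert p < 0.001
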