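"""GM(1,1): exact recovery, equivariance, accuracy diagnostics."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import tcm_equity as te
from tcm_equity.exceptions import (
    ContractError,
    DegenerateModelError,
    InsufficientDataError,
)
from tcm_equity.grey import accuracy_test, relative_errors


def grey_exact_values(a, u, x0_first, n):
    """Values satisfying the grey difference equation exactly.

    Solving X0(k) = -a z(k) + u with z(k) = X1(k-1) + X0(k)/2 for X0(k)
    gives the recursion X0(k) = (u - a X1(k-1)) / (1 + a/2); least squares
    on such consistent equations recovers (a, u) exactly.  Note the
    restored fit uses the continuous-time exponential, which deviates from
    this recursion by an O(a^2) trapezoid discretization error.
    """
    values = [x0_first]
    x1 = x0_first
    for _ in range(n - 1):
        nxt = (u - a * x1) / (1.0 + a / 2.0)
        values.append(nxt)
        x1 += nxt
    return values


def grey_exact_series(a, u, x0_first, n, first_year=2016):
    return te.NationalSeries(
        indicator="institutions",
        years=tuple(range(first_year, first_year + n)),
        values=tuple(grey_exact_values(a, u, x0_first, n)),
    )


def difference_form_residuals(model, series):
    """Residuals of the fitted difference equations X0(k) = -a z(k) + u."""
    x0 = np.asarray(series.values, dtype=float)
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    return x0[1:] - (-model.a * z + model.u)


class TestFit:
    @given(
        st.floats(-0.3, 0.3).filter(lambda a: abs(a) > 1e-3),
        st.floats(10.0, 1e6),
        st.floats(1.0, 1e5),
        st.integers(4, 12),
    )
    def test_exact_recovery_on_consistent_equations(self, a0, u0, x0, n):
        values = grey_exact_values(a0, u0, x0, n)
        assume(min(values) > 0 and max(values) / min(values) < 1e6)
        series = grey_exact_series(a0, u0, x0, n)
        model = te.fit_gm11(series)
        assert model.a == pytest.approx(a0, abs=1e-10, rel=1e-10)
        assert model.u == pytest.approx(u0, abs=1e-10, rel=1e-10)
        # the fitted difference equations are exactly consistent
        diff_res = difference_form_residuals(model, series)
        assert np.abs(diff_res).max() < 1e-8 * max(values)
        # restored values deviate only by the trapezoid discretization error
        rel = np.abs(model.residuals) / np.asarray(values)
        assert rel.max() <= 0.5 * a0**2 + 1e-9

    def test_first_fitted_value_equals_first_observation(self, institutions_model):
        assert institutions_model.fitted[0] == institutions_model.x0_first
        assert institutions_model.residuals[0] == 0.0

    def test_scale_equivariance(self):
        series = grey_exact_series(-0.1, 500.0, 80.0, 6)
        scaled = te.NationalSeries(
            indicator=series.indicator,
            years=series.years,
            values=tuple(3.0 * v for v in series.values),
        )
        m1, m3 = te.fit_gm11(series), te.fit_gm11(scaled)
        assert m3.a == pytest.approx(m1.a, rel=1e-9)
        assert m3.u == pytest.approx(3 * m1.u, rel=1e-9)
        f1, f3 = te.forecast(m1, 3), te.forecast(m3, 3)
        for year in f1:
            assert f3[year] == pytest.approx(3 * f1[year], rel=1e-9)

    def test_time_response_constants(self, institutions_model):
        m = institutions_model
        assert m.response_coefficient == pytest.approx(m.x0_first - m.u / m.a)
        assert m.asymptote == pytest.approx(m.u / m.a)

    def test_preconditions(self):
        with pytest.raises(Exception):
            te.fit_gm11(
                te.NationalSeries("beds", (2016, 2017, 2018), (1.0, 2.0, 3.0))
            )
        constant = te.NationalSeries(
            "beds", (2016, 2017, 2018, 2019), (5.0, 5.0, 5.0, 5.0)
        )
        with pytest.raises(DegenerateModelError):
            te.fit_gm11(constant)


class TestForecast:
    def test_continues_exact_construction(self):
        a0, u0, x0 = -0.08, 200.0, 60.0
        long = grey_exact_series(a0, u0, x0, 9)
        short = te.NationalSeries(
            indicator="institutions", years=long.years[:5], values=long.values[:5]
        )
        model = te.fit_gm11(short)
        predicted = te.forecast(model, 4)
        # continuation matches the generating recursion up to the O(a^2)
        # trapezoid discretization error of the exponential restoration
        for year, value in predicted.items():
            expected = long.values[year - long.years[0]]
            assert value == pytest.approx(expected, rel=0.5 * a0**2)

    def test_growth_model_forecasts_strictly_increase(self, institutions_model):
        values = list(te.forecast(institutions_model, 10).values())
        assert institutions_model.a < 0
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_horizon_contract(self, institutions_model):
        with pytest.raises(ContractError):
            te.forecast(institutions_model, 0)
        with pytest.raises(ContractError):
            te.forecast_table(institutions_model, 2019)


class TestAccuracy:
    def test_perfect_fit_is_level_one_with_zero_C(self):
        model = te.fit_gm11(grey_exact_series(-0.05, 100.0, 50.0, 5))
        report = accuracy_test(model)
        # C vanishes up to the squared O(a^2) discretization error
        assert report.C < 1e-6
        assert accuracy_test(model, convention="std").C < 1e-3
        assert report.P == 1.0
        assert report.level == 1 and report.reliable

    def test_variance_convention_squares_std_ratio(self, institutions_model):
        var = accuracy_test(institutions_model, convention="variance")
        std = accuracy_test(institutions_model, convention="std")
        assert var.C == pytest.approx(std.C**2, rel=1e-12)
        assert var.P == std.P
        assert var.S1 == std.S1 and var.S2 == std.S2

    def test_residuals_equal_to_series_give_unit_std_ratio(self):
        model = te.fit_gm11(grey_exact_series(-0.05, 100.0, 50.0, 5))
        x0 = np.array(model.fitted) + np.array(model.residuals)
        hypothetical = te.GreyModel(
            a=model.a, u=model.u, x0_first=model.x0_first, n=model.n,
            years=model.years, fitted=tuple(np.zeros_like(x0)),
            residuals=tuple(x0),
        )
        assert accuracy_test(hypothetical, convention="std").C == pytest.approx(1.0)

    def test_unknown_convention_rejected(self, institutions_model):
        with pytest.raises(ContractError):
            accuracy_test(institutions_model, convention="mad")


class TestRelativeErrors:
    def test_zero_for_first_year_and_matches_definition(self, institutions_model):
        errors = relative_errors(institutions_model)
        assert errors[2016] == 0.0
        actual_2017 = 54243.0
        fitted_2017 = institutions_model.fitted[1]
        assert errors[2017] == pytest.approx(
            100 * abs(fitted_2017 - actual_2017) / actual_2017, abs=1e-12
        )
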