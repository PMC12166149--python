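"""Hazard families, modifiers, and closed-form cumulative integrals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from sojourn import CouplingError, Hazard, Modifier, cumulative_hazard_segment, eval_hazard, total_hazard
from sojourn.hazards import tabulated_from_csv


def h_const(c):
    return Hazard("constant", {"c": c})


class TestEval:
    @pytest.mark.parametrize("t,tau", [(0, 0), (3.5, 1.2), (100, 0)])
    def test_constant_everywhere(self, t, tau):
        assert eval_hazard(h_const(0.2), t, tau) == 0.2

    def test_gompertz_at_zero_sojourn_is_p(self):
        hz = Hazard("gompertz", {"p": 1.197e-2, "r": 6.654e-2})
        assert eval_hazard(hz, 0.0, 0.0) == pytest.approx(1.197e-2)

    def test_lead_time_zero_gates_and_shifts(self):
        hz = Hazard("constant", {"c": 0.5},
                    modifiers=(Modifier("lead_time_zero", tau0=2.0),))
        assert eval_hazard(hz, 0.0, 1.0) == 0.0
        assert eval_hazard(hz, 0.0, 2.5) == pytest.approx(0.5)

    def test_lead_time_linear_ramps(self):
        hz = Hazard("constant", {"c": 1.0},
                    modifiers=(Modifier("lead_time_linear", tau0=4.0),))
        assert eval_hazard(hz, 0.0, 1.0) == pytest.approx(0.25)
        assert eval_hazard(hz, 0.0, 8.0) == pytest.approx(1.0)

    def test_negative_domain_rejected(self):
        with pytest.raises(ValueError):
            eval_hazard(h_const(1.0), -0.1, 0.0)
        with pytest.raises(ValueError):
            eval_hazard(h_const(1.0), 0.0, -0.1)

    def test_coupled_requires_occupancy(self):
        hz = Hazard("constant", {"c": 0.3}, dependence="model_time",
                    modifiers=(Modifier("mass_proportional", coupling_state="I"),))
        with pytest.raises(CouplingError):
            eval_hazard(hz, 1.0, 0.0)
        assert eval_hazard(hz, 1.0, 0.0, {"I": 0.5}) == pytest.approx(0.15)


class TestCumulative:
    def test_constant_segment(self):
        assert cumulative_hazard_segment(h_const(0.2), 0.0, 0.0, 5.0) == pytest.approx(1.0)

    def test_weibull_closed_form(self):
        hz = Hazard("weibull", {"b": 1.0, "k": 2.0})
        assert cumulative_hazard_segment(hz, 0.0, 0.0, 2.0) == pytest.approx(4.0)

    def test_gompertz_closed_form(self):
        hz = Hazard("gompertz", {"p": 1.197e-2, "r": 6.654e-2})
        expect = 1.197e-2 / 6.654e-2 * (math.exp(6.654e-2 * 10) - 1)
        got = cumulative_hazard_segment(hz, 0.0, 0.0, 10.0)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(0.170054, abs=1e-5)

    def test_piecewise_decompensation_analytic(self):
        # 0.0129 t + 0.00668 below t=6, 0.0359 above: exact integral over [0, 10]
        hz = Hazard("piecewise_linear_in_time",
                    {"breaks": [6.0], "slopes": [0.0129, 0.0],
                     "intercepts": [0.00668, 0.0359]}, dependence="model_time")
        expect = 0.0129 * 18 + 0.00668 * 6 + 0.0359 * 4
        assert cumulative_hazard_segment(hz, 0.0, 0.0, 10.0) == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(0.41588)

    def test_singular_weibull_cumulative_finite(self):
        # k < 1: rate is unbounded at tau=0 but b*tau**k stays finite
        k = 0.762
        hz = Hazard("weibull", {"b": 0.0336 / k, "k": k})
        assert np.isinf(eval_hazard(hz, 0.0, 0.0))
        got = cumulative_hazard_segment(hz, 0.0, 0.0, 10.0)
        assert got == pytest.approx(0.0336 / k * 10 ** k, rel=1e-12)

    def test_proportional_modifier_scales_linearly(self):
        base = Hazard("gompertz", {"p": 0.05, "r": 0.1})
        doubled = base.with_multiplier(2.0)
        for tau in (0.5, 3.0, 9.0):
            assert doubled.cumulative(0, 0, tau) == pytest.approx(
                2.0 * base.cumulative(0, 0, tau), rel=1e-14)

    def test_lead_time_zero_cumulative_shift(self):
        base = Hazard("gompertz", {"p": 0.05, "r": 0.1})
        shifted = Hazard("gompertz", {"p": 0.05, "r": 0.1},
                         modifiers=(Modifier("lead_time_zero", tau0=2.0),))
        assert shifted.cumulative(0.0, 0.0, 2.0) == 0.0
        assert shifted.cumulative(0.0, 2.0, 3.0) == pytest.approx(
            base.cumulative(0.0, 0.0, 3.0), rel=1e-12)

    def test_product_of_hazards_constant_scaling(self):
        prod = Hazard("product_of_hazards", {"components": (
            h_const(2.0), Hazard("gompertz", {"p": 0.05, "r": 0.1}))})
        base = Hazard("gompertz", {"p": 0.1, "r": 0.1})
        assert prod.cumulative(0, 0, 5.0) == pytest.approx(base.cumulative(0, 0, 5.0), rel=1e-12)

    def test_vectorised_over_tau_start(self):
        hz = Hazard("weibull", {"b": 0.3, "k": 1.5})
        tau0 = np.array([0.0, 1.0, 2.0])
        got = hz.cumulative(0.0, tau0, 0.5)
        expect = 0.3 * ((tau0 + 0.5) ** 1.5 - tau0 ** 1.5)
        np.testing.assert_allclose(got, expect, rtol=1e-13)


_family_cases = st.sampled_from(["constant", "weibull", "gompertz",
                                 "polynomial_in_sojourn", "piecewise_linear_in_time",
                                 "piecewise_constant", "tabulated"])


def _build_random_hazard(family, rng):
    if family == "constant":
        return Hazard("constant", {"c": rng.uniform(0.01, 2.0)})
    if family == "weibull":
        return Hazard("weibull", {"b": rng.uniform(0.05, 1.0), "k": rng.uniform(0.5, 2.5)})
    if family == "gompertz":
        return Hazard("gompertz", {"p": rng.uniform(0.01, 0.5), "r": rng.uniform(-0.2, 0.2)})
    if family == "polynomial_in_sojourn":
        return Hazard("polynomial_in_sojourn",
                      {"c0": rng.uniform(0.01, 0.5), "c1": rng.uniform(0, 0.1),
                       "c2": rng.uniform(0, 0.02)})
    if family == "piecewise_linear_in_time":
        return Hazard("piecewise_linear_in_time",
                      {"breaks": [rng.uniform(1, 4)], "slopes": [rng.uniform(0, 0.1), 0.0],
                       "intercepts": [rng.uniform(0.01, 0.2), rng.uniform(0.01, 0.3)]},
                      dependence="model_time")
    if family == "piecewise_constant":
        return Hazard("piecewise_constant",
                      {"breaks": [rng.uniform(0.5, 2), rng.uniform(3, 5)],
                       "values": list(rng.uniform(0.01, 0.5, size=3))},
                      dependence="sojourn")
    return Hazard("tabulated", {"ages": list(np.arange(0, 20.0)),
                                "rates": list(rng.uniform(0.005, 0.1, size=20))},
                  dependence="model_time", age_offset=rng.uniform(0, 5))


class TestClosedFormsAgreeWithQuadrature:
    """Every closed-form family must match adaptive quadrature of the rate."""

    @given(family=_family_cases, seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_segment_matches_quad(self, family, seed):
        rng = np.random.default_rng(seed)
        hz = _build_random_hazard(family, rng)
        t0 = rng.uniform(0, 3)
        tau0 = rng.uniform(0, 3)
        delta = rng.uniform(0.1, 6)
        pts = []
        for var, pos in hz.breakpoints():
            s = pos - (t0 if var == "model_time" else tau0)
            if 0 < s < delta:
                pts.append(s)
        ref, _ = quad(lambda s: float(hz.rate(t0 + s, tau0 + s)), 0, delta,
                      points=sorted(pts) or None, limit=300)
        got = float(hz.cumulative(t0, tau0, delta))
        assert got == pytest.approx(ref, rel=1e-8, abs=1e-12)


class TestTotalHazard:
    def test_additivity_of_competing_constants(self):
        assert total_hazard([h_const(1.0), h_const(3.0)], 0.0, 0.0) == 4.0

    def test_absorbing_state_has_zero_rate(self):
        assert total_hazard([], 5.0, 5.0) == 0.0

    def test_sir_susceptible_rate_scales_with_infected_mass(self):
        hz = Hazard("constant", {"c": 0.3}, dependence="model_time",
                    modifiers=(Modifier("mass_proportional", coupling_state="I"),))
        assert total_hazard([hz], 0.0, 0.0, {"I": 0.5}) == pytest.approx(0.15)


class TestValidation:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown hazard family"):
            Hazard("exponentialish", {})

    def test_decreasing_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Hazard("piecewise_constant", {"breaks": [3.0, 1.0], "values": [1, 2, 3]})

    def test_mass_proportional_needs_coupling_state(self):
        with pytest.raises(ValueError, match="coupling"):
            Modifier("mass_proportional")


def test_tabulated_from_csv_roundtrip(tmp_path):
    p = tmp_path / "lt.csv"
    p.write_text("age,annual_rate\n0,0.01\n1,0.02\n2,0.05\n")
    hz = tabulated_from_csv(p, age_offset=1.0)
    # age = 1 + t: t=0 -> age 1 bin, t in [1,inf) -> age-2 bin (last extends)
    assert eval_hazard(hz, 0.0, 0.0) == pytest.approx(0.02)
    assert eval_hazard(hz, 5.0, 0.0) == pytest.approx(0.05)
    assert hz.cumulative(0.0, 0.0, 2.0) == pytest.approx(0.02 + 0.05)
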