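"""Characteristic survival utilities and their consistency with the solver."""

import numpy as np
import pytest
from scipy.integrate import quad

from sojourn import (CharacteristicFrame, Hazard, ModelSpec, cause_specific_survival,
                     next_transition_cdf, next_transition_prob, overall_survival,
                     run, time_to_event_density)
from sojourn.model import GridSpec
from sojourn.oracles import mc_sample

from conftest import make_competing, make_random_semi_markov


class TestOverallSurvival:
    def test_competing_constants(self):
        m = make_competing(a=1.0, b=3.0, dt=0.1, max_t=1.0)
        assert overall_survival(m, CharacteristicFrame("src"), 0.25) == pytest.approx(
            np.exp(-1.0), rel=1e-12)

    def test_absorbing_state_survives_forever(self):
        m = make_competing(dt=0.1, max_t=1.0)
        assert overall_survival(m, CharacteristicFrame("ea"), 50.0) == 1.0

    def test_matches_solver_stay_in_state_mass(self, liver_model):
        """The compensated-cirrhosis occupancy is exactly the characteristic
        survival, since nothing re-enters that state."""
        res = run(liver_model)
        frame = CharacteristicFrame("Compensated cirrhosis")
        for t in (1.0, 5.0, 10.0):
            assert res.trajectory.occupancy_at(t, "Compensated cirrhosis") == pytest.approx(
                float(overall_survival(liver_model, frame, t)), abs=1e-10)

    def test_quadrature_cross_check(self, liver_model):
        # independent adaptive quadrature of the summed rates
        frame = CharacteristicFrame("Compensated cirrhosis")
        total = 0.0
        for tr in liver_model.transitions_from("Compensated cirrhosis"):
            val, _ = quad(lambda s, h=tr.hazard: float(h.rate(s, s)), 0, 10,
                          points=[6.0], limit=300)
            total += val
        assert float(overall_survival(liver_model, frame, 10.0)) == pytest.approx(
            np.exp(-total), rel=1e-7)


class TestCauseSpecific:
    def test_decompensation_ten_year_risk(self, liver_model):
        s = cause_specific_survival(liver_model, CharacteristicFrame("Compensated cirrhosis"),
                                    "Decompensated cirrhosis", 10.0)
        assert float(s) == pytest.approx(np.exp(-0.41588), rel=1e-10)
        assert 1 - float(s) == pytest.approx(0.3402, abs=2e-4)

    def test_zero_hazard_cause_survives(self):
        m = make_competing(a=0.0, b=1.0, dt=0.1, max_t=1.0)
        assert cause_specific_survival(m, CharacteristicFrame("src"), "ea", 9.0) == 1.0

    def test_product_over_causes_is_overall(self):
        for seed in (1, 2, 3):
            m = make_random_semi_markov(seed, dt=0.1, max_t=1.0)
            frame = CharacteristicFrame(m.states[0])
            prod = 1.0
            for tr in m.transitions_from(m.states[0]):
                prod *= float(cause_specific_survival(m, frame, tr.target, 7.0))
            assert prod == pytest.approx(float(overall_survival(m, frame, 7.0)), rel=1e-12)

    def test_unknown_cause_rejected(self):
        m = make_competing(dt=0.1, max_t=1.0)
        with pytest.raises(KeyError):
            cause_specific_survival(m, CharacteristicFrame("src"), "nope", 1.0)


class TestNextTransition:
    def test_cdf_zero_at_entry(self):
        m = make_competing(dt=0.1, max_t=1.0)
        assert next_transition_cdf(m, CharacteristicFrame("src"), "ea", 0.0) == 0.0

    def test_cdf_nondecreasing(self):
        m = make_competing(a=0.5, b=0.2, dt=0.1, max_t=1.0)
        frame = CharacteristicFrame("src")
        vals = [next_transition_cdf(m, frame, "ea", t) for t in (0.5, 1, 2, 4, 8)]
        assert np.all(np.diff(vals) >= 0)

    def test_limit_is_rate_share_for_constants(self):
        m = make_competing(a=1.0, b=3.0, dt=0.1, max_t=1.0)
        res = next_transition_prob(m, CharacteristicFrame("src"), "ea", horizon=30.0)
        assert res.prob == pytest.approx(0.25, abs=1e-9)
        assert res.tail_bound < 1e-12

    def test_cause_split_matches_monte_carlo(self):
        """Weibull vs constant competitor: analytic next-transition split
        against the trajectory sampler."""
        m = ModelSpec(states=["A", "B", "C"], grid=GridSpec(dt=0.1, max_t=1.0, max_tau=1.0))
        m.add_transition("A", "B", Hazard("weibull", {"b": 0.4, "k": 1.8}))
        m.add_transition("A", "C", Hazard("constant", {"c": 0.25}))
        m.set_initial_atom("A", 0.0, 1.0)
        n = 20_000
        mc = mc_sample(m, n, horizon=60.0, seed=11)
        p_b = next_transition_prob(m, CharacteristicFrame("A"), "B", horizon=60.0).prob
        got = float(mc.loc[mc.state == "B", "occupancy"].iloc[0])
        se = np.sqrt(p_b * (1 - p_b) / n)
        assert abs(got - p_b) < 3 * se

    def test_splits_plus_survival_sum_to_one(self):
        for seed in (5, 9):
            m = make_random_semi_markov(seed, dt=0.1, max_t=1.0)
            frame = CharacteristicFrame(m.states[0])
            tot = sum(next_transition_prob(m, frame, tr.target, horizon=150.0).prob
                      for tr in m.transitions_from(m.states[0]))
            tot += float(overall_survival(m, frame, 150.0))
            assert tot == pytest.approx(1.0, abs=1e-6)


class TestTimeToEventDensity:
    def test_constant_cause_gives_exponential_pdf(self):
        m = ModelSpec(states=["A", "B"], grid=GridSpec(dt=0.1, max_t=1.0))
        m.add_transition("A", "B", Hazard("constant", {"c": 0.7}))
        m.set_initial_atom("A", 0.0, 1.0)
        tau = np.array([0.0, 1.0, 3.0])
        got = time_to_event_density(m, CharacteristicFrame("A"), "B", tau)
        np.testing.assert_allclose(got, 0.7 * np.exp(-0.7 * tau), rtol=1e-12)

    def test_gompertz_density_at_zero_is_p(self, liver_model):
        d = time_to_event_density(liver_model, CharacteristicFrame("Compensated cirrhosis"),
                                  "Liver cancer", 0.0)
        assert float(d) == pytest.approx(1.197e-2, rel=1e-12)

    def test_densities_integrate_to_exit_probability(self):
        m = make_competing(a=0.4, b=0.6, dt=0.1, max_t=1.0)
        frame = CharacteristicFrame("src")
        total = 0.0
        for target in ("ea", "eb"):
            val, _ = quad(lambda s: float(time_to_event_density(m, frame, target, s)),
                          0, 40, limit=300)
            total += val
        assert total == pytest.approx(1.0, abs=1e-9)


def test_chained_entry_flux_is_convolution():
    """Flux into the third state of a chain equals the convolution of the
    second state's entry flux with its survival-adjusted hazard."""
    m = ModelSpec(states=["A", "B", "C"], grid=GridSpec(dt=0.01, max_t=4.0, max_tau=4.0))
    m.add_transition("A", "B", Hazard("gompertz", {"p": 0.4, "r": 0.1}))
    m.add_transition("B", "C", Hazard("weibull", {"b": 0.5, "k": 1.5}))
    m.set_initial_atom("A", 0.0, 1.0)
    res = run(m)
    traj = res.trajectory
    dt = traj.dt
    times = traj.times
    fB = traj.entry_flux[:, 1]
    hzBC = m.transitions[1].hazard
    # H(x) = lambda_BC(x) * S_B(x) on the sojourn grid
    S_B = np.exp(-np.asarray(hzBC.cumulative(0.0, 0.0, times), float))
    H = np.asarray(hzBC.rate(times, times), float) * S_B
    conv = np.array([dt * np.sum(fB[:k + 1] * H[:k + 1][::-1]) for k in range(len(times))])
    err = np.max(np.abs(conv - traj.entry_flux[:, 2]))
    assert err < 5 * dt  # first-order agreement in the grid spacing
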