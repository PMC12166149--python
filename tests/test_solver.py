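"""Transport solver: exactness on characteristics, boundary schemes,
conservation, sojourn-preserving exchanges, truncation handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from sojourn import Hazard, ModelSpec, run
from sojourn.model import GridSpec
from sojourn.solver import ModelValidationError

from conftest import make_competing, make_erlang2, make_random_semi_markov, make_two_state


class TestCharacteristicDecay:
    def test_degenerate_single_state_stays_put(self):
        m = ModelSpec(states=["only"], grid=GridSpec(dt=0.01, max_t=3.0, max_tau=3.0))
        m.set_initial_atom("only", 0.0, 1.0)
        res = run(m)
        np.testing.assert_allclose(res.trajectory.state_occupancy("only"), 1.0, atol=1e-14)

    def test_constant_hazard_survival_is_exponential(self):
        res = run(make_two_state(c=0.2, dt=0.01, max_t=10.0))
        g = res.trajectory.state_occupancy("alive")
        np.testing.assert_allclose(g, np.exp(-0.2 * res.trajectory.times), atol=1e-12)
        assert res.trajectory.occupancy_at(5.0, "alive") == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_absorbing_density_not_decayed(self):
        # mass arriving in an absorbing state must persist unchanged
        res = run(make_two_state(c=0.5, dt=0.01, max_t=4.0))
        dead = res.trajectory.state_occupancy("dead")
        assert np.all(np.diff(dead) >= -1e-15)
        assert dead[-1] == pytest.approx(1 - np.exp(-2.0), abs=1e-12)


class TestBoundarySchemes:
    def test_competing_split_converges_to_rate_ratio(self):
        res = run(make_competing(a=1.0, b=3.0, dt=0.001, max_t=15.0))
        assert res.trajectory.occupancy_at(15.0, "ea") == pytest.approx(0.25, abs=1e-3)
        assert res.trajectory.occupancy_at(15.0, "eb") == pytest.approx(0.75, abs=1e-3)

    def test_mass_conserving_total_constant_to_machine_precision(self):
        res = run(make_competing(dt=0.01, max_t=5.0))
        assert res.diagnostics["conservation_residual"] < 1e-13

    def test_single_absorbing_target_entry_equals_survival_complement(self):
        res = run(make_two_state(c=0.3, dt=0.01, max_t=5.0))
        entered = res.trajectory.dt * res.trajectory.entry_flux[1:, 1].sum()
        assert entered == pytest.approx(1 - np.exp(-0.3 * 5.0), abs=1e-12)

    def test_first_order_drift_shrinks_linearly_in_dt(self):
        drifts = []
        for dt in (0.004, 0.002, 0.001):
            res = run(make_erlang2(dt=dt), scheme="first_order")
            drifts.append(res.diagnostics["conservation_residual"])
        assert drifts[0] / drifts[1] >= 1.8
        assert drifts[1] / drifts[2] >= 1.8

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            run(make_two_state(dt=0.1, max_t=1.0), scheme="spectral")


class TestSojournPreserving:
    def test_zero_mu_leaves_grid_unchanged(self):
        m = make_two_state(c=0.2, dt=0.01, max_t=5.0)
        m.add_transition("alive", "dead", Hazard("constant", {"c": 0.0}),
                         kind="sojourn_preserving")
        res = run(m)
        np.testing.assert_allclose(res.trajectory.state_occupancy("alive"),
                                   np.exp(-0.2 * res.trajectory.times), atol=1e-12)

    def test_constant_mu_relaxes_to_markov_equilibrium(self):
        m = ModelSpec(states=["u", "v"], grid=GridSpec(dt=0.001, max_t=5.0, max_tau=5.0))
        m.add_transition("u", "v", Hazard("constant", {"c": 0.5}), kind="sojourn_preserving")
        m.add_transition("v", "u", Hazard("constant", {"c": 0.5}), kind="sojourn_preserving")
        m.set_initial_atom("u", 0.0, 1.0)
        res = run(m)
        Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
        for t in (0.5, 2.0, 5.0):
            exact = expm(Q.T * t) @ np.array([1.0, 0.0])
            np.testing.assert_allclose(res.trajectory.occupancy_at(t), exact, atol=1e-10)

    def test_category_split_does_not_perturb_disease_dynamics(self):
        """Unscreened/screened categories with identical disease hazards:
        total disease occupancy must match the single-category model."""
        single = make_two_state(c=0.3, dt=0.01, max_t=5.0)
        ref = run(single).trajectory.state_occupancy("dead")

        m = ModelSpec(states=["alive_u", "alive_s", "dead"],
                      grid=GridSpec(dt=0.01, max_t=5.0, max_tau=5.0))
        for s in ("alive_u", "alive_s"):
            m.add_transition(s, "dead", Hazard("constant", {"c": 0.3}))
        m.add_transition("alive_u", "alive_s", Hazard("constant", {"c": 0.8}),
                         kind="sojourn_preserving")
        m.set_initial_atom("alive_u", 0.0, 1.0)
        got = run(m).trajectory.state_occupancy("dead")
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_sojourn_dependent_mu_conserves_mass(self):
        m = ModelSpec(states=["u", "v"], grid=GridSpec(dt=0.05, max_t=1.0, max_tau=1.0))
        m.add_transition("u", "v", Hazard("weibull", {"b": 0.5, "k": 1.5}),
                         kind="sojourn_preserving")
        m.set_initial_atom("u", 0.0, 1.0)
        res = run(m)
        assert res.diagnostics["conservation_residual"] < 1e-12


class TestConservationProperty:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mass_conserving_scheme_on_random_models(self, seed):
        m = make_random_semi_markov(seed, dt=0.05, max_t=2.0)
        res = run(m)
        assert res.diagnostics["conservation_residual"] < 1e-12
        assert np.all(res.trajectory.occupancy >= -1e-15)
        assert np.all(res.density.values >= -1e-300)


class TestInitialConditions:
    def test_initial_atom_with_existing_sojourn(self):
        # entering with 2 years already accrued shifts the Weibull clock
        m = ModelSpec(states=["A", "B"], grid=GridSpec(dt=0.01, max_t=3.0))
        hz = Hazard("weibull", {"b": 0.2, "k": 2.0})
        m.add_transition("A", "B", hz)
        m.set_initial_atom("A", 2.0, 1.0)
        res = run(m)
        expect = np.exp(-0.2 * ((2.0 + res.trajectory.times) ** 2 - 4.0))
        np.testing.assert_allclose(res.trajectory.state_occupancy("A"), expect, atol=1e-12)

    def test_density_initial_condition_conserved(self):
        m = ModelSpec(states=["A", "B"], grid=GridSpec(dt=0.02, max_t=1.0, max_tau=3.0))
        m.add_transition("A", "B", Hazard("constant", {"c": 0.4}))
        taus = np.arange(0, 2.0 + 1e-9, 0.02)
        dens = np.exp(-taus)
        dens /= 0.02 * dens.sum()
        m.initial.density_samples["A"] = (list(taus), list(dens))
        res = run(m, check_validation=False)
        assert res.diagnostics["conservation_residual"] < 1e-12
        g = res.trajectory.state_occupancy("A")
        np.testing.assert_allclose(g / g[0], np.exp(-0.4 * res.trajectory.times), atol=1e-10)

    def test_validation_failure_aborts_run(self):
        m = ModelSpec(states=["A"], grid=GridSpec(dt=0.1, max_t=1.0, max_tau=1.0))
        m.set_initial_atom("A", 0.0, 0.5)
        with pytest.raises(ModelValidationError):
            run(m)


class TestTruncation:
    def test_terminal_bin_accumulates_instead_of_leaking(self):
        m = ModelSpec(states=["A", "B"], grid=GridSpec(dt=0.1, max_t=10.0, max_tau=2.0))
        m.add_transition("A", "B", Hazard("constant", {"c": 0.05}))
        m.set_initial_atom("A", 0.0, 1.0)
        res = run(m)
        assert res.diagnostics["conservation_residual"] < 1e-12
        # the atom rides past the cap; densities created early also reach it
        assert res.diagnostics["terminal_sojourn_bin_mass"] >= 0.0

    def test_large_step_hazard_warns(self):
        m = make_two_state(c=150.0, dt=0.01, max_t=0.5)
        with pytest.warns(RuntimeWarning, match="per-step cumulative hazard"):
            run(m)


def test_occupancy_trajectory_frame_layout():
    res = run(make_two_state(dt=0.1, max_t=1.0))
    df = res.trajectory.to_frame()
    assert list(df.columns) == ["time", "state", "occupancy", "entry_flux"]
    assert len(df) == 11 * 2
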