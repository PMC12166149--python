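import numpy as np
import pytest

from sojourn import Hazard, ModelSpec
from sojourn.model import GridSpec


def make_two_state(c: float = 0.2, dt: float = 0.001, max_t: float = 10.0) -> ModelSpec:
    m = ModelSpec(states=["alive", "dead"], grid=GridSpec(dt=dt, max_t=max_t, max_tau=max_t))
    m.add_transition("alive", "dead", Hazard("constant", {"c": c}))
    m.set_initial_atom("alive", 0.0, 1.0)
    return m


def make_competing(a: float = 1.0, b: float = 3.0, dt: float = 0.001,
                   max_t: float = 15.0) -> ModelSpec:
    m = ModelSpec(states=["src", "ea", "eb"], grid=GridSpec(dt=dt, max_t=max_t, max_tau=max_t))
    m.add_transition("src", "ea", Hazard("constant", {"c": a}))
    m.add_transition("src", "eb", Hazard("constant", {"c": b}))
    m.set_initial_atom("src", 0.0, 1.0)
    return m


def make_erlang2(c: float = 1.0, dt: float = 0.001, max_t: float = 2.0) -> ModelSpec:
    m = ModelSpec(states=["s1", "s2", "done"], grid=GridSpec(dt=dt, max_t=max_t, max_tau=max_t))
    m.add_transition("s1", "s2", Hazard("constant", {"c": c}))
    m.add_transition("s2", "done", Hazard("constant", {"c": c}))
    m.set_initial_atom("s1", 0.0, 1.0)
    return m


def make_random_semi_markov(seed: int, dt: float = 0.005, max_t: float = 10.0) -> ModelSpec:
    """A randomized 3-4 state progressive model with Weibull/Gompertz hazards."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 5))
    states = [f"s{i}" for i in range(n)]
    m = ModelSpec(states=states, grid=GridSpec(dt=dt, max_t=max_t, max_tau=max_t))
    for i in range(n - 1):
        for j in range(i + 1, n):  # forward transitions only: bounded jump count
            if j > i + 1 and rng.random() < 0.5:
                continue
            if rng.random() < 0.5:
                hz = Hazard("weibull", {"b": float(rng.uniform(0.05, 0.3)),
                                        "k": float(rng.uniform(0.6, 2.0))})
            else:
                hz = Hazard("gompertz", {"p": float(rng.uniform(0.02, 0.15)),
                                         "r": float(rng.uniform(-0.1, 0.12))})
            m.add_transition(states[i], states[j], hz)
    m.set_initial_atom(states[0], 0.0, 1.0)
    return m


@pytest.fixture(scope="session")
def liver_model():
    from sojourn.liver import build_liver_model

    return build_liver_model()
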