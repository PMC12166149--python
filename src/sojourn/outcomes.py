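"""Health-economic and risk summaries computed from a solved trajectory.

Quality-adjusted life-years are utility-weighted time integrals of state
occupancy; entry costs weight the probability of entering a state (the time
integral of the boundary flux); conditional risks restart the solver from the
stored sojourn density at the conditioning time, which is exactly the object
the framework tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .model import GridSpec, InitialCondition, ModelSpec
from .solver import OccupancyTrajectory, SolveResult, run

__all__ = [
    "OutcomeWeights",
    "expected_qalys",
    "entry_probability",
    "expected_entry_cost",
    "conditional_risk",
]


@dataclass
class OutcomeWeights:
    """Per-state utility and cost weights.

    ``qaly`` is in QALY per year in state, ``entry_cost`` in currency per
    entry into the state, ``ongoing_cost`` in currency per year in state.
    ``discount_rate`` is a continuous annual rate applied as ``exp(-d*t)``
    (0 disables discounting).
    """

    qaly: Mapping[str, float] = field(default_factory=dict)
    entry_cost: Mapping[str, float] = field(default_factory=dict)
    ongoing_cost: Mapping[str, float] = field(default_factory=dict)
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        import warnings

        for name, tbl in (("entry_cost", self.entry_cost), ("ongoing_cost", self.ongoing_cost)):
            for s, v in tbl.items():
                if not math.isfinite(v):
                    raise ValueError(f"{name}[{s!r}] must be finite")
                if v < 0:
                    warnings.warn(f"negative {name} for state {s!r}", stacklevel=2)
        for s, v in self.qaly.items():
            if not math.isfinite(v):
                raise ValueError(f"qaly[{s!r}] must be finite")


def _window_indices(traj: OccupancyTrajectory, t0: float, t1: float):
    dt = traj.dt
    if t0 < traj.times[0] - 1e-9 or t1 > traj.times[-1] + 1e-9 or t1 < t0:
        raise ValueError(f"window [{t0}, {t1}] outside solved horizon "
                         f"[{traj.times[0]}, {traj.times[-1]}]")
    m0 = int(round(t0 / dt))
    m1 = int(round(t1 / dt))
    for m, t in ((m0, t0), (m1, t1)):
        if abs(m * dt - t) > 1e-9 + 1e-9 * abs(t):
            raise ValueError(f"window endpoint {t} is not on the time grid (dt={dt})")
    return m0, m1


def _discount(times: np.ndarray, rate: float) -> np.ndarray:
    return np.exp(-rate * times) if rate else np.ones_like(times)


def expected_qalys(traj: OccupancyTrajectory, weights: OutcomeWeights,
                   t0: float, t1: float) -> float:
    """Utility-weighted occupancy-time integral over ``[t0, t1]`` (trapezoid)."""
    m0, m1 = _window_indices(traj, t0, t1)
    if m0 == m1:
        return 0.0
    disc = _discount(traj.times[m0:m1 + 1], weights.discount_rate)
    out = 0.0
    for s, x in weights.qaly.items():
        gi = traj.occupancy[m0:m1 + 1, traj.states.index(s)]
        out += x * float(np.trapezoid(gi * disc, dx=traj.dt))
    return out


def entry_probability(traj: OccupancyTrajectory, state: str,
                      t0: float, t1: float) -> float:
    """Probability of entering ``state`` during ``(t0, t1]``.

    Integrates the boundary flux with the scheme's own mass accounting (one
    rectangle per step), so for an absorbing target it equals
    ``g(t1) - g(t0)`` exactly.
    """
    m0, m1 = _window_indices(traj, t0, t1)
    i = traj.states.index(state)
    return float(traj.dt * traj.entry_flux[m0 + 1:m1 + 1, i].sum())


def expected_entry_cost(traj: OccupancyTrajectory, weights: OutcomeWeights,
                        t0: float, t1: float) -> float:
    """Entry costs plus ongoing per-year costs over the window (discounted)."""
    m0, m1 = _window_indices(traj, t0, t1)
    disc_step = _discount(traj.times, weights.discount_rate)
    out = 0.0
    for s, alpha in weights.entry_cost.items():
        i = traj.states.index(s)
        out += alpha * float(traj.dt * np.dot(traj.entry_flux[m0 + 1:m1 + 1, i],
                                              disc_step[m0 + 1:m1 + 1]))
    if weights.ongoing_cost and m1 > m0:
        disc = disc_step[m0:m1 + 1]
        for s, c in weights.ongoing_cost.items():
            gi = traj.occupancy[m0:m1 + 1, traj.states.index(s)]
            out += c * float(np.trapezoid(gi * disc, dx=traj.dt))
    return out


def conditional_risk(result: SolveResult, model: ModelSpec,
                     event_states: Iterable[str], horizon: float,
                     condition_states: Iterable[str], t: float,
                     scheme: str | None = None) -> float:
    """Probability of being in one of ``event_states`` at ``t + horizon``,
    conditional on being in ``condition_states`` at time ``t``.

    The solver is restarted from the stored sojourn density at ``t``,
    restricted to the conditioning states and renormalised; the sojourn
    distribution accumulated up to ``t`` is retained, which is the entire
    point of tracking the density.
    """
    event_states = list(event_states)
    condition_states = list(condition_states)
    for s in event_states + condition_states:
        model.index(s)  # raises for unknown states
    grid = result.density
    if grid.history is None:
        raise ValueError("conditional_risk needs a solve with store_history=True")
    dt = grid.dt
    m = int(round(t / dt))
    if abs(m * dt - t) > 1e-9 or not (0 <= m < grid.history.shape[0]):
        raise ValueError(f"t={t} is not on the solved grid")

    F_t = grid.history[m]
    atom_tau = grid.atom_tau_history[m]
    atom_m = grid.atom_mass_history[m].copy()
    keep = np.array([s in condition_states for s in grid.states])
    F_c = np.where(keep[:, None], F_t, 0.0)
    atom_m = np.where(keep[None, :], atom_m, 0.0)
    mass = dt * F_c.sum() + atom_m.sum()
    if mass <= 0:
        raise ValueError(f"no probability mass in {condition_states} at t={t}")
    F_c = F_c / mass
    atom_m = atom_m / mass

    from .model import Atom

    init = InitialCondition(
        atoms=[Atom(s, float(atom_tau[a]), float(atom_m[a, i]))
               for a in range(len(atom_tau))
               for i, s in enumerate(grid.states) if atom_m[a, i] > 0],
        density_cells={s: F_c[i].copy() for i, s in enumerate(grid.states)},
        density_cells_dt=dt)

    sub = ModelSpec(states=list(model.states),
                    grid=GridSpec(dt=dt, max_t=horizon,
                                  max_tau=(F_c.shape[1] - 1) * dt + horizon),
                    initial=init)
    sub.transitions = list(model.transitions)
    res = run(sub, scheme=scheme or result.scheme, t_offset=t + result.t_offset,
              check_validation=False)
    g_end = res.trajectory.occupancy[-1]
    return float(sum(g_end[sub.index(s)] for s in event_states))
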