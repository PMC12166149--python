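"""Independent brute-force oracles for the test suite.

* :func:`mc_sample` -- a Monte-Carlo semi-Markov trajectory sampler.  Sojourn
  times are drawn by inverse transform on the overall survival along each
  entry characteristic (monotone bisection on the closed-form cumulative
  hazard), which stays exact even for hazards that are unbounded at tau = 0;
  the cause is then drawn from the per-cause hazard shares at the drawn
  instant.  The sampler consumes the same Hazard objects as the transport
  solver, so the two routes share a single model specification.
* :func:`ode_oracle_sir` -- a high-accuracy adaptive ODE integration of the
  classical SIR system, for cross-checking occupancy-coupled models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .hazards import CouplingError
from .model import ModelSpec

__all__ = ["mc_sample", "ode_oracle_sir"]

_BISECT_TOL = 1e-10
_MAX_JUMPS = 64


def _state_cumulative(model: ModelSpec, state: str, entry, tau):
    """Total cumulative hazard of `state` over sojourn [0, tau], vectorised
    over parallel (entry, tau) arrays."""
    out = np.zeros(np.broadcast_shapes(np.shape(entry), np.shape(tau)))
    for tr in model.transitions_from(state):
        out = out + tr.hazard.cumulative(np.maximum(entry, 0.0), 0.0, tau)
    return out


def _record(rec: np.ndarray, times: np.ndarray, traj: np.ndarray,
            t_lo: np.ndarray, t_hi: np.ndarray, state_i: int) -> None:
    """Mark rec[traj, k] = state_i for all requested times in [t_lo, t_hi)."""
    mask = (times[None, :] >= t_lo[:, None] - 1e-12) & (times[None, :] < t_hi[:, None])
    sub = rec[traj]
    sub[mask] = state_i
    rec[traj] = sub


def mc_sample(model: ModelSpec, n_trajectories: int, horizon: float, seed: int,
              times=None) -> pd.DataFrame:
    """Estimate state occupancies by sampling semi-Markov trajectories.

    Returns a tidy frame with columns ``time, state, occupancy, se`` where
    ``se`` is the binomial standard error ``sqrt(p(1-p)/n)``.

    Randomness comes from a counter-based Philox generator keyed on ``seed``;
    all per-trajectory uniforms are drawn up front into a (trajectory, jump)
    table, each trajectory consuming its own row, so results do not depend on
    the order trajectories are advanced in.

    Sojourn-preserving transitions are sampled like resetting ones except
    that the destination inherits the sojourn clock.
    """
    if model.is_coupled:
        raise CouplingError("mc_sample does not support occupancy-coupled hazards")
    if times is None:
        times = [horizon]
    times = np.asarray(times, float)
    if np.any(times > horizon + 1e-12):
        raise ValueError("all requested times must be within the horizon")
    rng = np.random.Generator(np.random.Philox(key=seed))
    U = rng.random((n_trajectories, _MAX_JUMPS, 2))

    # draw initial (state, sojourn) from the initial condition components
    init = model.initial
    comps: list[tuple[str, object, float]] = [(a.state, a.sojourn, a.mass) for a in init.atoms]
    for s, (taus, vals) in init.density_samples.items():
        taus = np.asarray(taus, float)
        vals = np.asarray(vals, float)
        comps.append((s, ("density", taus, vals), float(np.trapezoid(vals, taus))))
    masses = np.array([c[2] for c in comps])
    pick = rng.choice(len(comps), size=n_trajectories, p=masses / masses.sum())
    current = np.empty(n_trajectories, dtype=int)
    sojourn0 = np.zeros(n_trajectories)
    for c, (s, tau_c, _w) in enumerate(comps):
        sel = pick == c
        current[sel] = model.index(s)
        if isinstance(tau_c, tuple):
            _tag, taus, vals = tau_c
            cdf = np.concatenate([[0.0], np.cumsum((vals[1:] + vals[:-1]) / 2 * np.diff(taus))])
            sojourn0[sel] = np.interp(rng.random(int(sel.sum())) * cdf[-1], cdf, taus)
        else:
            sojourn0[sel] = float(tau_c)

    entry = -sojourn0            # model time the current state was entered
    clock = np.zeros(n_trajectories)  # model time reached so far
    rec = np.full((n_trajectories, len(times)), -1, dtype=int)
    active = np.ones(n_trajectories, dtype=bool)
    used = np.zeros(n_trajectories, dtype=int)  # per-trajectory draws consumed
    eps = 1e-9 * max(horizon, 1.0)

    for _round in range(_MAX_JUMPS):
        if not active.any():
            break
        for i, s in enumerate(model.states):
            idx = np.where(active & (current == i))[0]
            if idx.size == 0:
                continue
            trs = model.transitions_from(s)
            if not trs:  # absorbing: occupy s for all remaining times
                _record(rec, times, idx, clock[idx], np.full(idx.size, np.inf), i)
                active[idx] = False
                continue
            if used[idx].max() >= _MAX_JUMPS:  # pragma: no cover - defensive
                raise RuntimeError("MC sampler exhausted its per-trajectory draw budget")
            ent = entry[idx]
            tau_now = clock[idx] - ent
            E = -np.log(U[idx, used[idx], 0])
            target = _state_cumulative(model, s, ent, tau_now) + E
            cap = horizon - ent + eps   # sojourn at which model time passes the horizon
            transits = _state_cumulative(model, s, ent, cap) >= target

            ti = idx[transits]
            if ti.size:
                a = tau_now[transits].copy()
                b = cap[transits].copy()
                tgt = target[transits]
                ent_t = ent[transits]
                for _ in range(100):
                    mid = 0.5 * (a + b)
                    go_up = _state_cumulative(model, s, ent_t, mid) < tgt
                    a = np.where(go_up, mid, a)
                    b = np.where(go_up, b, mid)
                    if float(np.max(b - a)) < _BISECT_TOL:
                        break
                tau_star = 0.5 * (a + b)
                t_star = ent_t + tau_star
                # cause draw from per-cause hazard shares at the drawn instant
                rates = np.stack([np.broadcast_to(np.asarray(
                    tr.hazard.rate(np.maximum(t_star, 0.0), tau_star), float), t_star.shape)
                    for tr in trs])
                tot = rates.sum(axis=0)
                shares = rates / np.where(tot > 0, tot, 1.0)
                cause = np.minimum((U[ti, used[ti], 1][None, :] > np.cumsum(shares, axis=0)).sum(axis=0),
                                   len(trs) - 1)
                _record(rec, times, ti, clock[ti], t_star, i)
                preserving = np.array([trs[c].kind == "sojourn_preserving" for c in cause])
                current[ti] = np.array([model.index(trs[c].target) for c in cause])
                clock[ti] = t_star
                entry[ti] = np.where(preserving, entry[ti], t_star)
                used[ti] += 1
            si = idx[~transits]
            if si.size:  # no further transition before the horizon
                _record(rec, times, si, clock[si], np.full(si.size, np.inf), i)
                active[si] = False
                used[si] += 1
        active &= clock <= horizon + eps

    if (rec < 0).any():  # pragma: no cover - defensive
        raise RuntimeError("MC sampler exhausted the jump budget before the horizon")

    rows = []
    for k, t in enumerate(times):
        for i, s in enumerate(model.states):
            p = float(np.mean(rec[:, k] == i))
            rows.append({"time": t, "state": s, "occupancy": p,
                         "se": float(np.sqrt(p * (1 - p) / n_trajectories))})
    return pd.DataFrame(rows)


def ode_oracle_sir(beta: float, gamma: float, initial, horizon: float,
                   tolerance: float = 1e-10, t_eval=None) -> pd.DataFrame:
    """Adaptive high-order integration of dS/dt = -beta S I, dI/dt = beta S I
    - gamma I, dR/dt = gamma I.  ``initial`` is (g_S, g_I, g_R) summing to 1."""
    g0 = np.asarray(initial, float)
    if abs(g0.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancies must sum to 1")

    def rhs(_t, y):
        S, I, _R = y
        return [-beta * S * I, beta * S * I - gamma * I, gamma * I]

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 201)
    sol = solve_ivp(rhs, (0.0, horizon), g0, method="DOP853",
                    rtol=tolerance, atol=tolerance, t_eval=np.asarray(t_eval, float))
    return pd.DataFrame({"time": sol.t, "g_S": sol.y[0], "g_I": sol.y[1], "g_R": sol.y[2]})
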