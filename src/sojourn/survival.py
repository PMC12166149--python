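"""Characteristic-wise survival quantities.

Everything here lives on a single characteristic: an individual enters state
``i`` at model time ``t0`` (sojourn 0) and we follow the line ``t = t0 + tau``.
Overall survival is ``exp(-Lambda_i)`` with ``Lambda_i`` the summed cumulative
hazard of all transitions leaving ``i``; cause-specific survival censors the
competing transitions.  The same closed-form segment integrals used by the
transport solver are used here, so the two routes cannot disagree by
quadrature choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .hazards import CouplingError
from .model import ModelSpec

__all__ = [
    "CharacteristicFrame",
    "cumulative_hazard",
    "overall_survival",
    "cause_specific_survival",
    "time_to_event_density",
    "next_transition_cdf",
    "next_transition_prob",
    "NextTransition",
]


@dataclass(frozen=True)
class CharacteristicFrame:
    """Entry of one individual into ``state`` at model time ``entry_time``."""

    state: str
    entry_time: float = 0.0
    horizon: float = np.inf

    def __post_init__(self) -> None:
        if self.entry_time < 0:
            raise ValueError("entry_time must be >= 0")
        if self.horizon < self.entry_time:
            raise ValueError("horizon must be >= entry_time")


def _outgoing(model: ModelSpec, frame: CharacteristicFrame, target: str | None = None):
    trs = [t for t in model.transitions if t.source == frame.state]
    if target is not None:
        trs = [t for t in trs if t.target == target]
        if not trs:
            raise KeyError(f"no transition {frame.state!r} -> {target!r}")
    for t in trs:
        if t.hazard.is_coupled:
            raise CouplingError(
                "survival quantities are undefined for occupancy-coupled hazards; "
                "solve the full model instead")
    return trs


def cumulative_hazard(model: ModelSpec, frame: CharacteristicFrame, tau,
                      target: str | None = None):
    """Cumulative hazard over sojourn ``[0, tau]`` along the entry characteristic.

    Summed over all transitions leaving the state, or restricted to
    ``target`` if given.  Vectorised over ``tau``.
    """
    tau = np.asarray(tau, float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    out = np.zeros(tau.shape)
    for t in _outgoing(model, frame, target):
        out = out + t.hazard.cumulative(frame.entry_time, 0.0, tau)
    return out if out.shape else float(out)


def overall_survival(model: ModelSpec, frame: CharacteristicFrame, tau):
    """Probability that no transition has occurred ``tau`` after entry."""
    return np.exp(-cumulative_hazard(model, frame, tau))


def cause_specific_survival(model: ModelSpec, frame: CharacteristicFrame,
                            target: str, tau):
    """Survival with all competing transitions censored, ``exp(-Lambda_ij)``."""
    return np.exp(-cumulative_hazard(model, frame, tau, target=target))


def time_to_event_density(model: ModelSpec, frame: CharacteristicFrame,
                          target: str, tau):
    """Sub-density of the next transition being to ``target`` at sojourn tau:
    ``lambda_ij(t0+tau, tau) * S_i(tau)`` (units 1/year)."""
    trs = _outgoing(model, frame, target)
    tau = np.asarray(tau, float)
    rate = np.zeros(tau.shape)
    for t in trs:
        rate = rate + t.hazard.rate(frame.entry_time + tau, tau)
    out = rate * overall_survival(model, frame, tau)
    return out if out.shape else float(out)


def _kink_points(model: ModelSpec, frame: CharacteristicFrame, lo: float, hi: float):
    pts = set()
    for t in model.transitions:
        if t.source != frame.state:
            continue
        for var, pos in t.hazard.breakpoints():
            s = pos - frame.entry_time if var == "model_time" else pos
            if lo < s < hi:
                pts.add(float(s))
    return sorted(pts)


def next_transition_cdf(model: ModelSpec, frame: CharacteristicFrame,
                        target: str, t: float) -> float:
    """P(next transition is to ``target`` and happens before model time t)."""
    if t < frame.entry_time:
        raise ValueError("t must be >= the entry time")
    hi = t - frame.entry_time
    if hi == 0.0:
        return 0.0
    pts = _kink_points(model, frame, 0.0, hi)
    val, _ = integrate.quad(
        lambda s: float(time_to_event_density(model, frame, target, s)),
        0.0, hi, points=pts or None, limit=200)
    return val


@dataclass(frozen=True)
class NextTransition:
    """A truncated improper integral: ``prob`` plus an upper bound on the
    probability mass beyond the evaluation horizon."""

    prob: float
    tail_bound: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.prob


def next_transition_prob(model: ModelSpec, frame: CharacteristicFrame,
                         target: str, horizon: float = 200.0) -> NextTransition:
    """Likelihood that the next transition is to ``target`` (horizon-truncated).

    The tail beyond ``horizon`` is bounded by the overall survival there,
    which is reported rather than silently dropped.
    """
    prob = next_transition_cdf(model, frame, target, frame.entry_time + horizon)
    tail = float(overall_survival(model, frame, horizon))
    return NextTransition(prob=prob, tail_bound=tail)
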