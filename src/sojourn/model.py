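"""Declarative specification of a sojourn density model.

A model is a labelled state space, a set of transitions carrying hazard
functions, an initial distribution over (state, sojourn time), and a grid
definition for the transport solver.  Transitions come in two kinds:

* ``sojourn_resetting`` -- the usual disease transitions; the destination
  state's sojourn clock restarts at 0.
* ``sojourn_preserving`` -- category changes (e.g. entering surveillance)
  that carry the sojourn clock across unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hazards import Hazard

__all__ = [
    "Transition",
    "Atom",
    "InitialCondition",
    "GridSpec",
    "ModelSpec",
    "Diagnostic",
    "validate_model",
]

KINDS = ("sojourn_resetting", "sojourn_preserving")


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    hazard: Hazard
    kind: str = "sojourn_resetting"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop {self.source!r} -> {self.target!r} is not allowed")
        if self.kind not in KINDS:
            raise ValueError(f"transition kind must be one of {KINDS}")


@dataclass(frozen=True)
class Atom:
    """A Dirac point mass at ``(state, sojourn)`` in the initial condition."""

    state: str
    sojourn: float
    mass: float

    def __post_init__(self) -> None:
        if self.sojourn < 0 or self.mass < 0:
            raise ValueError("atom sojourn and mass must be >= 0")


@dataclass
class InitialCondition:
    """Initial distribution over (state, sojourn time).

    ``atoms`` are first-class Dirac components (the common "no existing
    sojourn" start is a single atom at tau = 0).  ``density_samples`` gives a
    tabulated density per state as ``(tau_points, density_values)`` pairs;
    ``density_cells`` is the solver-internal grid-aligned form used when
    restarting from a stored density.
    """

    atoms: list[Atom] = field(default_factory=list)
    density_samples: dict[str, tuple[Sequence[float], Sequence[float]]] = field(default_factory=dict)
    density_cells: dict[str, np.ndarray] | None = None
    density_cells_dt: float | None = None

    def total_mass(self) -> float:
        mass = sum(a.mass for a in self.atoms)
        for taus, vals in self.density_samples.values():
            mass += float(np.trapezoid(np.asarray(vals, float), np.asarray(taus, float)))
        if self.density_cells is not None:
            for v in self.density_cells.values():
                mass += float(np.sum(v) * self.density_cells_dt)
        return mass

    def max_sojourn(self) -> float:
        out = 0.0
        for a in self.atoms:
            out = max(out, a.sojourn)
        for taus, _ in self.density_samples.values():
            out = max(out, float(np.max(np.asarray(taus, float))))
        if self.density_cells is not None:
            for v in self.density_cells.values():
                out = max(out, len(v) * (self.density_cells_dt or 0.0))
        return out


@dataclass
class GridSpec:
    dt: float
    max_t: float
    max_tau: float | None = None  # default: max_t + largest initial sojourn


@dataclass
class Diagnostic:
    level: str  # "error" | "warning"
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.level}] {self.field}: {self.message}"


class ModelSpec:
    """Builder-style container for states, transitions, initial condition, grid."""

    def __init__(self, states: Sequence[str] = (), grid: GridSpec | None = None,
                 initial: InitialCondition | None = None) -> None:
        self.states: list[str] = []
        self.transitions: list[Transition] = []
        self.initial: InitialCondition = initial or InitialCondition()
        self.grid: GridSpec = grid or GridSpec(dt=0.01, max_t=10.0)
        for s in states:
            self.add_state(s)

    # ----------------------------------------------------------------- build
    def add_state(self, name) -> "ModelSpec":
        if isinstance(name, (list, tuple)):
            for n in name:
                self.add_state(n)
            return self
        if name in self.states:
            raise ValueError(f"state {name!r} already defined")
        self.states.append(str(name))
        return self

    def add_transition(self, source: str, target: str, hazard: Hazard,
                       kind: str = "sojourn_resetting") -> "ModelSpec":
        for s in (source, target):
            if s not in self.states:
                raise KeyError(f"unknown state {s!r}; defined states: {self.states}")
        tr = Transition(source, target, hazard, kind)
        if any(t.source == source and t.target == target and t.kind == kind
               for t in self.transitions):
            raise ValueError(f"duplicate transition {source!r} -> {target!r} ({kind})")
        self.transitions.append(tr)
        return self

    def set_initial_atom(self, state: str, sojourn: float = 0.0, mass: float = 1.0) -> "ModelSpec":
        if state not in self.states:
            raise KeyError(f"unknown state {state!r}")
        self.initial.atoms.append(Atom(state, sojourn, mass))
        return self

    # ----------------------------------------------------------------- query
    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}") from None

    def transitions_from(self, state: str, kind: str | None = None) -> list[Transition]:
        return [t for t in self.transitions
                if t.source == state and (kind is None or t.kind == kind)]

    def is_absorbing(self, state: str) -> bool:
        return not self.transitions_from(state)

    @property
    def has_preserving(self) -> bool:
        return any(t.kind == "sojourn_preserving" for t in self.transitions)

    @property
    def is_coupled(self) -> bool:
        return any(t.hazard.is_coupled for t in self.transitions)

    def resolved_max_tau(self) -> float:
        if self.grid.max_tau is not None:
            return self.grid.max_tau
        return self.grid.max_t + self.initial.max_sojourn()

    # -------------------------------------------------------------- validate
    def validate(self) -> list[Diagnostic]:
        return validate_model(self)

    def __eq__(self, other) -> bool:
        from .config import model_to_dict

        if not isinstance(other, ModelSpec):
            return NotImplemented
        return model_to_dict(self) == model_to_dict(other)


def _is_multiple(x: float, dt: float, tol: float = 1e-9) -> bool:
    q = x / dt
    return abs(q - round(q)) < tol


def validate_model(model: ModelSpec) -> list[Diagnostic]:
    """Diagnostic sweep over a model; returns an empty list iff fully valid.

    Errors: unnormalised initial mass, bad grid, coupled hazards referencing
    unknown states.  Warnings: states unreachable from the initial support,
    no absorbing state (mass can pile up at the sojourn cap), sojourn cap
    shorter than the horizon requires.
    """
    diags: list[Diagnostic] = []
    if not model.states:
        diags.append(Diagnostic("error", "states", "model has no states"))
        return diags

    mass = model.initial.total_mass()
    if not math.isclose(mass, 1.0, abs_tol=1e-12):
        diags.append(Diagnostic(
            "error", "initial",
            f"initial (state, sojourn) mass must sum to 1, got {mass:.6g}"))
    for a in model.initial.atoms:
        if a.state not in model.states:
            diags.append(Diagnostic("error", "initial.atoms", f"unknown state {a.state!r}"))
    for s in model.initial.density_samples:
        if s not in model.states:
            diags.append(Diagnostic("error", "initial.density_samples", f"unknown state {s!r}"))

    g = model.grid
    if g.dt <= 0:
        diags.append(Diagnostic("error", "grid.dt", f"dt must be > 0, got {g.dt}"))
    else:
        if g.max_t <= 0 or not _is_multiple(g.max_t, g.dt):
            diags.append(Diagnostic("error", "grid.max_t", "max_t must be a positive multiple of dt"))
        mt = model.resolved_max_tau()
        if mt <= 0 or not _is_multiple(mt, g.dt):
            diags.append(Diagnostic("error", "grid.max_tau", "max_tau must be a positive multiple of dt"))
        elif mt < g.max_t + model.initial.max_sojourn() - 1e-12:
            diags.append(Diagnostic(
                "warning", "grid.max_tau",
                "max_tau is shorter than max_t + the largest initial sojourn; "
                "density reaching the cap accumulates in the terminal sojourn bin"))

    for t in model.transitions:
        for cs in t.hazard.coupling_states:
            if cs not in model.states:
                diags.append(Diagnostic(
                    "error", "transitions",
                    f"hazard {t.source!r}->{t.target!r} couples to unknown state {cs!r}"))

    # reachability from initial support
    support = {a.state for a in model.initial.atoms if a.mass > 0}
    support |= {s for s, (_, v) in model.initial.density_samples.items() if np.any(np.asarray(v) > 0)}
    if model.initial.density_cells:
        support |= {s for s, v in model.initial.density_cells.items() if np.any(v > 0)}
    frontier = list(support)
    reach = set(support)
    while frontier:
        s = frontier.pop()
        for t in model.transitions:
            if t.source == s and t.target not in reach:
                reach.add(t.target)
                frontier.append(t.target)
    for s in model.states:
        if s not in reach:
            diags.append(Diagnostic("warning", "states", f"state {s!r} unreachable from initial support"))

    if model.states and not any(model.is_absorbing(s) for s in model.states):
        diags.append(Diagnostic(
            "warning", "transitions",
            "no absorbing state: long-run mass may pile at the sojourn cap"))
    return diags
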