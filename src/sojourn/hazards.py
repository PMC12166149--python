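"""Cause-specific hazard rates and their cumulative integrals along characteristics.

A hazard rate ``lambda_ij(t, tau)`` is the instantaneous rate of the transition
``i -> j`` for an individual who has spent sojourn time ``tau`` in state ``i``
at model time ``t``.  All survival and transport computations in this package
reduce to integrating hazards along *characteristics* -- lines in the ``(t,
tau)`` plane on which model time and sojourn time advance together.  For the
parametric families provided here those integrals are available in closed
form, which keeps both the transport solver and the survival utilities free of
quadrature error wherever the model permits it.

Units are years throughout: rates are ``1/year`` and cumulative hazards are
dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "Hazard",
    "Modifier",
    "CouplingError",
    "eval_hazard",
    "cumulative_hazard_segment",
    "total_hazard",
]

FAMILIES = (
    "constant",
    "weibull",
    "gompertz",
    "polynomial_in_sojourn",
    "piecewise_linear_in_time",
    "piecewise_constant",
    "tabulated",
    "product_of_hazards",
)

MODIFIER_KINDS = ("proportional", "lead_time_zero", "lead_time_linear", "mass_proportional")

#: variable each family naturally depends on; ``None`` means "either"
_FAMILY_VARIABLE = {
    "constant": None,
    "weibull": "sojourn",
    "gompertz": "sojourn",
    "polynomial_in_sojourn": "sojourn",
    "piecewise_linear_in_time": "model_time",
    "piecewise_constant": None,
    "tabulated": "model_time",
    "product_of_hazards": None,
}


class CouplingError(ValueError):
    """An occupancy-coupled hazard was evaluated without the occupancy vector."""


@dataclass(frozen=True)
class Modifier:
    """A transformation applied on top of a base hazard rate.

    kinds
    -----
    ``proportional``
        Multiply the rate by ``exp(log_hr)`` (a Cox-style hazard ratio).
    ``lead_time_zero``
        Zero below the lead-time cutoff ``tau0``; above it the base rate is
        evaluated at the shifted sojourn ``tau - tau0``.
    ``lead_time_linear``
        Ramp the base rate linearly from 0 at ``tau = 0`` to its full value at
        ``tau = tau0``.
    ``mass_proportional``
        Multiply the rate by ``beta * g_c(t)`` where ``g_c`` is the occupancy
        of ``coupling_state`` (e.g. the force of infection in an SIR model).
    """

    kind: str
    log_hr: float = 0.0
    tau0: float = 0.0
    coupling_state: str | None = None
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in MODIFIER_KINDS:
            raise ValueError(f"unknown modifier kind {self.kind!r}; options: {MODIFIER_KINDS}")
        if self.kind in ("lead_time_zero", "lead_time_linear") and self.tau0 < 0:
            raise ValueError("lead-time cutoff tau0 must be >= 0")
        if self.kind == "mass_proportional" and not self.coupling_state:
            raise ValueError("mass_proportional modifier must declare exactly one coupling state")


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_domain(t, tau) -> None:
    if np.any(_as_float_array(t) < 0) or np.any(_as_float_array(tau) < 0):
        raise ValueError("hazards are defined for t >= 0 and tau >= 0")


def _piecewise_antiderivative(edges: np.ndarray, slopes: np.ndarray, intercepts: np.ndarray, x):
    """Exact antiderivative of a piecewise-linear function of one variable.

    Pieces are half-open ``[edges[k], edges[k+1])`` with the last piece
    extending to infinity; on piece ``k`` the value is
    ``slopes[k] * x + intercepts[k]``.  ``edges[0]`` must be 0.
    """
    x = _as_float_array(x)
    # exact cumulative integral up to each edge
    if len(edges) > 1:
        widths = np.diff(edges)
        seg_int = slopes[:-1] * (edges[1:] ** 2 - edges[:-1] ** 2) / 2 + intercepts[:-1] * widths
        cum_at_edge = np.concatenate([[0.0], np.cumsum(seg_int)])
    else:
        cum_at_edge = np.array([0.0])
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 1)
    x0 = edges[idx]
    return cum_at_edge[idx] + slopes[idx] * (x ** 2 - x0 ** 2) / 2 + intercepts[idx] * (x - x0)


@dataclass(frozen=True)
class Hazard:
    """A parametric cause-specific hazard rate with optional modifiers.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.  Parameterisations: ``constant`` rate ``c``;
        ``weibull`` rate ``b*k*tau**(k-1)``; ``gompertz`` rate ``p*exp(r*tau)``;
        ``polynomial_in_sojourn`` rate ``c0 + c1*tau + c2*tau**2``;
        ``piecewise_linear_in_time`` with ``breaks``/``slopes``/``intercepts``;
        ``piecewise_constant`` with ``breaks``/``values`` in the variable named
        by ``dependence``; ``tabulated`` with ``ages``/``rates`` indexed by
        age ``a0 + t``; ``product_of_hazards`` with ``components`` (a sequence
        of hazards whose rates multiply).
    dependence
        Which clock the rate varies with (``sojourn``, ``model_time`` or
        ``both``).  For most families this is implied and only
        ``piecewise_constant`` consults it.
    age_offset
        Age at model time 0, used by ``tabulated`` hazards (age = a0 + t).
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)
    dependence: str = "sojourn"
    age_offset: float = 0.0
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown hazard family {self.family!r}; options: {FAMILIES}")
        if self.dependence not in ("sojourn", "model_time", "both"):
            raise ValueError("dependence must be 'sojourn', 'model_time' or 'both'")
        object.__setattr__(self, "modifiers", tuple(self.modifiers))
        self._validate_params()

    # ------------------------------------------------------------------ setup
    def _validate_params(self) -> None:
        p = self.params
        need = {
            "constant": ("c",),
            "weibull": ("b", "k"),
            "gompertz": ("p", "r"),
            "polynomial_in_sojourn": ("c0", "c1", "c2"),
            "piecewise_linear_in_time": ("breaks", "slopes", "intercepts"),
            "piecewise_constant": ("breaks", "values"),
            "tabulated": ("ages", "rates"),
            "product_of_hazards": ("components",),
        }[self.family]
        missing = [k for k in need if k not in p]
        if missing:
            raise ValueError(f"{self.family} hazard missing params {missing}")
        if self.family in ("piecewise_linear_in_time", "piecewise_constant"):
            breaks = _as_float_array(p["breaks"])
            if breaks.size and (np.any(np.diff(breaks) <= 0) or np.any(breaks <= 0)):
                raise ValueError("piecewise breakpoints must be strictly increasing and positive")
        if self.family == "tabulated":
            ages = _as_float_array(p["ages"])
            if np.any(np.diff(ages) <= 0):
                raise ValueError("tabulated ages must be strictly increasing")

    # -------------------------------------------------------------- structure
    @property
    def variable(self) -> str | None:
        """The clock the *base* family varies with, or None if constant."""
        fam_var = _FAMILY_VARIABLE[self.family]
        if self.family == "piecewise_constant":
            return self.dependence if self.dependence != "both" else "both"
        if self.family == "product_of_hazards":
            vs = {c.variable for c in self.components if c.variable is not None}
            if not vs:
                return None
            return vs.pop() if len(vs) == 1 else "both"
        return fam_var

    @property
    def components(self) -> tuple["Hazard", ...]:
        if self.family != "product_of_hazards":
            raise AttributeError("components only defined for product_of_hazards")
        return tuple(self.params["components"])

    @property
    def is_coupled(self) -> bool:
        """True when the rate depends on the current state occupancy."""
        if any(m.kind == "mass_proportional" for m in self.modifiers):
            return True
        if self.family == "product_of_hazards":
            return any(c.is_coupled for c in self.components)
        return False

    @property
    def coupling_states(self) -> tuple[str, ...]:
        out = [m.coupling_state for m in self.modifiers if m.kind == "mass_proportional"]
        if self.family == "product_of_hazards":
            for c in self.components:
                out.extend(c.coupling_states)
        return tuple(s for s in out if s)

    def effective_dependence(self) -> str:
        """Solver-facing classification: which clocks the *modified* rate varies with."""
        dep_sojourn = self.variable in ("sojourn", "both")
        dep_time = self.variable in ("model_time", "both")
        for m in self.modifiers:
            if m.kind in ("lead_time_zero", "lead_time_linear"):
                dep_sojourn = True
            if m.kind == "mass_proportional":
                dep_time = True
        if dep_sojourn and dep_time:
            return "both"
        if dep_time:
            return "model_time"
        if dep_sojourn:
            return "sojourn"
        return "constant"

    @property
    def has_closed_form(self) -> bool:
        if any(m.kind == "lead_time_linear" for m in self.modifiers):
            return self.family == "constant"
        if self.is_coupled:
            return False
        if self.family == "product_of_hazards":
            nontrivial = [c for c in self.components if c.variable is not None]
            return len(nontrivial) <= 1 and all(c.has_closed_form for c in self.components)
        return True

    def breakpoints(self) -> tuple[tuple[str, float], ...]:
        """Kink locations as (variable, position) pairs, for quadrature splitting."""
        out: list[tuple[str, float]] = []
        if self.family == "piecewise_linear_in_time":
            out += [("model_time", float(b)) for b in self.params["breaks"]]
        elif self.family == "piecewise_constant":
            var = "sojourn" if self.dependence == "sojourn" else "model_time"
            out += [(var, float(b)) for b in self.params["breaks"]]
        elif self.family == "tabulated":
            out += [("model_time", float(a) - self.age_offset) for a in self.params["ages"]]
        elif self.family == "product_of_hazards":
            for c in self.components:
                out += list(c.breakpoints())
        for m in self.modifiers:
            if m.kind in ("lead_time_zero", "lead_time_linear"):
                out.append(("sojourn", m.tau0))
        return tuple(out)

    def with_multiplier(self, hazard_ratio: float) -> "Hazard":
        """Return a copy with an extra proportional modifier ``rate * hazard_ratio``."""
        if hazard_ratio <= 0:
            raise ValueError("proportional multiplier must be > 0")
        mod = Modifier("proportional", log_hr=math.log(hazard_ratio))
        return replace(self, modifiers=self.modifiers + (mod,))

    # ------------------------------------------------------------- evaluation
    def _base_rate(self, t, tau):
        t = _as_float_array(t)
        tau = _as_float_array(tau)
        p = self.params
        if self.family == "constant":
            return np.broadcast_to(float(p["c"]), np.broadcast_shapes(t.shape, tau.shape)).copy()
        if self.family == "weibull":
            b, k = float(p["b"]), float(p["k"])
            with np.errstate(divide="ignore"):
                return b * k * tau ** (k - 1.0)
        if self.family == "gompertz":
            return float(p["p"]) * np.exp(float(p["r"]) * tau)
        if self.family == "polynomial_in_sojourn":
            return float(p["c0"]) + float(p["c1"]) * tau + float(p["c2"]) * tau ** 2
        if self.family == "piecewise_linear_in_time":
            edges = np.concatenate([[0.0], _as_float_array(p["breaks"])])
            slopes = _as_float_array(p["slopes"])
            icept = _as_float_array(p["intercepts"])
            idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 1)
            return slopes[idx] * t + icept[idx]
        if self.family == "piecewise_constant":
            x = tau if self.dependence == "sojourn" else t
            edges = np.concatenate([[0.0], _as_float_array(p["breaks"])])
            values = _as_float_array(p["values"])
            idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 1)
            return values[idx]
        if self.family == "tabulated":
            ages = _as_float_array(p["ages"])
            rates = _as_float_array(p["rates"])
            age = self.age_offset + t
            idx = np.clip(np.searchsorted(ages, age, side="right") - 1, 0, len(ages) - 1)
            return rates[idx]
        if self.family == "product_of_hazards":
            out = np.ones(np.broadcast_shapes(t.shape, tau.shape))
            for c in self.components:
                out = out * c._base_rate(t, tau)
            return out
        raise AssertionError(self.family)

    def rate(self, t, tau, occupancy: Mapping[str, float] | None = None):
        """Modified hazard rate at ``(t, tau)``; vectorised over numpy inputs."""
        _check_domain(t, tau)
        t = _as_float_array(t)
        tau = _as_float_array(tau)
        # lead-time shifts act on the sojourn coordinate fed to the base family
        tau_eff = tau
        gate = np.ones(np.broadcast_shapes(t.shape, tau.shape))
        for m in self.modifiers:
            if m.kind == "lead_time_zero":
                gate = gate * (tau >= m.tau0)
                tau_eff = np.maximum(tau - m.tau0, 0.0)
            elif m.kind == "lead_time_linear":
                if m.tau0 > 0:
                    gate = gate * np.minimum(tau / m.tau0, 1.0)
        out = self._base_rate(t, tau_eff) * gate
        for m in self.modifiers:
            if m.kind == "proportional":
                out = out * math.exp(m.log_hr)
            elif m.kind == "mass_proportional":
                if occupancy is None:
                    raise CouplingError(
                        f"hazard is coupled to occupancy of state {m.coupling_state!r}; "
                        "an occupancy vector must be supplied"
                    )
                out = out * m.beta * float(occupancy[m.coupling_state])
        return out

    # ------------------------------------------------------------- cumulative
    def _base_cumulative(self, t0, tau0, delta):
        """Exact integral of the base rate along the characteristic from
        ``(t0, tau0)`` over duration ``delta`` (t and tau advance together)."""
        t0 = _as_float_array(t0)
        tau0 = _as_float_array(tau0)
        p = self.params
        if self.family == "constant":
            shape = np.broadcast_shapes(t0.shape, tau0.shape, np.shape(delta))
            return np.broadcast_to(float(p["c"]) * delta, shape).copy()
        if self.family == "weibull":
            b, k = float(p["b"]), float(p["k"])
            return b * ((tau0 + delta) ** k - tau0 ** k)
        if self.family == "gompertz":
            pp, r = float(p["p"]), float(p["r"])
            if abs(r) < 1e-14:
                return pp * delta * np.ones(np.broadcast_shapes(t0.shape, tau0.shape))
            return pp / r * (np.exp(r * (tau0 + delta)) - np.exp(r * tau0))
        if self.family == "polynomial_in_sojourn":
            c0, c1, c2 = (float(p[k]) for k in ("c0", "c1", "c2"))
            a, b_ = tau0, tau0 + delta
            return (c0 * (b_ - a) + c1 * (b_ ** 2 - a ** 2) / 2 + c2 * (b_ ** 3 - a ** 3) / 3)
        if self.family == "piecewise_linear_in_time":
            edges = np.concatenate([[0.0], _as_float_array(p["breaks"])])
            slopes = _as_float_array(p["slopes"])
            icept = _as_float_array(p["intercepts"])
            A = lambda x: _piecewise_antiderivative(edges, slopes, icept, x)
            return A(t0 + delta) - A(t0) + 0.0 * tau0
        if self.family == "piecewise_constant":
            edges = np.concatenate([[0.0], _as_float_array(p["breaks"])])
            values = _as_float_array(p["values"])
            slopes = np.zeros_like(values)
            A = lambda x: _piecewise_antiderivative(edges, slopes, values, x)
            x0 = tau0 if self.dependence == "sojourn" else t0
            other = t0 if self.dependence == "sojourn" else tau0
            return A(x0 + delta) - A(x0) + 0.0 * other
        if self.family == "tabulated":
            ages = _as_float_array(p["ages"])
            rates = _as_float_array(p["rates"])
            # extend the table down to age 0 with its first rate so the
            # antiderivative is defined on [0, inf)
            if ages[0] > 0:
                ages = np.concatenate([[0.0], ages])
                rates = np.concatenate([[rates[0]], rates])
            slopes = np.zeros_like(rates)
            A = lambda x: _piecewise_antiderivative(ages, slopes, rates, x)
            a0 = self.age_offset
            return A(a0 + t0 + delta) - A(a0 + t0) + 0.0 * tau0
        if self.family == "product_of_hazards":
            nontrivial = [c for c in self.components if c.variable is not None]
            consts = [float(c.params["c"]) * math.exp(sum(m.log_hr for m in c.modifiers if m.kind == "proportional"))
                      for c in self.components if c.variable is None and not c.is_coupled]
            scale = float(np.prod(consts)) if consts else 1.0
            if len(nontrivial) == 0:
                shape = np.broadcast_shapes(t0.shape, tau0.shape, np.shape(delta))
                return np.broadcast_to(scale * delta, shape).copy()
            if len(nontrivial) == 1 and nontrivial[0].has_closed_form:
                return scale * nontrivial[0].cumulative(t0, tau0, delta)
            raise NotImplementedError("no closed form for this product; use midpoint/quadrature")
        raise AssertionError(self.family)

    def cumulative(self, t0, tau0, delta, occupancy: Mapping[str, float] | None = None,
                   method: str = "exact"):
        """Cumulative hazard along the characteristic from ``(t0, tau0)`` over
        duration ``delta``.

        ``method='exact'`` uses the closed form where the family permits it and
        falls back to adaptive quadrature otherwise; ``method='midpoint'``
        always applies the one-point midpoint rule
        ``delta * rate(t0 + delta/2, tau0 + delta/2)``.
        """
        _check_domain(t0, tau0)
        if np.any(_as_float_array(delta) < 0):
            raise ValueError("delta must be >= 0")
        if method == "midpoint":
            return delta * self.rate(t0 + delta / 2.0, tau0 + delta / 2.0, occupancy)
        if not self.has_closed_form and not self.is_coupled:
            return self._quad_cumulative(t0, tau0, delta)
        if self.is_coupled:
            # occupancy is only known pointwise; a one-step integral uses the
            # midpoint value (the solver's explicit coupling)
            return delta * self.rate(t0 + delta / 2.0, tau0 + delta / 2.0, occupancy)

        mult = math.exp(sum(m.log_hr for m in self.modifiers if m.kind == "proportional"))
        shift = sum(m.tau0 for m in self.modifiers if m.kind == "lead_time_zero")
        if shift == 0.0:
            return mult * self._base_cumulative(t0, tau0, delta)
        # lead_time_zero: nothing accrues below tau0; above, the base hazard is
        # integrated over the shifted sojourn while model time runs unshifted.
        t0 = _as_float_array(t0)
        tau0 = _as_float_array(tau0)
        shape = np.broadcast_shapes(t0.shape, tau0.shape, np.shape(delta))
        t0b = np.broadcast_to(t0, shape)
        tau0b = np.broadcast_to(tau0, shape)
        db = np.broadcast_to(_as_float_array(delta), shape)
        wait = np.clip(shift - tau0b, 0.0, db)  # time spent below the cutoff
        if self.variable in ("both",):
            return self._quad_cumulative(t0, tau0, delta)
        eff_tau0 = np.maximum(tau0b - shift, 0.0)
        eff_t0 = t0b + wait
        eff_delta = db - wait
        out = np.zeros(shape)
        pos = eff_delta > 0
        if np.any(pos):
            base = replace(self, modifiers=tuple(m for m in self.modifiers
                                                 if m.kind not in ("lead_time_zero", "proportional")))
            out[pos] = base._base_cumulative(eff_t0[pos], eff_tau0[pos], eff_delta[pos])
        return mult * out

    def _quad_cumulative(self, t0, tau0, delta):
        t0 = _as_float_array(t0)
        tau0 = _as_float_array(tau0)
        shape = np.broadcast_shapes(t0.shape, tau0.shape, np.shape(delta))
        t0b = np.broadcast_to(t0, shape).ravel()
        tau0b = np.broadcast_to(tau0, shape).ravel()
        db = np.broadcast_to(_as_float_array(delta), shape).ravel()
        out = np.empty(t0b.shape)
        for i, (a, b, d) in enumerate(zip(t0b, tau0b, db)):
            pts = []
            for var, pos in self.breakpoints():
                s = pos - (a if var == "model_time" else b)
                if 0 < s < d:
                    pts.append(s)
            val, _ = integrate.quad(lambda s: float(self.rate(a + s, b + s)), 0.0, d,
                                    points=sorted(pts) or None, limit=200)
            out[i] = val
        return out.reshape(shape) if shape else float(out[0])


# ----------------------------------------------------------------- operations

def eval_hazard(hazard: Hazard, t, tau, occupancy: Mapping[str, float] | None = None):
    """Evaluate a (modified) hazard rate at ``(t, tau)``."""
    return hazard.rate(t, tau, occupancy)


def cumulative_hazard_segment(hazard: Hazard, t_start, tau_start, delta,
                              occupancy: Mapping[str, float] | None = None,
                              method: str = "exact"):
    """Per-cause cumulative hazard along a characteristic segment."""
    return hazard.cumulative(t_start, tau_start, delta, occupancy, method)


def total_hazard(transitions: Iterable, t, tau, occupancy: Mapping[str, float] | None = None):
    """Summed rate over all transitions leaving a state (zero if absorbing).

    ``transitions`` may be an iterable of :class:`Hazard` or of objects with a
    ``hazard`` attribute (e.g. model transitions).
    """
    tot = 0.0
    for tr in transitions:
        h = tr if isinstance(tr, Hazard) else tr.hazard
        tot = tot + h.rate(t, tau, occupancy)
    return tot


def tabulated_from_csv(path, age_offset: float = 0.0, modifiers: Sequence[Modifier] = ()) -> Hazard:
    """Build a tabulated (life-table style) hazard from a 2-column CSV.

    The file must have a header naming an age column (``age`` or
    ``age_lower_bound``) and ``annual_rate``; bins are half-open ``[a, next_a)``
    with the last bin extending upward.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    age_col = cols.get("age") or cols.get("age_lower_bound")
    if age_col is None or "annual_rate" not in cols:
        raise ValueError("life-table CSV needs columns (age|age_lower_bound, annual_rate)")
    return Hazard(
        "tabulated",
        {"ages": df[age_col].to_list(), "rates": df[cols["annual_rate"]].to_list()},
        dependence="model_time",
        age_offset=age_offset,
        modifiers=tuple(modifiers),
    )
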