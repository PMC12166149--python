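"""Worked four-state model of liver cirrhosis, decompensation, cancer and death.

A cohort enters with compensated cirrhosis (mean age 55) and faces competing
risks of decompensation, liver-cancer onset and death.  Liver cancer and
death are terminal.  The calibrated hazards:

==========================  =====================================================
transition                  hazard (1/year)
==========================  =====================================================
compensated -> decompensated  0.0129 t + 0.00668 for t < 6, 0.0359 for t >= 6
compensated -> liver cancer   Gompertz in sojourn, p = 1.197e-2, r = 6.654e-2
                              (alternative power-law reading 0.0102 tau^1.377)
compensated -> death          power law 0.0336 tau^-0.238
decompensated -> death        quadratic 0.447 - 0.150 tau + 0.0237 tau^2
any -> death (other causes)   age-indexed piecewise-constant life table (optional)
==========================  =====================================================

The two liver-cancer presets are both provided because the published formula
and the published code disagree; the Gompertz form is the default since it is
unambiguous machine-readable code.  The decompensated-death quadratic implies
near-certain death within 10 years, which is in tension with the published
ten-year value; it is used as printed and the discrepancy is documented in
the methods note rather than silently repaired.

Per-hazard lognormal hazard-ratio distributions drive the probabilistic
sensitivity analysis (PSA): each sample multiplies one hazard by a drawn
ratio and records the resulting risk outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize

from .hazards import Hazard, tabulated_from_csv
from .model import GridSpec, ModelSpec
from .survival import CharacteristicFrame, cumulative_hazard

__all__ = [
    "COMPENSATED", "DECOMPENSATED", "CANCER", "DEATH", "OTHER_CAUSE_DEATH",
    "decompensation_hazard", "cancer_hazard", "compensated_death_hazard",
    "decompensated_death_hazard", "other_cause_hazard",
    "build_liver_model", "HRDistribution", "TABLE_HR_DISTRIBUTIONS",
    "cause_specific_risk", "CalibrationTarget", "CalibrationResult",
    "calibrate_hazard", "calibrate_hr_distribution", "run_psa", "PSAResult",
]

COMPENSATED = "Compensated cirrhosis"
DECOMPENSATED = "Decompensated cirrhosis"
CANCER = "Liver cancer"
DEATH = "Death"
OTHER_CAUSE_DEATH = "Other-cause death"

COHORT_AGE = 55.0  # mean age at cirrhosis diagnosis


# ------------------------------------------------------------------- presets

def decompensation_hazard() -> Hazard:
    """Decompensation rate, piecewise linear in model time."""
    return Hazard("piecewise_linear_in_time",
                  {"breaks": [6.0], "slopes": [0.0129, 0.0],
                   "intercepts": [0.00668, 0.0359]},
                  dependence="model_time")


def cancer_hazard(variant: str = "gompertz_cancer") -> Hazard:
    """Liver-cancer onset rate in sojourn time.

    ``gompertz_cancer`` (default): p*exp(r*tau) with p=1.197e-2, r=6.654e-2.
    ``table_power_cancer``: the power-law reading 0.0102*tau**1.377,
    expressed as a Weibull rate b*k*tau**(k-1) with k = 2.377.
    """
    if variant == "gompertz_cancer":
        return Hazard("gompertz", {"p": 1.197e-2, "r": 6.654e-2})
    if variant == "table_power_cancer":
        k = 1.377 + 1.0
        return Hazard("weibull", {"b": 0.0102 / k, "k": k})
    raise ValueError("variant must be 'gompertz_cancer' or 'table_power_cancer'")


def compensated_death_hazard() -> Hazard:
    """Death from compensated cirrhosis: 0.0336*tau**-0.238, a decreasing
    Weibull rate (k = 0.762) whose cumulative b*tau**k stays finite despite
    the pointwise singularity at tau = 0."""
    k = 1.0 - 0.238
    return Hazard("weibull", {"b": 0.0336 / k, "k": k})


def decompensated_death_hazard() -> Hazard:
    """Death from decompensated cirrhosis: 0.447 - 0.150 tau + 0.0237 tau^2."""
    return Hazard("polynomial_in_sojourn", {"c0": 0.447, "c1": -0.150, "c2": 0.0237})


def other_cause_hazard(age_offset: float = COHORT_AGE, table_path=None) -> Hazard:
    """Age-indexed other-cause mortality from an annual life table.

    The bundled table is a synthetic stand-in with a Gompertz-Makeham shape;
    pass ``table_path`` to substitute real national life tables.
    """
    if table_path is None:
        table_path = resources.files("sojourn.data") / "synthetic_life_table.csv"
    return tabulated_from_csv(table_path, age_offset=age_offset)


def build_liver_model(variant: str = "gompertz_cancer", dt: float = 0.01,
                      max_t: float = 10.0, *, include_cancer: bool = True,
                      decompensated_to_cancer: bool = False,
                      other_cause: bool = False, max_tau: float | None = None) -> ModelSpec:
    """Assemble the liver model: cohort atom in compensated cirrhosis at tau=0.

    ``include_cancer=False`` gives the three-state (compensated,
    decompensated, death) reduction used for all-cause death outcomes with
    the cancer transition censored.  ``other_cause=True`` adds a separate
    absorbing "Other-cause death" state fed by life-table mortality from both
    cirrhosis states (excluded by default: the cirrhosis death hazards were
    calibrated against all-cause survival cohorts, so adding the life table
    to the same outcomes would double count).
    """
    states = [COMPENSATED, DECOMPENSATED]
    if include_cancer:
        states.append(CANCER)
    states.append(DEATH)
    if other_cause:
        states.append(OTHER_CAUSE_DEATH)
    model = ModelSpec(states=states, grid=GridSpec(dt=dt, max_t=max_t, max_tau=max_tau))
    model.add_transition(COMPENSATED, DECOMPENSATED, decompensation_hazard())
    if include_cancer:
        model.add_transition(COMPENSATED, CANCER, cancer_hazard(variant))
    model.add_transition(COMPENSATED, DEATH, compensated_death_hazard())
    model.add_transition(DECOMPENSATED, DEATH, decompensated_death_hazard())
    if include_cancer and decompensated_to_cancer:
        model.add_transition(DECOMPENSATED, CANCER, cancer_hazard(variant))
    if other_cause:
        for s in (COMPENSATED, DECOMPENSATED):
            model.add_transition(s, OTHER_CAUSE_DEATH, other_cause_hazard())
    model.set_initial_atom(COMPENSATED, 0.0, 1.0)
    return model


# ----------------------------------------------------------------- HR / PSA

@dataclass(frozen=True)
class HRDistribution:
    """Lognormal distribution of a multiplicative hazard ratio."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(self.mu + self.sigma * rng.standard_normal(n))

    def quantile(self, q) -> np.ndarray:
        from scipy.stats import norm

        return np.exp(self.mu + self.sigma * norm.ppf(q))


#: Published PSA hazard-ratio distributions, keyed by the hazard they multiply.
TABLE_HR_DISTRIBUTIONS: dict[str, HRDistribution] = {
    "decompensation": HRDistribution(-0.0213, 0.117),
    "cancer": HRDistribution(-0.00171, 0.158),
    "compensated_death": HRDistribution(-0.0254, 0.147),
    "decompensated_death": HRDistribution(0.0478, 0.0895),
}

#: Which (source, target) transition each PSA key multiplies.
PSA_TRANSITIONS: dict[str, tuple[str, str]] = {
    "decompensation": (COMPENSATED, DECOMPENSATED),
    "cancer": (COMPENSATED, CANCER),
    "compensated_death": (COMPENSATED, DEATH),
    "decompensated_death": (DECOMPENSATED, DEATH),
}


def cause_specific_risk(model: ModelSpec, source: str, target: str,
                        horizon: float, hazard_ratio: float = 1.0) -> float:
    """Cumulative incidence of ``source -> target`` by sojourn ``horizon``
    with competing events censored: ``1 - exp(-HR * Lambda_ij(horizon))``."""
    lam = cumulative_hazard(model, CharacteristicFrame(source), horizon, target=target)
    return float(1.0 - math.exp(-hazard_ratio * float(lam)))


# -------------------------------------------------------------- calibration

@dataclass(frozen=True)
class CalibrationTarget:
    """One observed point: cumulative risk (or survival) at a given time,
    optionally with a 95% CI used for inverse-variance weighting."""

    time: float
    value: float
    kind: str = "risk"  # or "survival"
    ci: tuple[float, float] | None = None

    def as_risk(self) -> float:
        return self.value if self.kind == "risk" else 1.0 - self.value

    def weight(self) -> float:
        if self.ci is None:
            return 1.0
        lo, hi = self.ci
        sd = abs(hi - lo) / (2 * 1.959963984540054)
        return 1.0 / max(sd, 1e-12) ** 2


@dataclass
class CalibrationResult:
    family: str
    params: dict
    loss: float
    converged: bool
    trace: list = field(default_factory=list)

    def hazard(self, dependence: str = "sojourn") -> Hazard:
        return Hazard(self.family, self.params, dependence=dependence)


_PARAM_NAMES = {"constant": ("c",), "weibull": ("b", "k"), "gompertz": ("p", "r")}
_LOG_SCALE = {"c": True, "b": True, "k": True, "p": True, "r": False}


def calibrate_hazard(family: str, targets: list[CalibrationTarget],
                     x0: dict | None = None) -> CalibrationResult:
    """Fit a parametric hazard to cumulative risk/survival points.

    Minimises the CI-weighted squared error between the model's cause-specific
    cumulative incidence ``1 - exp(-Lambda(t))`` and the target points, using
    a quasi-Newton (BFGS) search with finite-difference gradients.  Positive
    parameters are optimised on the log scale.  Non-convergence is flagged on
    the result, not raised.
    """
    names = _PARAM_NAMES.get(family)
    if names is None:
        raise ValueError(f"calibration supports families {sorted(_PARAM_NAMES)}")
    if len(targets) < len(names):
        raise ValueError("need at least as many target points as free parameters")
    defaults = {"c": 0.1, "b": 0.05, "k": 1.0, "p": 0.02, "r": 0.05}
    start = {**defaults, **(x0 or {})}
    x_init = np.array([math.log(start[n]) if _LOG_SCALE[n] else start[n] for n in names])

    t_pts = np.array([t.time for t in targets])
    y = np.array([t.as_risk() for t in targets])
    w = np.array([t.weight() for t in targets])
    w = w / w.mean()
    trace: list[float] = []

    def unpack(x):
        return {n: (math.exp(v) if _LOG_SCALE[n] else float(v)) for n, v in zip(names, x)}

    def loss(x):
        hz = Hazard(family, unpack(x))
        lam = np.asarray(hz.cumulative(0.0, 0.0, t_pts), float)
        r = 1.0 - np.exp(-lam)
        val = float(np.sum(w * (r - y) ** 2))
        trace.append(val)
        return val

    res = optimize.minimize(loss, x_init, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    # BFGS reports "precision loss" on perfect fits; a vanishing loss is converged
    converged = bool(res.success) or float(res.fun) < 1e-12
    return CalibrationResult(family=family, params=unpack(res.x), loss=float(res.fun),
                             converged=converged, trace=trace)


def calibrate_hr_distribution(model: ModelSpec, source: str, target: str,
                              horizon: float, center: float,
                              ci: tuple[float, float]) -> HRDistribution:
    """Lognormal HR distribution whose induced 2.5/50/97.5 percentiles of the
    ``horizon``-year cause-specific risk match the target central value and CI.

    For a risk target the map HR -> 1 - exp(-HR * Lambda) is monotone, so the
    matching HR quantiles are closed-form: HR_q = -log(1 - risk_q) / Lambda.
    """
    lo, hi = ci
    if not (0 < lo < center < hi < 1):
        raise ValueError("CI bounds must satisfy 0 < lower < center < upper < 1")
    lam = float(cumulative_hazard(model, CharacteristicFrame(source), horizon, target=target))
    hr = [-math.log1p(-q) / lam for q in (lo, center, hi)]
    mu = math.log(hr[1])
    z = 1.959963984540054
    sigma = (math.log(hr[2]) - math.log(hr[0])) / (2 * z)
    return HRDistribution(mu=mu, sigma=sigma)


# ---------------------------------------------------------------------- PSA

@dataclass
class PSAResult:
    samples: pd.DataFrame
    intervals: pd.DataFrame  # per outcome: 2.5%, 50%, 97.5% percentiles
    seed: int

    def interval(self, outcome: str) -> tuple[float, float]:
        row = self.intervals.loc[outcome]
        return float(row["q2.5"]), float(row["q97.5"])


def run_psa(model: ModelSpec, hr_distributions: dict[str, HRDistribution],
            n_samples: int, seed: int, horizons: tuple[float, ...] = (1.0, 10.0)) -> PSAResult:
    """Probabilistic sensitivity analysis over hazard-ratio draws.

    Each sample draws one hazard ratio per distribution (independently) and
    records the cause-specific cumulative incidence of the multiplied hazard
    at each horizon.  Cumulative hazards scale linearly in the ratio, so the
    per-sample outcomes follow from the base cumulative hazards exactly; no
    re-discretisation noise enters the percentiles.  Deterministic given
    ``seed``.  95% prediction intervals are the 2.5th/97.5th percentiles.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for key in sorted(hr_distributions):
        dist = hr_distributions[key]
        src, tgt = PSA_TRANSITIONS[key]
        if not any(t.source == src and t.target == tgt for t in model.transitions):
            continue
        hrs = dist.sample(rng, n_samples)
        cols[f"hr_{key}"] = hrs
        lam = {h: float(cumulative_hazard(model, CharacteristicFrame(src), h, target=tgt))
               for h in horizons}
        for h in horizons:
            label = f"{key}_risk_{h:g}y"
            cols[label] = 1.0 - np.exp(-hrs * lam[h])
    samples = pd.DataFrame(cols)
    outcome_cols = [c for c in samples.columns if not c.startswith("hr_")]
    qs = samples[outcome_cols].quantile([0.025, 0.5, 0.975]).T
    qs.columns = ["q2.5", "q50", "q97.5"]
    return PSAResult(samples=samples, intervals=qs, seed=seed)
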