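"""Model config (YAML/JSON) parsing, result serialisation and run manifests.

The config schema mirrors the model structure::

    states: [Healthy, Ill]
    transitions:
      - source: Healthy
        target: Ill
        kind: sojourn_resetting
        hazard:
          family: gompertz
          params: {p: 1.197e-2, r: 6.654e-2}
          dependence: sojourn
          modifiers: [{kind: proportional, log_hr: 0.0}]
    initial:
      atoms: [{state: Healthy, sojourn: 0.0, mass: 1.0}]
    grid: {dt: 0.01, max_t: 10, max_tau: 10}

All config units are years.  Round trips are lossless:
``load_model_config(save_model_config(model)) == model``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .hazards import FAMILIES, Hazard, Modifier
from .model import Atom, GridSpec, InitialCondition, ModelSpec
from .solver import SolveResult

__all__ = [
    "ConfigError", "hazard_to_dict", "hazard_from_dict",
    "model_to_dict", "model_from_dict",
    "load_model_config", "save_model_config", "save_results", "RunManifest",
]


class ConfigError(ValueError):
    """Schema violation; the message names the offending field path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


def _plain(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_plain(v) for v in x]
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    return x


def hazard_to_dict(h: Hazard) -> dict:
    params = dict(h.params)
    if h.family == "product_of_hazards":
        params["components"] = [hazard_to_dict(c) for c in h.components]
    out = {"family": h.family, "params": _plain(params), "dependence": h.dependence}
    if h.age_offset:
        out["age_offset"] = float(h.age_offset)
    if h.modifiers:
        out["modifiers"] = [
            {k: v for k, v in dataclasses.asdict(m).items()
             if v not in (None,) and not (k in ("log_hr", "tau0") and v == 0.0)
             and not (k == "beta" and v == 1.0)}
            for m in h.modifiers]
    return out


def hazard_from_dict(d: dict, path: str = "hazard") -> Hazard:
    if not isinstance(d, dict):
        raise ConfigError(path, "hazard block must be a mapping")
    family = d.get("family")
    if family not in FAMILIES:
        raise ConfigError(f"{path}.family",
                          f"unknown hazard family {family!r}; options: {', '.join(FAMILIES)}")
    params = dict(d.get("params", {}))
    if family == "product_of_hazards":
        comps = params.get("components", [])
        params["components"] = tuple(
            hazard_from_dict(c, f"{path}.params.components[{i}]") for i, c in enumerate(comps))
    mods = []
    for i, m in enumerate(d.get("modifiers", []) or []):
        try:
            mods.append(Modifier(**m))
        except (TypeError, ValueError) as e:
            raise ConfigError(f"{path}.modifiers[{i}]", str(e)) from e
    try:
        return Hazard(family, params, dependence=d.get("dependence", "sojourn"),
                      age_offset=float(d.get("age_offset", 0.0)), modifiers=tuple(mods))
    except ValueError as e:
        raise ConfigError(path, str(e)) from e


def model_to_dict(model: ModelSpec) -> dict:
    init: dict = {"atoms": [{"state": a.state, "sojourn": float(a.sojourn),
                             "mass": float(a.mass)} for a in model.initial.atoms]}
    if model.initial.density_samples:
        init["density_samples"] = {
            s: {"tau": _plain(list(t)), "density": _plain(list(v))}
            for s, (t, v) in model.initial.density_samples.items()}
    grid: dict = {"dt": float(model.grid.dt), "max_t": float(model.grid.max_t)}
    if model.grid.max_tau is not None:
        grid["max_tau"] = float(model.grid.max_tau)
    return {
        "states": list(model.states),
        "transitions": [{"source": t.source, "target": t.target, "kind": t.kind,
                         "hazard": hazard_to_dict(t.hazard)} for t in model.transitions],
        "initial": init,
        "grid": grid,
    }


def model_from_dict(d: dict) -> ModelSpec:
    states = d.get("states")
    if not isinstance(states, list) or not states:
        raise ConfigError("states", "must be a non-empty list of state names")
    g = d.get("grid", {})
    if not isinstance(g, dict):
        raise ConfigError("grid", "must be a mapping")
    dt = g.get("dt")
    if not isinstance(dt, (int, float)) or dt <= 0:
        raise ConfigError("grid.dt", f"must be a positive number, got {dt!r}")
    if not isinstance(g.get("max_t"), (int, float)) or g["max_t"] <= 0:
        raise ConfigError("grid.max_t", "must be a positive number")
    grid = GridSpec(dt=float(dt), max_t=float(g["max_t"]),
                    max_tau=float(g["max_tau"]) if "max_tau" in g else None)
    model = ModelSpec(grid=grid)
    for i, s in enumerate(states):
        try:
            model.add_state(s)
        except ValueError as e:
            raise ConfigError(f"states[{i}]", str(e)) from e
    for i, t in enumerate(d.get("transitions", [])):
        p = f"transitions[{i}]"
        for key in ("source", "target", "hazard"):
            if key not in t:
                raise ConfigError(f"{p}.{key}", "required")
        hz = hazard_from_dict(t["hazard"], f"{p}.hazard")
        try:
            model.add_transition(t["source"], t["target"], hz,
                                 t.get("kind", "sojourn_resetting"))
        except (KeyError, ValueError) as e:
            raise ConfigError(p, str(e)) from e
    init = d.get("initial", {})
    for i, a in enumerate(init.get("atoms", [])):
        try:
            model.initial.atoms.append(Atom(a["state"], float(a.get("sojourn", 0.0)),
                                            float(a["mass"])))
        except (KeyError, ValueError) as e:
            raise ConfigError(f"initial.atoms[{i}]", str(e)) from e
    for s, block in (init.get("density_samples") or {}).items():
        model.initial.density_samples[s] = (list(block["tau"]), list(block["density"]))
    return model


def load_model_config(path) -> ModelSpec:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return model_from_dict(data)


def save_model_config(model: ModelSpec, path) -> Path:
    path = Path(path)
    d = model_to_dict(model)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def config_digest(model: ModelSpec) -> str:
    """Stable digest over the canonical JSON form of the model config."""
    blob = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config_digest: str
    package_version: str
    scheme: str
    dt: float
    seed: int | None
    wall_time_s: float
    conservation_residual: float
    terminal_sojourn_bin_mass: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def save_results(result: SolveResult, model: ModelSpec, out_dir, *,
                 seed: int | None = None, wall_time_s: float = 0.0,
                 density: bool = False) -> dict[str, Path]:
    """Write occupancy (and optionally density) CSVs plus a run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    occ = result.trajectory.to_frame()
    files["occupancy"] = out_dir / "occupancy.csv"
    occ.to_csv(files["occupancy"], index=False)
    if density:
        files["density"] = out_dir / "density.csv"
        result.density.to_frame().to_csv(files["density"], index=False)
    manifest = RunManifest(
        config_digest=config_digest(model),
        package_version=__version__,
        scheme=result.scheme,
        dt=result.trajectory.dt,
        seed=seed,
        wall_time_s=wall_time_s,
        conservation_residual=result.diagnostics["conservation_residual"],
        terminal_sojourn_bin_mass=result.diagnostics["terminal_sojourn_bin_mass"],
    )
    files["manifest"] = out_dir / "manifest.json"
    files["manifest"].write_text(manifest.to_json())
    return files
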