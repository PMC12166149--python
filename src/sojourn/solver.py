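"""Characteristic-grid transport solver for the sojourn density equations.

The joint density ``f_i(t, tau)`` of (state, sojourn time) obeys a transport
equation: along characteristics of constant ``t - tau`` it decays by the
exponential of the accumulated total hazard, and mass removed by a transition
``i -> j`` re-enters state ``j`` on the boundary ``tau = 0``.  On a lattice
with step ``dt`` shared by both clocks, each cell ``F[i][m, n]`` (density at
``t = m*dt``, ``tau = n*dt``) is propagated one step along its characteristic
per time step.

Two boundary discretisations are provided:

* ``first_order`` -- rectangle-rule evaluation of the entry integral,
  ``F[i][m,0] = sum_j sum_{k>0} dt * lambda_ji(m dt, k dt) * F[j][m,k]``.
* ``mass_conserving`` -- the mass removed from every cell during the step is
  redistributed to entry boundaries in proportion to midpoint hazard shares,
  so total probability is conserved to machine precision.

Dirac components of the initial condition are carried as explicit point
masses on their own characteristics (decayed by the same survival factors),
which avoids the O(dt) smearing bias a density-only representation would
introduce for the standard "cohort enters at tau = 0" start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .model import ModelSpec, Diagnostic

__all__ = ["OccupancyTrajectory", "DensityGrid", "SolveResult", "run", "SCHEMES"]

SCHEMES = ("first_order", "mass_conserving")


@dataclass
class OccupancyTrajectory:
    """State probabilities and entry fluxes on the time grid."""

    times: np.ndarray          # (M+1,)
    states: list[str]
    occupancy: np.ndarray      # (M+1, N) -- g_i(m dt)
    entry_flux: np.ndarray     # (M+1, N) -- f_i(m dt, 0), 1/year

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def state_occupancy(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def occupancy_at(self, t: float, state: str | None = None):
        m = int(round(t / self.dt))
        if not (0 <= m < len(self.times)) or abs(m * self.dt - t) > 1e-9 + 1e-9 * abs(t):
            raise ValueError(f"t={t} is not on the solved grid")
        row = self.occupancy[m]
        return row if state is None else float(row[self.states.index(state)])

    def to_frame(self):
        """Long-format table with columns time, state, occupancy, entry_flux."""
        import pandas as pd

        M, N = self.occupancy.shape
        return pd.DataFrame({
            "time": np.repeat(self.times, N),
            "state": np.tile(self.states, M),
            "occupancy": self.occupancy.ravel(),
            "entry_flux": self.entry_flux.ravel(),
        })


@dataclass
class DensityGrid:
    """Discretised sojourn density plus residual point masses."""

    dt: float
    states: list[str]
    values: np.ndarray                       # (N, n_tau+1) at the final step
    atom_taus: np.ndarray                    # (A,) sojourn of each point mass
    atom_masses: np.ndarray                  # (A, N)
    history: np.ndarray | None = None        # (M+1, N, n_tau+1) if stored
    atom_tau_history: np.ndarray | None = None    # (M+1, A)
    atom_mass_history: np.ndarray | None = None   # (M+1, A, N)

    def total_mass(self, step: int = -1) -> float:
        if self.history is not None:
            vals = self.history[step]
            am = self.atom_mass_history[step]
        else:
            vals, am = self.values, self.atom_masses
        return float(self.dt * vals.sum() + am.sum())

    def to_frame(self, times=None):
        """Long-format density dump: time, sojourn, state, density."""
        import pandas as pd

        if self.history is None:
            raise ValueError("density history was not stored; run with store_history=True")
        M, N, K = self.history.shape
        all_t = np.arange(M) * self.dt
        rows = range(M) if times is None else [int(round(t / self.dt)) for t in times]
        frames = []
        for m in rows:
            frames.append(pd.DataFrame({
                "time": np.full(N * K, all_t[m]),
                "sojourn": np.tile(np.arange(K) * self.dt, N),
                "state": np.repeat(self.states, K),
                "density": self.history[m].ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class SolveResult:
    trajectory: OccupancyTrajectory
    density: DensityGrid
    diagnostics: dict
    scheme: str
    t_offset: float = 0.0


class ModelValidationError(ValueError):
    def __init__(self, diagnostics: list[Diagnostic]):
        self.diagnostics = diagnostics
        super().__init__("model validation failed:\n" + "\n".join(map(str, diagnostics)))


class _Stepper:
    """One solver instance; holds the per-transition precomputations."""

    def __init__(self, model: ModelSpec, scheme: str, segment_integration: str,
                 t_offset: float):
        if scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        self.model = model
        self.scheme = scheme
        self.integration = segment_integration
        self.t_offset = t_offset
        self.N = len(model.states)
        self.dt = model.grid.dt
        self.M = int(round(model.grid.max_t / self.dt))
        self.n_tau = int(round(model.resolved_max_tau() / self.dt))
        self.coupled = model.is_coupled
        self.lam = [t for t in model.transitions if t.kind == "sojourn_resetting"]
        self.mu = [t for t in model.transitions if t.kind == "sojourn_preserving"]
        self._precompute()

    # -------------------------------------------------------- precomputation
    def _classify(self, hz) -> str:
        dep = hz.effective_dependence()
        if hz.is_coupled:
            return "both" if dep == "both" else "model_time"
        return dep

    def _precompute(self) -> None:
        dt, n_tau = self.dt, self.n_tau
        # source sojourns for destination cells n = 1..n_tau, then terminal stay
        self.tau_src = dt * np.arange(0, n_tau)          # (n_tau,)
        self.tau_term = dt * n_tau
        self.tau_mid = dt * (np.arange(1, n_tau + 1) - 0.5)
        self.tau_mid_term = dt * (n_tau + 0.5)
        self.tau_bnd = dt * np.arange(1, n_tau + 1)      # first-order rate points

        self._cls = [self._classify(t.hazard) for t in self.lam]
        # closed forms where the family permits; the midpoint rule otherwise
        self._method = ["midpoint" if (self.integration == "midpoint" or
                                       not t.hazard.has_closed_form) else "exact"
                        for t in self.lam]
        self._seg_static: list[np.ndarray | None] = []
        self._segterm_static: list[float | None] = []
        self._mid_static: list[np.ndarray | None] = []
        self._midterm_static: list[float | None] = []
        self._bnd_static: list[np.ndarray | None] = []
        for tr, cls, method in zip(self.lam, self._cls, self._method):
            if cls == "constant":
                hz = tr.hazard
                self._seg_static.append(float(hz.cumulative(0.0, 0.0, dt, method=method)))
                self._segterm_static.append(float(hz.cumulative(0.0, self.tau_term, dt,
                                                                method=method)))
                r = float(hz.rate(0.0, 0.5 * dt))
                self._mid_static.append(r)
                self._midterm_static.append(r)
                self._bnd_static.append(float(hz.rate(0.0, dt)))
            elif cls == "sojourn":
                hz = tr.hazard
                seg = np.asarray(hz.cumulative(0.0, self.tau_src, dt, method=method), float)
                segterm = float(hz.cumulative(0.0, self.tau_term, dt, method=method))
                mid = np.asarray(hz.rate(0.0, self.tau_mid), float)
                midterm = float(hz.rate(0.0, self.tau_mid_term))
                bnd = np.asarray(hz.rate(0.0, self.tau_bnd), float)
                self._seg_static.append(np.broadcast_to(seg, (n_tau,)).copy())
                self._segterm_static.append(segterm)
                self._mid_static.append(np.broadcast_to(mid, (n_tau,)).copy())
                self._midterm_static.append(midterm)
                self._bnd_static.append(np.broadcast_to(bnd, (n_tau,)).copy())
            else:
                self._seg_static.append(None)
                self._segterm_static.append(None)
                self._mid_static.append(None)
                self._midterm_static.append(None)
                self._bnd_static.append(None)

        self._mu_cls = [self._classify(t.hazard) for t in self.mu]
        self._mu_static_P: np.ndarray | None = None
        if self.mu and all(c == "constant" for c in self._mu_cls):
            Q = np.zeros((self.N, self.N))
            for tr in self.mu:
                r = float(tr.hazard.rate(0.0, 0.0))
                i, j = self.model.index(tr.source), self.model.index(tr.target)
                Q[i, j] += r
                Q[i, i] -= r
            self._mu_static_P = expm(Q.T * self.dt)

    # ------------------------------------------------------- per-step pieces
    def _transition_arrays(self, m: int, occ: dict | None):
        """Per-transition (seg, seg_term, mid, mid_term, bnd) for step m."""
        dt = self.dt
        t0 = (m - 1) * dt + self.t_offset
        t_mid = (m - 0.5) * dt + self.t_offset
        t_now = m * dt + self.t_offset
        out = []
        for tr, cls, method, seg_s, segterm_s, mid_s, midterm_s, bnd_s in zip(
                self.lam, self._cls, self._method, self._seg_static, self._segterm_static,
                self._mid_static, self._midterm_static, self._bnd_static):
            hz = tr.hazard
            if seg_s is not None:
                out.append((seg_s, segterm_s, mid_s, midterm_s, bnd_s))
            elif cls == "model_time":
                seg = float(hz.cumulative(t0, 0.0, dt, occupancy=occ, method=method))
                mid = float(hz.rate(t_mid, 0.0, occ))
                bnd = float(hz.rate(t_now, 0.0, occ))
                out.append((seg, seg, mid, mid, bnd))
            else:  # genuinely (t, tau)-dependent: vectors recomputed each step
                seg = np.asarray(hz.cumulative(t0, self.tau_src, dt, occupancy=occ,
                                               method=method), float)
                segterm = float(hz.cumulative(t0, self.tau_term, dt, occupancy=occ,
                                              method=method))
                mid = np.asarray(hz.rate(t_mid, self.tau_mid, occ), float)
                midterm = float(hz.rate(t_mid, self.tau_mid_term, occ))
                bnd = np.asarray(hz.rate(t_now, self.tau_bnd, occ), float)
                out.append((seg, segterm, mid, midterm, bnd))
        return out

    def advance_characteristics(self, F, atom_tau, atom_masses, arrays, m, occ):
        """Decay every cell and atom along its characteristic; returns the
        advanced grid together with the per-cell and per-atom mass losses.

        States whose outgoing hazards are all sojourn-independent share one
        scalar survival factor across every cell, which is exploited to avoid
        materialising per-cell hazard arrays (``loss`` rows are ``None`` for
        such states and only the summed loss is tracked)."""
        N, n_tau, dt = self.N, self.n_tau, self.dt
        tot_seg: list = [0.0] * N
        tot_term = [0.0] * N
        for tr, (seg, segterm, *_rest) in zip(self.lam, arrays):
            i = self.model.index(tr.source)
            tot_seg[i] = tot_seg[i] + seg
            tot_term[i] = tot_term[i] + segterm

        newF = np.empty_like(F)
        newF[:, 0] = 0.0
        loss: list = [None] * N          # per-cell loss for vector states
        term_loss = np.zeros(N)
        loss_sum = np.zeros(N)           # total density loss per state
        scalar_state = np.zeros(N, dtype=bool)
        for i in range(N):
            if np.isscalar(tot_seg[i]):
                s = float(np.exp(-tot_seg[i]))
                scalar_state[i] = True
                newF[i, 1:] = F[i, :-1] * s
                newF[i, -1] += F[i, -1] * s
                loss_sum[i] = (1.0 - s) * float(F[i].sum())
            else:
                surv = np.exp(-np.asarray(tot_seg[i]))
                s_term = float(np.exp(-tot_term[i]))
                newF[i, 1:] = F[i, :-1] * surv
                newF[i, -1] += F[i, -1] * s_term
                loss[i] = F[i, :-1] * (1.0 - surv)     # dest cell n = 1..n_tau
                term_loss[i] = F[i, -1] * (1.0 - s_term)
                loss_sum[i] = float(loss[i].sum()) + term_loss[i]
        self._scalar_state = scalar_state

        # point masses: same survival factors along their own characteristics
        atom_loss = np.zeros_like(atom_masses)
        if atom_masses.size:
            t0 = (m - 1) * dt + self.t_offset
            seg_a = np.zeros((len(atom_tau), N))
            for tr, method in zip(self.lam, self._method):
                i = self.model.index(tr.source)
                seg_a[:, i] += np.asarray(tr.hazard.cumulative(
                    t0, atom_tau, dt, occupancy=occ, method=method), float)
            new_masses = atom_masses * np.exp(-seg_a)
            atom_loss = atom_masses - new_masses
            atom_masses = new_masses
        return newF, atom_masses, loss, term_loss, loss_sum, atom_loss

    def apply_sojourn_preserving(self, F, atom_tau, atom_masses, m, occ):
        """Exchange density between states at equal sojourn at rates mu."""
        if not self.mu:
            return F, atom_masses
        dt = self.dt
        t_mid = (m - 0.5) * dt + self.t_offset
        if self._mu_static_P is not None:
            P = self._mu_static_P
            F[:, 1:] = P @ F[:, 1:]
            if atom_masses.size:
                atom_masses = (P @ atom_masses.T).T
            return F, atom_masses
        if all(c in ("constant", "model_time") for c in self._mu_cls):
            Q = np.zeros((self.N, self.N))
            for tr in self.mu:
                r = float(tr.hazard.rate(t_mid, 0.0, occ))
                i, j = self.model.index(tr.source), self.model.index(tr.target)
                Q[i, j] += r
                Q[i, i] -= r
            P = expm(Q.T * dt)
            F[:, 1:] = P @ F[:, 1:]
            if atom_masses.size:
                atom_masses = (P @ atom_masses.T).T
            return F, atom_masses
        # tau-dependent mu: per-column matrix exponential (midpoint rates)
        for n in range(1, F.shape[1]):
            tau_mid = dt * (n - 0.5)
            Q = np.zeros((self.N, self.N))
            for tr in self.mu:
                r = float(tr.hazard.rate(t_mid, tau_mid, occ))
                i, j = self.model.index(tr.source), self.model.index(tr.target)
                Q[i, j] += r
                Q[i, i] -= r
            F[:, n] = expm(Q.T * dt) @ F[:, n]
        for a in range(len(atom_tau)):
            tau_mid = atom_tau[a] + 0.5 * dt
            Q = np.zeros((self.N, self.N))
            for tr in self.mu:
                r = float(tr.hazard.rate(t_mid, tau_mid, occ))
                i, j = self.model.index(tr.source), self.model.index(tr.target)
                Q[i, j] += r
                Q[i, i] -= r
            atom_masses[a] = expm(Q.T * dt) @ atom_masses[a]
        return F, atom_masses

    def compute_boundary(self, F, arrays, loss, term_loss, loss_sum, atom_loss,
                         atom_tau, atom_masses, m, occ):
        """Entry densities F[i][m, 0] under the selected scheme."""
        N, n_tau, dt = self.N, self.n_tau, self.dt
        boundary = np.zeros(N)
        if self.scheme == "mass_conserving":
            # midpoint hazard shares per source state (scalar where possible)
            tot_mid: list = [0.0] * N
            tot_mid_term = [0.0] * N
            for tr, (_s, _st, mid, midterm, _b) in zip(self.lam, arrays):
                i = self.model.index(tr.source)
                tot_mid[i] = tot_mid[i] + mid
                tot_mid_term[i] = tot_mid_term[i] + midterm
            if atom_loss.size:
                t_mid = (m - 0.5) * dt + self.t_offset
                tau_amid = atom_tau + 0.5 * dt
                rate_a = np.zeros((len(self.lam), len(atom_tau)))
                tot_a = np.zeros((len(atom_tau), N))
                for u, tr in enumerate(self.lam):
                    i = self.model.index(tr.source)
                    rate_a[u] = np.asarray(tr.hazard.rate(t_mid, tau_amid, occ), float)
                    tot_a[:, i] += rate_a[u]
            for u, (tr, (_s, _st, mid, midterm, _b)) in enumerate(zip(self.lam, arrays)):
                i, j = self.model.index(tr.source), self.model.index(tr.target)
                if loss[i] is None:  # scalar state: one share for every cell
                    tm = float(tot_mid[i])
                    if tm > 0:
                        boundary[j] += float(mid) / tm * loss_sum[i]
                else:
                    tm = np.asarray(tot_mid[i], float)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        w = np.where(tm > 0, mid / np.where(tm > 0, tm, 1.0), 0.0)
                    tmt = float(tot_mid_term[i])
                    w_term = float(midterm) / tmt if tmt > 0 else 0.0
                    boundary[j] += float(np.dot(w, loss[i])) + w_term * term_loss[i]
                if atom_loss.size:
                    ta = tot_a[:, i]
                    wa = np.where(ta > 0, rate_a[u] / np.where(ta > 0, ta, 1.0), 0.0)
                    boundary[j] += float(np.dot(wa, atom_loss[:, i])) / dt
        else:  # first_order, rectangle rule over k > 0 at time m dt
            for tr, (_s, _st, _m, _mt, bnd) in zip(self.lam, arrays):
                i, j = self.model.index(tr.source), self.model.index(tr.target)
                if np.isscalar(bnd) or np.ndim(bnd) == 0:
                    boundary[j] += dt * float(bnd) * float(F[i, 1:].sum())
                else:
                    boundary[j] += dt * float(np.dot(np.asarray(bnd, float), F[i, 1:]))
                if atom_masses.size:
                    t_now = m * dt + self.t_offset
                    r = np.asarray(tr.hazard.rate(t_now, atom_tau + dt, occ), float)
                    boundary[j] += float(np.dot(np.broadcast_to(r, (len(atom_tau),)),
                                                atom_masses[:, i]))
        return boundary


def _seed_initial(model: ModelSpec, n_tau: int):
    N = len(model.states)
    dt = model.grid.dt
    F = np.zeros((N, n_tau + 1))
    init = model.initial
    if init.density_cells is not None:
        if init.density_cells_dt is None or abs(init.density_cells_dt - dt) > 1e-12:
            raise ValueError("density_cells were stored at a different dt")
        for s, v in init.density_cells.items():
            i = model.index(s)
            k = min(len(v), n_tau + 1)
            F[i, :k] = v[:k]
            if len(v) > n_tau + 1:
                F[i, n_tau] += v[n_tau + 1:].sum()
    for s, (taus, vals) in init.density_samples.items():
        i = model.index(s)
        grid_tau = np.arange(n_tau + 1) * dt
        F[i] += np.interp(grid_tau, np.asarray(taus, float), np.asarray(vals, float),
                          left=0.0, right=0.0)
    taus = np.array([a.sojourn for a in init.atoms], float)
    masses = np.zeros((len(init.atoms), N))
    for k, a in enumerate(init.atoms):
        masses[k, model.index(a.state)] = a.mass
    return F, taus, masses


def run(model: ModelSpec, scheme: str = "mass_conserving", *,
        store_history: bool = False, t_offset: float = 0.0,
        segment_integration: str = "exact", check_validation: bool = True) -> SolveResult:
    """Solve the sojourn density model over ``[0, max_t]``.

    Parameters
    ----------
    scheme
        ``mass_conserving`` (default) redistributes exactly the mass each cell
        loses; ``first_order`` uses the rectangle-rule boundary.
    store_history
        Keep the full density lattice at every step (needed for conditional
        restarts; memory scales as steps x states x sojourn cells).
    t_offset
        Model time of the first step; hazards with explicit time dependence
        are evaluated at ``t_offset + t``.  Used when restarting mid-horizon.
    segment_integration
        ``exact`` (closed forms where available) or ``midpoint`` (the generic
        one-point rule applied everywhere).
    """
    if check_validation:
        errors = [d for d in model.validate() if d.level == "error"]
        if errors:
            raise ModelValidationError(errors)
    st = _Stepper(model, scheme, segment_integration, t_offset)
    N, M, n_tau, dt = st.N, st.M, st.n_tau, st.dt

    F, atom_tau, atom_masses = _seed_initial(model, n_tau)
    g = np.zeros((M + 1, N))
    flux = np.zeros((M + 1, N))
    g[0] = dt * F.sum(axis=1) + atom_masses.sum(axis=0)
    flux[0] = F[:, 0]
    total0 = g[0].sum()

    history = atom_hist_tau = atom_hist_m = None
    if store_history:
        history = np.zeros((M + 1, N, n_tau + 1))
        history[0] = F
        atom_hist_tau = np.zeros((M + 1, len(atom_tau)))
        atom_hist_m = np.zeros((M + 1, len(atom_tau), N))
        atom_hist_tau[0] = atom_tau
        atom_hist_m[0] = atom_masses

    max_step_hazard = 0.0
    residual = 0.0
    terminal_mass = 0.0
    occ = None
    for m in range(1, M + 1):
        if st.coupled:
            occ = dict(zip(model.states, g[m - 1]))
        arrays = st._transition_arrays(m, occ)
        F, atom_masses, loss, term_loss, loss_sum, atom_loss = st.advance_characteristics(
            F, atom_tau, atom_masses, arrays, m, occ)
        F, atom_masses = st.apply_sojourn_preserving(F, atom_tau, atom_masses, m, occ)
        boundary = st.compute_boundary(F, arrays, loss, term_loss, loss_sum, atom_loss,
                                       atom_tau, atom_masses, m, occ)
        F[:, 0] = boundary
        atom_tau = atom_tau + dt
        g[m] = dt * F.sum(axis=1) + atom_masses.sum(axis=0)
        flux[m] = F[:, 0]
        residual = max(residual, abs(g[m].sum() - total0))
        if store_history:
            history[m] = F
            atom_hist_tau[m] = atom_tau
            atom_hist_m[m] = atom_masses
        # step-size sanity: per-step total hazard should stay below 1
        step_hz = 0.0
        for tr, (seg, segterm, *_r) in zip(st.lam, arrays):
            step_hz = max(step_hz, float(np.max(np.atleast_1d(seg))), float(segterm))
        max_step_hazard = max(max_step_hazard, step_hz)
    terminal_mass = float(dt * F[:, -1].sum())
    if max_step_hazard >= 1.0:
        warnings.warn(
            f"per-step cumulative hazard reached {max_step_hazard:.3g} >= 1; "
            "reduce dt for acceptable accuracy", RuntimeWarning, stacklevel=2)

    traj = OccupancyTrajectory(
        times=np.arange(M + 1) * dt, states=list(model.states),
        occupancy=g, entry_flux=flux)
    grid = DensityGrid(
        dt=dt, states=list(model.states), values=F,
        atom_taus=atom_tau, atom_masses=atom_masses,
        history=history, atom_tau_history=atom_hist_tau, atom_mass_history=atom_hist_m)
    diagnostics = {
        "scheme": scheme,
        "dt": dt,
        "conservation_residual": residual,
        "max_step_hazard": max_step_hazard,
        "terminal_sojourn_bin_mass": terminal_mass,
    }
    return SolveResult(trajectory=traj, density=grid, diagnostics=diagnostics,
                       scheme=scheme, t_offset=t_offset)
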