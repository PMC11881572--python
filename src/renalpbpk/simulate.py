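"""Dose-event simulation of compartment networks.

Between dose events the system is linear and time-invariant, so the default
integrator propagates the exact solution with matrix exponentials of the
augmented system (state + constant infusion input), handling boluses as
state jumps and infusions as piecewise-constant inputs.  ``method="lsoda"``
integrates the same equations with a stiff adaptive solver
(``scipy.integrate.solve_ivp``) as an independent numerical route.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .config import DoseRegimen, DrugParameters
from .network import CompartmentNetwork

__all__ = [
    "SimulationResult",
    "simulate",
    "compute_auc",
    "mass_balance",
    "blood_to_unbound_plasma",
    "SolverError",
]

_NEGATIVE_TOL = 1e-9  # relative to peak state before a warning is raised


class SolverError(RuntimeError):
    """The ODE integration failed."""


class SimulationResult:
    """Time grid, per-compartment amounts and co-integrated AUC states."""

    def __init__(self, net: CompartmentNetwork, times: np.ndarray, states: np.ndarray,
                 regimen: DoseRegimen):
        self.network = net
        self.times = times
        self._states = states
        self.regimen = regimen
        self._names = net.names
        self._trackers = net.tracker_names

    # -- amounts and concentrations -----------------------------------
    def amount(self, compartment: str) -> np.ndarray:
        """Amount (mg) versus time in one compartment (sinks included)."""
        return self._states[:, self._names.index(compartment)]

    def concentration(self, compartment: str, driving: str = "total") -> np.ndarray:
        """Concentration (mg/L) versus time; ``driving`` selects the phase
        convention (total / plasma / unbound) of the emitted concentration."""
        k = self.network.rate_coefficient(compartment, driving)
        return self.amount(compartment) * k

    def tracker(self, name: str) -> np.ndarray:
        """Cumulative AUC state (mg*h/L) of a registered tracker."""
        if name not in self._trackers:
            raise KeyError(
                f"{name!r} is not a tracked AUC; register it with "
                f"CompartmentNetwork.track() before simulating "
                f"(available: {self._trackers})"
            )
        return self._states[:, len(self._names) + self._trackers.index(name)]

    def tracker_at(self, name: str, t: float) -> float:
        values = self.tracker(name)
        if not self.times[0] <= t <= self.times[-1]:
            raise ValueError(f"t={t} outside the simulated span "
                             f"[{self.times[0]}, {self.times[-1]}]")
        return float(np.interp(t, self.times, values))

    def total_in_system(self) -> np.ndarray:
        """Sum of all compartment and sink amounts over time."""
        return self._states[:, : len(self._names)].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy output: time_h, compartment, concentration_mg_L / amount_mg."""
        rows = []
        for comp in self.network.compartments:
            if comp.phase == "sink":
                rows.append(pd.DataFrame({
                    "time_h": self.times, "compartment": comp.name,
                    "concentration_mg_L": np.nan, "amount_mg": self.amount(comp.name),
                }))
            else:
                rows.append(pd.DataFrame({
                    "time_h": self.times, "compartment": comp.name,
                    "concentration_mg_L": self.concentration(comp.name),
                    "amount_mg": self.amount(comp.name),
                }))
        return pd.concat(rows, ignore_index=True)


def _infusion_rates(net: CompartmentNetwork, regimen: DoseRegimen, t: float) -> np.ndarray:
    """Input vector (mg/h) at time t from all active infusions."""
    u = np.zeros(net.n_states)
    for e in regimen.events:
        if e.infusion_duration > 0 and e.start <= t < e.start + e.infusion_duration:
            u[net.index(e.target)] += e.amount / e.infusion_duration
    return u


def _breakpoints(regimen: DoseRegimen, t_end: float) -> np.ndarray:
    pts = {0.0, t_end}
    for e in regimen.events:
        if e.start < t_end:
            pts.add(e.start)
        if e.infusion_duration > 0 and e.start + e.infusion_duration < t_end:
            pts.add(e.start + e.infusion_duration)
    return np.array(sorted(pts))


def simulate(
    net: CompartmentNetwork,
    regimen: DoseRegimen,
    t_end: float,
    grid: np.ndarray | None = None,
    method: str = "expm",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate ``net`` under ``regimen`` from 0 to ``t_end`` hours.

    ``grid`` is the output time grid (default 1001 equidistant points; dose
    event times are always included).  ``method`` is ``"expm"`` (exact
    piecewise matrix-exponential propagation, the default) or ``"lsoda"``.
    """
    for e in regimen.events:
        if e.target not in net:
            raise ValueError(f"dose target {e.target!r} is not in the network")
        if e.start >= t_end:
            raise ValueError(f"dose at t={e.start} h starts at/after t_end={t_end} h")
    if grid is None:
        grid = np.linspace(0.0, t_end, 1001)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    if grid[0] < 0 or grid[-1] > t_end:
        raise ValueError("grid must lie within [0, t_end]")

    times = np.unique(np.concatenate([grid, _breakpoints(regimen, t_end)]))
    times = times[(times >= grid[0] - 1e-12) & (times <= grid[-1] + 1e-12)]
    if times[0] > 0:
        times = np.concatenate([[0.0], times])

    a = net.matrices()
    n = net.n_states
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    states = np.empty((len(times), n))

    boluses: dict[float, np.ndarray] = {}
    for e in regimen.events:
        if e.infusion_duration == 0:
            v = boluses.setdefault(e.start, np.zeros(n))
            v[net.index(e.target)] += e.amount

    expm_cache: dict = {}

    def propagate_expm(x, t0, t1, u):
        dt = t1 - t0
        if dt <= 0:
            return x
        if np.any(u):
            key = ("aug", round(dt, 12), tuple(np.round(u, 12)))
            if key not in expm_cache:
                m = np.zeros((n + 1, n + 1))
                m[:n, :n] = a * dt
                m[:n, n] = u * dt
                expm_cache[key] = expm(m)
            e_full = expm_cache[key]
            return e_full[:n, :n] @ x + e_full[:n, n]
        key = ("hom", round(dt, 12))
        if key not in expm_cache:
            expm_cache[key] = expm(a * dt)
        return expm_cache[key] @ x

    if method not in ("expm", "lsoda"):
        raise ValueError(f"unknown method {method!r}")

    if method == "expm":
        for i, t in enumerate(times):
            if i > 0:
                t_prev = times[i - 1]
                u = _infusion_rates(net, regimen, 0.5 * (t_prev + t))
                x = propagate_expm(x, t_prev, t, u)
            if t in boluses:
                x = x + boluses[t]
            states[i] = x
    else:
        # integrate each inter-event segment in one adaptive solve
        seg_edges = _breakpoints(regimen, t_end)
        seg_edges = seg_edges[(seg_edges >= times[0]) & (seg_edges <= times[-1])]
        if times[0] in boluses:
            x = x + boluses[times[0]]
        states[0] = x
        pos = 1
        for lo, hi in zip(seg_edges[:-1], seg_edges[1:]):
            inside = times[(times > lo) & (times <= hi)]
            u = _infusion_rates(net, regimen, 0.5 * (lo + hi))
            sol = solve_ivp(
                lambda t, y: a @ y + u, (lo, hi), x,
                method="LSODA", jac=lambda t, y: a, rtol=rtol, atol=atol,
                t_eval=inside, dense_output=False,
            )
            if not sol.success:
                raise SolverError(f"LSODA failed on [{lo}, {hi}]: {sol.message}")
            n_inside = sol.y.shape[1]
            states[pos:pos + n_inside] = sol.y.T
            x = sol.y[:, -1].copy()
            pos += n_inside
            if hi in boluses:
                x = x + boluses[hi]
                states[pos - 1] = x  # bolus applies at the segment edge

    # numerical negativity guard
    n_comp = len(net.names)
    peak = np.abs(states[:, :n_comp]).max() or 1.0
    worst = states[:, :n_comp].min()
    if worst < -_NEGATIVE_TOL * peak:
        warnings.warn(
            f"negative concentration excursion ({worst:.3e} mg at peak scale "
            f"{peak:.3e}); flooring at 0", RuntimeWarning,
        )
    np.clip(states[:, :n_comp], 0.0, None, out=states[:, :n_comp])

    return SimulationResult(net, times, states, regimen)


def compute_auc(result: SimulationResult, tracker: str, t0: float, t1: float) -> float:
    """AUC (mg*h/L) between t0 and t1 from a co-integrated tracker state."""
    if t0 >= t1:
        raise ValueError("need t0 < t1")
    return result.tracker_at(tracker, t1) - result.tracker_at(tracker, t0)


def mass_balance(result: SimulationResult) -> float:
    """Max relative mass-balance error over the simulated span.

    Compares the cumulative dosed amount with the total amount in all
    compartments plus sinks at every output time; 0 for a perfect
    simulation of a conservative system.
    """
    total_dose = result.regimen.total_dose
    if total_dose == 0:
        return 0.0
    dosed = np.zeros_like(result.times)
    for e in result.regimen.events:
        if e.infusion_duration == 0:
            dosed += np.where(result.times >= e.start, e.amount, 0.0)
        else:
            frac = np.clip((result.times - e.start) / e.infusion_duration, 0.0, 1.0)
            dosed += e.amount * frac
    return float(np.max(np.abs(dosed - result.total_in_system())) / total_dose)


def blood_to_unbound_plasma(c_blood, drug: DrugParameters):
    """Unbound plasma concentration from a whole-blood concentration.

    Divides by the blood:plasma ratio and multiplies by the unbound
    fraction: ``C_u = fu * C_blood / BP``.
    """
    c_blood = np.asarray(c_blood, dtype=float)
    if np.any(c_blood < 0):
        raise ValueError("blood concentration must be >= 0")
    out = c_blood / drug.blood_plasma_ratio * drug.fu_plasma
    return float(out) if out.ndim == 0 else out
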