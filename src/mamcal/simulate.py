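"""Rest-state computation and stiff integration of stimulation protocols.

Every protocol simulation starts, by convention, from the P_s = 0 steady
state of its parameter set (the "rest state"), found by long relaxation
followed by Newton polishing and cached per parameter set.  Integration
uses LSODA (stiff-capable, Adams/BDF switching) with the protocol
breakpoints as hard solver restarts, so square IP3 pulses are resolved
exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import (
    STATE_VARS,
    ModelState,
    ParameterSet,
    calcium_fluxes,
    compute_CER,
    ipr_gating,
    mitochondrial_rates,
    plasma_membrane_fluxes,
    rhs_fixed_input,
)
from .stimulation import StimulusProtocol

__all__ = [
    "SimulationError",
    "Trajectory",
    "find_rest_state",
    "integrate",
    "clear_rest_cache",
    "DEFAULT_RTOL",
    "default_atol",
]

DEFAULT_RTOL = 1e-8
#: Per-variable absolute tolerances: 1e-10 µM for concentrations,
#: 1e-8 for the dimensionless gates, 1e-6 mV for the membrane potential.
_ATOL_BY_VAR = {
    "C_cyt": 1e-10, "C_MAM": 1e-10, "C_mito": 1e-10, "C_t": 1e-10, "P": 1e-10,
    "h42": 1e-8, "hn42": 1e-8,
    "ADP_c": 1e-10, "ADP_m": 1e-10, "N": 1e-10,
    "V_m": 1e-6,
}

REST_RESIDUAL_TOL = 1e-9  # scaled sup-norm defining convergence


def default_atol() -> np.ndarray:
    return np.array([_ATOL_BY_VAR[v] for v in STATE_VARS])


class SimulationError(RuntimeError):
    """Raised when the integrator or the rest-state search fails."""


@dataclass
class Trajectory:
    """A simulated solution on a uniform time grid.

    ``states`` is an (n_times, 11) array in :data:`mamcal.model.STATE_VARS`
    order.  Derived observables (ER Ca2+, ATP/NAD via the conservation
    relations, individual fluxes) are computed on demand.
    """

    t: np.ndarray
    states: np.ndarray
    params: ParameterSet = None
    protocol: StimulusProtocol = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.t.ndim != 1 or self.states.shape != (self.t.size, len(STATE_VARS)):
            raise ValueError("t must be 1-D and states (len(t), 11)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def __getitem__(self, var: str) -> np.ndarray:
        if var in STATE_VARS:
            return self.states[:, STATE_VARS.index(var)]
        return self.derived()[var]

    def state_at(self, i: int) -> ModelState:
        return ModelState.from_array(self.states[i])

    def derived(self) -> dict:
        """ER Ca2+ and the algebraically conserved metabolite pools."""
        p = self.params
        C_cyt, C_MAM, C_mito, C_t = (self.states[:, i] for i in range(4))
        C_ER = p.R_V2 * p.f_c * (
            C_t - C_MAM / (p.R_V1 * p.f_c) - C_cyt / p.f_c
            - C_mito / (p.R_V3 * p.f_m)
        )
        return {
            "C_ER": C_ER,
            "ATP_c": p.A_tot_cyt - self["ADP_c"],
            "ATP_m": p.A_tot_mito - self["ADP_m"],
            "NAD": p.N_tot_mito - self["N"],
        }

    def fluxes(self) -> pd.DataFrame:
        """All J_* and I_* rates along the trajectory (µM/s)."""
        rows = []
        C_ER = self.derived()["C_ER"]
        for i in range(self.t.size):
            s = self.state_at(i)
            g = ipr_gating(s, C_ER[i], self.params)
            f = calcium_fluxes(s, C_ER[i], g, self.params)
            pm = plasma_membrane_fluxes(s, C_ER[i], self.params)
            f.J_leakin, f.J_SOCC, f.J_ROCC = pm["J_leakin"], pm["J_SOCC"], pm["J_ROCC"]
            f.J_in, f.J_pm = pm["J_in"], pm["J_pm"]
            mitochondrial_rates(s, f, self.params, bound_tol=1e-3)
            rows.append(vars(f) if hasattr(f, "__dict__") else {
                k: getattr(f, k) for k in f.__slots__})
        return pd.DataFrame(rows, index=self.t)

    def to_dataframe(self, derived: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_VARS))
        df.insert(0, "t", self.t)
        if derived and self.params is not None:
            for k, v in self.derived().items():
                df[k] = v
        return df

    @property
    def params_id(self) -> str:
        """Provenance hash of the parameter set and protocol."""
        h = hashlib.sha256(repr(self.params).encode())
        if self.protocol is not None:
            h.update(repr(self.protocol.to_dict()).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Rest state
# ---------------------------------------------------------------------------

_REST_CACHE: dict = {}


def clear_rest_cache() -> None:
    _REST_CACHE.clear()


def _default_guess(params: ParameterSet) -> np.ndarray:
    # A physiologically sensible starting point; the relaxation integration
    # does the real work.
    C_cyt = 0.05
    C_MAM = 0.05
    C_mito = 0.05
    C_ER = 500.0
    p = params
    C_t = (
        C_ER / (p.R_V2 * p.f_c)
        + C_MAM / (p.R_V1 * p.f_c)
        + C_cyt / p.f_c
        + C_mito / (p.R_V3 * p.f_m)
    )
    return np.array([
        C_cyt, C_MAM, C_mito, C_t, 0.0, 0.99, 0.99,
        1000.0, 7000.0, 125.0, 150.0,
    ])


def _scaled_residual(y: np.ndarray, params: ParameterSet) -> float:
    dy = rhs_fixed_input(0.0, y, params, 0.0, 0.0)
    return float(np.max(np.abs(dy) / (1.0 + np.abs(y))))


def find_rest_state(
    params: ParameterSet,
    guess=None,
    t_relax: float = 5000.0,
    use_cache: bool = True,
) -> ModelState:
    """P_s = 0 steady state of the model.

    Long relaxation (``t_relax`` seconds of unstimulated dynamics) followed
    by Newton polishing; convergence means a state-scaled residual
    sup-norm below 1e-9.  At this state the SERCA net fluxes vanish, which
    pins the resting concentration ratio to C_cyt/C_ER = sqrt(k_bar).
    Results are cached per parameter set.
    """
    key = params.key()
    if use_cache and key in _REST_CACHE:
        return ModelState.from_array(_REST_CACHE[key].copy())

    if guess is None:
        y = _default_guess(params)
    elif isinstance(guess, ModelState):
        y = guess.to_array()
    else:
        y = np.asarray(guess, dtype=float).copy()

    def fun(t, yy):
        return rhs_fixed_input(t, yy, params, 0.0, 0.0)

    best = y
    for attempt in range(3):
        if attempt > 0 or guess is None:
            span = t_relax * (4 ** max(attempt - (0 if guess is None else 1), 0))
            sol = solve_ivp(
                fun, (0.0, span), best, method="LSODA",
                rtol=DEFAULT_RTOL, atol=default_atol(),
            )
            if not sol.success:
                raise SimulationError(
                    f"rest-state relaxation failed: {sol.message}"
                )
            best = sol.y[:, -1]
        res = root(lambda yy: fun(0.0, yy), best, method="hybr")
        if res.success and _scaled_residual(res.x, params) < REST_RESIDUAL_TOL:
            best = res.x
            break
        if _scaled_residual(best, params) < REST_RESIDUAL_TOL:
            break
    else:
        raise SimulationError(
            "rest state did not converge: scaled residual "
            f"{_scaled_residual(best, params):.3e} (tolerance {REST_RESIDUAL_TOL})"
        )

    if use_cache:
        _REST_CACHE[key] = np.asarray(best, dtype=float).copy()
    return ModelState.from_array(best)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def integrate(
    params: ParameterSet,
    protocol: StimulusProtocol,
    t_end: float = None,
    initial="rest",
    output_dt: float = 0.1,
    rtol: float = DEFAULT_RTOL,
    atol=None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model under ``protocol`` and sample on a uniform grid.

    ``initial`` is either the string ``"rest"`` (start from the cached
    P_s = 0 steady state of ``params``), a :class:`ModelState`, or an
    11-vector.  The solver restarts at every protocol breakpoint; between
    breakpoints the IP3 target and pulse rate are constants, so the square
    pulse is represented exactly.
    """
    t_start, span_end = protocol.span
    if t_end is None:
        t_end = span_end
    if not (t_start < t_end <= span_end):
        raise ValueError(
            f"t_end={t_end!r} must lie in ({t_start}, {span_end}]"
        )
    if output_dt <= 0:
        raise ValueError("output_dt must be > 0")
    if atol is None:
        atol = default_atol()

    if isinstance(initial, str):
        if initial != "rest":
            raise ValueError(f"unknown initial condition {initial!r}")
        y0 = find_rest_state(params).to_array()
    elif isinstance(initial, ModelState):
        y0 = initial.to_array()
    else:
        y0 = np.asarray(initial, dtype=float).copy()

    grid = t_start + output_dt * np.arange(int(round((t_end - t_start) / output_dt)) + 1)
    grid = grid[grid <= t_end + 1e-9]
    if grid[-1] < t_end - 1e-9:
        grid = np.append(grid, t_end)

    edges = [t for t in protocol.breakpoints() if t_start < t < t_end]
    pieces = np.array([t_start] + edges + [t_end])

    out = np.empty((grid.size, len(STATE_VARS)))
    out[0] = y0
    filled = 1
    y = y0
    for a, b in zip(pieces[:-1], pieces[1:]):
        tm = 0.5 * (a + b)
        Ps = protocol.ps_at(tm)
        pulse = protocol.pulse_at(tm)

        def fun(t, yy, Ps=Ps, pulse=pulse):
            return rhs_fixed_input(t, yy, params, Ps, pulse)

        idx = np.nonzero((grid > a + 1e-12) & (grid <= b + 1e-12))[0]
        t_req = np.clip(grid[idx], a, b)  # grid points may miss the edge by ~1 ulp
        t_eval = np.unique(np.append(t_req, b))
        sol = solve_ivp(
            fun, (a, b), y, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        )
        if not sol.success:
            t_fail = sol.t[-1] if sol.t.size else a
            y_fail = sol.y[:, -1] if sol.t.size else y
            dy = rhs_fixed_input(t_fail, y_fail, params, Ps, pulse)
            worst = STATE_VARS[int(np.argmax(np.abs(dy)))]
            raise SimulationError(
                f"integration failed at t={t_fail:.6g}: {sol.message} "
                f"(largest derivative term d{worst}/dt = {dy[np.argmax(np.abs(dy))]:.3e})"
            )
        y = sol.y[:, -1]
        if idx.size:
            pos = np.searchsorted(sol.t, t_req)
            out[idx] = sol.y[:, pos].T
            filled += idx.size
    if filled != grid.size:
        raise SimulationError(
            f"internal grid bookkeeping error: filled {filled} of {grid.size}"
        )
    return Trajectory(t=grid, states=out, params=params, protocol=protocol)
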