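"""The tumor-immune ODE system and its integrators.

Four coupled ODEs describe cancer volume C, CD8+ T-cell volume T, MDSC
volume M (all mm^3) and gemcitabine concentration G (uM):

    dC/dt = pC*C*(1 - C/Cmax) - kTC*T*C - kGC*C*G/(G + Km)
    dT/dt = nCT*C*T - sMT*M*T - dT*T + hT - kGT*T*G/(G + Km) + uT(t)
    dM/dt = rCM*C - sTM*T*M - dM*M + hM - kGM*M*G/(G + Km)
    dG/dt = uG(t) - dG*G

Gem kill terms saturate through the ENT1 transporter (Michaelis-Menten
factor G/(G+Km)).  The homeostatic influxes hT, hM are chosen so that
(C, T, M) = (0, T0, M0) is exactly the tumor-free equilibrium (see
:func:`homeostatic_influx`).  Doses uG, uT are impulses: instantaneous
increments of G or T at the scheduled times, between which the system
is integrated as an autonomous ODE.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import (
    DoseTarget,
    DosingSchedule,
    ModelParams,
    Regimen,
    schedule_for_regimen,
)

__all__ = [
    "homeostatic_influx",
    "rhs_full",
    "rhs_treatment_free",
    "Trajectory",
    "simulate",
    "simulate_regimen",
    "simulate_batch",
    "IntegrationError",
]

#: tolerance below zero accepted as integrator round-off and clipped
_NEG_TOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (t = {t_fail:g})")
        self.t_fail = t_fail


def homeostatic_influx(params: ModelParams) -> tuple[float, float]:
    """Influx rates (hT, hM) fixing (0, T0, M0) as tumor-free equilibrium.

    Substituting (C, T, M) = (0, T0, M0), G = 0 into the T and M
    equations and requiring dT/dt = dM/dt = 0 gives

        hT = sMT*M0*T0 + dT*T0,     hM = sTM*T0*M0 + dM*M0,

    i.e. the suppression terms are evaluated at the homeostatic volumes
    (they are bilinear in suppressor and target), so the equilibrium
    holds by construction for every parameterization.
    """
    hT = (params.sMT * params.M0 + params.dT) * params.T0
    hM = (params.sTM * params.T0 + params.dM) * params.M0
    return hT, hM


def rhs_full(state: Sequence[float], params: ModelParams) -> tuple[float, float, float, float]:
    """Right-hand side of the full four-equation system (no impulses)."""
    C, T, M, G = state
    if min(C, T, M, G) < -_NEG_TOL:
        raise ValueError(f"negative state component: {state}")
    hT, hM = homeostatic_influx(params)
    sat = G / (G + params.Km)
    # T and M terms grouped so the tumor-free equilibrium cancels exactly
    dC = params.pC * C * (1.0 - C / params.Cmax) - params.kTC * T * C - params.kGC * C * sat
    dT = T * (params.nCT * C - params.sMT * M - params.dT - params.kGT * sat) + hT
    dM = params.rCM * C + M * (-params.sTM * T - params.dM - params.kGM * sat) + hM
    dG = -params.dG * G
    return dC, dT, dM, dG


def rhs_treatment_free(state: Sequence[float], params: ModelParams) -> tuple[float, float, float]:
    """Right-hand side of the treatment-free (C, T, M) subsystem."""
    C, T, M = state
    if min(C, T, M) < -_NEG_TOL:
        raise ValueError(f"negative state component: {state}")
    hT, hM = homeostatic_influx(params)
    dC = params.pC * C * (1.0 - C / params.Cmax) - params.kTC * T * C
    dT = T * (params.nCT * C - params.sMT * M - params.dT) + hT
    dM = params.rCM * C + M * (-params.sTM * T - params.dM) + hM
    return dC, dT, dM


@dataclass(frozen=True)
class Trajectory:
    """Simulated states on a time grid under one treatment regimen."""

    times: np.ndarray            # (n,), days
    states: np.ndarray           # (n, 4): columns C, T, M, G
    regimen: Regimen

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def M(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def G(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def total_volume(self) -> np.ndarray:
        """Total tumor volume C + T + M, the ultrasound observable."""
        return self.states[:, :3].sum(axis=1)

    def at(self, day: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, day))
        if idx.size == 0:
            raise KeyError(f"day {day} not on the trajectory grid")
        return self.states[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regimen": self.regimen.value,
                "day": self.times,
                "C": self.C,
                "T": self.T,
                "M": self.M,
                "G": self.G,
                "total": self.total_volume,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _solve_segment(
    params: ModelParams,
    y0: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray,
    method: str,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one dose-free segment; returns (states at t_eval, y(t1))."""

    def f(t: float, y: np.ndarray) -> list[float]:
        return list(rhs_full(np.maximum(y, 0.0), params))

    sol = solve_ivp(
        f,
        (t0, t1),
        y0,
        method=method,
        t_eval=t_eval if t_eval.size else None,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}", sol.t[-1] if sol.t.size else t0)
    if t_eval.size:
        states = sol.y.T
        y_end = states[-1] if np.isclose(t_eval[-1], t1) else None
    else:
        states = np.empty((0, 4))
        y_end = None
    if y_end is None:
        sol_end = solve_ivp(f, (t0, t1), y0, method=method, rtol=rtol, atol=atol)
        if not sol_end.success:
            raise IntegrationError(f"ODE solver failed: {sol_end.message}", t1)
        y_end = sol_end.y[:, -1]
    return states, np.asarray(y_end, dtype=float)


def simulate(
    params: ModelParams,
    schedule: DosingSchedule,
    init: Sequence[float],
    t_grid: Sequence[float],
    regimen: Regimen = Regimen.CONTROL,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model on ``t_grid``, applying impulse doses.

    Each dose instantaneously increments the targeted compartment
    (G += amount for Gem, T += amount for OT-1) and the integration is
    restarted from the post-dose state, so a grid point that coincides
    with an event time reports the post-dose state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be nondecreasing")
    t0, t_end = float(t_grid[0]), float(t_grid[-1])
    events = [e for e in schedule.events if t0 < e.time <= t_end]
    if any(e.time < t0 or e.time > t_end for e in schedule.events):
        raise ValueError("t_grid must cover all dose event times")

    y = np.asarray(init, dtype=float)
    if y.shape != (4,) or np.any(y < 0):
        raise ValueError("init must be four nonnegative components (C, T, M, G)")

    out = np.empty((t_grid.size, 4))
    filled = np.zeros(t_grid.size, dtype=bool)
    # grid points exactly at the start
    at_start = np.isclose(t_grid, t0)
    out[at_start] = y
    filled |= at_start

    seg_start = t0
    boundaries = [e.time for e in events] + [t_end]
    doses: list[DoseTarget | None] = [e.target for e in events] + [None]
    amounts = [e.amount for e in events] + [0.0]
    for seg_end, target, amount in zip(boundaries, doses, amounts):
        if seg_end > seg_start:
            # evaluate at grid points inside (seg_start, seg_end]; a point
            # equal to seg_end is reported pre-dose only if it is t_end
            mask = (
                (t_grid > seg_start)
                & (t_grid <= seg_end)
                & ~np.isclose(t_grid, seg_end)
                & ~filled
            )
            if np.isclose(seg_end, t_end) and target is None:
                mask |= np.isclose(t_grid, t_end) & ~filled
            t_eval = np.unique(np.concatenate([t_grid[mask], [seg_end]]))
            states, y = _solve_segment(params, y, seg_start, seg_end, t_eval, method, rtol, atol)
            eval_times = t_eval
            for tg in np.flatnonzero(mask):
                j = int(np.argmin(np.abs(eval_times - t_grid[tg])))
                out[tg] = states[j]
            filled |= mask
        if target is DoseTarget.GEM:
            y = y.copy()
            y[3] += amount
        elif target is DoseTarget.OT1:
            y = y.copy()
            y[1] += amount
        # grid points at the event time report the post-dose state
        if target is not None:
            at_event = np.isclose(t_grid, seg_end) & ~filled
            out[at_event] = y
            filled |= at_event
        seg_start = seg_end

    if not filled.all():  # pragma: no cover - defensive
        raise RuntimeError("internal error: unfilled grid points")
    if out.min() < -_NEG_TOL:
        raise IntegrationError(
            "state fell below zero beyond solver tolerance",
            float(t_grid[int(np.argmin(out.min(axis=1)))]),
        )
    out = np.maximum(out, 0.0)
    return Trajectory(times=t_grid.copy(), states=out, regimen=regimen)


def simulate_regimen(
    params: ModelParams,
    regimen: Regimen,
    t_grid: Sequence[float],
    init: Sequence[float] | None = None,
    **kwargs,
) -> Trajectory:
    """Simulate under a named regimen with the standard dosing calendar."""
    from .params import DAY6_INIT

    if init is None:
        init = DAY6_INIT
    return simulate(params, schedule_for_regimen(regimen), init, t_grid, regimen=regimen, **kwargs)


# ---------------------------------------------------------------------
# Vectorized ensemble integration
# ---------------------------------------------------------------------


def _rhs_batch(y: np.ndarray, p: Mapping[str, np.ndarray | float]) -> np.ndarray:
    """Vectorized RHS for an ensemble; y has shape (n, 4)."""
    C, T, M, G = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
    hT = (p["sMT"] * p["M0"] + p["dT"]) * p["T0"]
    hM = (p["sTM"] * p["T0"] + p["dM"]) * p["M0"]
    sat = G / (G + p["Km"])
    out = np.empty_like(y)
    out[:, 0] = p["pC"] * C * (1.0 - C / p["Cmax"]) - p["kTC"] * T * C - p["kGC"] * C * sat
    out[:, 1] = p["nCT"] * C * T - p["sMT"] * M * T - p["dT"] * T + hT - p["kGT"] * T * sat
    out[:, 2] = p["rCM"] * C - p["sTM"] * T * M - p["dM"] * M + hM - p["kGM"] * M * sat
    out[:, 3] = -p["dG"] * G
    return out


def simulate_batch(
    param_table: Mapping[str, np.ndarray | float],
    regimen: Regimen,
    init: np.ndarray,
    output_days: Sequence[float],
    t_start: float = 6.0,
    dt: float = 0.005,
    gem_dose: float | None = None,
    ot1_dose: float | None = None,
) -> np.ndarray:
    """Integrate an ensemble of parameterizations with fixed-step RK4.

    ``param_table`` maps each of the 16 parameter names to a scalar or a
    length-n array; ``init`` is (n, 4) or (4,).  Returns states of shape
    (len(output_days), n, 4).  Used for the large virtual-cohort and
    sensitivity ensembles where per-member adaptive integration would be
    prohibitively slow; agreement with :func:`simulate` is covered by
    the test suite.
    """
    from .params import GEM_DOSE_UM, OT1_DOSE_MM3, GEM_DAY, OT1_DAY

    p = dict(param_table)
    n = max((np.size(v) for v in p.values()), default=1)
    init = np.atleast_2d(np.asarray(init, dtype=float))
    if init.shape[0] == 1 and n > 1:
        init = np.repeat(init, n, axis=0)
    n = max(n, init.shape[0])

    output_days = np.asarray(output_days, dtype=float)
    t_end = float(output_days.max())
    events: list[tuple[float, int, float]] = []
    if regimen.gem_treated and t_start < GEM_DAY <= t_end:
        events.append((GEM_DAY, 3, GEM_DOSE_UM if gem_dose is None else gem_dose))
    if regimen.ot1_treated and t_start < OT1_DAY <= t_end:
        events.append((OT1_DAY, 1, OT1_DOSE_MM3 if ot1_dose is None else ot1_dose))
    events.sort()

    # build a step grid that lands exactly on events and output days
    knots = np.unique(np.concatenate([[t_start, t_end], output_days, [e[0] for e in events]]))
    grid = [np.array([t_start])]
    for a, b in zip(knots[:-1], knots[1:]):
        nseg = max(1, int(np.ceil((b - a) / dt)))
        grid.append(np.linspace(a, b, nseg + 1)[1:])
    t_pts = np.concatenate(grid)

    event_times = {e[0]: (e[1], e[2]) for e in events}
    out = np.empty((output_days.size, n, 4))
    out_idx = {d: i for i, d in enumerate(output_days)}

    y = init.copy()
    if t_start in out_idx:
        out[out_idx[t_start]] = y
    for a, b in zip(t_pts[:-1], t_pts[1:]):
        h = b - a
        k1 = _rhs_batch(y, p)
        k2 = _rhs_batch(np.maximum(y + 0.5 * h * k1, 0.0), p)
        k3 = _rhs_batch(np.maximum(y + 0.5 * h * k2, 0.0), p)
        k4 = _rhs_batch(np.maximum(y + h * k3, 0.0), p)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.maximum(y, 0.0, out=y)
        if b in event_times:
            comp, amount = event_times[b]
            y[:, comp] += amount
        if b in out_idx:
            out[out_idx[b]] = y
    return out
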