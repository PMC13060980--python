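"""Hierarchical population-level parameter estimation.

Fitting proceeds in two stages against per-cell-type volume data:

* stage 1 fits the treatment-free parameters {pC, Cmax, kTC, nCT, sMT,
  T0, sTM, M0} to the two non-Gem arms (control and OT-1);
* stage 2 fixes those and fits the Gem kill rates {kGC, kGT, kGM} to
  the two Gem arms (Gem and Gem+OT-1).

{dT, rCM, dM, dG, Km} stay fixed at literature/data values throughout.
The reported objective is the summed relative error over the fitted
points; the inner optimizer minimizes the equivalent smooth
least-squares form of the relative residuals (same zero-residual
minimizer) with bounds, started from the best of a Latin-hypercube
parameter scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import simulate_regimen
from .params import DAY6_INIT, ModelParams, Regimen, default_ranges

__all__ = [
    "STAGE1_NAMES",
    "STAGE2_NAMES",
    "FIXED_NAMES",
    "FitResult",
    "summed_relative_error",
    "predict_subpopulations",
    "fit_stage1",
    "fit_stage2",
    "fit_hierarchical",
]

STAGE1_NAMES = ("pC", "Cmax", "kTC", "nCT", "sMT", "T0", "sTM", "M0")
STAGE2_NAMES = ("kGC", "kGT", "kGM")
FIXED_NAMES = ("dT", "rCM", "dM", "dG", "Km")

STAGE1_REGIMENS = (Regimen.CONTROL, Regimen.OT1)
STAGE2_REGIMENS = (Regimen.GEM, Regimen.GEM_OT1)

_CELL_COL = {"C": 0, "T": 1, "M": 2}


@dataclass
class FitResult:
    """Outcome of the two-stage hierarchical fit."""

    stage1_params: dict[str, float]
    stage2_params: dict[str, float]
    fixed_params: dict[str, float]
    objective_stage1: float
    objective_stage2: float
    n_lhs: int
    seed: int
    converged: bool = True
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    def to_params(self) -> ModelParams:
        return ModelParams.from_dict(
            {**self.stage1_params, **self.stage2_params, **self.fixed_params}
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage1_params": self.stage1_params,
            "stage2_params": self.stage2_params,
            "fixed_params": self.fixed_params,
            "objective_stage1": self.objective_stage1,
            "objective_stage2": self.objective_stage2,
            "n_lhs": self.n_lhs,
            "seed": self.seed,
            "converged": self.converged,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "messages": self.messages,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def summed_relative_error(
    sim: pd.DataFrame,
    data: pd.DataFrame,
    regimens: Sequence[Regimen] | None = None,
) -> float:
    """Sum over cohorts, cell populations and days of |data - sim| / data.

    Only rows flagged ``used_in_fit`` in ``data`` contribute; every such
    row must have a matching prediction (same regimen, day, cell_type)
    in ``sim`` and a strictly positive data value.
    """
    used = data[data["used_in_fit"]].copy()
    if regimens is not None:
        names = {r.value for r in regimens}
        used = used[used["regimen"].isin(names)]
    if (used["volume"] <= 0).any():
        bad = used[used["volume"] <= 0].iloc[0]
        raise ValueError(
            f"non-positive data value at regimen={bad['regimen']} day={bad['day']}"
            f" cell={bad['cell_type']}"
        )
    merged = used.merge(
        sim.rename(columns={"volume": "sim_volume"}),
        on=["regimen", "day", "cell_type"],
        how="left",
        validate="one_to_one",
    )
    if merged["sim_volume"].isna().any():
        missing = merged[merged["sim_volume"].isna()].iloc[0]
        raise ValueError(
            f"no prediction for regimen={missing['regimen']} day={missing['day']}"
            f" cell={missing['cell_type']}"
        )
    return float(
        (np.abs(merged["volume"] - merged["sim_volume"]) / merged["volume"]).sum()
    )


def predict_subpopulations(
    params: ModelParams,
    regimens: Sequence[Regimen],
    days: Sequence[float],
    init: Sequence[float] = DAY6_INIT,
) -> pd.DataFrame:
    """Model-predicted per-cell-type volumes at the measurement days."""
    t_grid = np.unique(np.concatenate([[6.0], np.asarray(days, float)]))
    records = []
    for regimen in regimens:
        traj = simulate_regimen(params, regimen, t_grid, init=init)
        for day in days:
            s = traj.at(day)
            for cell, col in _CELL_COL.items():
                records.append(
                    {
                        "regimen": regimen.value,
                        "day": float(day),
                        "cell_type": cell,
                        "volume": float(s[col]),
                    }
                )
    return pd.DataFrame.from_records(records)


def _relative_residuals(
    params: ModelParams, data_used: pd.DataFrame, regimens: Sequence[Regimen]
) -> np.ndarray:
    days = sorted(data_used["day"].unique())
    sim = predict_subpopulations(params, regimens, days)
    merged = data_used.merge(
        sim.rename(columns={"volume": "sim_volume"}),
        on=["regimen", "day", "cell_type"],
        how="left",
        validate="one_to_one",
    )
    return np.asarray((merged["sim_volume"] - merged["volume"]) / merged["volume"])


def _prepare_used(data: pd.DataFrame, regimens: Sequence[Regimen]) -> pd.DataFrame:
    names = {r.value for r in regimens}
    used = data[(data["used_in_fit"]) & (data["regimen"].isin(names))].copy()
    if used.empty:
        raise ValueError(f"no usable data points for regimens {sorted(names)}")
    if (used["volume"] <= 0).any():
        raise ValueError("data values must be > 0 among fitted points")
    return used.sort_values(["regimen", "cell_type", "day"]).reset_index(drop=True)


def _fit_subset(
    free_names: Sequence[str],
    base: ModelParams,
    data: pd.DataFrame,
    regimens: Sequence[Regimen],
    bounds: Mapping[str, tuple[float, float]],
    n_lhs: int,
    seed: int,
    n_polish: int = 3,
) -> tuple[dict[str, float], float, bool, list[str]]:
    used = _prepare_used(data, regimens)
    lo = np.array([bounds[n][0] for n in free_names])
    hi = np.array([bounds[n][1] for n in free_names])

    def residuals(x: np.ndarray) -> np.ndarray:
        p = base.with_values(**dict(zip(free_names, x)))
        return _relative_residuals(p, used, regimens)

    def sre(x: np.ndarray) -> float:
        return float(np.abs(residuals(x)).sum())

    sampler = qmc.LatinHypercube(d=len(free_names), seed=seed)
    pts = lo + sampler.random(n=max(1, n_lhs)) * (hi - lo)
    scores = np.array([sre(x) for x in pts])
    order = np.argsort(scores)

    messages: list[str] = []
    best_x, best_obj, ok = pts[order[0]], scores[order[0]], False
    for idx in order[: max(1, n_polish)]:
        res = least_squares(
            residuals,
            np.clip(pts[idx], lo, hi),
            bounds=(lo, hi),
            x_scale=np.maximum(hi - lo, 1e-12),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        obj = sre(res.x)
        if obj < best_obj:
            best_x, best_obj = res.x, obj
        ok = ok or res.success
        if not res.success:
            messages.append(f"optimizer did not report convergence: {res.message}")
    return dict(zip(free_names, map(float, best_x))), best_obj, ok, messages


def fit_stage1(
    data: pd.DataFrame,
    fixed: Mapping[str, float] | ModelParams | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_lhs: int = 500,
    seed: int = 0,
) -> FitResult:
    """Fit the treatment-free parameters to the control and OT-1 arms.

    ``fixed`` supplies {dT, rCM, dM, dG, Km} (and placeholder Gem kill
    rates, irrelevant for the non-Gem arms); defaults come from the
    shipped parameter set.
    """
    base = _base_params(fixed)
    bounds = dict(bounds or default_ranges())
    values, obj, ok, msgs = _fit_subset(
        STAGE1_NAMES, base, data, STAGE1_REGIMENS, bounds, n_lhs, seed
    )
    return FitResult(
        stage1_params=values,
        stage2_params={},
        fixed_params={n: getattr(base, n) for n in FIXED_NAMES},
        objective_stage1=obj,
        objective_stage2=float("nan"),
        n_lhs=n_lhs,
        seed=seed,
        converged=ok,
        bounds={n: tuple(bounds[n]) for n in STAGE1_NAMES},
        messages=msgs,
    )


def fit_stage2(
    data: pd.DataFrame,
    stage1: FitResult,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_lhs: int = 500,
    seed: int = 0,
) -> FitResult:
    """Fix stage-1 values and fit the Gem kill rates to the Gem arms."""
    base = _base_params(stage1.fixed_params).with_values(**stage1.stage1_params)
    bounds = dict(bounds or default_ranges())
    values, obj, ok, msgs = _fit_subset(
        STAGE2_NAMES, base, data, STAGE2_REGIMENS, bounds, n_lhs, seed
    )
    return FitResult(
        stage1_params=dict(stage1.stage1_params),
        stage2_params=values,
        fixed_params=dict(stage1.fixed_params),
        objective_stage1=stage1.objective_stage1,
        objective_stage2=obj,
        n_lhs=n_lhs,
        seed=seed,
        converged=stage1.converged and ok,
        bounds={**stage1.bounds, **{n: tuple(bounds[n]) for n in STAGE2_NAMES}},
        messages=stage1.messages + msgs,
    )


def fit_hierarchical(
    data: pd.DataFrame,
    fixed: Mapping[str, float] | ModelParams | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_lhs: int = 500,
    seed: int = 0,
) -> FitResult:
    """Run both stages in sequence."""
    s1 = fit_stage1(data, fixed=fixed, bounds=bounds, n_lhs=n_lhs, seed=seed)
    return fit_stage2(data, s1, bounds=bounds, n_lhs=n_lhs, seed=seed + 1)


def _base_params(fixed: Mapping[str, float] | ModelParams | None) -> ModelParams:
    from .params import default_params

    base = default_params()
    if fixed is None:
        return base
    if isinstance(fixed, ModelParams):
        return fixed
    return base.with_values(**dict(fixed))
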