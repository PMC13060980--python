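"""Synthetic cohort generation and the percentage-interpolation transforms.

The murine study measured total tumor volume by ultrasound (days 6, 9,
13, 16, 20 in four arms: control, Gem, OT-1, Gem+OT-1), tumor
composition by histology (T-cell and MDSC area fractions at days 17 and
23) and flow cytometry (Gem-treated vs untreated cell ratios at day
14).  Because total volume alone cannot identify the model, the
composition measurements are linearly interpolated over time and used
to split ultrasound volumes into per-cell-type volumes.

This module generates datasets with that exact structure from a known
ground-truth parameterization, so every downstream stage (fitting,
profiling, cohort building, validation) can be exercised against data
whose generating process is known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Trajectory, simulate_batch, simulate_regimen
from .params import (
    DAY6_MEAN_MM3,
    DAY6_SD_MM3,
    ULTRASOUND_DAYS,
    ModelParams,
    Regimen,
    default_ranges,
    fractions_day6,
)

__all__ = [
    "HISTOLOGY_DAYS",
    "FLOW_DAY",
    "RegimenData",
    "CohortDataset",
    "PercentageInterpolant",
    "SynthConfig",
    "build_percentage_interpolant",
    "subpopulation_volumes",
    "generate_cohort",
    "exact_subpopulation_data",
]

HISTOLOGY_DAYS = (17.0, 23.0)
FLOW_DAY = 14.0
#: day treatment starts; before it all arms share the untreated composition
TREATMENT_START = 10.0

#: days on which T-cell and MDSC volumes enter the fit (nearest ultrasound
#: days to the histology collections); cancer volumes are used at every
#: ultrasound day
TM_FIT_DAYS = (16.0, 20.0)


@dataclass
class RegimenData:
    """Measurements for one treatment arm."""

    ultrasound_days: np.ndarray               # (d,)
    mouse_volumes: pd.DataFrame               # mouse_id x day, NaN = missing
    means: np.ndarray                         # (d,) per-day mean total volume
    sds: np.ndarray                           # (d,) per-day SD
    histology_knots: list[tuple[float, float, float]]  # (day, frac_T, frac_M)

    def __post_init__(self) -> None:
        if np.any(self.sds < 0):
            raise ValueError("SDs must be >= 0")
        for day, f_t, f_m in self.histology_knots:
            if not (0 <= f_t <= 1 and 0 <= f_m <= 1 and f_t + f_m <= 1):
                raise ValueError(f"invalid histology fractions at day {day}")

    @property
    def n_mice(self) -> int:
        return len(self.mouse_volumes)


@dataclass
class CohortDataset:
    """Per-regimen measurement series plus the day-14 flow ratios."""

    regimens: dict[Regimen, RegimenData]
    flow_ratio_day14: tuple[float, float]  # (ratio_T, ratio_M), Gem / untreated

    def n_mice(self, regimen: Regimen) -> int:
        return self.regimens[regimen].n_mice


@dataclass
class PercentageInterpolant:
    """Piecewise-linear tumor composition t -> (frac_C, frac_T, frac_M).

    Knots per regimen: (1, 0, 0) on implantation day 0; the untreated
    interpolation up to treatment start; the flow-cytometry ratio at day
    14 separating Gem-treated arms; regimen-specific histology fractions
    at days 17 and 23.  Beyond the last knot the composition is held
    constant.  frac_C is always the complement 1 - frac_T - frac_M.
    """

    knots: dict[Regimen, np.ndarray]  # (k, 3) columns: day, frac_T, frac_M

    def __post_init__(self) -> None:
        for regimen, arr in self.knots.items():
            days = arr[:, 0]
            if np.any(np.diff(days) <= 0):
                raise ValueError(f"{regimen.value}: knot days must increase")
            f = arr[:, 1:]
            if np.any(f < 0) or np.any(f.sum(axis=1) > 1 + 1e-12):
                raise ValueError(f"{regimen.value}: fractions outside [0, 1]")
            if not np.allclose(arr[0], [0.0, 0.0, 0.0]):
                raise ValueError("composition must be 100% cancer at day 0")

    def fractions(self, regimen: Regimen, t: float | np.ndarray) -> np.ndarray:
        """Composition at time(s) t; returns (..., 3) = (C, T, M)."""
        arr = self.knots[regimen]
        t = np.asarray(t, dtype=float)
        f_t = np.interp(t, arr[:, 0], arr[:, 1])
        f_m = np.interp(t, arr[:, 0], arr[:, 2])
        return np.stack([1.0 - f_t - f_m, f_t, f_m], axis=-1)


def _untreated_line(dataset: CohortDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The untreated composition interpolation: day-0 anchor + histology."""
    knots = sorted(dataset.regimens[Regimen.CONTROL].histology_knots)
    days = np.array([0.0] + [k[0] for k in knots])
    f_t = np.array([0.0] + [k[1] for k in knots])
    f_m = np.array([0.0] + [k[2] for k in knots])
    return days, f_t, f_m


def build_percentage_interpolant(dataset: CohortDataset) -> PercentageInterpolant:
    """Assemble the per-regimen composition interpolant from a dataset."""
    u_days, u_ft, u_fm = _untreated_line(dataset)
    ratio_t, ratio_m = dataset.flow_ratio_day14
    knots: dict[Regimen, np.ndarray] = {}
    for regimen, rdata in dataset.regimens.items():
        ft10 = float(np.interp(TREATMENT_START, u_days, u_ft))
        fm10 = float(np.interp(TREATMENT_START, u_days, u_fm))
        ft14 = float(np.interp(FLOW_DAY, u_days, u_ft))
        fm14 = float(np.interp(FLOW_DAY, u_days, u_fm))
        if regimen.gem_treated:
            ft14 *= ratio_t
            fm14 *= ratio_m
        rows = [(0.0, 0.0, 0.0), (TREATMENT_START, ft10, fm10), (FLOW_DAY, ft14, fm14)]
        rows += [tuple(k) for k in sorted(rdata.histology_knots)]
        knots[regimen] = np.array(rows)
    return PercentageInterpolant(knots=knots)


def subpopulation_volumes(
    dataset: CohortDataset, interp: PercentageInterpolant
) -> pd.DataFrame:
    """Split mean ultrasound volumes into per-cell-type volumes.

    Returns a tidy frame with columns regimen, day, cell_type (C/T/M),
    volume and used_in_fit.  Cancer volumes enter the fit at every
    ultrasound day; T and M volumes only at days 16 and 20, the
    ultrasound days closest to the histology collections.
    """
    records = []
    for regimen, rdata in dataset.regimens.items():
        for day, mean in zip(rdata.ultrasound_days, rdata.means):
            if not np.isfinite(mean):
                raise ValueError(f"missing ultrasound mean at day {day} ({regimen.value})")
            fr = interp.fractions(regimen, day)
            for cell, f in zip("CTM", fr):
                used = True if cell == "C" else day in TM_FIT_DAYS
                records.append(
                    {
                        "regimen": regimen.value,
                        "day": float(day),
                        "cell_type": cell,
                        "volume": float(mean * f),
                        "used_in_fit": bool(used),
                    }
                )
    return pd.DataFrame.from_records(records)


def exact_subpopulation_data(
    truth: ModelParams,
    regimens: Sequence[Regimen] = tuple(Regimen),
    days: Sequence[float] = ULTRASOUND_DAYS,
) -> pd.DataFrame:
    """Idealized noiseless subpopulation volumes straight from the model.

    Bypasses the histology-interpolation approximation: per-cell-type
    volumes are the simulated C, T, M at the measurement days.  This is
    the reference input for parameter-recovery experiments, where the
    data-generating process must coincide exactly with the fitted model.
    """
    records = []
    t_grid = np.unique(np.concatenate([[6.0], np.asarray(days, dtype=float)]))
    for regimen in regimens:
        traj = simulate_regimen(truth, regimen, t_grid)
        for day in days:
            state = traj.at(day)
            for i, cell in enumerate("CTM"):
                used = True if cell == "C" else day in TM_FIT_DAYS
                records.append(
                    {
                        "regimen": regimen.value,
                        "day": float(day),
                        "cell_type": cell,
                        "volume": float(state[i]),
                        "used_in_fit": bool(used),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------


@dataclass
class SynthConfig:
    """Settings of the synthetic-cohort generator.

    Defaults emulate the murine study: 13 mice per arm, day-6 volumes
    Normal(27.6554, 11.2253^2) mm^3 truncated at zero, per-mouse
    biological variability through the generating triple (nCT, rCM,
    kGM) drawn uniformly over the sampling ranges, and 10% multiplicative
    lognormal measurement noise on ultrasound volumes.
    """

    n_mice: int = 13
    ultrasound_days: tuple[float, ...] = ULTRASOUND_DAYS
    day6_mean: float = DAY6_MEAN_MM3
    day6_sd: float = DAY6_SD_MM3
    noise_cv: float = 0.10
    vary_triples: bool = True
    triple_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            k: default_ranges()[k] for k in ("nCT", "rCM", "kGM")
        }
    )
    knot_noise_sd: float = 0.0
    dropout_rate: float = 0.0  # per-mouse chance of death after day 13

    def __post_init__(self) -> None:
        if self.n_mice < 2:
            raise ValueError("n_mice must be >= 2")
        if self.day6_sd < 0 or self.noise_cv < 0 or self.knot_noise_sd < 0:
            raise ValueError("scales must be >= 0")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        for name, (lo, hi) in self.triple_ranges.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {name}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd^2) draws resampled until strictly positive."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _truth_fractions(
    truth: ModelParams, regimen: Regimen, days: Sequence[float]
) -> np.ndarray:
    t_grid = np.unique(np.concatenate([[6.0], np.asarray(days, dtype=float)]))
    traj = simulate_regimen(truth, regimen, t_grid)
    out = []
    for day in days:
        s = traj.at(day)
        total = s[:3].sum()
        out.append([s[1] / total, s[2] / total])
    return np.array(out)  # (len(days), 2): frac_T, frac_M


def generate_cohort(
    truth: ModelParams, config: SynthConfig | None = None, seed: int = 0
) -> CohortDataset:
    """Generate a four-arm cohort dataset from a ground-truth model.

    Per-mouse trajectories are simulated with mouse-specific generating
    triples and day-6 volumes; ultrasound totals carry multiplicative
    lognormal noise.  Histology knots and day-14 flow ratios are
    computed from the truth simulation's subpopulation fractions, so the
    composed interpolation/splitting transform approximately recovers
    the simulated subpopulation volumes.  Fully reproducible from seed.
    """
    if config is None:
        config = SynthConfig()
    rng = np.random.default_rng(seed)
    days = np.asarray(config.ultrasound_days, dtype=float)
    f_day6 = np.array(fractions_day6())
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    # composition knots from the truth simulation
    hist = {r: _truth_fractions(truth, r, HISTOLOGY_DAYS) for r in Regimen}
    f14 = {r: _truth_fractions(truth, r, [FLOW_DAY])[0] for r in (Regimen.CONTROL, Regimen.GEM)}
    ratio_t = float(f14[Regimen.GEM][0] / f14[Regimen.CONTROL][0])
    ratio_m = float(f14[Regimen.GEM][1] / f14[Regimen.CONTROL][1])

    regimen_data: dict[Regimen, RegimenData] = {}
    for regimen in Regimen:
        n = config.n_mice
        v6 = _truncated_normal(rng, config.day6_mean, config.day6_sd, n)
        table = {name: getattr(truth, name) for name in truth.to_dict()}
        if config.vary_triples:
            for name, (lo, hi) in config.triple_ranges.items():
                table[name] = rng.uniform(lo, hi, size=n)
        init = v6[:, None] * np.array([f_day6[0], f_day6[1], f_day6[2], 0.0])
        states = simulate_batch(table, regimen, init, days)  # (d, n, 4)
        totals = states[:, :, :3].sum(axis=2).T  # (n, d)
        if config.noise_cv > 0:
            noise = np.exp(sigma * rng.standard_normal(totals.shape) - 0.5 * sigma**2)
            totals = totals * noise
        volumes = pd.DataFrame(
            totals, index=[f"{regimen.value}_{i:02d}" for i in range(n)], columns=days
        )
        if config.dropout_rate > 0:
            censorable = days[days > 13.0]
            for mid in volumes.index:
                if rng.uniform() < config.dropout_rate and censorable.size:
                    cut = rng.choice(censorable)
                    volumes.loc[mid, volumes.columns >= cut] = np.nan

        knots = []
        for day, (f_t, f_m) in zip(HISTOLOGY_DAYS, hist[regimen]):
            if config.knot_noise_sd > 0:
                f_t = float(np.clip(f_t * np.exp(rng.normal(0, config.knot_noise_sd)), 0, 1))
                f_m = float(np.clip(f_m * np.exp(rng.normal(0, config.knot_noise_sd)), 0, 1))
            knots.append((float(day), float(f_t), float(f_m)))

        regimen_data[regimen] = RegimenData(
            ultrasound_days=days.copy(),
            mouse_volumes=volumes,
            means=np.asarray(volumes.mean(axis=0, skipna=True)),
            sds=np.asarray(volumes.std(axis=0, ddof=1, skipna=True)),
            histology_knots=knots,
        )

    return CohortDataset(regimens=regimen_data, flow_ratio_day14=(ratio_t, ratio_m))
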