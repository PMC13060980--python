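"""Accept-or-reject generation of the virtual murine cohort.

Plausible mice are sampled by varying the generating triple (nCT, rCM,
kGM) uniformly within its ranges and the day-6 total volume normally
(truncated at zero), all other parameters fixed at the best fit.  Each
candidate is simulated under the generation regimens (by default
control, Gem and OT-1; the Gem+OT-1 arm is held out for cohort-level
cross-validation) and accepted iff its simulated total volume lies
within mean +/- k*SD of the data at every ultrasound day of every
generation regimen (k = 2 by default, band edges inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import simulate_batch
from .params import (
    DAY6_MEAN_MM3,
    DAY6_SD_MM3,
    ModelParams,
    Regimen,
    default_ranges,
    fractions_day6,
)
from .synth import CohortDataset

__all__ = [
    "DEFAULT_GENERATION_REGIMENS",
    "PlausibleMouse",
    "CandidateSet",
    "VirtualCohort",
    "sample_plausible",
    "accept_or_reject",
]

DEFAULT_GENERATION_REGIMENS = (Regimen.CONTROL, Regimen.GEM, Regimen.OT1)
TRIPLE_NAMES = ("nCT", "rCM", "kGM")


@dataclass(frozen=True)
class PlausibleMouse:
    """One sampled candidate (exposed for inspection; bulk storage is array-based)."""

    mouse_id: int
    nCT: float
    rCM: float
    kGM: float
    V6: float
    init: tuple[float, float, float, float]
    accepted: bool | None = None
    rejection_record: tuple[str, float] | None = None  # (regimen, day)


@dataclass
class CandidateSet:
    """Array-of-columns container for n sampled plausible mice."""

    nCT: np.ndarray
    rCM: np.ndarray
    kGM: np.ndarray
    V6: np.ndarray
    init: np.ndarray  # (n, 4)
    base_params: ModelParams
    seed: int
    ranges: dict[str, tuple[float, float]]

    @property
    def n(self) -> int:
        return self.V6.size

    def mouse(self, i: int) -> PlausibleMouse:
        return PlausibleMouse(
            mouse_id=i,
            nCT=float(self.nCT[i]),
            rCM=float(self.rCM[i]),
            kGM=float(self.kGM[i]),
            V6=float(self.V6[i]),
            init=tuple(self.init[i]),
        )

    def param_table(self) -> dict[str, np.ndarray | float]:
        table: dict[str, np.ndarray | float] = dict(self.base_params.to_dict())
        table["nCT"] = self.nCT
        table["rCM"] = self.rCM
        table["kGM"] = self.kGM
        return table


def sample_plausible(
    n: int,
    base_params: ModelParams,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    day6_mean: float = DAY6_MEAN_MM3,
    day6_sd: float = DAY6_SD_MM3,
    fractions: Sequence[float] | None = None,
    seed: int = 0,
) -> CandidateSet:
    """Draw n plausible mice: uniform triples, truncated-normal day-6 volume."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if day6_sd < 0:
        raise ValueError("day6_sd must be >= 0")
    all_ranges = default_ranges()
    ranges = {k: tuple(v) for k, v in (ranges or {}).items()}
    for name in TRIPLE_NAMES:
        ranges.setdefault(name, all_ranges[name])
        lo, hi = ranges[name]
        if not (0 <= lo < hi):
            raise ValueError(f"invalid range for {name}: {(lo, hi)}")
    if fractions is None:
        fractions = fractions_day6()
    f_c, f_t, f_m = fractions

    rng = np.random.default_rng(seed)
    triples = {name: rng.uniform(*ranges[name], size=n) for name in TRIPLE_NAMES}
    if day6_sd == 0:
        v6 = np.full(n, float(day6_mean))
    else:
        v6 = rng.normal(day6_mean, day6_sd, size=n)
        bad = v6 <= 0
        while bad.any():
            v6[bad] = rng.normal(day6_mean, day6_sd, size=int(bad.sum()))
            bad = v6 <= 0
    init = np.column_stack([v6 * f_c, v6 * f_t, v6 * f_m, np.zeros(n)])
    return CandidateSet(
        nCT=triples["nCT"],
        rCM=triples["rCM"],
        kGM=triples["kGM"],
        V6=v6,
        init=init,
        base_params=base_params,
        seed=seed,
        ranges={k: tuple(ranges[k]) for k in TRIPLE_NAMES},
    )


@dataclass
class VirtualCohort:
    """Accepted virtual mice with their per-regimen total-volume curves."""

    mice: pd.DataFrame          # mouse_id, nCT, rCM, kGM, V6 (accepted only)
    totals: dict[Regimen, pd.DataFrame]  # per regimen: mouse_id x day totals
    generation_regimens: tuple[Regimen, ...]
    holdout_regimens: tuple[Regimen, ...]
    threshold_k: float
    seed: int
    n_sampled: int
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_accepted(self) -> int:
        return len(self.mice)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_sampled

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.mice.to_csv(directory / "virtual_mice.csv", index=False)
        for regimen, df in self.totals.items():
            df.to_csv(directory / f"totals_{regimen.value}.csv")


def _bands(
    data: CohortDataset, regimen: Regimen, k: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rdata = data.regimens[regimen]
    days = np.asarray(rdata.ultrasound_days, dtype=float)
    means = np.asarray(rdata.means, dtype=float)
    sds = np.asarray(rdata.sds, dtype=float)
    if not (np.all(np.isfinite(means)) and np.all(np.isfinite(sds))):
        raise ValueError(f"missing mean/SD band data for regimen {regimen.value}")
    return days, means - k * sds, means + k * sds


def accept_or_reject(
    candidates: CandidateSet,
    data: CohortDataset,
    generation_regimens: Sequence[Regimen] = DEFAULT_GENERATION_REGIMENS,
    k: float = 2.0,
    dt: float = 0.005,
) -> VirtualCohort:
    """Screen candidates against mean +/- k*SD ultrasound bands.

    A candidate joins the virtual cohort iff its simulated total volume
    lies inside the band at every ultrasound day of every generation
    regimen (inclusive edges).  Rejected candidates record the first
    violated (regimen, day).  Hold-out regimens are simulated for the
    accepted mice only and never influence acceptance.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    generation_regimens = tuple(generation_regimens)
    holdout = tuple(r for r in Regimen if r not in generation_regimens)
    n = candidates.n
    table = candidates.param_table()

    accepted = np.ones(n, dtype=bool)
    rej_regimen = np.full(n, "", dtype=object)
    rej_day = np.full(n, np.nan)
    totals_by_regimen: dict[Regimen, np.ndarray] = {}
    days_by_regimen: dict[Regimen, np.ndarray] = {}

    for regimen in generation_regimens:
        days, lo, hi = _bands(data, regimen, k)
        states = simulate_batch(table, regimen, candidates.init, days, dt=dt)
        totals = states[:, :, :3].sum(axis=2).T  # (n, d)
        totals_by_regimen[regimen] = totals
        days_by_regimen[regimen] = days
        finite = np.all(np.isfinite(totals), axis=1)
        inside = finite & np.all((totals >= lo) & (totals <= hi), axis=1)
        # record first violated day for newly rejected candidates
        newly = accepted & ~inside
        if newly.any():
            viol = ~((totals >= lo) & (totals <= hi)) | ~np.isfinite(totals)
            first = np.argmax(viol[newly], axis=1)
            rej_regimen[newly] = regimen.value
            rej_day[newly] = days[first]
        accepted &= inside

    idx = np.flatnonzero(accepted)
    mice = pd.DataFrame(
        {
            "mouse_id": idx,
            "nCT": candidates.nCT[idx],
            "rCM": candidates.rCM[idx],
            "kGM": candidates.kGM[idx],
            "V6": candidates.V6[idx],
        }
    )
    totals: dict[Regimen, pd.DataFrame] = {}
    for regimen in generation_regimens:
        totals[regimen] = pd.DataFrame(
            totals_by_regimen[regimen][idx],
            index=idx,
            columns=days_by_regimen[regimen],
        )
    # hold-out arms: simulate only the accepted mice
    if idx.size:
        sub = CandidateSet(
            nCT=candidates.nCT[idx],
            rCM=candidates.rCM[idx],
            kGM=candidates.kGM[idx],
            V6=candidates.V6[idx],
            init=candidates.init[idx],
            base_params=candidates.base_params,
            seed=candidates.seed,
            ranges=candidates.ranges,
        )
        for regimen in holdout:
            days = np.asarray(data.regimens[regimen].ultrasound_days, dtype=float)
            states = simulate_batch(sub.param_table(), regimen, sub.init, days, dt=dt)
            totals[regimen] = pd.DataFrame(
                states[:, :, :3].sum(axis=2).T, index=idx, columns=days
            )
    else:
        for regimen in holdout:
            days = np.asarray(data.regimens[regimen].ultrasound_days, dtype=float)
            totals[regimen] = pd.DataFrame(columns=days)

    rejections = pd.DataFrame(
        {
            "mouse_id": np.flatnonzero(~accepted),
            "regimen": rej_regimen[~accepted],
            "day": rej_day[~accepted],
        }
    )
    return VirtualCohort(
        mice=mice,
        totals=totals,
        generation_regimens=generation_regimens,
        holdout_regimens=holdout,
        threshold_k=float(k),
        seed=candidates.seed,
        n_sampled=n,
        rejections=rejections,
    )
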