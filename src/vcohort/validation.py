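"""Virtual-cohort validation: distribution tests and digital twins.

"Before and after" cohort-level validation compares the distribution of
virtual total volumes with the experimental per-mouse volumes at every
ultrasound day of every generation regimen using the two-sample
Kolmogorov-Smirnov test; cohort-level cross-validation runs the same
comparison against the held-out arm, which never entered acceptance.
Digital twins match each experimental mouse to the virtual cohort
member minimizing the least-squares error over the mouse's observed
days (from day 9, truncated at its last observation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import VirtualCohort
from .params import Regimen
from .synth import CohortDataset

__all__ = [
    "KSReport",
    "TwinMatch",
    "ks_two_sample",
    "before_after_validation",
    "cross_validation",
    "digital_twin",
    "TWIN_START_DAY",
]

TWIN_START_DAY = 9.0
ALPHA = 0.05


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], method: str = "asymp"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value.

    D = sup |ECDF_a - ECDF_b|; ``method`` is "asymp" (default, matching
    typical practice for arms of ~10-15 mice), "exact", or "auto".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KSReport:
    """Per-(regimen, day) KS comparisons of virtual vs experimental."""

    table: pd.DataFrame  # regimen, day, D, p_value, n_virtual, n_experimental, significant
    alpha: float = ALPHA

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_comparisons(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _ks_rows(
    cohort: VirtualCohort,
    data: CohortDataset,
    regimens: Sequence[Regimen],
    method: str,
    alpha: float,
) -> pd.DataFrame:
    rows = []
    for regimen in regimens:
        rdata = data.regimens[regimen]
        if rdata.mouse_volumes.empty:
            raise ValueError(
                f"per-mouse volumes required for KS validation ({regimen.value})"
            )
        virt = cohort.totals[regimen]
        for day in rdata.ultrasound_days:
            exp = rdata.mouse_volumes[day].dropna().to_numpy()
            if exp.size == 0:
                raise ValueError(
                    f"no experimental observations at day {day} ({regimen.value})"
                )
            v = virt[day].to_numpy()
            D, p = ks_two_sample(v, exp, method=method)
            rows.append(
                {
                    "regimen": regimen.value,
                    "day": float(day),
                    "D": D,
                    "p_value": p,
                    "n_virtual": int(v.size),
                    "n_experimental": int(exp.size),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def before_after_validation(
    cohort: VirtualCohort,
    data: CohortDataset,
    method: str = "asymp",
    alpha: float = ALPHA,
) -> KSReport:
    """KS test per (generation regimen, ultrasound day)."""
    return KSReport(
        table=_ks_rows(cohort, data, cohort.generation_regimens, method, alpha),
        alpha=alpha,
    )


def cross_validation(
    cohort: VirtualCohort,
    data: CohortDataset,
    holdout_regimen: Regimen = Regimen.GEM_OT1,
    method: str = "asymp",
    alpha: float = ALPHA,
) -> KSReport:
    """KS test per day against the held-out arm.

    Refuses regimens that participated in cohort generation: comparing
    against them is "before and after" validation, not cross-validation.
    """
    if holdout_regimen in cohort.generation_regimens:
        raise ValueError(
            f"{holdout_regimen.value} was used for cohort generation;"
            " cross-validation requires a held-out regimen"
        )
    return KSReport(
        table=_ks_rows(cohort, data, [holdout_regimen], method, alpha), alpha=alpha
    )


@dataclass(frozen=True)
class TwinMatch:
    """Best-matching virtual mouse for one experimental mouse."""

    experimental_mouse: str
    virtual_mouse: int
    sse: float
    comparison_days: tuple[float, ...]


def digital_twin(
    mouse_series: tuple[Sequence[float], Sequence[float]],
    cohort: VirtualCohort,
    regimen: Regimen,
    experimental_id: str = "mouse",
    start_day: float = TWIN_START_DAY,
) -> TwinMatch:
    """Find the virtual mouse minimizing the SSE to one volume series.

    Comparison days are the mouse's observed days from ``start_day``
    onward, truncated at its last observation (a censored mouse is
    matched over its available days only).  Ties in SSE break to the
    lowest virtual mouse id.
    """
    days, volumes = mouse_series
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    keep = (days >= start_day) & np.isfinite(volumes)
    days, volumes = days[keep], volumes[keep]
    if days.size == 0:
        raise ValueError("mouse series has no usable observations")
    totals = cohort.totals[regimen]
    if totals.empty:
        raise ValueError("virtual cohort is empty")
    missing = [d for d in days if d not in totals.columns]
    if missing:
        raise ValueError(f"virtual trajectories lack days {missing}")
    sim = totals[list(days)].to_numpy()  # (n_virtual, n_days)
    sse = ((sim - volumes[None, :]) ** 2).sum(axis=1)
    best_pos = int(np.argmin(sse))  # argmin returns the first (lowest id) on ties
    return TwinMatch(
        experimental_mouse=experimental_id,
        virtual_mouse=int(totals.index[best_pos]),
        sse=float(sse[best_pos]),
        comparison_days=tuple(days),
    )
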