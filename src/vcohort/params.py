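"""Model parameters, dosing schedules and treatment regimens.

The model tracks three cell subpopulations by volume (mm^3) -- cancer
cells C, CD8+ T cells T, myeloid-derived suppressor cells (MDSCs) M --
and the gemcitabine concentration G (uM) in an orthotopic murine
bladder tumor.  Sixteen parameters govern the dynamics; the homeostatic
influx rates hT and hM are *derived* from the tumor-free equilibrium
(0, T0, M0) and are never stored independently.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, asdict, replace, fields
from pathlib import Path

import yaml

__all__ = [
    "ModelParams",
    "DoseTarget",
    "DoseEvent",
    "DosingSchedule",
    "Regimen",
    "GEM_DOSE_UM",
    "OT1_DOSE_MM3",
    "GEM_DAY",
    "OT1_DAY",
    "DAY6_INIT",
    "DAY6_MEAN_MM3",
    "DAY6_SD_MM3",
    "ULTRASOUND_DAYS",
    "fractions_day6",
    "default_params",
    "default_ranges",
    "schedule_for_regimen",
]

# Treatment calendar (days post tumor implantation) and doses.
GEM_DAY = 10.0
OT1_DAY = 14.0
GEM_DOSE_UM = 3.8e4      # intravesical gemcitabine bolus, uM
OT1_DOSE_MM3 = 1.0695    # adoptively transferred OT-1 T cells, mm^3

# Day-6 initial condition (C, T, M, G) used for all population-level
# fitting: the day-6 ultrasound mean split by the interpolated cell-type
# percentages.
DAY6_INIT = (26.85, 0.07217, 0.7288, 0.0)

# Day-6 ultrasound summary across the untreated cohort.
DAY6_MEAN_MM3 = 27.6554
DAY6_SD_MM3 = 11.2253

# Ultrasound imaging days shared by all four arms.
ULTRASOUND_DAYS = (6.0, 9.0, 13.0, 16.0, 20.0)


def fractions_day6() -> tuple[float, float, float]:
    """Day-6 tumor composition (fraction_C, fraction_T, fraction_M).

    T and M fractions are the day-6 subpopulation volumes over the day-6
    ultrasound mean; the cancer fraction is the complement so the three
    sum to exactly 1.
    """
    f_t = DAY6_INIT[1] / DAY6_MEAN_MM3
    f_m = DAY6_INIT[2] / DAY6_MEAN_MM3
    return (1.0 - f_t - f_m, f_t, f_m)


class DoseTarget(enum.Enum):
    GEM = "gem"
    OT1 = "ot1"


class Regimen(enum.Enum):
    CONTROL = "control"
    GEM = "gem"
    OT1 = "ot1"
    GEM_OT1 = "gem_ot1"

    @property
    def gem_treated(self) -> bool:
        return self in (Regimen.GEM, Regimen.GEM_OT1)

    @property
    def ot1_treated(self) -> bool:
        return self in (Regimen.OT1, Regimen.GEM_OT1)


REGIMENS = tuple(Regimen)


@dataclass(frozen=True)
class ModelParams:
    """The 16 model parameters.

    Rates are per day; volumes are mm^3; Km is a concentration in uM.
    T0 and M0 are the tumor-free homeostatic volumes of T cells and
    MDSCs from which the influx rates hT, hM are derived.
    """

    pC: float      # logistic cancer growth rate
    Cmax: float    # tumor carrying capacity, mm^3
    kTC: float     # T-cell kill rate of cancer, mm^-3 day^-1
    kGC: float     # maximal Gem kill rate of cancer
    Km: float      # Michaelis constant of ENT1-mediated Gem uptake, uM
    nCT: float     # cancer-mediated T-cell proliferation, mm^-3 day^-1
    sMT: float     # MDSC suppression of T cells, mm^-3 day^-1
    dT: float      # T-cell natural death
    kGT: float     # maximal Gem kill rate of T cells
    rCM: float     # cancer-mediated MDSC recruitment
    sTM: float     # T-cell suppression of MDSCs, mm^-3 day^-1
    dM: float      # MDSC natural death
    kGM: float     # maximal Gem kill rate of MDSCs
    dG: float      # Gem decay rate
    T0: float      # homeostatic T-cell volume, mm^3
    M0: float      # homeostatic MDSC volume, mm^3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.Cmax <= 0:
            raise ValueError("Cmax must be > 0")
        if self.Km <= 0:
            raise ValueError("Km must be > 0")

    def with_values(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        missing = names - set(d)
        if missing:
            raise ValueError(f"missing parameter names: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    # -- serialization ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class DoseEvent:
    time: float
    target: DoseTarget
    amount: float  # uM for GEM, mm^3 for OT1

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")


@dataclass(frozen=True)
class DosingSchedule:
    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose event times must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "events": [
                {"time": e.time, "target": e.target.value, "amount": e.amount}
                for e in self.events
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DosingSchedule":
        return cls(
            events=tuple(
                DoseEvent(float(e["time"]), DoseTarget(e["target"]), float(e["amount"]))
                for e in d["events"]
            )
        )


def schedule_for_regimen(
    regimen: Regimen,
    gem_dose: float = GEM_DOSE_UM,
    ot1_dose: float = OT1_DOSE_MM3,
) -> DosingSchedule:
    """Standard dosing calendar: Gem at day 10, OT-1 cells at day 14."""
    events: list[DoseEvent] = []
    if regimen.gem_treated:
        events.append(DoseEvent(GEM_DAY, DoseTarget.GEM, gem_dose))
    if regimen.ot1_treated:
        events.append(DoseEvent(OT1_DAY, DoseTarget.OT1, ot1_dose))
    return DosingSchedule(events=tuple(events))


# ---------------------------------------------------------------------
# Shipped defaults.  These are the package's synthetic-truth parameter
# set: a self-consistent parameterization used to generate all synthetic
# cohorts and as the reference point for profiles / sensitivity runs.
# ---------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def default_params() -> ModelParams:
    """The shipped synthetic-truth best-fit parameter set."""
    return ModelParams.from_file(_DATA_DIR / "best_fit.yaml")


def default_ranges() -> dict[str, tuple[float, float]]:
    """Sampling/fitting ranges per parameter (lower, upper)."""
    raw = yaml.safe_load((_DATA_DIR / "ranges.yaml").read_text())
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
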