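"""Reading and writing cohort datasets.

A :class:`~vcohort.synth.CohortDataset` round-trips through a long-form
CSV (columns: regimen, mouse_id, day, volume; one row per observation,
missing observations simply absent) plus a JSON sidecar holding the
ultrasound day grid, histology knots and the day-14 flow ratios.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import Regimen
from .synth import CohortDataset, RegimenData

__all__ = ["write_cohort_csv", "read_cohort_csv"]

_CSV_NAME = "cohort_volumes.csv"
_JSON_NAME = "cohort_meta.json"
_REQUIRED_COLUMNS = ("regimen", "mouse_id", "day", "volume")


def write_cohort_csv(dataset: CohortDataset, directory: str | Path) -> None:
    """Write the long-format CSV and JSON sidecar into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    meta: dict = {"flow_ratio_day14": list(dataset.flow_ratio_day14), "regimens": {}}
    for regimen, rdata in dataset.regimens.items():
        meta["regimens"][regimen.value] = {
            "ultrasound_days": [float(d) for d in rdata.ultrasound_days],
            "histology_knots": [list(k) for k in rdata.histology_knots],
        }
        long = rdata.mouse_volumes.reset_index(names="mouse_id").melt(
            id_vars="mouse_id", var_name="day", value_name="volume"
        )
        long = long.dropna(subset=["volume"])
        long.insert(0, "regimen", regimen.value)
        rows.append(long)
    pd.concat(rows, ignore_index=True).to_csv(directory / _CSV_NAME, index=False)
    (directory / _JSON_NAME).write_text(json.dumps(meta, indent=2) + "\n")


def read_cohort_csv(directory: str | Path) -> CohortDataset:
    """Read a dataset written by :func:`write_cohort_csv`.

    Schema violations are reported with the offending row numbers.
    """
    directory = Path(directory)
    csv_path = directory / _CSV_NAME
    json_path = directory / _JSON_NAME
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not json_path.exists():
        raise FileNotFoundError(json_path)
    frame = pd.read_csv(csv_path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    bad = frame.index[frame["volume"].isna() | (frame["volume"] < 0)].tolist()
    if bad:
        raise ValueError(f"invalid volume values at CSV rows {[i + 2 for i in bad]}")
    bad = frame.index[~frame["regimen"].isin([r.value for r in Regimen])].tolist()
    if bad:
        raise ValueError(f"unknown regimen names at CSV rows {[i + 2 for i in bad]}")

    meta = json.loads(json_path.read_text())
    regimens: dict[Regimen, RegimenData] = {}
    for name, rmeta in meta["regimens"].items():
        regimen = Regimen(name)
        days = np.asarray(rmeta["ultrasound_days"], dtype=float)
        sub = frame[frame["regimen"] == name]
        table = sub.pivot_table(index="mouse_id", columns="day", values="volume")
        table = table.reindex(columns=days)
        regimens[regimen] = RegimenData(
            ultrasound_days=days,
            mouse_volumes=table,
            means=np.asarray(table.mean(axis=0, skipna=True)),
            sds=np.asarray(table.std(axis=0, ddof=1, skipna=True)),
            histology_knots=[tuple(k) for k in rmeta["histology_knots"]],
        )
    ratio = meta["flow_ratio_day14"]
    return CohortDataset(regimens=regimens, flow_ratio_day14=(ratio[0], ratio[1]))
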