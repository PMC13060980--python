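"""Validate the virtual cohort: KS distribution tests and digital twins.

"Before and after": two-sample KS per (generation regimen, ultrasound
day) between virtual and experimental totals.  Cross-validation: the
same per-day comparison against the held-out Gem+OT-1 arm, which never
entered acceptance.  Finally each synthetic mouse is matched to its
digital twin -- the virtual cohort member minimizing the least-squares
error over the mouse's observed days from day 9 onward.
"""

import json
from pathlib import Path

import pandas as pd

from vcohort.cohort import VirtualCohort
from vcohort.io import read_cohort_csv
from vcohort.params import Regimen
from vcohort.validation import before_after_validation, cross_validation, digital_twin

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "results" / "virtual_cohort"
OUT = ROOT / "results"


def load_cohort() -> VirtualCohort:
    mice = pd.read_csv(COHORT_DIR / "virtual_mice.csv")
    totals = {}
    for regimen in Regimen:
        df = pd.read_csv(COHORT_DIR / f"totals_{regimen.value}.csv", index_col=0)
        df.columns = df.columns.astype(float)
        totals[regimen] = df
    return VirtualCohort(
        mice=mice,
        totals=totals,
        generation_regimens=(Regimen.CONTROL, Regimen.GEM, Regimen.OT1),
        holdout_regimens=(Regimen.GEM_OT1,),
        threshold_k=2.0,
        seed=40,
        n_sampled=25_000,
    )


def main() -> None:
    dataset = read_cohort_csv(ROOT / "results" / "data")
    cohort = load_cohort()

    before = before_after_validation(cohort, dataset)
    cross = cross_validation(cohort, dataset)
    before.to_csv(OUT / "ks_before_after.csv")
    cross.to_csv(OUT / "ks_cross_validation.csv")
    n_cells = before.n_comparisons + cross.n_comparisons
    n_ok = n_cells - before.n_significant - cross.n_significant
    print(
        f"before/after: {before.n_significant}/{before.n_comparisons} significant; "
        f"cross-validation: {cross.n_significant}/{cross.n_comparisons} significant"
    )
    print(f"{n_ok}/{n_cells} (regimen, day) cells indistinguishable at alpha = 0.05")

    twins = []
    for regimen in Regimen:
        rdata = dataset.regimens[regimen]
        for mouse_id, row in rdata.mouse_volumes.iterrows():
            match = digital_twin(
                (rdata.ultrasound_days, row.to_numpy()), cohort, regimen,
                experimental_id=str(mouse_id),
            )
            twins.append(
                {
                    "regimen": regimen.value,
                    "experimental_mouse": match.experimental_mouse,
                    "virtual_mouse": match.virtual_mouse,
                    "sse": match.sse,
                    "n_days": len(match.comparison_days),
                }
            )
    twins_df = pd.DataFrame(twins)
    twins_df.to_csv(OUT / "digital_twins.csv", index=False)
    rmse = (twins_df["sse"] / twins_df["n_days"]) ** 0.5
    print(
        f"digital twins for {len(twins_df)} mice; per-day RMSE median "
        f"{rmse.median():.1f} mm^3 (max {rmse.max():.1f})"
    )
    (OUT / "validation_summary.json").write_text(
        json.dumps(
            {
                "before_after_significant": before.n_significant,
                "cross_significant": cross.n_significant,
                "n_cells": n_cells,
                "twin_rmse_median": float(rmse.median()),
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
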