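"""Build the virtual murine cohort by accept-or-reject sampling.

25,000 plausible mice (a scaled-down analogue of the study's 500,000;
the machinery is identical) are drawn by varying the generating triple
(nCT, rCM, kGM) uniformly and the day-6 volume from the truncated
Normal(27.6554, 11.2253^2).  Each is simulated under the control, Gem
and OT-1 arms and accepted iff its total volume stays within
mean +/- 2 SD of the data at every ultrasound day; the Gem+OT-1 arm is
held out for cross-validation and simulated only for accepted mice.
"""

import json
from pathlib import Path

from vcohort.cohort import accept_or_reject, sample_plausible
from vcohort.io import read_cohort_csv
from vcohort.params import default_params

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "virtual_cohort"
N = 25_000
SEED = 40


def main() -> None:
    dataset = read_cohort_csv(ROOT / "results" / "data")
    candidates = sample_plausible(N, base_params=default_params(), seed=SEED)
    cohort = accept_or_reject(candidates, dataset, k=2.0)
    cohort.save(OUT)

    accepted = cohort.mice
    summary = {
        "n_sampled": cohort.n_sampled,
        "n_accepted": cohort.n_accepted,
        "acceptance_rate": cohort.acceptance_rate,
        "threshold_k": cohort.threshold_k,
        "generation_regimens": [r.value for r in cohort.generation_regimens],
        "holdout_regimens": [r.value for r in cohort.holdout_regimens],
        "accepted_triple_ranges": {
            name: [float(accepted[name].min()), float(accepted[name].max())]
            for name in ("nCT", "rCM", "kGM")
        },
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(
        f"accepted {cohort.n_accepted}/{cohort.n_sampled} plausible mice "
        f"({100 * cohort.acceptance_rate:.2f}%) within +/-2 SD bands"
    )
    for name, (lo, hi) in summary["accepted_triple_ranges"].items():
        print(f"  accepted {name} spans [{lo:.4g}, {hi:.4g}]")


if __name__ == "__main__":
    main()
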