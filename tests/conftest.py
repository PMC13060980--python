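"""Shared fixtures: the synthetic truth, datasets, and one full fit.

The hierarchical fit and the larger synthetic cohorts are expensive, so
they are session-scoped and shared by every test that inspects them.
"""

from __future__ import annotations

import numpy as np
import pytest

from vcohort.estimation import fit_stage1, fit_stage2
from vcohort.params import default_params
from vcohort.synth import CohortDataset, RegimenData, SynthConfig, exact_subpopulation_data, generate_cohort


@pytest.fixture(scope="session")
def truth():
    return default_params()


@pytest.fixture(scope="session")
def exact_data(truth):
    """Noiseless per-cell-type volumes straight from the truth model."""
    return exact_subpopulation_data(truth)


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    """Default synthetic four-arm cohort (13 mice/arm, 10% noise)."""
    return generate_cohort(truth, SynthConfig(), seed=42)


@pytest.fixture(scope="session")
def clean_dataset(truth):
    """Degenerate cohort: no noise, no between-mouse variability."""
    config = SynthConfig(noise_cv=0.0, vary_triples=False, day6_sd=0.0, n_mice=3)
    return generate_cohort(truth, config, seed=1)


@pytest.fixture(scope="session")
def hierarchical_fit(exact_data):
    """Two-stage fit of the noiseless exact data (shared; ~10 s)."""
    s1 = fit_stage1(exact_data, n_lhs=100, seed=3)
    return fit_stage2(exact_data, s1, n_lhs=100, seed=4)


def make_manual_dataset(
    means_by_regimen: dict,
    knots_by_regimen: dict,
    flow_ratio=(1.0, 1.0),
    days=(6.0, 9.0, 13.0, 16.0, 20.0),
    sds=None,
) -> CohortDataset:
    """Small hand-built dataset for interpolation/band tests."""
    import pandas as pd

    from vcohort.params import Regimen

    regimens = {}
    days = np.asarray(days, dtype=float)
    for regimen in Regimen:
        means = np.asarray(means_by_regimen[regimen], dtype=float)
        sd = np.asarray(
            sds[regimen] if sds is not None else np.full(days.size, 1.0), dtype=float
        )
        volumes = pd.DataFrame(
            [means - sd / 2, means + sd / 2],
            index=[f"{regimen.value}_0", f"{regimen.value}_1"],
            columns=days,
        )
        regimens[regimen] = RegimenData(
            ultrasound_days=days.copy(),
            mouse_volumes=volumes,
            means=means,
            sds=sd,
            histology_knots=list(knots_by_regimen[regimen]),
        )
    return CohortDataset(regimens=regimens, flow_ratio_day14=flow_ratio)
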