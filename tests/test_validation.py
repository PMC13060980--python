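"""Validation: KS machinery, cohort comparisons, digital twins."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from vcohort.cohort import VirtualCohort, accept_or_reject, sample_plausible
from vcohort.params import Regimen
from vcohort.validation import (
    before_after_validation,
    cross_validation,
    digital_twin,
    ks_two_sample,
)


def exact_ks_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force exact two-sample KS p-value by enumerating orderings.

    Under H0 every assignment of the pooled (distinct) values to the two
    samples is equally likely; the p-value is the fraction of
    assignments with D at least as large as observed.
    """
    n, m = len(a), len(b)
    pooled = np.sort(np.concatenate([a, b]))

    def stat(idx_a: tuple[int, ...]) -> float:
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx_a)] = True
        cdf_a = np.cumsum(mask) / n
        cdf_b = np.cumsum(~mask) / m
        return float(np.max(np.abs(cdf_a - cdf_b)))

    observed_idx = tuple(np.flatnonzero(np.isin(pooled, np.sort(a))))
    d_obs = stat(observed_idx)
    count = total = 0
    for idx in combinations(range(n + m), n):
        total += 1
        if stat(idx) >= d_obs - 1e-12:
            count += 1
    return count / total


class TestKsTwoSample:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        D, p = ks_two_sample(a, a)
        assert D == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        D, _ = ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0])
        assert D == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=12), rng.normal(0.5, 1.2, size=9)
        d1, p1 = ks_two_sample(a, b)
        d2, p2 = ks_two_sample(b, a)
        assert d1 == d2 and p1 == p2
        d3, p3 = ks_two_sample(np.exp(a), np.exp(b))
        assert d3 == pytest.approx(d1)
        assert p3 == pytest.approx(p1)

    @pytest.mark.parametrize("n,m", [(4, 5), (6, 6), (8, 5)])
    def test_exact_pvalue_matches_enumeration(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        a = rng.normal(size=n)
        b = rng.normal(0.8, 1.0, size=m)
        _, p_scipy = ks_two_sample(a, b, method="exact")
        p_brute = exact_ks_pvalue(a, b)
        assert p_scipy == pytest.approx(p_brute, abs=1e-10)


@pytest.fixture(scope="module")
def small_cohort(truth, noisy_dataset):
    cand = sample_plausible(4000, truth, seed=21)
    vc = accept_or_reject(cand, noisy_dataset, k=2.0)
    assert vc.n_accepted > 50
    return vc


class TestCohortComparisons:
    def test_null_self_test(self, small_cohort, noisy_dataset):
        """Virtual totals resampled from the experimental sample itself
        trigger few rejections (bootstrap KS is conservative)."""
        rng = np.random.default_rng(7)
        n_sig = n_tot = 0
        for _ in range(100):
            exp = noisy_dataset.regimens[Regimen.CONTROL].mouse_volumes[13.0].dropna()
            fake_virtual = rng.choice(exp.to_numpy(), size=500, replace=True)
            _, p = ks_two_sample(fake_virtual, exp.to_numpy())
            n_tot += 1
            n_sig += p < 0.05
        assert n_sig / n_tot <= 0.05 + 0.05

    def test_before_after_on_matched_cohort(self, small_cohort, noisy_dataset):
        report = before_after_validation(small_cohort, noisy_dataset)
        assert report.n_comparisons == 15  # 3 generation arms x 5 days
        assert report.n_significant <= report.n_comparisons
        assert ((report.table["D"] >= 0) & (report.table["D"] <= 1)).all()

    def test_gross_mismatch_all_significant(self, small_cohort, noisy_dataset):
        shifted = VirtualCohort(
            mice=small_cohort.mice,
            totals={
                r: df + 10.0 * noisy_dataset.regimens[r].sds.max()
                for r, df in small_cohort.totals.items()
            },
            generation_regimens=small_cohort.generation_regimens,
            holdout_regimens=small_cohort.holdout_regimens,
            threshold_k=2.0,
            seed=0,
            n_sampled=small_cohort.n_sampled,
        )
        report = before_after_validation(shifted, noisy_dataset)
        assert report.n_significant == report.n_comparisons

    def test_cross_validation_requires_holdout(self, small_cohort, noisy_dataset):
        with pytest.raises(ValueError):
            cross_validation(small_cohort, noisy_dataset, holdout_regimen=Regimen.CONTROL)
        report = cross_validation(small_cohort, noisy_dataset, holdout_regimen=Regimen.GEM_OT1)
        assert report.n_comparisons == 5

    def test_means_only_dataset_rejected(self, small_cohort, noisy_dataset):
        stripped = noisy_dataset.regimens[Regimen.CONTROL].mouse_volumes
        try:
            noisy_dataset.regimens[Regimen.CONTROL].mouse_volumes = stripped.iloc[:0]
            with pytest.raises(ValueError):
                before_after_validation(small_cohort, noisy_dataset)
        finally:
            noisy_dataset.regimens[Regimen.CONTROL].mouse_volumes = stripped


class TestDigitalTwin:
    def test_self_match_has_zero_sse(self, small_cohort):
        totals = small_cohort.totals[Regimen.CONTROL]
        member = totals.index[3]
        series = (totals.columns.to_numpy(), totals.loc[member].to_numpy())
        match = digital_twin(series, small_cohort, Regimen.CONTROL)
        assert match.virtual_mouse == member
        assert match.sse == 0.0

    def test_comparison_starts_at_day9(self, small_cohort):
        totals = small_cohort.totals[Regimen.CONTROL]
        member = totals.index[0]
        days = totals.columns.to_numpy()
        vols = totals.loc[member].to_numpy().copy()
        vols[days < 9.0] = 1e9  # day 6 must be ignored
        match = digital_twin((days, vols), small_cohort, Regimen.CONTROL)
        assert match.virtual_mouse == member
        assert 6.0 not in match.comparison_days

    def test_censored_series_truncated(self, small_cohort):
        totals = small_cohort.totals[Regimen.GEM]
        member = totals.index[1]
        days = totals.columns.to_numpy()
        vols = totals.loc[member].to_numpy().copy()
        vols[days > 13.0] = np.nan  # death after day 13
        match = digital_twin((days, vols), small_cohort, Regimen.GEM)
        assert match.comparison_days == (9.0, 13.0)
        assert match.sse == 0.0

    def test_matches_brute_force(self, small_cohort):
        rng = np.random.default_rng(3)
        totals = small_cohort.totals[Regimen.OT1]
        days = totals.columns.to_numpy()
        target = totals.iloc[7].to_numpy() * rng.uniform(0.8, 1.2, size=days.size)
        match = digital_twin((days, target), small_cohort, Regimen.OT1)
        keep = days >= 9.0
        sses = ((totals.to_numpy()[:, keep] - target[None, keep]) ** 2).sum(axis=1)
        assert match.virtual_mouse == totals.index[int(np.argmin(sses))]
        assert match.sse == pytest.approx(float(sses.min()))

    def test_sse_never_increases_with_larger_cohort(self, small_cohort):
        totals = small_cohort.totals[Regimen.CONTROL]
        days = totals.columns.to_numpy()
        target = totals.iloc[0].to_numpy() * 1.1
        halves = totals.iloc[: len(totals) // 2]
        small = VirtualCohort(
            mice=small_cohort.mice.iloc[: len(halves)],
            totals={Regimen.CONTROL: halves},
            generation_regimens=(Regimen.CONTROL,),
            holdout_regimens=(),
            threshold_k=2.0,
            seed=0,
            n_sampled=len(halves),
        )
        sse_small = digital_twin((days, target), small, Regimen.CONTROL).sse
        sse_full = digital_twin((days, target), small_cohort, Regimen.CONTROL).sse
        assert sse_full <= sse_small

    def test_tie_breaks_to_lowest_id(self, small_cohort):
        totals = small_cohort.totals[Regimen.CONTROL]
        days = totals.columns.to_numpy()
        dup = pd.concat([totals.iloc[[0]], totals])  # duplicate trajectory
        dup.index = [totals.index[0] - 1] + list(totals.index)
        tied = VirtualCohort(
            mice=small_cohort.mice,
            totals={Regimen.CONTROL: dup.sort_index()},
            generation_regimens=(Regimen.CONTROL,),
            holdout_regimens=(),
            threshold_k=2.0,
            seed=0,
            n_sampled=len(dup),
        )
        target = totals.iloc[0].to_numpy()
        match = digital_twin((days, target), tied, Regimen.CONTROL)
        assert match.virtual_mouse == totals.index[0] - 1

    def test_empty_series_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            digital_twin((np.array([6.0]), np.array([np.nan])), small_cohort, Regimen.CONTROL)
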