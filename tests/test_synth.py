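"""Synthetic cohorts: composition interpolation, volume splitting, generator."""

from __future__ import annotations

import numpy as np
import pytest

from vcohort.params import DAY6_INIT, DAY6_MEAN_MM3, Regimen, fractions_day6
from vcohort.synth import (
    SynthConfig,
    build_percentage_interpolant,
    exact_subpopulation_data,
    generate_cohort,
    subpopulation_volumes,
)
from vcohort.model import simulate_regimen

from conftest import make_manual_dataset


def calibrated_dataset(scale: float = 1.0):
    """Dataset whose untreated knots put the day-6 fractions at the
    calibrated initial-composition anchor (linear through day 0)."""
    _, f_t6, f_m6 = fractions_day6()
    knots_u = [(17.0, f_t6 * 17 / 6, f_m6 * 17 / 6), (23.0, f_t6 * 23 / 6, f_m6 * 23 / 6)]
    knots_gem = [(17.0, 0.03, 0.02), (23.0, 0.05, 0.015)]
    means = np.array([DAY6_MEAN_MM3, 60.0, 150.0, 250.0, 350.0]) * scale
    return make_manual_dataset(
        means_by_regimen={r: means for r in Regimen},
        knots_by_regimen={
            Regimen.CONTROL: knots_u,
            Regimen.OT1: knots_u,
            Regimen.GEM: knots_gem,
            Regimen.GEM_OT1: knots_gem,
        },
        flow_ratio=(1.4, 0.5),
    )


class TestPercentageInterpolant:
    def test_pure_cancer_at_implantation(self):
        interp = build_percentage_interpolant(calibrated_dataset())
        for regimen in Regimen:
            assert interp.fractions(regimen, 0.0) == pytest.approx([1.0, 0.0, 0.0])

    def test_histology_knots_reproduced_exactly(self):
        ds = calibrated_dataset()
        interp = build_percentage_interpolant(ds)
        for regimen in Regimen:
            for day, f_t, f_m in ds.regimens[regimen].histology_knots:
                got = interp.fractions(regimen, day)
                assert got[1] == pytest.approx(f_t)
                assert got[2] == pytest.approx(f_m)
                assert got.sum() == pytest.approx(1.0)

    def test_midpoint_is_mean_of_knots(self):
        ds = calibrated_dataset()
        interp = build_percentage_interpolant(ds)
        a = interp.fractions(Regimen.GEM, 17.0)
        b = interp.fractions(Regimen.GEM, 23.0)
        mid = interp.fractions(Regimen.GEM, 20.0)
        assert mid == pytest.approx((a + b) / 2)

    def test_flow_ratio_distinguishes_gem_arms(self):
        ds = calibrated_dataset()
        interp = build_percentage_interpolant(ds)
        f_gem = interp.fractions(Regimen.GEM, 14.0)
        f_ctrl = interp.fractions(Regimen.CONTROL, 14.0)
        assert f_gem[1] == pytest.approx(1.4 * f_ctrl[1])
        assert f_gem[2] == pytest.approx(0.5 * f_ctrl[2])
        # untreated interpolation shared by all arms before treatment
        for regimen in Regimen:
            assert interp.fractions(regimen, 8.0) == pytest.approx(
                interp.fractions(Regimen.CONTROL, 8.0)
            )


class TestSubpopulationVolumes:
    def test_day6_matches_printed_initial_condition(self):
        """Calibrated day-6 fractions split 27.6554 into ~(26.85, 0.072, 0.729)."""
        ds = calibrated_dataset()
        sub = subpopulation_volumes(ds, build_percentage_interpolant(ds))
        day6 = sub[(sub["regimen"] == "control") & (sub["day"] == 6.0)]
        vols = {r.cell_type: r.volume for r in day6.itertuples()}
        assert vols["C"] == pytest.approx(26.85, rel=2e-4)
        assert vols["T"] == pytest.approx(0.07217, rel=1e-6)
        assert vols["M"] == pytest.approx(0.7288, rel=1e-6)

    def test_pure_cancer_split(self):
        ds = calibrated_dataset()
        interp = build_percentage_interpolant(ds)
        fr = interp.fractions(Regimen.CONTROL, 0.0)
        assert (10.0 * fr).tolist() == pytest.approx([10.0, 0.0, 0.0])

    def test_linearity_in_ultrasound_means(self):
        sub1 = subpopulation_volumes(
            calibrated_dataset(), build_percentage_interpolant(calibrated_dataset())
        )
        sub2 = subpopulation_volumes(
            calibrated_dataset(2.0), build_percentage_interpolant(calibrated_dataset(2.0))
        )
        assert np.allclose(sub2["volume"], 2.0 * sub1["volume"])

    def test_fit_mask(self):
        ds = calibrated_dataset()
        sub = subpopulation_volumes(ds, build_percentage_interpolant(ds))
        c_rows = sub[sub["cell_type"] == "C"]
        tm_rows = sub[sub["cell_type"] != "C"]
        assert c_rows["used_in_fit"].all()
        assert set(tm_rows[tm_rows["used_in_fit"]]["day"]) == {16.0, 20.0}


class TestGenerateCohort:
    def test_degenerate_generator_reproduces_truth(self, truth, clean_dataset):
        """No noise, no variability: every mouse equals the truth totals."""
        for regimen, rdata in clean_dataset.regimens.items():
            traj = simulate_regimen(truth, regimen, rdata.ultrasound_days)
            want = traj.total_volume
            for _, row in rdata.mouse_volumes.iterrows():
                assert np.allclose(row.to_numpy(), want, rtol=2e-3)
            assert np.allclose(rdata.sds, 0.0, atol=1e-8)

    def test_sds_positive_with_noise(self, noisy_dataset):
        for rdata in noisy_dataset.regimens.values():
            assert (rdata.sds > 0).all()

    def test_deterministic_from_seed(self, truth):
        cfg = SynthConfig(n_mice=3)
        a = generate_cohort(truth, cfg, seed=9)
        b = generate_cohort(truth, cfg, seed=9)
        for regimen in Regimen:
            assert a.regimens[regimen].mouse_volumes.equals(
                b.regimens[regimen].mouse_volumes
            )
            assert a.regimens[regimen].histology_knots == b.regimens[regimen].histology_knots
        assert a.flow_ratio_day14 == b.flow_ratio_day14

    def test_generated_fractions_sum_to_one(self, noisy_dataset):
        interp = build_percentage_interpolant(noisy_dataset)
        for regimen in Regimen:
            fr = interp.fractions(regimen, np.linspace(0, 23, 24))
            assert np.allclose(fr.sum(axis=-1), 1.0)

    def test_roundtrip_recovers_simulated_subpopulations(self, truth, clean_dataset):
        """Interpolation-split volumes track the simulated ones.

        The day-14/17/23 knots linearize the smooth composition curves,
        so the T/M recovery is approximate; C (fraction near 1) is tight.
        """
        interp = build_percentage_interpolant(clean_dataset)
        split = subpopulation_volumes(clean_dataset, interp)
        exact = exact_subpopulation_data(truth).rename(columns={"volume": "exact"})
        merged = split.merge(exact, on=["regimen", "day", "cell_type"])
        late = merged[merged["day"] >= 16.0]
        c = late[late["cell_type"] == "C"]
        tm = late[late["cell_type"] != "C"]
        assert np.allclose(c["volume"], c["exact"], rtol=0.05)
        # T/M fractions are small and convex in time, so the piecewise-linear
        # knots bias them; require agreement within a factor of three
        ratio = tm["volume"] / tm["exact"]
        assert ratio.between(1 / 3.0, 3.0).all()

    def test_dropout_censors_trailing_days(self, truth):
        cfg = SynthConfig(n_mice=10, dropout_rate=0.7)
        ds = generate_cohort(truth, cfg, seed=2)
        any_censored = False
        for rdata in ds.regimens.values():
            table = rdata.mouse_volumes
            for _, row in table.iterrows():
                isna = row.isna().to_numpy()
                if isna.any():
                    any_censored = True
                    # missingness is a trailing block (death, not gaps)
                    first = int(np.argmax(isna))
                    assert isna[first:].all()
        assert any_censored

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(n_mice=1)
        with pytest.raises(ValueError):
            SynthConfig(noise_cv=-0.1)
        with pytest.raises(ValueError):
            SynthConfig(triple_ranges={"nCT": (0.5, 0.1)})
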