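"""Model core: equilibrium structure, dosing impulses, integrator accuracy."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from vcohort.model import (
    homeostatic_influx,
    rhs_full,
    rhs_treatment_free,
    simulate,
    simulate_batch,
    simulate_regimen,
)
from vcohort.params import (
    DAY6_INIT,
    DoseEvent,
    DoseTarget,
    DosingSchedule,
    ModelParams,
    Regimen,
    schedule_for_regimen,
)

GRID = np.arange(6.0, 20.25, 0.25)


def params_with(**over) -> ModelParams:
    base = dict(
        pC=0.0, Cmax=1.0, kTC=0.0, kGC=0.0, Km=1.0, nCT=0.0, sMT=0.0, dT=0.0,
        kGT=0.0, rCM=0.0, sTM=0.0, dM=0.0, kGM=0.0, dG=0.0, T0=0.0, M0=0.0,
    )
    base.update(over)
    return ModelParams(**base)


class TestHomeostaticInflux:
    def test_zero_baseline(self):
        assert homeostatic_influx(params_with()) == (0.0, 0.0)

    def test_hand_evaluated(self):
        p = params_with(sMT=0.1, M0=2.0, dT=0.2, T0=5.0)
        hT, hM = homeostatic_influx(p)
        # suppression evaluated at the homeostatic point: sMT*M0*T0 + dT*T0
        assert hT == pytest.approx(0.1 * 2 * 5 + 0.2 * 5)
        assert hM == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st_.floats(0.0, 1.0), st_.floats(0.0, 1.0), st_.floats(0.0, 1.0),
        st_.floats(0.0, 1.0), st_.floats(0.0, 5.0), st_.floats(0.0, 5.0),
    )
    def test_tumor_free_equilibrium_exact(self, sMT, sTM, dT, dM, T0, M0):
        """(0, T0, M0) is an exact fixed point for any valid parameters."""
        p = params_with(pC=0.3, Cmax=10.0, kTC=0.1, nCT=0.2, rCM=0.1,
                        sMT=sMT, sTM=sTM, dT=dT, dM=dM, T0=T0, M0=M0)
        assert rhs_treatment_free((0.0, T0, M0), p) == (0.0, 0.0, 0.0)


class TestRhs:
    def test_trivial_equilibrium(self):
        assert rhs_full((0, 0, 0, 0), params_with()) == (0, 0, 0, 0)

    def test_logistic_at_capacity(self):
        p = params_with(pC=0.7, Cmax=50.0)
        dC, *_ = rhs_full((50.0, 0, 0, 0), p)
        assert dC == pytest.approx(0.0, abs=1e-14)

    def test_rejects_negative_state(self):
        with pytest.raises(ValueError):
            rhs_full((-1.0, 0, 0, 0), params_with())
        with pytest.raises(ValueError):
            rhs_treatment_free((0.0, -0.5, 0.0), params_with())

    def test_hand_arithmetic_oracle(self):
        """Fully numeric case checked against exact Fraction arithmetic."""
        vals = dict(
            pC=Fraction(1, 2), Cmax=Fraction(8), kTC=Fraction(1, 3),
            kGC=Fraction(1, 5), Km=Fraction(2), nCT=Fraction(1, 7),
            sMT=Fraction(1, 11), dT=Fraction(1, 13), kGT=Fraction(1, 17),
            rCM=Fraction(1, 19), sTM=Fraction(1, 23), dM=Fraction(1, 29),
            kGM=Fraction(1, 31), dG=Fraction(1, 37), T0=Fraction(1, 41),
            M0=Fraction(1, 43),
        )
        C, T, M, G = Fraction(3), Fraction(2), Fraction(5, 2), Fraction(7, 2)
        hT = (vals["sMT"] * vals["M0"] + vals["dT"]) * vals["T0"]
        hM = (vals["sTM"] * vals["T0"] + vals["dM"]) * vals["M0"]
        sat = G / (G + vals["Km"])
        want = (
            vals["pC"] * C * (1 - C / vals["Cmax"]) - vals["kTC"] * T * C - vals["kGC"] * C * sat,
            vals["nCT"] * C * T - vals["sMT"] * M * T - vals["dT"] * T + hT - vals["kGT"] * T * sat,
            vals["rCM"] * C - vals["sTM"] * T * M - vals["dM"] * M + hM - vals["kGM"] * M * sat,
            -vals["dG"] * G,
        )
        p = ModelParams(**{k: float(v) for k, v in vals.items()})
        got = rhs_full((float(C), float(T), float(M), float(G)), p)
        for g, w in zip(got, want):
            assert g == pytest.approx(float(w), rel=1e-12)

    def test_treatment_free_reduction(self, truth):
        """The treatment-free RHS equals the full RHS at G = 0."""
        state = (12.0, 0.4, 1.3)
        full = rhs_full((*state, 0.0), truth)
        assert rhs_treatment_free(state, truth) == pytest.approx(full[:3], rel=1e-14)


class TestSimulate:
    def test_gem_closed_form_decay(self):
        """With only dG active, G decays exponentially after the bolus."""
        p = params_with(dG=0.3)
        schedule = DosingSchedule((DoseEvent(10.0, DoseTarget.GEM, 5.0),))
        traj = simulate(p, schedule, (0, 0, 0, 0), GRID)
        after = GRID >= 10.0
        want = 5.0 * np.exp(-0.3 * (GRID[after] - 10.0))
        assert np.max(np.abs(traj.G[after] - want) / want) < 1e-6
        assert np.all(traj.G[~after] == 0.0)

    def test_equilibrium_preserved(self, truth):
        traj = simulate(truth, DosingSchedule(()), (0.0, truth.T0, truth.M0, 0.0), GRID)
        assert np.allclose(traj.states, [0.0, truth.T0, truth.M0, 0.0], atol=1e-9)

    def test_tolerance_refinement(self, truth):
        """Default-tolerance control run agrees with a tighter rerun."""
        a = simulate_regimen(truth, Regimen.CONTROL, GRID, rtol=1e-8, atol=1e-10)
        b = simulate_regimen(truth, Regimen.CONTROL, GRID, rtol=1e-10, atol=1e-12)
        rel = np.abs(a.total_volume - b.total_volume) / np.abs(b.total_volume)
        assert rel.max() < 1e-5

    def test_nonnegativity(self, truth):
        for regimen in Regimen:
            traj = simulate_regimen(truth, regimen, GRID)
            assert traj.states.min() >= -1e-9

    def test_regimen_nesting(self, truth):
        """Arms are indistinguishable before their first distinct dose."""
        control = simulate_regimen(truth, Regimen.CONTROL, GRID)
        ot1 = simulate_regimen(truth, Regimen.OT1, GRID)
        gem = simulate_regimen(truth, Regimen.GEM, GRID)
        pre14 = GRID < 14.0
        pre10 = GRID < 10.0
        assert np.allclose(control.states[pre14], ot1.states[pre14], rtol=1e-7, atol=1e-10)
        assert np.allclose(control.states[pre10], gem.states[pre10], rtol=1e-7, atol=1e-10)
        # and they separate afterwards
        assert not np.allclose(control.states[~pre14], ot1.states[~pre14], rtol=1e-3)

    def test_grid_must_cover_events(self, truth):
        with pytest.raises(ValueError):
            simulate(truth, schedule_for_regimen(Regimen.GEM), DAY6_INIT, [6.0, 9.0])

    def test_dose_is_impulse(self, truth):
        """The dosed compartment jumps by the dose amount at the event."""
        grid = np.array([6.0, 13.999, 14.0, 16.0])
        ot1 = simulate_regimen(truth, Regimen.OT1, grid)
        control = simulate_regimen(truth, Regimen.CONTROL, grid)
        jump = ot1.at(14.0)[1] - control.at(14.0)[1]
        assert jump == pytest.approx(1.0695, rel=1e-4)

    def test_batch_matches_adaptive(self, truth):
        """Vectorized RK4 ensemble agrees with the adaptive scalar solver."""
        days = [6.0, 9.0, 13.0, 16.0, 20.0]
        table = {k: v for k, v in truth.to_dict().items()}
        table["nCT"] = np.array([truth.nCT, 0.005])
        states = simulate_batch(table, Regimen.GEM_OT1, np.array(DAY6_INIT), days)
        for j, n in enumerate(table["nCT"]):
            p = truth.with_values(nCT=float(n))
            traj = simulate_regimen(p, Regimen.GEM_OT1, np.asarray(days))
            for i, d in enumerate(days):
                ref = traj.at(d)
                got = states[i, j]
                assert np.allclose(got, ref, rtol=2e-3, atol=1e-6)


class TestSerialization:
    def test_params_roundtrip(self, truth, tmp_path):
        truth.to_json(tmp_path / "p.json")
        truth.to_yaml(tmp_path / "p.yaml")
        assert ModelParams.from_file(tmp_path / "p.json") == truth
        assert ModelParams.from_file(tmp_path / "p.yaml") == truth

    def test_schedule_roundtrip(self):
        s = schedule_for_regimen(Regimen.GEM_OT1)
        assert DosingSchedule.from_dict(s.to_dict()) == s

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            params_with(pC=-0.1)
        with pytest.raises(ValueError):
            params_with(Cmax=0.0)

    def test_trajectory_csv(self, truth, tmp_path):
        traj = simulate_regimen(truth, Regimen.CONTROL, np.array([6.0, 9.0]))
        traj.to_csv(tmp_path / "t.csv")
        import pandas as pd

        frame = pd.read_csv(tmp_path / "t.csv")
        assert list(frame.columns) == ["regimen", "day", "C", "T", "M", "G", "total"]
        assert np.allclose(frame["total"], frame[["C", "T", "M"]].sum(axis=1))
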