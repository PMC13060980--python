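"""eFAST: search-curve sampling, index accuracy, subset ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vcohort.efast import DUMMY, EfastDesign, efast_indices, efast_run, efast_sample, rank_subsets

UNIT3 = {"x1": (0.0, 1.0), "x2": (0.0, 1.0), "x3": (0.0, 1.0)}
PI3 = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}

A_ISH, B_ISH = 7.0, 0.1


def ishigami(tab: pd.DataFrame) -> np.ndarray:
    x = np.asarray(tab[["x1", "x2", "x3"]])
    return np.sin(x[:, 0]) + A_ISH * np.sin(x[:, 1]) ** 2 + B_ISH * x[:, 2] ** 4 * np.sin(x[:, 0])


def ishigami_first_order() -> dict[str, float]:
    v1 = 0.5 * (1 + B_ISH * np.pi**4 / 5) ** 2
    v2 = A_ISH**2 / 8
    v = v2 + B_ISH * np.pi**4 / 5 + B_ISH**2 * np.pi**8 / 18 + 0.5
    return {"x1": v1 / v, "x2": v2 / v, "x3": 0.0, DUMMY: 0.0}


class TestDesignAndSampling:
    def test_design_invariants(self):
        d = EfastDesign(parameters=dict(UNIT3), NS=1977, Nr=2, M=4)
        assert d.NS >= 2 * d.M * d.omega_max + 1
        assert d.omega_max == 247
        assert DUMMY in d.parameters
        freqs = d.frequencies(0)
        assert freqs[0] == d.omega_max
        assert (freqs[1:] * 2 * d.M <= d.omega_max).all()

    def test_even_ns_rejected(self):
        with pytest.raises(ValueError):
            EfastDesign(parameters=dict(UNIT3), NS=1978)

    def test_samples_in_unit_interval(self):
        d = EfastDesign(parameters=dict(UNIT3), NS=257, Nr=1, include_dummy=False)
        tab = efast_sample(d)
        vals = tab[["x1", "x2", "x3"]].to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_marginals_uniform(self):
        """Each column passes a KS uniformity test at alpha = 0.01."""
        d = EfastDesign(parameters=dict(UNIT3), NS=1977, Nr=1, include_dummy=False, seed=4)
        tab = efast_sample(d)
        block = tab[tab["_interest"] == "x1"]
        for name in UNIT3:
            p = stats.kstest(block[name], "uniform").pvalue
            assert p > 0.01, name

    def test_deterministic(self):
        d1 = EfastDesign(parameters=dict(UNIT3), NS=129, Nr=2, seed=8)
        d2 = EfastDesign(parameters=dict(UNIT3), NS=129, Nr=2, seed=8)
        assert efast_sample(d1).equals(efast_sample(d2))

    def test_scaling_to_ranges(self):
        d = EfastDesign(
            parameters={"a": (2.0, 6.0), "b": (-1.0, 1.0)}, NS=129, Nr=1,
            include_dummy=False,
        )
        tab = efast_sample(d)
        assert tab["a"].min() >= 2.0 and tab["a"].max() <= 6.0
        assert tab["b"].min() >= -1.0 and tab["b"].max() <= 1.0


class TestIndices:
    def test_additive_linear_model(self):
        """Si matches the closed-form variance shares; STi ~ Si (no interactions)."""
        coeff = np.array([1.0, 2.0, 3.0])

        def model(tab):
            return np.asarray(tab[["x1", "x2", "x3"]]) @ coeff

        d = EfastDesign(parameters=dict(UNIT3), NS=1977, Nr=2, seed=2)
        res = efast_run(model, d)
        shares = coeff**2 / (coeff**2).sum()  # equal Var(X_i) cancels
        for name, want in zip(("x1", "x2", "x3"), shares):
            si, sti = res.lookup(name, "output", 0.0)
            assert si == pytest.approx(want, abs=0.03)
            assert sti == pytest.approx(si, abs=0.03)

    def test_ishigami_against_analytic(self):
        d = EfastDesign(parameters=dict(PI3), NS=1977, Nr=2, seed=11)
        res = efast_run(ishigami, d)
        for name, want in ishigami_first_order().items():
            si, _ = res.lookup(name, "output", 0.0)
            assert si == pytest.approx(want, abs=0.05), name

    def test_dummy_parameter_below_noise_floor(self):
        d = EfastDesign(parameters=dict(PI3), NS=1977, Nr=2, seed=11)
        res = efast_run(ishigami, d)
        si, sti = res.lookup(DUMMY, "output", 0.0)
        assert si < 0.05 and sti < 0.05

    def test_first_order_sum_bounded(self):
        d = EfastDesign(parameters=dict(PI3), NS=1977, Nr=2, seed=5)
        res = efast_run(ishigami, d)
        total = res.table[res.table["parameter"] != DUMMY]["Si"].sum()
        assert total <= 1.0 + 0.09

    def test_si_not_above_sti(self):
        d = EfastDesign(parameters=dict(PI3), NS=513, Nr=2, seed=6)
        res = efast_run(ishigami, d)
        assert (res.table["Si"] <= res.table["STi"] + 1e-6).all()

    def test_affine_output_invariance(self):
        d = EfastDesign(parameters=dict(PI3), NS=513, Nr=2, seed=7)
        res_a = efast_run(ishigami, d)
        res_b = efast_run(lambda t: 3.0 * ishigami(t) - 11.0, d)
        assert np.allclose(res_a.table["Si"], res_b.table["Si"], atol=1e-10)
        assert np.allclose(res_a.table["STi"], res_b.table["STi"], atol=1e-10)

    def test_convergence_with_ns(self):
        """Doubling NS barely moves the Ishigami estimates."""
        want = ishigami_first_order()
        got = {}
        for ns in (1977, 3955):
            d = EfastDesign(parameters=dict(PI3), NS=ns, Nr=2, seed=3)
            res = efast_run(ishigami, d)
            got[ns] = np.array([res.lookup(p, "output", 0.0)[0] for p in ("x1", "x2", "x3")])
        assert np.abs(got[1977] - got[3955]).max() < 0.02

    def test_constant_output_flagged(self):
        d = EfastDesign(parameters=dict(UNIT3), NS=129, Nr=1, seed=1)
        res = efast_run(lambda t: np.ones(len(t)), d)
        assert res.degenerate
        assert np.isnan(res.table["Si"]).all()

    def test_row_count_validated(self):
        d = EfastDesign(parameters=dict(UNIT3), NS=129, Nr=1)
        with pytest.raises(ValueError):
            efast_indices(np.zeros(10), d)


class TestRankSubsets:
    @pytest.fixture()
    def result(self):
        """Synthetic index table: x1 strong, x2 middling, x3 ~ zero."""
        rows = []
        strengths = {"x1": 0.6, "x2": 0.3, "x3": 0.001, "shared": 0.2}
        for p, s in strengths.items():
            rows.append(
                {"parameter": p, "output": "C", "time": 20.0, "Si": s,
                 "STi": min(1.0, s + 0.05), "D": 1.0, "D_minus_i": 1.0 - s}
            )
        d = EfastDesign(parameters={p: (0, 1) for p in strengths}, NS=129, Nr=1)
        from vcohort.efast import SensitivityResult

        return SensitivityResult(table=pd.DataFrame(rows), design=d)

    def test_zero_sensitivity_subset_ranks_last(self, result):
        subsets = [("x1", "shared"), ("x2", "shared"), ("x3", "shared")]
        ordering, log = rank_subsets(result, subsets, times=(20.0,), shared=("shared",))
        assert ordering[0] == ("x1", "shared")
        assert ordering[-1] == ("x3", "shared")
        assert any("drop" in line for line in log)

    def test_permutation_invariance(self, result):
        subsets = [("x1", "shared"), ("x2", "shared"), ("x3", "shared")]
        a, _ = rank_subsets(result, subsets, times=(20.0,), shared=("shared",))
        b, _ = rank_subsets(result, list(reversed(subsets)), times=(20.0,), shared=("shared",))
        assert a == b

    def test_ties_reported(self, result):
        subsets = [("x1",), ("x1", "shared")]  # same distinguishing parameter
        _, log = rank_subsets(result, subsets, times=(20.0,), shared=("shared",))
        assert any("tie" in line for line in log)
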