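"""Extended Fourier Amplitude Sensitivity Test (eFAST).

Variance-based global sensitivity analysis: each parameter is driven
along a sinusoidal search curve through the unit hypercube,

    x_j(s) = 1/2 + (1/pi) * arcsin(sin(omega_j * s + phi_j)),

and the variance of the model output is decomposed by Fourier analysis
of the output along the curve.  For each parameter of interest a
dedicated curve assigns it the maximal frequency omega_max while the
complementary set receives low frequencies; the spectrum at omega_max
and its harmonics gives the first-order index Si, and the spectrum
below omega_max/2 gives the complementary variance D(-i), whence the
total-order index STi = (D - D(-i)) / D.  Random phase shifts define
Nr independent resamplings whose indices are averaged.  A dummy
parameter that does not enter the model provides a noise floor for
significance screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EfastDesign",
    "SensitivityResult",
    "efast_sample",
    "efast_indices",
    "efast_run",
    "rank_subsets",
]

DUMMY = "_dummy"


@dataclass
class EfastDesign:
    """Sampling design of an eFAST experiment.

    NS samples per search curve (odd), Nr random-phase resamplings, and
    interference factor M: frequencies up to the M-th harmonic must not
    interfere, which requires NS >= 2 * M * omega_max + 1.
    """

    parameters: dict[str, tuple[float, float]]  # name -> (lower, upper)
    NS: int = 1977
    Nr: int = 2
    M: int = 4
    include_dummy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.NS % 2 == 0:
            raise ValueError("NS must be odd")
        if self.Nr < 1 or self.M < 1:
            raise ValueError("Nr and M must be >= 1")
        if self.omega_max < 1:
            raise ValueError("NS too small for the interference factor")
        if self.include_dummy and DUMMY not in self.parameters:
            self.parameters = {**self.parameters, DUMMY: (0.0, 1.0)}

    @property
    def names(self) -> list[str]:
        return list(self.parameters)

    @property
    def k(self) -> int:
        return len(self.parameters)

    @property
    def omega_max(self) -> int:
        """Frequency of the parameter of interest."""
        return (self.NS - 1) // (2 * self.M)

    @property
    def omega_complementary_max(self) -> int:
        """Largest frequency available to the complementary set."""
        return max(1, self.omega_max // (2 * self.M))

    def frequencies(self, interest: int) -> np.ndarray:
        """Integer frequency per parameter when ``interest`` is focal.

        The focal parameter gets omega_max; the complementary set is
        spread as evenly as possible over 1..omega_complementary_max so
        its spectrum (including harmonics up to M) stays below
        omega_max/2.
        """
        freqs = np.empty(self.k, dtype=int)
        freqs[interest] = self.omega_max
        comp = [j for j in range(self.k) if j != interest]
        cmax = self.omega_complementary_max
        if len(comp) == 1:
            spread = np.array([cmax])
        elif comp:
            spread = np.unique(np.round(np.linspace(1, cmax, len(comp))).astype(int))
        else:
            spread = np.array([], dtype=int)
        for pos, j in enumerate(comp):
            freqs[j] = spread[pos % len(spread)]
        return freqs


def _s_grid(NS: int) -> np.ndarray:
    """Symmetric sample points of the curve parameter s in (-pi, pi)."""
    j = np.arange(1, NS + 1)
    return np.pi * (2.0 * j - NS - 1.0) / NS


def efast_sample(design: EfastDesign) -> pd.DataFrame:
    """Scaled sample table, one block of NS rows per (interest, resample).

    Columns: the parameter names plus ``_interest`` (focal parameter of
    the block) and ``_resample``.  Values follow the search curve with a
    per-(block, parameter) random phase, then scale linearly from the
    unit hypercube to the declared ranges.
    """
    rng = np.random.default_rng(design.seed)
    s = _s_grid(design.NS)
    names = design.names
    blocks = []
    for i, focal in enumerate(names):
        freqs = design.frequencies(i)
        for r in range(design.Nr):
            phases = rng.uniform(0.0, 2.0 * np.pi, size=design.k)
            unit = 0.5 + (1.0 / np.pi) * np.arcsin(
                np.sin(freqs[None, :] * s[:, None] + phases[None, :])
            )
            block = pd.DataFrame(unit, columns=names)
            for name in names:
                lo, hi = design.parameters[name]
                block[name] = lo + block[name] * (hi - lo)
            block["_interest"] = focal
            block["_resample"] = r
            blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def _spectrum(y: np.ndarray, NS: int) -> np.ndarray:
    """Power 2*(A_w^2 + B_w^2) at integer frequencies 1..(NS-1)/2.

    y may be (NS,) or (NS, n_outputs); the s grid is the symmetric one
    from :func:`_s_grid`.
    """
    s = _s_grid(NS)
    wmax = (NS - 1) // 2
    w = np.arange(1, wmax + 1)
    cos = np.cos(np.outer(w, s))
    sin = np.sin(np.outer(w, s))
    A = cos @ y / NS
    B = sin @ y / NS
    return 2.0 * (A**2 + B**2)


@dataclass
class SensitivityResult:
    """First- and total-order indices per (parameter, output, time)."""

    table: pd.DataFrame  # columns: parameter, output, time, Si, STi, D, D_minus_i
    design: EfastDesign
    degenerate: list[tuple[str, float]] = field(default_factory=list)

    def lookup(self, parameter: str, output: str, time: float) -> tuple[float, float]:
        row = self.table[
            (self.table["parameter"] == parameter)
            & (self.table["output"] == output)
            & (self.table["time"] == time)
        ]
        if row.empty:
            raise KeyError((parameter, output, time))
        return float(row["Si"].iloc[0]), float(row["STi"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def efast_indices(
    outputs: np.ndarray | pd.DataFrame,
    design: EfastDesign,
    output_labels: Sequence[tuple[str, float]] | None = None,
) -> SensitivityResult:
    """Compute Si and STi from model outputs aligned with the sample table.

    ``outputs`` has one row per sample-table row and one column per
    model output (a (output, time) pair when ``output_labels`` is
    given).  Outputs with zero variance along a curve are flagged as
    degenerate and their indices set to NaN.
    """
    y = np.asarray(outputs, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n_out = y.shape[1]
    if output_labels is None:
        output_labels = [("output", float(i)) for i in range(n_out)]
    expected = design.k * design.Nr * design.NS
    if y.shape[0] != expected:
        raise ValueError(f"outputs have {y.shape[0]} rows, expected {expected}")
    if not np.all(np.isfinite(y)):
        raise ValueError("model outputs must be finite")

    wmax_i = design.omega_max
    half = wmax_i // 2
    harmonics = np.arange(1, design.M + 1) * wmax_i

    rows = []
    degenerate: list[tuple[str, float]] = []
    idx = 0
    for i, focal in enumerate(design.names):
        Si_acc = np.zeros((design.Nr, n_out))
        STi_acc = np.zeros((design.Nr, n_out))
        D_acc = np.zeros((design.Nr, n_out))
        Dmi_acc = np.zeros((design.Nr, n_out))
        for r in range(design.Nr):
            block = y[idx : idx + design.NS]
            idx += design.NS
            spec = _spectrum(block, design.NS)  # (wmax, n_out)
            D = spec.sum(axis=0)
            Di = spec[harmonics - 1].sum(axis=0)
            Dci = spec[:half].sum(axis=0)
            # a variance at round-off level means the output is constant
            floor = 1e-14 * np.maximum(1.0, np.mean(block**2, axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                Si_acc[r] = np.where(D > floor, Di / D, np.nan)
                STi_acc[r] = np.where(D > floor, 1.0 - Dci / D, np.nan)
            D_acc[r] = D
            Dmi_acc[r] = Dci
        Si = Si_acc.mean(axis=0)
        STi = STi_acc.mean(axis=0)
        for j, (label, t) in enumerate(output_labels):
            if not np.isfinite(Si[j]):
                degenerate.append((label, t))
            rows.append(
                {
                    "parameter": focal,
                    "output": label,
                    "time": t,
                    "Si": Si[j],
                    "STi": STi[j],
                    "D": D_acc[:, j].mean(),
                    "D_minus_i": Dmi_acc[:, j].mean(),
                }
            )
    return SensitivityResult(table=pd.DataFrame(rows), design=design, degenerate=degenerate)


def efast_run(
    model_fn: Callable[[pd.DataFrame], np.ndarray],
    design: EfastDesign,
    output_labels: Sequence[tuple[str, float]] | None = None,
) -> SensitivityResult:
    """Sample, evaluate ``model_fn`` on the parameter columns, decompose.

    ``model_fn`` receives the full sample table (dummy column included;
    it must ignore it) and returns one output row per sample row.
    """
    table = efast_sample(design)
    y = model_fn(table[design.names])
    return efast_indices(np.asarray(y), design, output_labels=output_labels)


def rank_subsets(
    result: SensitivityResult,
    candidate_subsets: Sequence[Sequence[str]],
    focus_output: str = "C",
    times: Sequence[float] = (20.0,),
    shared: Sequence[str] = ("kGM",),
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Order candidate generating subsets by focal-output sensitivity.

    Implements the elimination logic as explicit weakest-link dominance
    rules: a subset is dominated when, at every comparison time, its
    least sensitive distinguishing parameter (member outside the shared
    core) has both a lower Si and a lower STi on the focal output than
    the least sensitive distinguishing parameter of some other subset.
    Survivors (and then the dominated) are ordered by mean STi of their
    distinguishing parameters; exact ties are reported in the log, not
    broken silently.
    """
    subsets = [tuple(s) for s in candidate_subsets]
    shared_set = set(shared)
    log: list[str] = []

    def dist(subset: tuple[str, ...]) -> list[str]:
        return [p for p in subset if p not in shared_set]

    def indices(p: str, t: float) -> tuple[float, float]:
        return result.lookup(p, focus_output, t)

    dominated: set[tuple[str, ...]] = set()
    for a in subsets:
        for b in subsets:
            if a == b or a in dominated:
                continue
            da, db = dist(a), dist(b)
            if not da or not db:
                continue
            dominates = True
            for t in times:
                a_si = min(indices(p, t)[0] for p in da)
                a_st = min(indices(p, t)[1] for p in da)
                b_si = min(indices(p, t)[0] for p in db)
                b_st = min(indices(p, t)[1] for p in db)
                if not (a_si < b_si and a_st < b_st):
                    dominates = False
                    break
            if dominates:
                dominated.add(a)
                log.append(
                    f"drop {a}: weakest distinguishing member of {da} below that"
                    f" of {db} ({b}) in Si and STi at all times {tuple(times)}"
                )

    def score(subset: tuple[str, ...]) -> float:
        vals = [
            np.mean([indices(p, t)[1] for t in times]) for p in dist(subset) or subset
        ]
        return float(np.mean(vals))

    scores = {s: score(s) for s in subsets}
    for a in subsets:
        for b in subsets:
            if a < b and scores[a] == scores[b]:
                log.append(f"tie between {a} and {b} at score {scores[a]:.6g}")
    ordering = sorted(
        subsets, key=lambda s: (s in dominated, -scores[s], s)
    )
    log.append("ordering: " + " > ".join(map(str, ordering)))
    return ordering, log
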