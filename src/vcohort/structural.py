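"""A-priori (structural) identifiability via the differential-algebra approach.

The input-output relation of an ODE model is the system rewritten in the
observed quantities and their derivatives; after clearing denominators,
the coefficients of its monomials form the set of identifiable parameter
combinations.  A parameter is globally structurally identifiable when it
can be solved uniquely from those combinations.

Two results are reproduced for the shipped tumor-immune model:

* observed through total tumor volume C+T+M (treatment-free system) the
  relation yields 7 combinations for 11 parameters, so the model is
  *not* identifiable from ultrasound data alone;
* observed through all of C, T, M, G with known doses, the coefficient
  set determines all 16 parameters analytically.

Scope is deliberately limited to direct coefficient reading after
denominator clearing (the route the shipped model admits); general
differential elimination to characteristic sets is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp

__all__ = [
    "IORelationReport",
    "ToyModel",
    "io_coefficients_total_volume",
    "io_coefficients_full",
    "check_identifiability",
    "model_symbols",
    "treatment_free_rhs",
    "full_model_rhs",
]

# -- symbols -----------------------------------------------------------

_C, _T, _M, _G = sp.symbols("C T M G", nonnegative=True)
_STATES = (_C, _T, _M, _G)
_P = sp.symbols(
    "pC Cmax kTC kGC Km nCT sMT dT kGT rCM sTM dM kGM dG hT hM", positive=True
)
(pC, Cmax, kTC, kGC, Km, nCT, sMT, dT, kGT, rCM, sTM, dM, kGM, dG, hT, hM) = _P
uOT1, uGEM = sp.symbols("uOT1 uGEM", positive=True)

#: the 16 parameters of the full treated model (hT, hM in place of T0, M0,
#: exactly as they enter the equations)
FULL_PARAMS: tuple[sp.Symbol, ...] = _P
#: the 11 parameters of the treatment-free subsystem
TREATMENT_FREE_PARAMS: tuple[sp.Symbol, ...] = (
    pC, Cmax, kTC, nCT, sMT, dT, rCM, sTM, dM, hT, hM
)


def model_symbols() -> dict[str, sp.Symbol]:
    """All state/parameter/input symbols keyed by name."""
    out = {str(s): s for s in _STATES + _P}
    out["uOT1"], out["uGEM"] = uOT1, uGEM
    return out


def treatment_free_rhs() -> dict[sp.Symbol, sp.Expr]:
    """Symbolic right-hand sides of the treatment-free (C, T, M) system."""
    return {
        _C: pC * _C * (1 - _C / Cmax) - kTC * _T * _C,
        _T: nCT * _C * _T - sMT * _M * _T - dT * _T + hT,
        _M: rCM * _C - sTM * _T * _M - dM * _M + hM,
    }


def full_model_rhs() -> dict[sp.Symbol, sp.Expr]:
    """Symbolic right-hand sides of the full treated system.

    The dosing inputs enter as the constants uOT1 (known OT-1 dose) and
    uGEM (known Gem dose), mirroring how they appear in the relations.
    """
    sat = _G / (_G + Km)
    return {
        _C: pC * _C * (1 - _C / Cmax) - kTC * _T * _C - kGC * _C * sat,
        _T: nCT * _C * _T - sMT * _M * _T - dT * _T + hT + uOT1 - kGT * _T * sat,
        _M: rCM * _C - sTM * _T * _M - dM * _M + hM - kGM * _M * sat,
        _G: uGEM - dG * _G,
    }


@dataclass
class ToyModel:
    """A small user-supplied ODE system for the generic driver."""

    states: Sequence[sp.Symbol]
    rhs: Mapping[sp.Symbol, sp.Expr]
    params: Sequence[sp.Symbol]
    known_inputs: Sequence[sp.Symbol] = ()


@dataclass
class IORelationReport:
    """Outcome of reading identifiable combinations off an I/O relation."""

    observable: str
    combinations: list[sp.Expr]
    n_combinations: int
    n_parameters: int
    globally_identifiable: bool
    recovered: dict[str, sp.Expr] | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "observable": self.observable,
            "combinations": [str(c) for c in self.combinations],
            "n_combinations": self.n_combinations,
            "n_parameters": self.n_parameters,
            "globally_identifiable": self.globally_identifiable,
            "recovered": None
            if self.recovered is None
            else {k: str(v) for k, v in self.recovered.items()},
            "notes": list(self.notes),
        }

    def summary(self) -> str:
        lines = [
            f"observable: {self.observable}",
            f"identifiable combinations ({self.n_combinations}):",
        ]
        lines += [f"  {sp.sstr(c)}" for c in self.combinations]
        lines.append(f"free parameters: {self.n_parameters}")
        lines.append(f"globally identifiable: {self.globally_identifiable}")
        if self.recovered:
            lines.append("recovered parameters:")
            lines += [f"  {k} = {sp.sstr(v)}" for k, v in self.recovered.items()]
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)


# -- coefficient machinery ---------------------------------------------


def _canonical(expr: sp.Expr) -> sp.Expr:
    """Canonical representative of a combination, up to overall sign."""
    e = sp.cancel(sp.expand(sp.together(expr)))
    if e.could_extract_minus_sign():
        e = -e
    return e


def _relation_coefficients(
    relation: sp.Expr,
    monomial_vars: Sequence[sp.Symbol],
    params: Sequence[sp.Symbol],
    deriv: sp.Symbol | None = None,
) -> list[sp.Expr]:
    """Distinct parameter combinations among the monomial coefficients.

    When ``deriv`` is given, the relation is first made monic in its
    leading derivative monomial (the differential-algebra normalization),
    so denominator clearing does not inject spurious overall factors.
    Coefficients free of parameters (the monic leader, known inputs)
    carry no identifiable information and are dropped.
    """
    poly = sp.Poly(sp.expand(relation), *monomial_vars)
    if deriv is not None:
        d_idx = list(poly.gens).index(deriv)
        leaders = [
            (mono, coeff)
            for mono, coeff in zip(poly.monoms(), poly.coeffs())
            if mono[d_idx] > 0
        ]
        if leaders:
            # monoms() is sorted descending, so the first is the leader
            _, lead_coeff = leaders[0]
            poly = sp.Poly(
                sp.expand(sp.cancel(poly.as_expr() / lead_coeff)), *monomial_vars
            )
    combos: list[sp.Expr] = []
    seen: set[sp.Expr] = set()
    pset = set(params)
    for coeff in poly.coeffs():
        if not (coeff.free_symbols & pset):
            continue
        c = _canonical(coeff)
        if c not in seen:
            seen.add(c)
            combos.append(c)
    return combos


def _solve_parameters(
    combos: Sequence[sp.Expr],
    params: Sequence[sp.Symbol],
    known: Sequence[sp.Symbol] = (),
) -> dict[str, sp.Expr] | None:
    """Solve coefficient equations v_k = combo_k for the parameters.

    Returns the unique solution as param-name -> expression in the
    coefficient symbols v0..vK (and known inputs), or None when no
    unique solution exists.
    """
    if len(combos) < len(params):
        return None
    values = sp.symbols(f"v0:{len(combos)}", positive=True)
    eqs = [sp.Eq(v, c) for v, c in zip(values, combos)]
    allowed = set(values) | set(known)
    solution: dict[sp.Symbol, sp.Expr] = {}
    remaining = set(params)

    # greedy triangular pass: repeatedly solve any equation left with a
    # single unknown parameter, back-substituting as we go
    progress = True
    while progress and remaining:
        progress = False
        for eq in eqs:
            expr = eq.rhs.subs(solution)
            unknowns = expr.free_symbols & remaining
            if len(unknowns) != 1:
                continue
            (u,) = unknowns
            try:
                sols = sp.solve(sp.Eq(eq.lhs, expr), u)
            except Exception:
                continue
            sols = [s for s in sols if s.free_symbols <= allowed]
            if len(sols) != 1:
                continue
            solution[u] = sols[0]
            remaining.discard(u)
            progress = True

    if remaining:
        # joint solve of whatever equations still involve unsolved params
        pend = [
            sp.Eq(eq.lhs, eq.rhs.subs(solution))
            for eq in eqs
            if eq.rhs.subs(solution).free_symbols & remaining
        ]
        try:
            sols = sp.solve(pend, list(remaining), dict=True)
        except Exception:
            return None
        full = [
            s
            for s in sols
            if set(s) == remaining
            and all(expr.free_symbols <= allowed for expr in s.values())
        ]
        if len(full) != 1:
            return None
        solution.update(full[0])

    return {str(k): sp.simplify(v) for k, v in solution.items()}


# -- shipped-model results ---------------------------------------------


def io_coefficients_total_volume() -> IORelationReport:
    """Treatment-free model observed through total volume V = C+T+M.

    The aggregated equation dV/dt is treated as the model, with access
    to the individual subpopulations when reading coefficients: the
    relation cannot be reduced to V and its derivatives alone, so the
    coefficients are read off the monomials in C, T, M directly.
    """
    rhs = treatment_free_rhs()
    aggregated = sp.expand(rhs[_C] + rhs[_T] + rhs[_M])
    combos = _relation_coefficients(aggregated, (_C, _T, _M), TREATMENT_FREE_PARAMS)
    n_par = len(TREATMENT_FREE_PARAMS)
    report = IORelationReport(
        observable="C+T+M",
        combinations=combos,
        n_combinations=len(combos),
        n_parameters=n_par,
        globally_identifiable=False,
        recovered=None,
        notes=[
            "fewer combinations than parameters: parameter values cannot be"
            " deduced, so total-volume (ultrasound) data cannot identify the"
            " model"
        ],
    )
    if len(combos) >= n_par:  # pragma: no cover - structural guarantee
        report.notes.append("unexpected: combination count reached parameter count")
    return report


def _cleared_relations(
    rhs: Mapping[sp.Symbol, sp.Expr], states: Sequence[sp.Symbol]
) -> dict[sp.Symbol, sp.Expr]:
    """Form x_dot - f(x) = 0 per state and clear denominators."""
    relations = {}
    for x in states:
        xdot = sp.Symbol(f"{x}dot")
        rel = xdot - rhs[x]
        numer, _ = sp.fraction(sp.together(rel))
        relations[x] = sp.expand(numer)
    return relations


def io_coefficients_full() -> IORelationReport:
    """Full treated model observed through C, T, M and G with known doses.

    Each equation is rearranged to equal zero and multiplied through by
    the Michaelis-Menten denominator (G + Km); the coefficients of the
    resulting polynomials in the states are the identifiable
    combinations, from which all 16 parameters are solved analytically
    (Km via (pC*Km)/pC, hT via (hT + uOT1) - uOT1).
    """
    rhs = full_model_rhs()
    relations = _cleared_relations(rhs, _STATES)
    combos: list[sp.Expr] = []
    seen: set[sp.Expr] = set()
    for x in _STATES:
        xdot = sp.Symbol(f"{x}dot")
        for c in _relation_coefficients(
            relations[x], list(_STATES) + [xdot], FULL_PARAMS, deriv=xdot
        ):
            if c not in seen:
                seen.add(c)
                combos.append(c)
    recovered = _solve_parameters(combos, FULL_PARAMS, known=(uOT1, uGEM))
    identifiable = recovered is not None
    return IORelationReport(
        observable="C,T,M,G",
        combinations=combos,
        n_combinations=len(combos),
        n_parameters=len(FULL_PARAMS),
        globally_identifiable=identifiable,
        recovered=recovered,
        notes=["doses uOT1, uGEM treated as known inputs"],
    )


# -- generic driver ----------------------------------------------------


def check_identifiability(
    model: ToyModel | str = "full",
    observable: Sequence[sp.Symbol] | sp.Expr | str = "subpops",
) -> IORelationReport:
    """Dispatching driver for coefficient-reading identifiability.

    For the shipped model pass ``model="full"`` with ``observable``
    either ``"subpops"`` (C, T, M, G observed) or ``"total"`` (total
    volume of the treatment-free system).  A :class:`ToyModel` may be
    supplied with a sequence of observed state symbols; every equation
    whose variables are all observed contributes coefficients, and the
    model is declared non-identifiable when unobserved states prevent
    direct reading (elimination is out of scope).
    """
    if isinstance(model, str):
        if model not in ("full", "treatment_free"):
            raise ValueError(f"unknown model spec {model!r}")
        if observable == "total":
            return io_coefficients_total_volume()
        if observable == "subpops":
            return io_coefficients_full()
        if isinstance(observable, str):
            raise ValueError(f"unknown observable spec {observable!r}")
        rhs = full_model_rhs() if model == "full" else treatment_free_rhs()
        states = _STATES if model == "full" else (_C, _T, _M)
        params = FULL_PARAMS if model == "full" else TREATMENT_FREE_PARAMS
        toy = ToyModel(states=states, rhs=rhs, params=params, known_inputs=(uOT1, uGEM))
        return _check_toy(toy, observable)
    return _check_toy(model, observable)


def _check_toy(
    model: ToyModel, observable: Sequence[sp.Symbol] | sp.Expr
) -> IORelationReport:
    states = list(model.states)
    if isinstance(observable, sp.Expr) and not isinstance(observable, sp.Symbol):
        # only the sum-of-all-states aggregated reading is supported
        if sp.simplify(observable - sp.Add(*states)) != 0:
            raise NotImplementedError(
                "general observables require differential elimination, which"
                " is outside the scope of direct coefficient reading"
            )
        aggregated = sp.expand(sum(model.rhs[x] for x in states))
        numer, _ = sp.fraction(sp.together(aggregated))
        combos = _relation_coefficients(numer, states, model.params)
        recovered = _solve_parameters(combos, model.params, known=model.known_inputs)
        return IORelationReport(
            observable="+".join(map(str, states)),
            combinations=combos,
            n_combinations=len(combos),
            n_parameters=len(model.params),
            globally_identifiable=recovered is not None,
            recovered=recovered,
        )

    observed = list(observable)
    unobserved = [x for x in states if x not in observed]
    relations = _cleared_relations(model.rhs, states)
    combos: list[sp.Expr] = []
    seen: set[sp.Expr] = set()
    notes: list[str] = []
    readable = True
    for x in states:
        rel_vars = relations[x].free_symbols
        if x not in observed or any(u in rel_vars for u in unobserved):
            if x in observed:
                readable = False
                notes.append(
                    f"equation for {x} involves unobserved states; direct"
                    " coefficient reading impossible"
                )
            else:
                readable = False
                notes.append(f"state {x} unobserved; its relation is unavailable")
            continue
        xdot = sp.Symbol(f"{x}dot")
        for c in _relation_coefficients(
            relations[x], observed + [xdot], model.params, deriv=xdot
        ):
            if c not in seen:
                seen.add(c)
                combos.append(c)
    recovered = None
    if readable:
        recovered = _solve_parameters(combos, model.params, known=model.known_inputs)
    return IORelationReport(
        observable=",".join(map(str, observed)),
        combinations=combos,
        n_combinations=len(combos),
        n_parameters=len(model.params),
        globally_identifiable=recovered is not None,
        recovered=recovered,
        notes=notes,
    )
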