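"""Control matrix equation and its symbolic inversion.

The independent control coefficients C satisfy ``C @ E = I`` where
``E = [K~ | -eps~ @ L~]`` combines the flux kernel scaled by steady-state
fluxes with the scaled elasticity and link matrices.  Inverting ``E``
symbolically yields one common denominator (Sigma, the determinant) and a
numerator per coefficient whose additive monomial terms are the control
patterns.

Internally the rows of ``E`` are cleared of flux denominators (each row is
multiplied by its reaction's flux symbol), which keeps every entry a signed
monomial; determinants are computed by sparse cofactor expansion with
memoised minors.  After expansion, monomial factors common to every
numerator term and every Sigma term are cancelled, which reproduces the
compact published form of the expressions.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import sympy as sp

from .elasticities import ElasticityMatrix, symbolic_elasticities
from .model_core import KineticModel, ModelError, elasticity_symbol, flux_symbol
from .steady_state import CompiledModel, SteadyState, find_steady_state
from .stoichiometry import StoichiometryInfo, stoichiometric_analysis

__all__ = [
    "EMatrix",
    "ControlPattern",
    "ControlCoefficientExpression",
    "build_control_matrix_equation",
    "symbolic_invert",
    "control_coefficient_expression",
    "numeric_control_coefficients",
    "fd_control_coefficient",
    "verify_theorems",
    "symbol_values",
]

Monomial = tuple[str, ...]  # sorted symbol names, repetition encodes powers
Poly = dict[Monomial, Fraction]


def _mono_mul(a: Monomial, b: Monomial) -> Monomial:
    return tuple(sorted(a + b))


def _poly_gcd_monomial(polys: list[Poly]) -> Monomial:
    """Largest monomial dividing every term of every polynomial."""
    from collections import Counter

    common: Counter | None = None
    for p in polys:
        for mono in p:
            c = Counter(mono)
            common = c if common is None else (common & c)
            if not common:
                return ()
    if not common:
        return ()
    return tuple(sorted(common.elements()))


def _mono_div(mono: Monomial, g: Monomial) -> Monomial:
    from collections import Counter

    c = Counter(mono)
    c.subtract(Counter(g))
    if any(v < 0 for v in c.values()):
        raise ValueError(f"{g} does not divide {mono}")
    return tuple(sorted(c.elements()))


def _poly_to_expr(p: Poly) -> sp.Expr:
    return sp.Add(
        *[
            sp.Rational(c) * sp.Mul(*[sp.Symbol(s) for s in mono])
            for mono, c in p.items()
        ]
    )


def _poly_eval(p: Poly, values: dict[str, float]) -> float:
    total = 0.0
    for mono, c in p.items():
        term = float(c)
        for s in mono:
            term *= values[s]
        total += term
    return total


def _sparse_minor(
    entries: dict[tuple[int, int], list[tuple[Fraction, Monomial]]],
    rows: tuple[int, ...],
    cols: tuple[int, ...],
    cache: dict,
) -> Poly:
    """Determinant of the submatrix by cofactor expansion along the sparsest
    column, with memoisation on (rows, cols)."""
    if not rows:
        return {(): Fraction(1)}
    key = (rows, cols)
    if key in cache:
        return cache[key]
    best, best_nz = None, None
    for c in cols:
        nz = [r for r in rows if (r, c) in entries]
        if best_nz is None or len(nz) < len(best_nz):
            best, best_nz = c, nz
            if len(nz) <= 1:
                break
    result: Poly = {}
    if best_nz:
        ci = cols.index(best)
        rest_cols = cols[:ci] + cols[ci + 1 :]
        for r in best_nz:
            ri = rows.index(r)
            sign = -1 if (ri + ci) % 2 else 1
            sub = _sparse_minor(
                entries, rows[:ri] + rows[ri + 1 :], rest_cols, cache
            )
            for coeff, mono in entries[(r, best)]:
                for smono, sc in sub.items():
                    m = _mono_mul(mono, smono)
                    result[m] = result.get(m, Fraction(0)) + sign * coeff * sc
        result = {m: c for m, c in result.items() if c != 0}
    cache[key] = result
    return result


@dataclass
class EMatrix:
    """The square control matrix equation operand, row-cleared of fluxes.

    ``entries[(row, col)]`` is a list of (rational coefficient, monomial)
    pairs; rows are reactions, the first block of columns are flux modes
    (labelled by their independent flux) and the remaining columns are the
    independent species.
    """

    model: KineticModel
    stoich: StoichiometryInfo
    elasticities: ElasticityMatrix
    entries: dict[tuple[int, int], list[tuple[Fraction, Monomial]]]
    kernel_scale: dict[str, int]  # independent flux -> identity-row coefficient
    link_symbolic: dict[tuple[str, str], sp.Expr]

    @property
    def reactions(self) -> list[str]:
        return self.stoich.reactions

    @property
    def n_modes(self) -> int:
        return self.stoich.K.cols

    @property
    def dimension(self) -> int:
        return len(self.reactions)

    def column_label(self, col: int) -> str:
        if col < self.n_modes:
            return f"J:{self.stoich.independent_fluxes[col]}"
        return f"S:{self.stoich.independent_species[col - self.n_modes]}"

    def numeric(self, values: dict[str, float]) -> np.ndarray:
        """Evaluate the *unscaled* E (rows divided back by fluxes, kernel
        columns normalised to identity rows) for the numeric oracle."""
        n = self.dimension
        M = np.zeros((n, n))
        for (r, c), terms in self.entries.items():
            total = 0.0
            for coeff, mono in terms:
                term = float(coeff)
                for s in mono:
                    term *= values[s]
                total += term
            M[r, c] = total
        # undo row clearing and kernel integer scaling
        J = np.array([values[str(flux_symbol(rid))] for rid in self.reactions])
        M /= J[:, None]
        for k, rid in enumerate(self.stoich.independent_fluxes):
            M[:, k] /= self.kernel_scale[rid]
        return M


def build_control_matrix_equation(
    model: KineticModel,
    elasticities: ElasticityMatrix | None = None,
    stoich: StoichiometryInfo | None = None,
    prefer_independent_fluxes: list[str] | None = None,
) -> EMatrix:
    """Assemble E with structural-zero elasticities already substituted."""
    if stoich is None:
        stoich = stoichiometric_analysis(
            model, prefer_independent_fluxes=prefer_independent_fluxes
        )
    if elasticities is None:
        elasticities = symbolic_elasticities(model)
    reactions = stoich.reactions
    n = len(reactions)
    n_modes = stoich.K.cols
    if n_modes + len(stoich.independent_species) != n:
        raise ModelError(
            "rank inconsistency: kernel and link dimensions do not add up to "
            f"the reaction count ({n_modes} + {len(stoich.independent_species)} != {n})"
        )

    entries: dict[tuple[int, int], list[tuple[Fraction, Monomial]]] = {}
    kernel_scale: dict[str, int] = {}
    for k, rid in enumerate(stoich.independent_fluxes):
        lam = int(stoich.K[reactions.index(rid), k])
        kernel_scale[rid] = lam
        jk = str(flux_symbol(rid))
        for r in range(n):
            coef = stoich.K[r, k]
            if coef != 0:
                entries[(r, k)] = [(Fraction(int(coef)), (jk,))]

    link = stoich.scaled_link_entries()
    for j, sj in enumerate(stoich.independent_species):
        col = n_modes + j
        for r, rid in enumerate(reactions):
            terms: list[tuple[Fraction, Monomial]] = []
            jr = str(flux_symbol(rid))
            for s in stoich.species:
                lij = link.get((s, sj))
                if lij is None:
                    continue
                if elasticities.is_structural_zero(rid, s):
                    continue
                esym = str(elasticity_symbol(rid, s))
                if lij != 1:
                    raise ModelError(
                        "symbolic inversion with a non-trivial link matrix is "
                        "not supported; apply the moiety-ratio transform to "
                        f"eliminate the conservation involving {s!r} first"
                    )
                terms.append((Fraction(-1), tuple(sorted((jr, esym)))))
            if terms:
                entries[(r, col)] = entries.get((r, col), []) + terms
    return EMatrix(
        model=model,
        stoich=stoich,
        elasticities=elasticities,
        entries=entries,
        kernel_scale=kernel_scale,
        link_symbolic={k: v for k, v in link.items() if v != 1},
    )


@dataclass
class ControlPattern:
    """One additive numerator term: integer coefficient times a product of
    flux and elasticity symbols.

    ``kernel_picks`` records, per reaction row not covered by an elasticity
    factor, the flux-kernel entry the determinant term used: reaction ->
    (independent flux, integer kernel coefficient).  It is None when the
    term arose from more than one expansion path (merged monomials), in
    which case subpattern coefficients cannot be attributed.
    """

    id: str
    coefficient: int
    factors: Monomial
    kernel_picks: dict[str, tuple[str, int]] | None = None

    def expression(self) -> sp.Expr:
        return sp.Integer(self.coefficient) * sp.Mul(
            *[sp.Symbol(s) for s in self.factors]
        )

    def evaluate(self, values: dict[str, float]) -> float:
        term = float(self.coefficient)
        for s in self.factors:
            term *= values[s]
        return term

    def value(self, values: dict[str, float], sigma: Poly) -> float:
        return self.evaluate(values) / _poly_eval(sigma, values)


@dataclass
class ControlCoefficientExpression:
    """Sum of control patterns over the common denominator Sigma."""

    variable: str  # "J:<rid>" or "S:<sid>"
    reaction: str  # perturbed reaction
    patterns: list[ControlPattern]
    sigma: Poly
    cancelled: Monomial = ()
    cancelled_coefficient: int = 1

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def numerator_expression(self) -> sp.Expr:
        return sp.Add(*[p.expression() for p in self.patterns])

    def sigma_expression(self) -> sp.Expr:
        return _poly_to_expr(self.sigma)

    def expression(self) -> sp.Expr:
        return self.numerator_expression() / self.sigma_expression()

    def evaluate(self, values: dict[str, float]) -> float:
        num = sum(p.evaluate(values) for p in self.patterns)
        return num / _poly_eval(self.sigma, values)

    def pattern_values(self, values: dict[str, float]) -> dict[str, float]:
        den = _poly_eval(self.sigma, values)
        return {p.id: p.evaluate(values) / den for p in self.patterns}

    def to_json(self) -> str:
        return json.dumps(
            {
                "variable": self.variable,
                "reaction": self.reaction,
                "denominator": sp.sstr(self.sigma_expression()),
                "cancelled_common_factor": list(self.cancelled),
                "patterns": [
                    {
                        "id": p.id,
                        "coefficient": p.coefficient,
                        "factors": list(p.factors),
                    }
                    for p in self.patterns
                ],
            },
            indent=2,
        )


def _assign_pattern_ids(
    terms: list[tuple[Fraction, Monomial]],
    picks: dict[Monomial, dict[str, tuple[str, int]] | None],
) -> list[ControlPattern]:
    terms = sorted(terms, key=lambda t: (t[1], t[0]))
    width = max(3, len(str(len(terms))))
    out = []
    for i, (coeff, mono) in enumerate(terms, start=1):
        if coeff.denominator != 1:
            raise ModelError(f"non-integer pattern coefficient {coeff} for {mono}")
        out.append(
            ControlPattern(
                id=f"CP{i:0{width}d}",
                coefficient=int(coeff),
                factors=mono,
                kernel_picks=picks.get(mono),
            )
        )
    return out


def _kernel_provenance(
    E: EMatrix,
    term: Monomial,
    coeff: Fraction,
    deleted_row: int,
    deleted_kernel_col: int | None,
) -> dict[str, tuple[str, int]] | None:
    """Reconstruct which kernel column each non-elasticity row of a
    determinant term used.  The elasticity factors fix their rows; the
    remaining rows must match the remaining kernel columns such that the
    multiset of independent-flux symbols agrees with the term's flux
    content.  Returns None when the assignment is not unique."""
    from collections import Counter

    reactions = E.reactions
    n = E.dimension
    eps_rows: set[int] = set()
    mono_J = Counter()
    for s in term:
        m = re.match(r"^ec_(.+?)_[A-Za-z_][A-Za-z0-9_]*$", s)
        if m:
            eps_rows.add(reactions.index(m.group(1)))
        elif s.startswith("J_"):
            mono_J[s] += 1
    # subtract the row-clearing fluxes (one per elasticity row) and the
    # perturbed reaction's flux factor
    for r in eps_rows:
        mono_J[str(flux_symbol(reactions[r]))] -= 1
    mono_J[str(flux_symbol(reactions[deleted_row]))] -= 1
    if any(v < 0 for v in mono_J.values()):
        return None
    required = Counter({k: v for k, v in mono_J.items() if v > 0})

    rows = [
        r for r in range(n) if r != deleted_row and r not in eps_rows
    ]
    cols = [
        k
        for k in range(E.n_modes)
        if k != deleted_kernel_col
    ]
    if len(rows) != len(cols):
        return None
    jsym = [str(flux_symbol(rid)) for rid in E.stoich.independent_fluxes]

    solutions: list[dict[int, int]] = []

    def backtrack(i: int, used: set[int], avail: Counter, assign: dict[int, int]):
        if len(solutions) > 1:
            return
        if i == len(rows):
            if not +avail:
                solutions.append(dict(assign))
            return
        r = rows[i]
        for k in cols:
            if k in used or E.stoich.K[r, k] == 0:
                continue
            s = jsym[k]
            if avail[s] <= 0:
                continue
            avail[s] -= 1
            used.add(k)
            assign[r] = k
            backtrack(i + 1, used, avail, assign)
            del assign[r]
            used.discard(k)
            avail[s] += 1

    backtrack(0, set(), Counter(required), {})
    if len(solutions) != 1:
        return None
    sol = solutions[0]
    return {
        reactions[r]: (E.stoich.independent_fluxes[k], int(E.stoich.K[r, k]))
        for r, k in sol.items()
    }


def symbolic_invert(
    E: EMatrix,
    coefficients: list[tuple[str, str]],
    reference_values: dict[str, float] | None = None,
    cancel_common: bool = True,
) -> dict[tuple[str, str], ControlCoefficientExpression]:
    """Invert E symbolically for the requested (variable, reaction) pairs.

    ``coefficients`` lists (controlled variable, perturbed reaction) pairs;
    the controlled variable is ``"J:<rid>"`` for a flux (the reaction must be
    an independent flux of the kernel ordering) or ``"S:<sid>"`` for an
    independent species concentration.  ``reference_values`` (symbol -> value)
    fixes the global sign convention Sigma > 0 at the reference state.
    """
    n = E.dimension
    cache: dict = {}
    entries = E.entries
    all_rows = tuple(range(n))
    all_cols = tuple(range(n))
    sigma = _sparse_minor(entries, all_rows, all_cols, cache)
    if not sigma:
        raise ModelError("structurally singular: the determinant is identically zero")

    results: dict[tuple[str, str], list[tuple[Fraction, Monomial]]] = {}
    provenance: dict[tuple[str, str], dict[Monomial, dict | None]] = {}
    for variable, rxn in coefficients:
        kind, _, label = variable.partition(":")
        if kind == "J":
            if label not in E.stoich.independent_fluxes:
                raise ModelError(
                    f"flux {label} is not in the kernel identity block; rebuild E "
                    "with prefer_independent_fluxes"
                )
            col = E.stoich.independent_fluxes.index(label)
            lam = E.kernel_scale[label]
        elif kind == "S":
            col = E.n_modes + E.stoich.independent_species.index(label)
            lam = 1
        else:
            raise ModelError(f"bad controlled variable {variable!r}")
        i = E.reactions.index(rxn)
        rows = all_rows[:i] + all_rows[i + 1 :]
        cols = all_cols[:col] + all_cols[col + 1 :]
        minor = _sparse_minor(entries, rows, cols, cache)
        sign = -1 if (i + col) % 2 else 1
        ji = (str(flux_symbol(rxn)),)
        num: Poly = {}
        for mono, c in minor.items():
            num[_mono_mul(mono, ji)] = sign * c * lam
        results[(variable, rxn)] = [(c, m) for m, c in num.items()]
        kcol = col if kind == "J" else None
        provenance[(variable, rxn)] = {
            m: _kernel_provenance(E, m, c, i, kcol) for m, c in num.items()
        }

    # global sign: Sigma > 0 at the reference state
    if reference_values is not None:
        if _poly_eval(sigma, reference_values) < 0:
            sigma = {m: -c for m, c in sigma.items()}
            results = {
                k: [(-c, m) for c, m in terms] for k, terms in results.items()
            }

    # cancel the monomial and integer factor common to every numerator term
    # and every Sigma term
    cancelled: Monomial = ()
    cancelled_int = 1
    if cancel_common:
        polys = [sigma] + [dict((m, c) for c, m in t) for t in results.values()]
        g = _poly_gcd_monomial(polys)
        if g:
            cancelled = g
            sigma = {_mono_div(m, g): c for m, c in sigma.items()}
            results = {
                k: [(c, _mono_div(m, g)) for c, m in terms]
                for k, terms in results.items()
            }
            provenance = {
                k: {_mono_div(m, g): v for m, v in pv.items()}
                for k, pv in provenance.items()
            }
        import math

        ints = [abs(int(c)) for c in sigma.values() if c.denominator == 1]
        for terms in results.values():
            ints += [abs(int(c)) for c, _ in terms if c.denominator == 1]
        if len(ints) == len(sigma) + sum(len(t) for t in results.values()):
            gi = math.gcd(*ints)
            if gi > 1:
                cancelled_int = gi
                sigma = {m: c / gi for m, c in sigma.items()}
                results = {
                    k: [(c / gi, m) for c, m in terms]
                    for k, terms in results.items()
                }

    out: dict[tuple[str, str], ControlCoefficientExpression] = {}
    for (variable, rxn), terms in results.items():
        out[(variable, rxn)] = ControlCoefficientExpression(
            variable=variable,
            reaction=rxn,
            patterns=_assign_pattern_ids(terms, provenance[(variable, rxn)]),
            sigma=sigma,
            cancelled=cancelled,
            cancelled_coefficient=cancelled_int,
        )
    return out


# ---------------------------------------------------------------------------
# numeric evaluation
# ---------------------------------------------------------------------------


def symbol_values(
    model: KineticModel,
    state: SteadyState,
    elasticities: ElasticityMatrix | None = None,
    parameter_overrides: dict[str, float] | None = None,
) -> dict[str, float]:
    """Numeric values for every flux and elasticity symbol at a state."""
    if elasticities is None:
        elasticities = symbolic_elasticities(model)
    values: dict[str, float] = {}
    for rid, J in state.fluxes.items():
        values[str(flux_symbol(rid))] = J
    for (rid, x), val in elasticities.evaluate(state, parameter_overrides).items():
        values[str(elasticity_symbol(rid, x))] = val
    for s, c in state.concentrations.items():
        values[s] = c
    return values


def control_coefficient_expression(
    model: KineticModel,
    flux: str,
    reaction: str,
    state: SteadyState | None = None,
) -> ControlCoefficientExpression:
    """Convenience wrapper: symbolic expression of one flux-control
    coefficient, with the sign convention anchored at ``state`` (or the
    model's converged reference state when omitted)."""
    if state is None:
        state = find_steady_state(model)
        if not state.converged:
            raise ModelError("reference steady state did not converge")
    elas = symbolic_elasticities(model)
    E = build_control_matrix_equation(
        model, elasticities=elas, prefer_independent_fluxes=[flux]
    )
    values = symbol_values(model, state, elas)
    return symbolic_invert(E, [(f"J:{flux}", reaction)], reference_values=values)[
        (f"J:{flux}", reaction)
    ]


def numeric_control_coefficients(
    model: KineticModel,
    state: SteadyState,
    elasticities: ElasticityMatrix | None = None,
    stoich: StoichiometryInfo | None = None,
    parameter_overrides: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Numeric flux- and concentration-control coefficient matrices via
    matrix inversion of E evaluated at a converged state.

    Returns (C_J, C_S): rows are controlled fluxes/species, columns the
    perturbed reactions.  A condition-number warning is attached when E is
    ill-conditioned.
    """
    if elasticities is None:
        elasticities = symbolic_elasticities(model)
    if stoich is None:
        stoich = stoichiometric_analysis(model)
    reactions = stoich.reactions
    n = len(reactions)
    n_modes = stoich.K.cols

    # numeric E assembled directly: kernel block K~ and elasticity block -eps~ L~
    J = state.flux_vector(reactions)
    conc = state.concentrations
    evals = elasticities.evaluate(state, parameter_overrides)
    Kn = np.array(stoich.K, dtype=float)
    for k, rid in enumerate(stoich.independent_fluxes):
        Kn[:, k] /= float(stoich.K[reactions.index(rid), k])
    Jind = np.array([state.fluxes[r] for r in stoich.independent_fluxes])
    M = np.zeros((n, n))
    M[:, :n_modes] = (Kn * Jind[None, :]) / J[:, None]
    Lnum = np.zeros((len(stoich.species), len(stoich.independent_species)))
    for i, s in enumerate(stoich.species):
        for j, sj in enumerate(stoich.independent_species):
            lij = stoich.L[i, j]
            if lij != 0:
                Lnum[i, j] = float(lij) * conc[sj] / conc[s]
    eps = np.zeros((n, len(stoich.species)))
    for r, rid in enumerate(reactions):
        for i, s in enumerate(stoich.species):
            eps[r, i] = evals.get((rid, s), 0.0)
    if len(stoich.species):
        M[:, n_modes:] = -eps @ Lnum
    cond = np.linalg.cond(M)
    if cond > 1e12:
        warnings.warn(
            f"E matrix is ill-conditioned (cond={cond:.3g}); control "
            "coefficients may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    C = np.linalg.inv(M)
    C_J_full = M[:, :n_modes] @ C[:n_modes, :]  # K~ rows recover dependent fluxes
    C_S_full = (
        Lnum @ C[n_modes:, :] if len(stoich.species) else np.zeros((0, n))
    )

    C_J = pd.DataFrame(C_J_full, index=reactions, columns=reactions)
    C_S = pd.DataFrame(C_S_full, index=stoich.species, columns=reactions)
    C_J.attrs["condition_number"] = cond
    C_S.attrs["condition_number"] = cond
    return C_J, C_S


def fd_control_coefficient(
    model: KineticModel,
    flux: str,
    reaction: str,
    state: SteadyState | None = None,
    rel: float = 1e-5,
) -> float:
    """Finite-difference oracle: central difference of ln|J_flux| with
    respect to ln(activity of ``reaction``)."""
    compiled = CompiledModel(model)
    if state is None:
        state = find_steady_state(compiled)
    up = find_steady_state(
        compiled, initial=state.concentrations, activities={reaction: 1.0 + rel}
    )
    dn = find_steady_state(
        compiled, initial=state.concentrations, activities={reaction: 1.0 - rel}
    )
    if not (up.converged and dn.converged):
        raise ModelError("finite-difference perturbation did not converge")
    dlne = np.log(1.0 + rel) - np.log(1.0 - rel)
    return float((up.fluxes[flux] - dn.fluxes[flux]) / (state.fluxes[flux] * dlne))


@dataclass
class TheoremReport:
    summation: dict[str, float]
    connectivity: dict[tuple[str, str], float]
    tolerance: float = 1e-8

    @property
    def max_summation_residual(self) -> float:
        return max((abs(v - 1.0) for v in self.summation.values()), default=0.0)

    @property
    def max_connectivity_residual(self) -> float:
        return max((abs(v) for v in self.connectivity.values()), default=0.0)

    @property
    def ok(self) -> bool:
        return (
            self.max_summation_residual <= self.tolerance
            and self.max_connectivity_residual <= self.tolerance
        )

    def flagged(self) -> list[str]:
        out = [
            f"summation J:{rid} residual {abs(v - 1.0):.3g}"
            for rid, v in self.summation.items()
            if abs(v - 1.0) > self.tolerance
        ]
        out += [
            f"connectivity (J:{rid}, {x}) residual {abs(v):.3g}"
            for (rid, x), v in self.connectivity.items()
            if abs(v) > self.tolerance
        ]
        return out


def verify_theorems(
    model: KineticModel,
    state: SteadyState,
    tolerance: float = 1e-8,
    parameter_overrides: dict[str, float] | None = None,
) -> TheoremReport:
    """Summation and connectivity identities of the numeric flux-control
    coefficients at a converged state (report only, never raises).

    Connectivity is checked per independent species; with conserved
    moieties the elasticity columns are combined through the scaled link
    matrix, which is the form in which the theorem holds."""
    elas = symbolic_elasticities(model)
    stoich = stoichiometric_analysis(model)
    C_J, _ = numeric_control_coefficients(
        model, state, elas, stoich, parameter_overrides
    )
    evals = elas.evaluate(state, parameter_overrides)
    conc = state.concentrations
    summation = {rid: float(C_J.loc[rid].sum()) for rid in C_J.index}
    connectivity: dict[tuple[str, str], float] = {}
    for rid in C_J.index:
        for j, sj in enumerate(stoich.independent_species):
            total = 0.0
            for other in C_J.columns:
                combined = 0.0
                for i, s in enumerate(stoich.species):
                    lij = stoich.L[stoich.species.index(s), j]
                    if lij != 0:
                        combined += (
                            evals.get((other, s), 0.0)
                            * float(lij)
                            * conc[sj]
                            / conc[s]
                        )
                total += C_J.loc[rid, other] * combined
            connectivity[(rid, sj)] = float(total)
    return TheoremReport(summation=summation, connectivity=connectivity, tolerance=tolerance)
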