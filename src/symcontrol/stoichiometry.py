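"""Exact stoichiometric analysis: reduced matrix, link matrix, flux kernel
and conservation relations, all over rational arithmetic."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import sympy as sp

from .model_core import KineticModel

__all__ = ["StoichiometryInfo", "stoichiometric_analysis"]


def _integerize(vec: sp.Matrix) -> sp.Matrix:
    """Scale a rational vector to primitive integer form with positive lead."""
    dens = [sp.Rational(v).q for v in vec]
    v = vec * sp.ilcm(*dens, 1) if dens else vec
    g = sp.igcd(*[int(x) for x in v if x != 0], 0) or 1
    v = v / g
    lead = next((x for x in v if x != 0), 1)
    if lead < 0:
        v = -v
    return v


@dataclass
class StoichiometryInfo:
    """Structural decomposition of a stoichiometric matrix N.

    ``N = L @ N_r`` with ``N_r`` the rows of the independent species,
    ``N_r @ K == 0`` exactly, and each conservation relation ``c`` satisfying
    ``c @ N == 0``.  Independent species/fluxes are selected by Gaussian
    elimination over rationals in declared order (deterministic); a preferred
    set of independent fluxes may be requested, in which case those reaction
    columns are eliminated last.
    """

    species: list[str]
    reactions: list[str]
    N: sp.Matrix
    N_r: sp.Matrix
    L: sp.Matrix
    K: sp.Matrix
    conservation_relations: list[sp.Matrix]
    independent_species: list[str]
    independent_fluxes: list[str]
    dependent_species: list[str] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return len(self.independent_species)

    def is_conserved_pair(self, a: str, b: str) -> bool:
        """True if some conservation relation has support exactly {a, b}."""
        ia, ib = self.species.index(a), self.species.index(b)
        for c in self.conservation_relations:
            support = {i for i in range(len(self.species)) if c[i] != 0}
            if support == {ia, ib}:
                return True
        return False

    def scaled_link_entries(self) -> dict[tuple[str, str], sp.Expr]:
        """Entries of the scaled link matrix L~ = D_s^-1 L D_si as symbolic
        concentration ratios, keyed by (species, independent species)."""
        out: dict[tuple[str, str], sp.Expr] = {}
        ind_idx = [self.species.index(s) for s in self.independent_species]
        for i, s in enumerate(self.species):
            for j, sj in enumerate(self.independent_species):
                lij = self.L[i, j]
                if lij == 0:
                    continue
                if i == ind_idx[j]:
                    out[(s, sj)] = sp.Integer(1)
                else:
                    out[(s, sj)] = lij * sp.Symbol(sj) / sp.Symbol(s)
        return out

    def to_json(self) -> str:
        def mat(m: sp.Matrix) -> list[list[str]]:
            return [[str(sp.Rational(m[i, j])) for j in range(m.cols)] for i in range(m.rows)]

        payload = {
            "species": self.species,
            "reactions": self.reactions,
            "N": mat(self.N),
            "N_r": mat(self.N_r),
            "L": mat(self.L),
            "K": mat(self.K),
            "conservation_relations": [
                [str(sp.Rational(c[i])) for i in range(c.cols * c.rows)]
                for c in self.conservation_relations
            ],
            "independent_species": self.independent_species,
            "independent_fluxes": self.independent_fluxes,
        }
        return json.dumps(payload, indent=2)


def stoichiometric_analysis(
    model: KineticModel,
    prefer_independent_fluxes: list[str] | None = None,
) -> StoichiometryInfo:
    """Decompose the model's stoichiometric matrix.

    ``prefer_independent_fluxes`` lists reaction ids whose columns should end
    up in the kernel's identity block when structurally possible (their
    columns are moved to the end of the elimination order).
    """
    species = model.variable_ids
    reactions = model.reaction_ids
    ns, nr = len(species), len(reactions)
    N = sp.zeros(ns, nr)
    for j, r in enumerate(model.reactions):
        for sid, coef in r.stoichiometry.items():
            if sid in species:
                N[species.index(sid), j] = sp.Integer(coef)

    # column order: preferred independent fluxes eliminated last
    prefer = [r for r in (prefer_independent_fluxes or []) if r in reactions]
    order = [j for j in range(nr) if reactions[j] not in prefer] + [
        reactions.index(r) for r in prefer
    ]
    Np = N[:, order]

    # flux kernel (nullspace of N == nullspace of N_r), integer primitive
    _, pivots = Np.rref()
    free_cols = [c for c in range(nr) if c not in pivots]
    basis = Np.nullspace()
    K = sp.zeros(nr, len(basis))
    independent_fluxes = [reactions[order[c]] for c in free_cols]
    for k, vec in enumerate(basis):
        iv = _integerize(vec)
        for p, orig in enumerate(order):
            K[orig, k] = iv[p]

    # independent species: first-come linearly independent rows of N
    _, row_pivots = N.T.rref()
    ind_rows = list(row_pivots)
    dep_rows = [i for i in range(ns) if i not in ind_rows]
    N_r = N[ind_rows, :]

    # link matrix: N = L N_r  (solve row-wise; identity on independent rows)
    L = sp.zeros(ns, len(ind_rows))
    if ind_rows:
        Nr_T = N_r.T
        for i in range(ns):
            if i in ind_rows:
                L[i, ind_rows.index(i)] = sp.Integer(1)
            else:
                sol, _ = Nr_T.gauss_jordan_solve(N[i, :].T)
                for j in range(len(ind_rows)):
                    L[i, j] = sol[j]

    conservation = [
        _integerize(v).T for v in N.T.nullspace()
    ]  # row vectors c with c N = 0

    return StoichiometryInfo(
        species=species,
        reactions=reactions,
        N=N,
        N_r=N_r,
        L=L,
        K=K,
        conservation_relations=conservation,
        independent_species=[species[i] for i in ind_rows],
        independent_fluxes=independent_fluxes,
        dependent_species=[species[i] for i in dep_rows],
    )
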