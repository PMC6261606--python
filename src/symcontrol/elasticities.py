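"""Scaled elasticity coefficients, their structural zeros, and the
partitioning of an elasticity into binding and mass-action components.

The partition writes a rate law as ``v = k * M * Theta`` where ``M`` is the
mass-action core (``prod s^n - prod p^m / Keq``, or ``prod s^n`` for an
irreversible reaction) and ``Theta`` collects binding/regulatory saturation
terms.  Logarithmic differentiation then gives the additive split
``eps = eps_theta + eps_ma``.  For a substrate with stoichiometric
coefficient n the mass-action component has the closed form ``n/(1-rho)``;
for a product with coefficient m it is ``-m*rho/(1-rho)``, with
``rho = Gamma/Keq`` the disequilibrium ratio.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import sympy as sp

from .model_core import KineticModel, ModelError, Reaction, elasticity_symbol
from .steady_state import SteadyState

__all__ = [
    "ElasticityMatrix",
    "ElasticityPartition",
    "symbolic_elasticities",
    "partition_elasticity",
    "classify_regime",
    "disequilibrium_ratio",
    "closed_form_mass_action",
]

# regime thresholds on the disequilibrium ratio
RHO_KINETIC = 0.1
RHO_THERMO = 0.9


class PartitionError(ModelError):
    """Rate law cannot be split into mass-action and binding factors."""


def classify_regime(rho: float) -> str:
    """Classify thermodynamic/kinetic control from the disequilibrium ratio.

    Bands: kinetic_fwd (rho <= 0.1), mixed (0.1 < rho < 0.9),
    near_equilibrium (0.9 <= rho <= 1/0.9), mixed_reverse
    (1/0.9 < rho < 1/0.1) and kinetic_rev (rho >= 1/0.1).
    """
    if rho < 0 or math.isnan(rho):
        raise ValueError(f"disequilibrium ratio must be non-negative, got {rho}")
    if rho <= RHO_KINETIC:
        return "kinetic_fwd"
    if rho < RHO_THERMO:
        return "mixed"
    if rho <= 1.0 / RHO_THERMO:
        return "near_equilibrium"
    if rho < 1.0 / RHO_KINETIC:
        return "mixed_reverse"
    return "kinetic_rev"


@dataclass
class ElasticityMatrix:
    """Symbolic scaled elasticities ``(x/v) dv/dx`` keyed by (reaction, x)."""

    model: KineticModel
    entries: dict[tuple[str, str], sp.Expr]
    structural_zeros: set[tuple[str, str]]
    variables: list[str]

    def expression(self, reaction_id: str, x: str) -> sp.Expr:
        return self.entries.get((reaction_id, x), sp.Integer(0))

    def is_structural_zero(self, reaction_id: str, x: str) -> bool:
        return (reaction_id, x) in self.structural_zeros

    def evaluate(
        self, state: SteadyState, parameter_overrides: dict[str, float] | None = None
    ) -> dict[tuple[str, str], float]:
        keys, fn, argnames = self._compiled()
        values = {str(k): v for k, v in self.model.constant_values().items()}
        if parameter_overrides:
            values.update(parameter_overrides)
        values.update(state.concentrations)
        out = fn(*[values[a] for a in argnames])
        return dict(zip(keys, map(float, out)))

    def _compiled(self):
        if not hasattr(self, "_compiled_cache"):
            keys = list(self.entries)
            syms = sorted(
                {str(s) for e in self.entries.values() for s in e.free_symbols}
            )
            fn = sp.lambdify(
                [sp.Symbol(s) for s in syms],
                [self.entries[k] for k in keys],
                modules="numpy",
            )
            self._compiled_cache = (keys, fn, syms)
        return self._compiled_cache

    def _subs(self, state, parameter_overrides):
        subs = {k: v for k, v in self.model.constant_values().items()}
        if parameter_overrides:
            for k, v in parameter_overrides.items():
                subs[sp.Symbol(k)] = v
        for s, c in state.concentrations.items():
            subs[sp.Symbol(s)] = c
        return subs

    def to_json(self) -> str:
        payload = {
            f"ec_{rid}_{x}": sp.sstr(expr) for (rid, x), expr in self.entries.items()
        }
        payload["_structural_zeros"] = sorted(
            f"ec_{rid}_{x}" for rid, x in self.structural_zeros
        )
        return json.dumps(payload, indent=2, sort_keys=True)

    def symbol_map(self) -> dict[sp.Symbol, sp.Expr]:
        return {
            elasticity_symbol(rid, x): expr for (rid, x), expr in self.entries.items()
        }


def symbolic_elasticities(
    model: KineticModel, extra_variables: list[str] | None = None
) -> ElasticityMatrix:
    """Differentiate every rate law with respect to every variable species
    (plus any requested parameters/effectors).  An entry is a structural
    zero iff the symbol does not appear in the rate law; those entries are
    recorded and later substituted by zero before symbolic inversion."""
    variables = model.variable_ids + list(extra_variables or [])
    entries: dict[tuple[str, str], sp.Expr] = {}
    zeros: set[tuple[str, str]] = set()
    for r in model.reactions:
        free = {str(s) for s in r.rate_law.free_symbols}
        for x in variables:
            if x not in free:
                zeros.add((r.id, x))
                continue
            xs = sp.Symbol(x)
            d = sp.diff(r.rate_law, xs)
            if d.has(sp.Derivative):
                raise ModelError(
                    f"reaction {r.id}: rate law is not differentiable in {x}"
                )
            entries[(r.id, x)] = sp.cancel(xs * d / r.rate_law)
    return ElasticityMatrix(
        model=model, entries=entries, structural_zeros=zeros, variables=variables
    )


@dataclass
class ElasticityPartition:
    reaction: str
    species: str
    total: float
    binding: float
    mass_action: float
    gamma: float
    keq: float
    rho: float
    regime: str

    @property
    def additive_residual(self) -> float:
        return abs(self.total - (self.binding + self.mass_action))


def disequilibrium_ratio(
    model: KineticModel,
    reaction: Reaction | str,
    state: SteadyState,
    parameter_overrides: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Return (Gamma, rho) at a state.  Requires a declared keq parameter."""
    r = model.reaction_by_id(reaction) if isinstance(reaction, str) else reaction
    if r.keq_ref is None:
        raise PartitionError(f"reaction {r.id}: no keq parameter declared")
    subs = model.constant_values()
    if parameter_overrides:
        for k, v in parameter_overrides.items():
            subs[sp.Symbol(k)] = v
    for s, c in state.concentrations.items():
        subs[sp.Symbol(s)] = c
    gamma = float(r.gamma_expression().evalf(subs=subs))
    keq = model.parameters[r.keq_ref]
    if parameter_overrides and r.keq_ref in parameter_overrides:
        keq = parameter_overrides[r.keq_ref]
    return gamma, gamma / keq


def closed_form_mass_action(coefficient: int, rho: float, role: str) -> float:
    """Closed-form mass-action elasticity: substrates n/(1-rho), products
    -m*rho/(1-rho)."""
    if rho == 1.0:
        return math.inf if role == "substrate" else -math.inf
    if role == "substrate":
        return coefficient / (1.0 - rho)
    if role == "product":
        return -coefficient * rho / (1.0 - rho)
    raise ValueError(f"role must be substrate or product, got {role!r}")


def partition_elasticity(
    model: KineticModel,
    reaction_id: str,
    species: str,
    state: SteadyState,
    elasticities: ElasticityMatrix | None = None,
    parameter_overrides: dict[str, float] | None = None,
) -> ElasticityPartition:
    """Split the scaled elasticity of ``reaction_id`` w.r.t. ``species`` into
    binding (Theta) and mass-action components, evaluated at ``state``.

    The mass-action core is taken from the reaction's stoichiometry and
    declared equilibrium-constant parameter; a reversible reaction without
    one cannot be partitioned and raises :class:`PartitionError`.
    """
    r = model.reaction_by_id(reaction_id)
    M = r.mass_action_core()
    if M is None:
        raise PartitionError(
            f"cannot partition reaction {reaction_id}: reversible rate law "
            "without a declared keq parameter"
        )
    if elasticities is None:
        elasticities = symbolic_elasticities(model)
    total_expr = elasticities.expression(reaction_id, species)

    subs = model.constant_values()
    if parameter_overrides:
        for k, v in parameter_overrides.items():
            subs[sp.Symbol(k)] = v
    for s, c in state.concentrations.items():
        subs[sp.Symbol(s)] = c

    xs = sp.Symbol(species)
    if r.reversible:
        gamma, rho = disequilibrium_ratio(model, r, state, parameter_overrides)
        keq = model.parameters[r.keq_ref]
        if parameter_overrides and r.keq_ref in parameter_overrides:
            keq = parameter_overrides[r.keq_ref]
    else:
        gamma, rho, keq = 0.0, 0.0, math.inf

    total = float(total_expr.evalf(subs=subs)) if total_expr != 0 else 0.0
    ma_expr = sp.cancel(xs * sp.diff(M, xs) / M)
    if rho == 1.0:
        # at equilibrium M = 0: the mass-action component diverges
        n = r.substrates.get(species)
        ma = math.inf if n else -math.inf
        binding = float(sp.cancel(xs * sp.diff(r.rate_law / M, xs) / (r.rate_law / M)).evalf(subs=subs))
    else:
        ma = float(ma_expr.evalf(subs=subs)) if ma_expr != 0 else 0.0
        binding = total - ma
    return ElasticityPartition(
        reaction=reaction_id,
        species=species,
        total=total,
        binding=binding,
        mass_action=ma,
        gamma=gamma,
        keq=keq,
        rho=rho,
        regime=classify_regime(rho),
    )
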