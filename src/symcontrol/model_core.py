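"""Kinetic model representation, the plain-text model dialect, and the
moiety-ratio transformation.

The dialect is line oriented and consists of named blocks::

    MODEL <name>
    SPECIES          # variable species:  <id> <initial value>
    FIXED            # fixed species:     <id> <value>
    PARAMETERS       # parameters:        <name> <value>
    REACTIONS        # <id>: <lhs> = <rhs> [! key=value ...]   (reversible)
                     # <id>: <lhs> -> <rhs> [! ...]            (irreversible)
    RATES            # <reaction id>: <sympy expression>
    RATIOS           # <ratio symbol>: <numerator> / <denominator>

``#`` starts a comment.  Stoichiometric coefficients are integers
(``2 Pyr``).  Recognised reaction modifiers are ``keq=<parameter>`` (the
equilibrium-constant parameter used for thermodynamic analysis) and
``core=<name>`` (rate-law family tag used by the elasticity partition
registry).  See ``docs/model-dialect.md`` for the full grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import sympy as sp

__all__ = [
    "Species",
    "Reaction",
    "KineticModel",
    "RatioTransform",
    "ModelError",
    "ParseError",
    "parse_model",
    "serialize_model",
    "apply_ratio_transform",
    "flux_symbol",
    "elasticity_symbol",
]

_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ModelError(ValueError):
    """A structurally invalid model."""


class ParseError(ModelError):
    """Invalid model-dialect text; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def flux_symbol(reaction_id: str) -> sp.Symbol:
    """Canonical steady-state flux symbol for a reaction (``J_3`` for ``v3``)."""
    m = re.fullmatch(r"v(\d+)", reaction_id)
    return sp.Symbol(f"J_{m.group(1) if m else reaction_id}")


def elasticity_symbol(reaction_id: str, variable: str) -> sp.Symbol:
    """Canonical scaled-elasticity symbol (``ec_v3_Pyr`` style)."""
    return sp.Symbol(f"ec_{reaction_id}_{variable}")


@dataclass(frozen=True)
class Species:
    id: str
    role: str  # "variable" | "fixed"
    initial_value: float

    def __post_init__(self):
        if self.role not in ("variable", "fixed"):
            raise ModelError(f"species {self.id}: bad role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction with integer stoichiometry and a symbolic rate law.

    ``stoichiometry`` maps species id -> signed integer coefficient
    (negative for substrates).  Fixed species may appear; they never enter
    the stoichiometric matrix but are used for the mass-action ratio.

    ``ma_core_expr`` and ``gamma_expr`` hold the mass-action core M and the
    mass-action ratio Γ as expressions over concentrations.  They default to
    the forms implied by the stoichiometry and are rewritten by the
    moiety-ratio transform (which changes the stoichiometry mapping but must
    preserve the underlying thermodynamics).
    """

    id: str
    stoichiometry: dict[str, int]
    rate_law: sp.Expr
    reversible: bool = True
    keq_ref: str | None = None
    core: str | None = None
    ma_core_expr: sp.Expr | None = None
    gamma_expr: sp.Expr | None = None

    @property
    def substrates(self) -> dict[str, int]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, int]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    def mass_action_core(self) -> sp.Expr | None:
        """Mass-action core M = prod(s^n) - prod(p^m)/Keq (irreversible: no
        product term).  Returns None when a reversible reaction declares no
        equilibrium constant: such a rate law cannot be partitioned."""
        if self.ma_core_expr is not None:
            return self.ma_core_expr
        fwd = sp.Integer(1)
        for s, n in self.substrates.items():
            fwd *= sp.Symbol(s) ** n
        if not self.reversible:
            return fwd
        if self.keq_ref is None:
            return None
        rev = sp.Integer(1)
        for s, m in self.products.items():
            rev *= sp.Symbol(s) ** m
        return fwd - rev / sp.Symbol(self.keq_ref)

    def gamma_expression(self) -> sp.Expr:
        """Mass-action ratio Γ = prod(p^m) / prod(s^n)."""
        if self.gamma_expr is not None:
            return self.gamma_expr
        expr = sp.Integer(1)
        for s, m in self.products.items():
            expr *= sp.Symbol(s) ** m
        for s, n in self.substrates.items():
            expr /= sp.Symbol(s) ** n
        return expr


@dataclass
class RatioTransform:
    """Replace a conserved pair by its ratio φ = numerator/denominator."""

    numerator_species: str
    denominator_species: str
    ratio_symbol: str
    total: float
    mode: str = "free"  # "free" | "fixed"

    def __post_init__(self):
        if self.mode not in ("free", "fixed"):
            raise ModelError(f"ratio {self.ratio_symbol}: bad mode {self.mode!r}")
        if self.total <= 0:
            raise ModelError(f"ratio {self.ratio_symbol}: total must be > 0")

    @property
    def total_parameter(self) -> str:
        return f"{self.ratio_symbol}_total"

    def substitutions(self) -> dict[sp.Symbol, sp.Expr]:
        phi = sp.Symbol(self.ratio_symbol)
        tot = sp.Symbol(self.total_parameter)
        return {
            sp.Symbol(self.numerator_species): tot * phi / (1 + phi),
            sp.Symbol(self.denominator_species): tot / (1 + phi),
        }


@dataclass
class KineticModel:
    name: str
    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, float]
    ratios: list[RatioTransform] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    @property
    def variable_species(self) -> list[Species]:
        return [s for s in self.species if s.role == "variable"]

    @property
    def fixed_species(self) -> list[Species]:
        return [s for s in self.species if s.role == "fixed"]

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def variable_ids(self) -> list[str]:
        return [s.id for s in self.variable_species]

    def constant_values(self) -> dict[sp.Symbol, float]:
        """Values of all parameters and fixed species."""
        vals = {sp.Symbol(k): v for k, v in self.parameters.items()}
        for s in self.fixed_species:
            vals[sp.Symbol(s.id)] = s.initial_value
        return vals

    def initial_concentrations(self) -> dict[str, float]:
        return {s.id: s.initial_value for s in self.variable_species}

    # -- editing ---------------------------------------------------------
    def with_parameters(self, **updates: float) -> "KineticModel":
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ModelError(f"unknown parameters: {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(updates)
        return replace(self, parameters=params)

    def copy(self) -> "KineticModel":
        return replace(
            self,
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=dict(self.parameters),
            ratios=list(self.ratios),
            annotations=dict(self.annotations),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.reactions:
            raise ModelError("model has no reactions")
        seen: set[str] = set()
        for s in self.species:
            if s.id in seen:
                raise ModelError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        rids: set[str] = set()
        declared = seen | set(self.parameters)
        for r in self.reactions:
            if r.id in rids:
                raise ModelError(f"duplicate reaction id {r.id!r}")
            rids.add(r.id)
            for sid in r.stoichiometry:
                if sid not in seen:
                    raise ModelError(
                        f"reaction {r.id}: undeclared species {sid!r} in stoichiometry"
                    )
            for sym in r.rate_law.free_symbols:
                if str(sym) not in declared:
                    raise ModelError(
                        f"reaction {r.id}: undeclared symbol {sym!r} in rate law"
                    )
            if r.keq_ref is not None and r.keq_ref not in self.parameters:
                raise ModelError(
                    f"reaction {r.id}: keq parameter {r.keq_ref!r} not declared"
                )
            if not r.reversible and r.keq_ref is None:
                pass  # irreversible: mass-action core has no product term
        for ratio in self.ratios:
            for sid in (ratio.numerator_species, ratio.denominator_species):
                if sid not in seen:
                    raise ModelError(
                        f"ratio {ratio.ratio_symbol}: undeclared species {sid!r}"
                    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_BLOCKS = ("SPECIES", "FIXED", "PARAMETERS", "REACTIONS", "RATES", "RATIOS")


def _parse_float(tok: str, lineno: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise ParseError(f"expected a number, got {tok!r}", lineno) from None


def _parse_side(text: str, sign: int, stoich: dict[str, int], lineno: int) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        toks = term.split()
        if len(toks) == 1:
            coef, sid = 1, toks[0]
        elif len(toks) == 2:
            try:
                coef = int(toks[0])
            except ValueError:
                raise ParseError(
                    f"malformed stoichiometry {term.strip()!r} "
                    "(coefficient must be an integer)",
                    lineno,
                )
            sid = toks[1]
        else:
            raise ParseError(f"malformed stoichiometry term {term.strip()!r}", lineno)
        if not _ID_RE.match(sid):
            raise ParseError(f"bad species id {sid!r}", lineno)
        stoich[sid] = stoich.get(sid, 0) + sign * coef


def parse_model(text: str, strict: bool = True) -> KineticModel:
    """Parse model-dialect text into a validated :class:`KineticModel`.

    With ``strict=False`` the structural validation step is skipped (used by
    tooling that assembles partial models); parsing errors always raise.
    """
    name = "model"
    species: list[Species] = []
    parameters: dict[str, float] = {}
    reactions_raw: list[tuple[str, dict[str, int], bool, dict[str, str], int]] = []
    rates_raw: dict[str, tuple[str, int]] = {}
    ratios: list[RatioTransform] = []
    ratio_raw: list[tuple[str, str, str, float | None, int]] = []
    block: str | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("MODEL"):
            toks = line.split()
            if len(toks) != 2:
                raise ParseError("MODEL needs exactly one name", lineno)
            name = toks[1]
            continue
        if line in _BLOCKS:
            block = line
            continue
        if block is None:
            raise ParseError(f"statement outside any block: {line!r}", lineno)

        if block in ("SPECIES", "FIXED", "PARAMETERS"):
            toks = line.split()
            if len(toks) != 2:
                raise ParseError(f"expected '<name> <value>', got {line!r}", lineno)
            ident, value = toks[0], _parse_float(toks[1], lineno)
            if not _ID_RE.match(ident):
                raise ParseError(f"bad identifier {ident!r}", lineno)
            if block == "PARAMETERS":
                if ident in parameters:
                    raise ParseError(f"duplicate parameter {ident!r}", lineno)
                parameters[ident] = value
            else:
                role = "variable" if block == "SPECIES" else "fixed"
                species.append(Species(ident, role, value))
        elif block == "REACTIONS":
            if ":" not in line:
                raise ParseError(f"expected '<id>: <equation>', got {line!r}", lineno)
            rid, eq = (t.strip() for t in line.split(":", 1))
            if not _ID_RE.match(rid):
                raise ParseError(f"bad reaction id {rid!r}", lineno)
            if any(r[0] == rid for r in reactions_raw):
                raise ParseError(f"duplicate reaction id {rid!r}", lineno)
            mods: dict[str, str] = {}
            if "!" in eq:
                eq, modtext = (t.strip() for t in eq.split("!", 1))
                for mod in modtext.split():
                    if "=" not in mod:
                        raise ParseError(f"bad modifier {mod!r}", lineno)
                    k, v = mod.split("=", 1)
                    mods[k] = v
            if "->" in eq:
                lhs, rhs = eq.split("->", 1)
                reversible = False
            elif "=" in eq:
                lhs, rhs = eq.split("=", 1)
                reversible = True
            else:
                raise ParseError(
                    f"reaction {rid}: equation needs '=' or '->'", lineno
                )
            stoich: dict[str, int] = {}
            _parse_side(lhs, -1, stoich, lineno)
            _parse_side(rhs, +1, stoich, lineno)
            stoich = {s: c for s, c in stoich.items() if c != 0}
            reactions_raw.append((rid, stoich, reversible, mods, lineno))
        elif block == "RATES":
            if ":" not in line:
                raise ParseError(f"expected '<id>: <expression>', got {line!r}", lineno)
            rid, expr = (t.strip() for t in line.split(":", 1))
            rates_raw[rid] = (expr, lineno)
        elif block == "RATIOS":
            m = re.fullmatch(
                r"(\w+)\s*:\s*(\w+)\s*/\s*(\w+)(?:\s+total\s*=\s*(\S+))?", line
            )
            if not m:
                raise ParseError(
                    f"expected '<phi>: <num> / <den> [total=<x>]', got {line!r}", lineno
                )
            total = _parse_float(m.group(4), lineno) if m.group(4) else None
            ratio_raw.append((m.group(1), m.group(2), m.group(3), total, lineno))

    allowed = {s.id: sp.Symbol(s.id) for s in species}
    allowed.update({p: sp.Symbol(p) for p in parameters})

    reactions: list[Reaction] = []
    for rid, stoich, reversible, mods, lineno in reactions_raw:
        if rid not in rates_raw:
            raise ParseError(f"reaction {rid} has no rate law", lineno)
        expr_text, rate_line = rates_raw[rid]
        try:
            expr = sp.parse_expr(expr_text, local_dict=dict(allowed), evaluate=True)
        except Exception as exc:  # noqa: BLE001 - sympy raises many types
            raise ParseError(f"reaction {rid}: bad rate expression ({exc})", rate_line)
        undeclared = {str(s) for s in expr.free_symbols} - set(allowed)
        if undeclared:
            raise ParseError(
                f"reaction {rid}: undeclared symbol(s) {sorted(undeclared)}", rate_line
            )
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                rate_law=expr,
                reversible=reversible,
                keq_ref=mods.get("keq"),
                core=mods.get("core"),
            )
        )
    unknown_rates = set(rates_raw) - {r.id for r in reactions}
    if unknown_rates:
        raise ParseError(f"rate law for undeclared reaction(s) {sorted(unknown_rates)}")

    by_id = {s.id: s for s in species}
    for phi, num, den, total, lineno in ratio_raw:
        if num not in by_id or den not in by_id:
            raise ParseError(f"ratio {phi}: undeclared species", lineno)
        if total is None:
            total = by_id[num].initial_value + by_id[den].initial_value
        ratios.append(RatioTransform(num, den, phi, total))

    model = KineticModel(
        name=name,
        species=species,
        reactions=reactions,
        parameters=parameters,
        ratios=ratios,
    )
    if strict:
        model.validate()
    return model


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _format_side(stoich: dict[str, int], sign: int) -> str:
    terms = []
    for sid, coef in stoich.items():
        if (coef < 0) != (sign < 0):
            continue
        c = abs(coef)
        terms.append(sid if c == 1 else f"{c} {sid}")
    return " + ".join(terms)


def _format_value(x: float) -> str:
    return repr(float(x))


def serialize_model(model: KineticModel) -> str:
    """Emit dialect text; ``parse_model(serialize_model(m))`` reproduces ``m``
    field by field (declared ordering is preserved)."""
    out = [f"MODEL {model.name}"]
    if model.variable_species:
        out.append("SPECIES")
        for s in model.variable_species:
            out.append(f"  {s.id} {_format_value(s.initial_value)}")
    if model.fixed_species:
        out.append("FIXED")
        for s in model.fixed_species:
            out.append(f"  {s.id} {_format_value(s.initial_value)}")
    if model.parameters:
        out.append("PARAMETERS")
        for k, v in model.parameters.items():
            out.append(f"  {k} {_format_value(v)}")
    out.append("REACTIONS")
    for r in model.reactions:
        arrow = "=" if r.reversible else "->"
        lhs = _format_side(r.stoichiometry, -1)
        rhs = _format_side(r.stoichiometry, +1)
        mods = []
        if r.keq_ref:
            mods.append(f"keq={r.keq_ref}")
        if r.core:
            mods.append(f"core={r.core}")
        tail = f" ! {' '.join(mods)}" if mods else ""
        out.append(f"  {r.id}: {lhs} {arrow} {rhs}{tail}")
    out.append("RATES")
    for r in model.reactions:
        out.append(f"  {r.id}: {sp.sstr(r.rate_law)}")
    if model.ratios:
        out.append("RATIOS")
        for rt in model.ratios:
            out.append(
                f"  {rt.ratio_symbol}: {rt.numerator_species} / "
                f"{rt.denominator_species} total={_format_value(rt.total)}"
            )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# moiety-ratio transformation
# ---------------------------------------------------------------------------


def apply_ratio_transform(model: KineticModel, transform: RatioTransform) -> KineticModel:
    """Replace a conserved species pair by its ratio φ.

    Both member concentrations are replaced in every rate law by
    ``total*φ/(1+φ)`` and ``total/(1+φ)``.  In ``free`` mode φ becomes a
    variable species whose stoichiometry is that of the numerator member
    (this preserves steady states but not time courses).  In ``fixed`` mode
    φ becomes a parameter.
    """
    from .stoichiometry import stoichiometric_analysis  # local: avoid cycle

    num, den = transform.numerator_species, transform.denominator_species
    sn = model.species_by_id(num)
    sd = model.species_by_id(den)
    if sn.role != "variable" or sd.role != "variable":
        raise ModelError(f"ratio {transform.ratio_symbol}: pair must be variable species")

    info = stoichiometric_analysis(model)
    if not info.is_conserved_pair(num, den):
        raise ModelError(
            f"species pair ({num}, {den}) does not form a conservation relation"
        )

    subs = transform.substitutions()
    phi0 = sn.initial_value / sd.initial_value

    new_species: list[Species] = []
    inserted = False
    for s in model.species:
        if s.id in (num, den):
            if not inserted:
                role = "variable" if transform.mode == "free" else "fixed"
                new_species.append(Species(transform.ratio_symbol, role, phi0))
                inserted = True
            continue
        new_species.append(s)

    new_reactions: list[Reaction] = []
    for r in model.reactions:
        stoich = dict(r.stoichiometry)
        n_num = stoich.pop(num, 0)
        stoich.pop(den, 0)
        if n_num != 0:
            stoich[transform.ratio_symbol] = n_num
        ma = r.mass_action_core()
        gamma = r.gamma_expression()
        new_reactions.append(
            replace(
                r,
                stoichiometry=stoich,
                rate_law=r.rate_law.xreplace(subs),
                ma_core_expr=ma.xreplace(subs) if ma is not None else None,
                gamma_expr=gamma.xreplace(subs),
            )
        )

    params = dict(model.parameters)
    params[transform.total_parameter] = transform.total
    annotations = dict(model.annotations)
    annotations[f"ratio_transform.{transform.ratio_symbol}"] = (
        f"{num}/{den} total={transform.total} mode={transform.mode}"
    )
    new_model = KineticModel(
        name=model.name,
        species=new_species,
        reactions=new_reactions,
        parameters=params,
        ratios=[rt for rt in model.ratios if rt.ratio_symbol != transform.ratio_symbol],
        annotations=annotations,
    )
    new_model.validate()
    return new_model
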