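"""Quantification of control patterns over a scan, selection of dominant
patterns by the two-cut-off grid procedure, factorization of patterns into
backbone and multiplier subpatterns on the pathway graph, and grouping of
dominant patterns by their ranges of dominance."""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import KineticModel, ModelError
from .steady_state import ScanResult
from .symca import (
    ControlCoefficientExpression,
    ControlPattern,
    Monomial,
    _poly_eval,
    symbol_values,
)
from .elasticities import ElasticityMatrix, symbolic_elasticities

__all__ = [
    "PatternContribution",
    "DominanceSelection",
    "SubpatternFactorization",
    "quantify_patterns",
    "select_dominant",
    "factorize_pattern",
    "group_by_dominance",
]


@dataclass
class PatternContribution:
    """Per-scan-row values and absolute-percentage contributions of every
    pattern of one control coefficient.

    The importance metric is the percentage of the absolute pattern value
    relative to the sum of absolute values of all patterns of the
    coefficient (never relative to the coefficient value, whose sign
    structure could push a single pattern above 100%).
    """

    expression: ControlCoefficientExpression
    parameter: str
    parameter_values: np.ndarray
    values: pd.DataFrame  # rows: scan values; columns: pattern ids
    percentages: pd.DataFrame
    coefficient: np.ndarray  # coefficient value per row
    flagged_rows: list[int] = field(default_factory=list)

    @property
    def pattern_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        df = pd.concat(
            [
                self.values.rename(columns=lambda c: f"value.{c}"),
                self.percentages.rename(columns=lambda c: f"pct.{c}"),
            ],
            axis=1,
        )
        df.insert(0, "coefficient", self.coefficient)
        df.to_csv(path)


def quantify_patterns(
    expression: ControlCoefficientExpression,
    scan: ScanResult,
    elasticities: ElasticityMatrix | None = None,
) -> PatternContribution:
    """Evaluate every pattern (term/Sigma) and its absolute percentage at
    every converged scan row."""
    model = scan.model
    if elasticities is None:
        elasticities = symbolic_elasticities(model)
    rows_values: list[dict[str, float]] = []
    coeff: list[float] = []
    flagged: list[int] = []
    for idx, (pval, state) in enumerate(zip(scan.values, scan.states)):
        if not state.converged:
            rows_values.append({p.id: np.nan for p in expression.patterns})
            coeff.append(np.nan)
            flagged.append(idx)
            continue
        sv = symbol_values(
            model, state, elasticities, parameter_overrides={scan.parameter: pval}
        )
        den = _poly_eval(expression.sigma, sv)
        vals = {p.id: p.evaluate(sv) / den for p in expression.patterns}
        rows_values.append(vals)
        coeff.append(sum(vals.values()))
    values = pd.DataFrame(rows_values, index=pd.Index(scan.values, name=scan.parameter))
    abs_sum = values.abs().sum(axis=1)
    zero_rows = np.where(abs_sum.to_numpy() == 0)[0]
    for i in zero_rows:
        flagged.append(int(i))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = values.abs().div(abs_sum, axis=0) * 100.0
    return PatternContribution(
        expression=expression,
        parameter=scan.parameter,
        parameter_values=scan.values,
        values=values,
        percentages=pct,
        coefficient=np.array(coeff),
        flagged_rows=sorted(set(flagged)),
    )


@dataclass
class DominanceSelection:
    cutoff_contribution: int  # percent
    cutoff_span: int  # percent of the log-scale scan range
    selected: list[str]
    coverage: float  # percent of the absolute pattern sum captured
    floor_met: bool
    grid: pd.DataFrame | None = None  # per-pair set size / coverage

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _passes(
    pct: np.ndarray, logx: np.ndarray, cutoff_contribution: float, cutoff_span: float
) -> bool:
    """True when pct exceeds the contribution cut-off over one contiguous
    log-slice at least cutoff_span percent of the full log range wide."""
    span_needed = cutoff_span / 100.0 * (logx[-1] - logx[0])
    above = pct > cutoff_contribution
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if logx[j] - logx[i] >= span_needed:
                return True
            i = j + 1
        else:
            i += 1
    return False


def select_dominant(
    contribs: PatternContribution,
    grid_lo: int = 1,
    grid_hi: int = 15,
    grid_step: int = 1,
    coverage_floor: float = 70.0,
) -> DominanceSelection:
    """Exhaustive grid over (contribution, span) cut-off pairs; returns the
    accepted pair with the smallest selected set (ties: larger coverage,
    then smaller cut-offs)."""
    if len(contribs.parameter_values) < 2:
        raise ModelError("dominance selection needs a scan with at least two rows")
    ok = ~np.isnan(contribs.coefficient)
    pct = contribs.percentages.to_numpy()[ok]
    logx = np.log10(contribs.parameter_values[ok])
    ids = contribs.pattern_ids

    # coverage of a candidate set: percentage of the aggregate absolute
    # pattern sum captured over the whole scan
    absvals = contribs.values.abs().to_numpy()[ok]
    total_abs = absvals.sum()

    records = []
    best = None
    for c1 in range(grid_lo, grid_hi + 1, grid_step):
        for c2 in range(grid_lo, grid_hi + 1, grid_step):
            sel = [
                ids[k]
                for k in range(len(ids))
                if _passes(pct[:, k], logx, float(c1), float(c2))
            ]
            cols = [ids.index(s) for s in sel]
            coverage = 100.0 * absvals[:, cols].sum() / total_abs if total_abs else 0.0
            meets = coverage >= coverage_floor
            records.append(
                {
                    "cutoff_contribution": c1,
                    "cutoff_span": c2,
                    "n_selected": len(sel),
                    "coverage": coverage,
                    "floor_met": meets,
                }
            )
            key = (not meets, len(sel) if meets else 0, -coverage, c1, c2)
            cand = (key, c1, c2, sel, coverage, meets)
            if meets and (best is None or key < best[0]):
                best = cand
    grid = pd.DataFrame.from_records(records)
    if best is None:
        # no pair reaches the floor: report the best-coverage pair, flagged
        i = int(grid["coverage"].idxmax())
        row = grid.loc[i]
        sel = [
            ids[k]
            for k in range(len(ids))
            if _passes(
                pct[:, k], logx, float(row.cutoff_contribution), float(row.cutoff_span)
            )
        ]
        return DominanceSelection(
            int(row.cutoff_contribution),
            int(row.cutoff_span),
            sel,
            float(row.coverage),
            floor_met=False,
            grid=grid,
        )
    _, c1, c2, sel, coverage, _ = best
    return DominanceSelection(c1, c2, sel, coverage, floor_met=True, grid=grid)


# ---------------------------------------------------------------------------
# backbone / multiplier factorization
# ---------------------------------------------------------------------------

_EC_RE = re.compile(r"^ec_(.+?)_([A-Za-z_][A-Za-z0-9_]*)$")


def _split_factors(model: KineticModel, factors: Monomial):
    """Partition a pattern's symbols into elasticity links and flux factors."""
    rids = set(model.reaction_ids)
    eps_links: list[tuple[str, str]] = []  # (reaction, species)
    flux_of: list[str] = []
    for s in factors:
        m = _EC_RE.match(s)
        if m and m.group(1) in rids:
            eps_links.append((m.group(1), m.group(2)))
        elif s.startswith("J_"):
            tail = s[2:]
            rid = tail if tail in rids else f"v{tail}"
            if rid not in rids:
                raise ModelError(f"flux symbol {s!r} does not match any reaction")
            flux_of.append(rid)
        else:
            raise ModelError(f"cannot classify pattern factor {s!r}")
    return eps_links, flux_of


@dataclass(frozen=True)
class Subpattern:
    """A backbone or multiplier factor: integer coefficient times symbols."""

    coefficient: int
    factors: Monomial

    def key(self) -> tuple:
        return (self.coefficient, self.factors)


@dataclass
class SubpatternFactorization:
    """``backbone * prod(multipliers)`` reconstitutes the original term.

    The backbone is the chain of local effects through the controlled flux,
    terminating at fixed (terminal) metabolites; multipliers are the
    remaining factors grouped by the branch subgraph (connected component of
    the pathway graph with backbone reactions and chain species removed)
    they occupy.  Branch labels are ``br<k>`` with k the smallest reaction
    number among the multiplier's factors.  Integer kernel coefficients are
    attributed to the branch whose component produced them (via the
    pattern's kernel-pick provenance); the backbone carries the remaining
    coefficient and the overall sign.
    """

    pattern: ControlPattern
    backbone: Subpattern
    backbone_reactions: tuple[str, ...]
    multipliers: dict[str, Subpattern]

    @property
    def coefficient(self) -> int:
        c = self.backbone.coefficient
        for m in self.multipliers.values():
            c *= m.coefficient
        return c

    def reconstituted(self) -> Monomial:
        out: tuple[str, ...] = tuple(self.backbone.factors)
        for m in self.multipliers.values():
            out = out + tuple(m.factors)
        return tuple(sorted(out))

    def is_exact(self) -> bool:
        return (
            self.reconstituted() == self.pattern.factors
            and self.coefficient == self.pattern.coefficient
        )


def _reaction_number(rid: str) -> tuple[int, str]:
    m = re.search(r"(\d+)$", rid)
    return (int(m.group(1)) if m else 10**9, rid)


def _ratio_species(model: KineticModel) -> set[str]:
    """Species ids introduced by moiety-ratio transforms (conserved-cycle
    ratios are not terminal metabolites even when fixed)."""
    return {
        key.split(".", 1)[1]
        for key in model.annotations
        if key.startswith("ratio_transform.")
    }


def _is_terminal(model: KineticModel, rid: str, variable: set[str]) -> bool:
    """A reaction ends a backbone arm when it touches a terminal (fixed)
    metabolite or is a pure boundary step (single-species stoichiometry).
    Fixed moiety ratios do not count as terminal metabolites."""
    ratios = _ratio_species(model)
    stoich = model.reaction_by_id(rid).stoichiometry
    if any(s not in variable and s not in ratios for s in stoich):
        return True
    return len(stoich) == 1


def factorize_pattern(
    model: KineticModel,
    pattern: ControlPattern,
    reference_flux: str,
    perturbed_reaction: str,
) -> SubpatternFactorization:
    """Factor one control pattern into its backbone and multiplier chains.

    Each elasticity factor ``ec_r_s`` is a link "species s modulates
    reaction r"; a pattern carries at most one elasticity per species, so
    the chain of effects through any species is unambiguous.  The backbone
    is the path of links radiating from the perturbed reaction that passes
    through the controlled flux, each arm truncated at the first
    terminal-touching reaction; of the remaining arms the one reaching the
    lowest-numbered terminal reaction completes the backbone.  All other
    factors are multipliers, grouped by the branch component (connected
    component of the pathway graph with backbone reactions and chain
    species removed) they occupy.
    """
    import networkx as nx

    eps_links, flux_of = _split_factors(model, pattern.factors)
    link_of: dict[str, str] = {}
    for rid, s in eps_links:
        if s in link_of:
            raise ModelError(
                f"pattern {pattern.id}: two elasticity factors through species {s}"
            )
        link_of[s] = rid

    variable = set(model.variable_ids)

    def touched(rid: str) -> set[str]:
        return {s for s in model.reaction_by_id(rid).stoichiometry if s in variable}

    def walk(species: str, visited: frozenset[str]) -> list[tuple[str, str]] | None:
        """Follow links from ``species`` to the first terminal reaction;
        returns the chain of (species, reaction) links, or None.  A pattern
        has at most one elasticity per species, so each step is determined
        up to the choice of continuing species (resolved in sorted order)."""
        rid = link_of.get(species)
        if rid is None or rid in visited:
            return None
        if _is_terminal(model, rid, variable):
            return [(species, rid)]
        for s2 in sorted(touched(rid) - {species}):
            tail = walk(s2, visited | {rid})
            if tail is not None:
                return [(species, rid)] + tail
        return None

    def walk_to(start: str, target: str) -> list[tuple[str, str]] | None:
        """Shortest chain of links from species ``start`` to reaction
        ``target`` (breadth-first over the link graph)."""
        from collections import deque

        queue = deque([(start, (root,), ())])
        seen = {start}
        while queue:
            species, visited, path = queue.popleft()
            rid = link_of.get(species)
            if rid is None or rid in visited:
                continue
            path2 = path + ((species, rid),)
            if rid == target:
                return list(path2)
            for s2 in sorted(touched(rid) - {species}):
                if s2 not in seen:
                    seen.add(s2)
                    queue.append((s2, visited + (rid,), path2))
        return None

    root = perturbed_reaction
    arm_species = sorted(touched(root))

    # arm through the controlled flux: shortest link chain to the reference
    # reaction (over all root species), continued to the first terminal
    ref_arm = None
    ref_arm_species = None
    if root == reference_flux:
        ref_arm, ref_arm_species = [], None
    else:
        candidates_ref = []
        for s in arm_species:
            arm = walk_to(s, reference_flux)
            if arm is not None:
                candidates_ref.append((len(arm), s, arm))
        if candidates_ref:
            _, ref_arm_species, ref_arm = min(candidates_ref)
    if ref_arm is None:
        raise ModelError(
            f"pattern {pattern.id}: effect chain from {perturbed_reaction} does "
            f"not reach the controlled flux {reference_flux}"
        )
    if ref_arm and not _is_terminal(model, ref_arm[-1][1], variable):
        last_rid = ref_arm[-1][1]
        used = frozenset([root] + [r for _, r in ref_arm])
        for s2 in sorted(touched(last_rid) - {ref_arm[-1][0]}):
            tail = walk(s2, used)
            if tail is not None:
                ref_arm = ref_arm + tail
                break

    # the opposite arm: remaining root species, lowest-numbered terminal wins
    other_arm: list[tuple[str, str]] = []
    candidates = []
    for s in arm_species:
        if s == ref_arm_species:
            continue
        arm = walk(s, frozenset([root]))
        if arm is not None:
            candidates.append((arm[-1][1], arm))
    if candidates and not _is_terminal(model, root, variable):
        candidates.sort(key=lambda t: _reaction_number(t[0]))
        other_arm = candidates[0][1]

    backbone_links = list(ref_arm) + list(other_arm)
    backbone_rxns = [root] + [r for _, r in backbone_links]
    backbone_species = {s for s, _ in backbone_links}

    # branch components: pathway graph minus backbone reactions and species
    G = nx.Graph()
    for rid in model.reaction_ids:
        G.add_node(("R", rid))
        for s in touched(rid):
            G.add_edge(("R", rid), ("S", s))
    H = G.copy()
    H.remove_nodes_from(
        [("R", r) for r in backbone_rxns] + [("S", s) for s in backbone_species]
    )
    comp_index: dict[str, int] = {}
    comps: list[set[str]] = []
    for comp in nx.connected_components(H):
        rxns = {n[1] for n in comp if n[0] == "R"}
        if rxns:
            for r in rxns:
                comp_index[r] = len(comps)
            comps.append(rxns)

    backbone_factors: list[str] = []
    mult_by_comp: dict[int, list[str]] = {}

    def place(rid: str, sym: str) -> None:
        if rid in backbone_rxns:
            backbone_factors.append(sym)
        elif rid in comp_index:
            mult_by_comp.setdefault(comp_index[rid], []).append(sym)
        else:
            raise ModelError(
                f"pattern {pattern.id}: factor {sym} (reaction {rid}) is neither "
                "on the backbone nor in any branch component"
            )

    backbone_link_set = {(s, r) for s, r in backbone_links}
    for rid, s in eps_links:
        if rid in backbone_rxns and (s, rid) not in backbone_link_set:
            raise ModelError(
                f"pattern {pattern.id}: elasticity ec_{rid}_{s} targets a "
                "backbone reaction outside the effect chain"
            )
        place(rid, f"ec_{rid}_{s}")
    from .model_core import flux_symbol

    for rid in flux_of:
        place(rid, str(flux_symbol(rid)))

    multipliers: dict[str, Subpattern] = {}
    for ci, syms in mult_by_comp.items():
        rxns = sorted(
            {r for r in comps[ci] if any(_factor_mentions(sym, r) for sym in syms)},
            key=_reaction_number,
        )
        label = f"br{_reaction_number(rxns[0])[0]}" if rxns else f"br?{ci}"
        multipliers[label] = Subpattern(1, tuple(sorted(syms)))

    # the full integer starts on the backbone; allocate_subpattern_coefficients
    # redistributes it consistently across a whole pattern collection
    return SubpatternFactorization(
        pattern=pattern,
        backbone=Subpattern(pattern.coefficient, tuple(sorted(backbone_factors))),
        backbone_reactions=tuple(sorted(set(backbone_rxns), key=_reaction_number)),
        multipliers=dict(sorted(multipliers.items())),
    )


def allocate_subpattern_coefficients(
    factorizations: dict[str, SubpatternFactorization],
) -> dict[str, SubpatternFactorization]:
    """Distribute each pattern's integer coefficient over its subpatterns
    consistently across the whole collection.

    Backbone classes (grouped by factor content) receive the gcd of the
    absolute pattern coefficients over their class; each multiplier content
    class receives the gcd of the per-pattern residuals over its
    occurrences.  Any per-pattern leftover is then assigned to the
    multiplier content shared by the most leftover-carrying patterns, so a
    content class is only split into two coefficient variants when the
    term coefficients force it.  Signs stay on the backbone.
    """
    import math
    from collections import Counter

    facts = dict(factorizations)
    ids = sorted(facts)

    bb_class: dict[Monomial, int] = {}
    for pid in ids:
        f = facts[pid]
        key = f.backbone.factors
        bb_class[key] = math.gcd(bb_class.get(key, 0), abs(f.pattern.coefficient))

    residual = {
        pid: abs(facts[pid].pattern.coefficient)
        // bb_class[facts[pid].backbone.factors]
        for pid in ids
    }

    # base value per multiplier content class: gcd over occurrences
    base: dict[Monomial, int] = {}
    for pid in ids:
        for m in facts[pid].multipliers.values():
            base[m.factors] = math.gcd(base.get(m.factors, 0), residual[pid])
    assigned: dict[str, dict[str, int]] = {}
    leftover: dict[str, int] = {}
    for pid in ids:
        f = facts[pid]
        assigned[pid] = {lb: base[m.factors] or 1 for lb, m in f.multipliers.items()}
        prod = math.prod(assigned[pid].values())
        leftover[pid] = residual[pid] // prod if residual[pid] % prod == 0 else 1

    # leftovers: prefer the content shared by the most leftover patterns
    popularity: Counter = Counter()
    for pid in ids:
        if leftover[pid] > 1:
            for m in facts[pid].multipliers.values():
                popularity[m.factors] += 1
    for pid in ids:
        if leftover[pid] <= 1:
            continue
        f = facts[pid]
        if f.multipliers:
            target = max(
                f.multipliers.items(),
                key=lambda kv: (popularity[kv[1].factors], kv[0]),
            )[0]
            assigned[pid][target] *= leftover[pid]
        # no multipliers: the leftover stays on the backbone

    out: dict[str, SubpatternFactorization] = {}
    for pid in ids:
        f = facts[pid]
        sign = -1 if f.pattern.coefficient < 0 else 1
        mult = {
            lb: Subpattern(assigned[pid][lb], m.factors)
            for lb, m in f.multipliers.items()
        }
        prod = math.prod(m.coefficient for m in mult.values())
        bb = Subpattern(sign * (abs(f.pattern.coefficient) // prod), f.backbone.factors)
        out[pid] = SubpatternFactorization(
            pattern=f.pattern,
            backbone=bb,
            backbone_reactions=f.backbone_reactions,
            multipliers=mult,
        )
    return out


def _factor_mentions(sym: str, rid: str) -> bool:
    m = _EC_RE.match(sym)
    if m:
        return m.group(1) == rid
    if sym.startswith("J_"):
        tail = sym[2:]
        return rid == tail or rid == f"v{tail}"
    return False


def factorization_census(
    factorizations: list[SubpatternFactorization],
) -> dict[str, int]:
    """Distinct backbone and multiplier expressions (coefficient included,
    backbone sign ignored) across a set of factorizations."""
    backbones = {
        (abs(f.backbone.coefficient), f.backbone.factors) for f in factorizations
    }
    mults = {m.key() for f in factorizations for m in f.multipliers.values()}
    return {"backbones": len(backbones), "multipliers": len(mults)}


def factorizations_to_json(factorizations: list[SubpatternFactorization]) -> str:
    return json.dumps(
        [
            {
                "pattern": f.pattern.id,
                "coefficient": f.coefficient,
                "backbone": {
                    "coefficient": f.backbone.coefficient,
                    "factors": list(f.backbone.factors),
                },
                "backbone_reactions": list(f.backbone_reactions),
                "multipliers": [
                    {
                        "label": label,
                        "coefficient": m.coefficient,
                        "factors": list(m.factors),
                    }
                    for label, m in f.multipliers.items()
                ],
            }
            for f in factorizations
        ],
        indent=2,
    )


@dataclass
class DominanceGroup:
    key: tuple
    patterns: list[str]
    dominant_slice: tuple[int, int]  # [start, stop) row indices of the scan
    parameter_range: tuple[float, float]


def group_by_dominance(
    selection: DominanceSelection,
    contribs: PatternContribution,
    factorizations: dict[str, SubpatternFactorization],
    top_branch_reactions: set[str] | None = None,
) -> list[DominanceGroup]:
    """Group selected patterns sharing a backbone and top-branch multiplier;
    each group's dominance range is the longest contiguous run of scan rows
    where its summed percentage is maximal among groups.

    ``top_branch_reactions`` identifies the branch whose multiplier (when
    present) distinguishes groups; by default every multiplier is part of
    the grouping key.
    """
    if not selection.selected:
        raise ModelError("dominance grouping needs a non-empty selection")

    def group_key(f: SubpatternFactorization) -> tuple:
        if top_branch_reactions is None:
            return (
                f.backbone.key(),
                tuple(sorted(m.key() for m in f.multipliers.values())),
            )
        top = tuple(
            sorted(
                m.key()
                for m in f.multipliers.values()
                if any(
                    _factor_mentions(sym, rid)
                    for sym in m.factors
                    for rid in top_branch_reactions
                )
            )
        )
        return (f.backbone.key(), top)

    groups: dict[tuple, list[str]] = {}
    for pid in selection.selected:
        groups.setdefault(group_key(factorizations[pid]), []).append(pid)

    pct = contribs.percentages
    x = contribs.parameter_values
    keys = list(groups)
    summed = np.vstack(
        [pct[groups[k]].sum(axis=1).to_numpy() for k in keys]
    )
    winner = np.nanargmax(summed, axis=0)

    out: list[DominanceGroup] = []
    for gi, key in enumerate(keys):
        runs: list[tuple[int, int]] = []
        i = 0
        n = len(winner)
        while i < n:
            if winner[i] == gi:
                j = i
                while j + 1 < n and winner[j + 1] == gi:
                    j += 1
                runs.append((i, j + 1))
                i = j + 1
            else:
                i += 1
        best = max(runs, key=lambda r: r[1] - r[0], default=(0, 0))
        out.append(
            DominanceGroup(
                key=key,
                patterns=sorted(groups[key]),
                dominant_slice=best,
                parameter_range=(
                    float(x[best[0]]) if best[1] > best[0] else float("nan"),
                    float(x[best[1] - 1]) if best[1] > best[0] else float("nan"),
                ),
            )
        )
    out.sort(key=lambda g: g.dominant_slice[0])
    return out
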