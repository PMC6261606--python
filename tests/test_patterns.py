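import numpy as np
import pandas as pd
import pytest

import symcontrol as sc
from symcontrol.elasticities import symbolic_elasticities
from symcontrol.patterns import (
    PatternContribution,
    allocate_subpattern_coefficients,
    factorization_census,
    factorize_pattern,
    group_by_dominance,
    quantify_patterns,
    select_dominant,
)
from symcontrol.symca import control_coefficient_expression, symbol_values


def _contrib_from_values(values: pd.DataFrame, x: np.ndarray) -> PatternContribution:
    abs_sum = values.abs().sum(axis=1)
    pct = values.abs().div(abs_sum, axis=0) * 100.0
    return PatternContribution(
        expression=None,
        parameter="p",
        parameter_values=x,
        values=values,
        percentages=pct,
        coefficient=values.sum(axis=1).to_numpy(),
    )


def test_percentage_arithmetic():
    x = np.array([1.0, 10.0])
    values = pd.DataFrame({"a": [3.0, 3.0], "b": [-1.0, -1.0]}, index=x)
    c = _contrib_from_values(values, x)
    assert c.percentages["a"].iloc[0] == pytest.approx(75.0)
    assert c.percentages["b"].iloc[0] == pytest.approx(25.0)
    assert c.percentages.sum(axis=1).iloc[0] == pytest.approx(100.0)


def test_single_pattern_is_100_percent(two_step):
    state = sc.find_steady_state(two_step)
    expr = control_coefficient_expression(two_step, flux="v1", reaction="v2", state=state)
    assert expr.n_patterns == 1
    scan = sc.parameter_scan(two_step, "kv1", np.geomspace(0.5, 2.0, 5))
    contribs = quantify_patterns(expr, scan)
    assert np.allclose(contribs.percentages.to_numpy(), 100.0)


def test_percentage_closure(fixture_fixed, fixed_expr, fixed_scan):
    contribs = quantify_patterns(fixed_expr, fixed_scan)
    sums = contribs.percentages.sum(axis=1).to_numpy()
    assert np.max(np.abs(sums - 100.0)) < 1e-9


class TestSelectDominant:
    def test_dominant_singleton(self):
        x = np.geomspace(1e-3, 1.0, 30)
        vals = pd.DataFrame(
            {"big": np.full(30, 9.0), "s1": np.full(30, 0.5), "s2": np.full(30, 0.5)},
            index=x,
        )
        sel = select_dominant(_contrib_from_values(vals, x))
        assert sel.selected == ["big"]
        assert sel.floor_met

    def test_floor_not_met_flagged(self):
        x = np.geomspace(1e-3, 1.0, 40)
        # 200 equal patterns, each 0.5%: below every grid cut-off, so no
        # pattern is ever selected and the coverage floor cannot be met
        vals = pd.DataFrame(
            {f"p{i}": np.full(40, 1.0) for i in range(200)}, index=x
        )
        sel = select_dominant(_contrib_from_values(vals, x))
        assert not sel.floor_met

    def test_span_requirement_excludes_spikes(self):
        x = np.geomspace(1e-3, 1.0, 50)
        spike = np.full(50, 0.01)
        spike[25] = 100.0  # single-row spike: wide span cut-offs exclude it
        base = np.full(50, 10.0)
        vals = pd.DataFrame({"spike": spike, "base": base}, index=x)
        c = _contrib_from_values(vals, x)
        pct = c.percentages["spike"].to_numpy()
        from symcontrol.patterns import _passes

        assert not _passes(pct, np.log10(x), 5.0, 10.0)
        assert _passes(c.percentages["base"].to_numpy(), np.log10(x), 5.0, 10.0)

    def test_fixture_selection_reasonable(self, fixture_fixed, fixed_expr, fixed_scan):
        contribs = quantify_patterns(fixed_expr, fixed_scan)
        sel = select_dominant(contribs)
        assert sel.floor_met
        assert sel.coverage >= 70.0
        assert 1 <= sel.n_selected <= 20
        # the winning pair is minimal: no accepted pair selects fewer
        accepted = sel.grid[sel.grid.floor_met]
        assert sel.n_selected == accepted.n_selected.min()


class TestFactorization:
    def test_fixture_census(self, fixed_factorizations):
        census = factorization_census(list(fixed_factorizations.values()))
        assert census == {"backbones": 6, "multipliers": 13}

    def test_reconstitution(self, fixed_factorizations):
        assert all(f.is_exact() for f in fixed_factorizations.values())

    def test_backbone_passes_through_reference(self, fixed_factorizations):
        for f in fixed_factorizations.values():
            assert "v6" in f.backbone_reactions
            assert "v3" in f.backbone_reactions

    def test_pattern_composition_rule(self, fixed_factorizations):
        # every pattern: one backbone plus one or two multipliers
        for f in fixed_factorizations.values():
            assert 1 <= len(f.multipliers) <= 2

    def test_branched_toy_single_multiplier(self, branched):
        state = sc.find_steady_state(branched)
        expr = control_coefficient_expression(branched, flux="v1", reaction="v1", state=state)
        facts = {
            p.id: factorize_pattern(branched, p, "v1", "v1") for p in expr.patterns
        }
        assert all(f.is_exact() for f in facts.values())
        assert all(len(f.multipliers) <= 1 for f in facts.values())
        with_mult = [f for f in facts.values() if f.multipliers]
        assert with_mult  # branch elasticities do appear as multipliers


class TestGrouping:
    def test_fixture_groups(self, fixture_fixed, fixed_expr, fixed_scan, fixed_factorizations):
        contribs = quantify_patterns(fixed_expr, fixed_scan)
        sel = select_dominant(contribs)
        groups = group_by_dominance(sel, contribs, fixed_factorizations, {"v8"})
        assert len(groups) >= 2
        assert sorted(p for g in groups for p in g.patterns) == sorted(sel.selected)
        # groups ordered by dominance-range position
        starts = [g.dominant_slice[0] for g in groups]
        assert starts == sorted(starts)

    def test_single_pattern_single_group(self):
        x = np.geomspace(1e-2, 1.0, 10)
        vals = pd.DataFrame({"only": np.ones(10)}, index=x)
        c = _contrib_from_values(vals, x)
        sel = select_dominant(c)
        from symcontrol.patterns import Subpattern, SubpatternFactorization
        from symcontrol.symca import ControlPattern

        cp = ControlPattern("only", 1, ("J_1",))
        f = SubpatternFactorization(cp, Subpattern(1, ("J_1",)), ("v1",), {})
        groups = group_by_dominance(sel, c, {"only": f})
        assert len(groups) == 1
        assert groups[0].dominant_slice == (0, 10)

    def test_synthetic_two_group_crossover(self):
        # two patterns dominant on disjoint halves by construction
        x = np.geomspace(1e-3, 1.0, 40)
        a = np.where(np.arange(40) < 20, 10.0, 0.1)
        b = np.where(np.arange(40) < 20, 0.1, 10.0)
        vals = pd.DataFrame({"a": a, "b": b}, index=x)
        c = _contrib_from_values(vals, x)
        sel = select_dominant(c)
        assert set(sel.selected) == {"a", "b"}
        from symcontrol.patterns import Subpattern, SubpatternFactorization
        from symcontrol.symca import ControlPattern

        facts = {
            pid: SubpatternFactorization(
                ControlPattern(pid, 1, (f"J_{i}",)),
                Subpattern(1, (f"J_{i}",)),
                (f"v{i}",),
                {},
            )
            for i, pid in enumerate(["a", "b"], start=1)
        }
        groups = group_by_dominance(sel, c, facts)
        assert len(groups) == 2
        assert groups[0].dominant_slice == (0, 20)
        assert groups[1].dominant_slice == (20, 40)


def test_keq_robustness(fixture_fixed, fixed_expr, fixed_scan):
    """Multiplying Keq11 by 1000 leaves the coefficient profile within 1e-2
    relative while individual subpattern contributions shift."""
    elas = symbolic_elasticities(fixture_fixed)
    contribs_ref = quantify_patterns(fixed_expr, fixed_scan, elas)

    pert = fixture_fixed.with_parameters(Keq11=fixture_fixed.parameters["Keq11"] * 1000)
    state_p = sc.find_steady_state(pert)
    expr_p = control_coefficient_expression(pert, flux="v6", reaction="v3", state=state_p)
    scan_p = sc.parameter_scan(pert, "phiN", fixed_scan.values)
    contribs_p = quantify_patterns(expr_p, scan_p)

    a, b = contribs_ref.coefficient, contribs_p.coefficient
    denom = np.maximum(np.abs(a), 1e-12)
    assert np.nanmax(np.abs(b - a) / denom) < 1e-2
    shifts = [
        np.nanmax(
            np.abs(contribs_p.values[pid] - contribs_ref.values[pid])
            / np.maximum(np.abs(contribs_ref.values[pid]), 1e-12)
        )
        for pid in contribs_ref.values.columns
    ]
    assert max(shifts) > 0.05  # compensation: parts move, the whole does not
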