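import numpy as np
import pytest
import sympy as sp

import symcontrol as sc
from symcontrol.elasticities import symbolic_elasticities
from symcontrol.model_core import elasticity_symbol, flux_symbol
from symcontrol.stoichiometry import stoichiometric_analysis
from symcontrol.symca import (
    build_control_matrix_equation,
    control_coefficient_expression,
    fd_control_coefficient,
    numeric_control_coefficients,
    symbol_values,
    symbolic_invert,
    verify_theorems,
)


class TestTwoStep:
    @pytest.fixture()
    def expr_pair(self, two_step):
        state = sc.find_steady_state(two_step)
        elas = symbolic_elasticities(two_step)
        E = build_control_matrix_equation(
            two_step, elas, prefer_independent_fluxes=["v1"]
        )
        vals = symbol_values(two_step, state, elas)
        out = symbolic_invert(
            E, [("J:v1", "v1"), ("J:v1", "v2")], reference_values=vals
        )
        return out, state

    def test_e_matrix_shape(self, two_step):
        E = build_control_matrix_equation(two_step)
        assert E.dimension == 2
        assert E.n_modes == 1

    def test_closed_forms(self, expr_pair):
        out, _ = expr_pair
        e1 = elasticity_symbol("v1", "X")
        e2 = elasticity_symbol("v2", "X")
        J1, J2 = flux_symbol("v1"), flux_symbol("v2")
        c1 = out[("J:v1", "v1")].expression().subs({J2: J1})
        c2 = out[("J:v1", "v2")].expression().subs({J2: J1})
        assert sp.simplify(c1 - e2 / (e2 - e1)) == 0
        assert sp.simplify(c2 - (-e1) / (e2 - e1)) == 0

    def test_symmetric_elasticities_give_half(self, expr_pair):
        out, _ = expr_pair
        vals = {
            str(flux_symbol("v1")): 1.0,
            str(flux_symbol("v2")): 1.0,
            str(elasticity_symbol("v1", "X")): -1.0,
            str(elasticity_symbol("v2", "X")): 1.0,
        }
        assert out[("J:v1", "v1")].evaluate(vals) == pytest.approx(0.5)
        assert out[("J:v1", "v2")].evaluate(vals) == pytest.approx(0.5)

    def test_theorems_symbolically(self, expr_pair):
        out, _ = expr_pair
        e1 = elasticity_symbol("v1", "X")
        e2 = elasticity_symbol("v2", "X")
        J1, J2 = flux_symbol("v1"), flux_symbol("v2")
        total = (
            out[("J:v1", "v1")].expression() + out[("J:v1", "v2")].expression()
        ).subs({J2: J1})
        conn = (
            out[("J:v1", "v1")].expression() * e1
            + out[("J:v1", "v2")].expression() * e2
        ).subs({J2: J1})
        assert sp.simplify(total - 1) == 0
        assert sp.simplify(conn) == 0


def _toy_models():
    yield sc.generate(sc.GeneratorSpec(topology="two_step", seed=1))
    yield sc.generate(sc.GeneratorSpec(topology="linear_chain", n=3, seed=2))
    yield sc.generate(sc.GeneratorSpec(topology="branched_fig1", seed=3))


@pytest.mark.parametrize("model", list(_toy_models()), ids=lambda m: m.name)
def test_oracle_equivalence(model):
    """Symbolic expressions equal numeric inversion and finite differences."""
    state = sc.find_steady_state(model)
    assert state.converged
    elas = symbolic_elasticities(model)
    C_J, _ = numeric_control_coefficients(model, state, elas)
    flux = model.reaction_ids[0]
    for rxn in model.reaction_ids:
        expr = control_coefficient_expression(model, flux=flux, reaction=rxn, state=state)
        symbolic = expr.evaluate(symbol_values(model, state, elas))
        assert symbolic == pytest.approx(C_J.loc[flux, rxn], rel=1e-6, abs=1e-9)
        fd = fd_control_coefficient(model, flux, rxn, state)
        assert symbolic == pytest.approx(fd, rel=1e-4, abs=1e-6)


def test_oracle_equivalence_many_states():
    """20 seeded parameterizations of the branched toy match the numeric
    matrix-inversion oracle."""
    for seed in range(20):
        model = sc.generate(sc.GeneratorSpec(topology="branched_fig1", seed=seed))
        state = sc.find_steady_state(model)
        if not state.converged:
            continue
        elas = symbolic_elasticities(model)
        C_J, _ = numeric_control_coefficients(model, state, elas)
        expr = control_coefficient_expression(model, flux="v1", reaction="v1", state=state)
        val = expr.evaluate(symbol_values(model, state, elas))
        assert val == pytest.approx(C_J.loc["v1", "v1"], rel=1e-6, abs=1e-9)


def test_fixture_summation(fixture_fixed, fixed_state):
    C_J, _ = numeric_control_coefficients(fixture_fixed, fixed_state)
    sums = C_J.sum(axis=1)
    assert np.max(np.abs(sums - 1.0)) < 1e-9


def test_fixture_theorem_report(fixture_fixed, fixed_state):
    report = verify_theorems(fixture_fixed, fixed_state)
    assert report.ok
    assert report.max_summation_residual < 1e-8
    assert report.max_connectivity_residual < 1e-8
    assert report.flagged() == []


def test_summation_holds_when_ratio_fixed(fixture_fixed, fixed_scan):
    # fixing the conserved ratio changes coefficients but not their sum
    for idx in (0, len(fixed_scan.values) // 2, -1):
        st = fixed_scan.states[idx]
        C_J, _ = numeric_control_coefficients(fixture_fixed, st)
        assert np.max(np.abs(C_J.sum(axis=1) - 1.0)) < 1e-8


def test_fixture_symbolic_value_matches_oracles(fixture_fixed, fixed_state, fixed_expr):
    vals = symbol_values(fixture_fixed, fixed_state)
    symbolic = fixed_expr.evaluate(vals)
    C_J, _ = numeric_control_coefficients(fixture_fixed, fixed_state)
    assert symbolic == pytest.approx(C_J.loc["v6", "v3"], rel=1e-6)
    fd = fd_control_coefficient(fixture_fixed, "v6", "v3", fixed_state)
    assert symbolic == pytest.approx(fd, rel=1e-4)


def test_pattern_sum_identity(fixture_fixed, fixed_expr, fixed_scan):
    elas = symbolic_elasticities(fixture_fixed)
    for val, st in list(zip(fixed_scan.values, fixed_scan.states))[::6]:
        sv = symbol_values(fixture_fixed, st, elas, {"phiN": float(val)})
        total = sum(p.evaluate(sv) for p in fixed_expr.patterns)
        from symcontrol.symca import _poly_eval

        coeff = total / _poly_eval(fixed_expr.sigma, sv)
        assert coeff == pytest.approx(
            sum(fixed_expr.pattern_values(sv).values()), rel=1e-12
        )
        C_J, _ = numeric_control_coefficients(
            fixture_fixed, st, parameter_overrides={"phiN": float(val)}
        )
        assert coeff == pytest.approx(C_J.loc["v6", "v3"], rel=1e-9, abs=1e-12)


def test_cancellation_soundness(fixture_fixed, fixed_state):
    """Multiplying the cancelled factor back reproduces the raw adjugate."""
    elas = symbolic_elasticities(fixture_fixed)
    E = build_control_matrix_equation(
        fixture_fixed, elas, prefer_independent_fluxes=["v6"]
    )
    vals = symbol_values(fixture_fixed, fixed_state, elas)
    cooked = symbolic_invert(E, [("J:v6", "v3")], reference_values=vals)[("J:v6", "v3")]
    raw = symbolic_invert(
        E, [("J:v6", "v3")], reference_values=vals, cancel_common=False
    )[("J:v6", "v3")]
    g = sp.Mul(*[sp.Symbol(s) for s in cooked.cancelled]) * cooked.cancelled_coefficient
    restored = sp.expand(cooked.numerator_expression() * g)
    assert sp.expand(restored - raw.numerator_expression()) == 0
    restored_sigma = sp.expand(cooked.sigma_expression() * g)
    assert sp.expand(restored_sigma - raw.sigma_expression()) == 0


def test_structurally_singular_raises():
    # two reactions, no species dependencies at all -> E singular
    from symcontrol.model_core import parse_model
    from symcontrol.symca import build_control_matrix_equation, symbolic_invert
    from symcontrol.model_core import ModelError

    m = parse_model(
        "MODEL s\nSPECIES\n  X 1.0\nFIXED\n  S 1.0\nPARAMETERS\n  k 1.0\n"
        "REACTIONS\n  v1: S -> X\n  v2: X ->\nRATES\n  v1: k*S\n  v2: k*S\n"
    )
    E = build_control_matrix_equation(m)
    with pytest.raises(ModelError, match="singular"):
        symbolic_invert(E, [("J:" + E.stoich.independent_fluxes[0], "v1")])


def test_dependent_flux_requires_preference(fixture_fixed, fixed_state):
    from symcontrol.model_core import ModelError

    elas = symbolic_elasticities(fixture_fixed)
    E = build_control_matrix_equation(fixture_fixed, elas)
    if "v6" not in E.stoich.independent_fluxes:
        with pytest.raises(ModelError, match="identity block"):
            symbolic_invert(E, [("J:v6", "v3")])


def test_kernel_basis_independence(fixture_fixed, fixed_state):
    """The expanded pattern system is canonical: a different admissible
    kernel ordering yields identical coefficient/monomial pairs."""
    elas = symbolic_elasticities(fixture_fixed)
    vals = symbol_values(fixture_fixed, fixed_state, elas)
    systems = []
    for prefer in (["v6"], ["v6", "v2", "v9"]):
        E = build_control_matrix_equation(
            fixture_fixed, elas, prefer_independent_fluxes=prefer
        )
        expr = symbolic_invert(E, [("J:v6", "v3")], reference_values=vals)[("J:v6", "v3")]
        systems.append(sorted((p.coefficient, p.factors) for p in expr.patterns))
    assert systems[0] == systems[1]
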