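import math

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import symcontrol as sc
from symcontrol.model_core import (
    ModelError,
    ParseError,
    RatioTransform,
    apply_ratio_transform,
    parse_model,
    serialize_model,
)

TWO_STEP_TEXT = """
MODEL eq1
SPECIES
  X 1.0
FIXED
  S 2.0
  P 0.5
PARAMETERS
  k1 1.0
  k2 1.0
  Keq1 10.0
  Keq2 10.0
REACTIONS
  v1: S = X ! keq=Keq1
  v2: X = P ! keq=Keq2
RATES
  v1: k1*(S - X/Keq1)
  v2: k2*(X - P/Keq2)
"""


def test_parse_two_step():
    m = parse_model(TWO_STEP_TEXT)
    assert len(m.reactions) == 2
    assert [s.id for s in m.variable_species] == ["X"]
    assert {s.id for s in m.fixed_species} == {"S", "P"}
    assert m.reaction_by_id("v1").reversible
    assert m.reaction_by_id("v1").keq_ref == "Keq1"


def test_empty_reaction_block_errors():
    text = "MODEL m\nSPECIES\n  X 1.0\nREACTIONS\nRATES\n"
    with pytest.raises(ModelError, match="no reactions"):
        parse_model(text)


def test_undeclared_symbol_named_in_error():
    bad = TWO_STEP_TEXT.replace("k2*(X - P/Keq2)", "k2*(X - P/Keq2) + mystery")
    with pytest.raises(ParseError, match="mystery"):
        parse_model(bad)


def test_duplicate_reaction_id_errors():
    bad = TWO_STEP_TEXT.replace("v2: X = P", "v1: X = P")
    with pytest.raises(ModelError, match="duplicate|no rate law"):
        parse_model(bad)


def test_malformed_stoichiometry_reports_line():
    bad = TWO_STEP_TEXT.replace("v1: S = X ! keq=Keq1", "v1: 1.5 S = X")
    with pytest.raises(ParseError, match=r"line \d+"):
        parse_model(bad)


def test_missing_rate_law_errors():
    bad = TWO_STEP_TEXT.replace("  v2: k2*(X - P/Keq2)\n", "")
    with pytest.raises(ParseError, match="v2"):
        parse_model(bad)


def test_fixture_structure(fixture_raw):
    assert len(fixture_raw.reactions) == 14
    v8 = fixture_raw.reaction_by_id("v8")
    assert v8.stoichiometry == {"Pyr": -2, "Aclac": 1}
    v1 = fixture_raw.reaction_by_id("v1")
    assert v1.stoichiometry["Pyr"] == 2
    assert v1.stoichiometry["ATP"] == 2
    assert v1.stoichiometry["NADH"] == 2
    assert fixture_raw.parameters["Keq11"] == pytest.approx(1.4e3)


def test_roundtrip_fixture(fixture_raw):
    text = serialize_model(fixture_raw)
    again = parse_model(text)
    assert serialize_model(again) == text
    assert [r.id for r in again.reactions] == [r.id for r in fixture_raw.reactions]
    for a, b in zip(again.reactions, fixture_raw.reactions):
        assert a.stoichiometry == b.stoichiometry
        assert sp.simplify(a.rate_law - b.rate_law) == 0


@settings(max_examples=15, deadline=None)
@given(
    topology=st.sampled_from(
        ["two_step", "linear_chain", "branched_fig1", "cofactor_cycle"]
    ),
    seed=st.integers(0, 1000),
)
def test_roundtrip_generated(topology, seed):
    m = sc.generate(sc.GeneratorSpec(topology=topology, seed=seed))
    text = serialize_model(m)
    assert serialize_model(parse_model(text)) == text


class TestRatioTransform:
    def test_symmetric_substitution(self):
        t = RatioTransform("A", "B", "phi", total=2.0)
        subs = t.substitutions()
        phi = sp.Symbol("phi")
        tot = sp.Symbol("phi_total")
        vals = {phi: 1.0, tot: 2.0}
        assert float(subs[sp.Symbol("A")].subs(vals)) == pytest.approx(1.0)
        assert float(subs[sp.Symbol("B")].subs(vals)) == pytest.approx(1.0)

    def test_conservation_invariant(self):
        t = RatioTransform("A", "B", "phi", total=3.5)
        subs = t.substitutions()
        total = sp.simplify(subs[sp.Symbol("A")] + subs[sp.Symbol("B")])
        assert total == sp.Symbol("phi_total")

    def test_total_must_be_positive(self):
        with pytest.raises(ModelError):
            RatioTransform("A", "B", "phi", total=0.0)

    def test_non_conserved_pair_errors(self, two_step):
        # X and the fixed S do not form a conservation relation
        spec = sc.GeneratorSpec(topology="linear_chain", n=3, seed=1)
        m = sc.generate(spec)
        with pytest.raises(ModelError, match="conservation"):
            apply_ratio_transform(m, RatioTransform("s1", "s2", "phi", total=2.0))

    def test_fixed_mode_isolates_demand(self, fixture_raw):
        from tests.conftest import transformed_fixture

        fixed = transformed_fixture("fixed")
        v13 = fixed.reaction_by_id("v13")
        variables = set(fixed.variable_ids)
        assert not ({str(s) for s in v13.rate_law.free_symbols} & variables)

    def test_free_mode_preserves_steady_state_fluxes(self, cofactor):
        rt = cofactor.ratios[0]
        free = apply_ratio_transform(cofactor, rt)
        st_raw = sc.find_steady_state(cofactor)
        st_free = sc.find_steady_state(free)
        assert st_raw.converged and st_free.converged
        for rid in cofactor.reaction_ids:
            assert st_free.fluxes[rid] == pytest.approx(
                st_raw.fluxes[rid], rel=1e-6, abs=1e-10
            )

    def test_fixed_vs_free_fluxes_at_matched_ratio(self, cofactor):
        import dataclasses

        rt = cofactor.ratios[0]
        free = apply_ratio_transform(cofactor, rt)
        st_free = sc.find_steady_state(free)
        phi_ss = st_free.concentrations["phi"]
        fixed = apply_ratio_transform(
            cofactor, dataclasses.replace(rt, mode="fixed")
        )
        st_fixed = sc.find_steady_state(
            fixed, parameter_overrides={"phi": phi_ss}
        )
        for rid in cofactor.reaction_ids:
            assert st_fixed.fluxes[rid] == pytest.approx(
                st_free.fluxes[rid], rel=1e-6, abs=1e-10
            )
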