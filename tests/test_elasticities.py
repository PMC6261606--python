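import math

import numpy as np
import pytest
import sympy as sp

import symcontrol as sc
from symcontrol.elasticities import (
    PartitionError,
    classify_regime,
    closed_form_mass_action,
    disequilibrium_ratio,
    partition_elasticity,
    symbolic_elasticities,
)
from symcontrol.model_core import parse_model
from symcontrol.steady_state import SteadyState, find_steady_state


def test_first_order_mass_action_elasticity_is_one():
    m = parse_model(
        "MODEL m\nSPECIES\n  X 1.0\nFIXED\n  S 1.0\nPARAMETERS\n  k 2.0\n"
        "REACTIONS\n  v1: S -> X\n  v2: X ->\nRATES\n  v1: k*S\n  v2: k*X\n"
    )
    elas = symbolic_elasticities(m)
    assert sp.simplify(elas.expression("v2", "X") - 1) == 0


def test_irreversible_product_is_structural_zero(fixture_fixed):
    elas = symbolic_elasticities(fixture_fixed)
    # v10 (irreversible efflux) has no product; v3 is irreversible and its
    # product side (phiC) enters only through binding terms -- the defining
    # structural zeros are entries whose species is absent from the law
    assert elas.is_structural_zero("v10", "Aclac")
    assert elas.is_structural_zero("v13", "Acet")
    assert not elas.is_structural_zero("v10", "Acet")


def test_reversible_mm_matches_finite_difference():
    m = sc.generate(sc.GeneratorSpec(topology="two_step", rate_law="rev_mm", seed=21))
    elas = symbolic_elasticities(m)
    r = m.reaction_by_id("v1")
    x0 = 0.7
    st = SteadyState({"X": x0}, {}, 0.0, True)
    val = elas.evaluate(st)[("v1", "X")]
    consts = m.constant_values()
    f = sp.lambdify(sp.Symbol("X"), r.rate_law.subs(consts))
    h = 1e-6
    fd = (math.log(abs(f(x0 * (1 + h)))) - math.log(abs(f(x0 * (1 - h))))) / (
        math.log(1 + h) - math.log(1 - h)
    )
    assert val == pytest.approx(fd, abs=1e-6)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            (0.05, "kinetic_fwd"),
            (0.1, "kinetic_fwd"),
            (0.5, "mixed"),
            (0.9, "near_equilibrium"),
            (1.0, "near_equilibrium"),
            (1.05, "near_equilibrium"),  # 1.05 <= 1/0.9
            (2.0, "mixed_reverse"),
            (10.0, "kinetic_rev"),
            (100.0, "kinetic_rev"),
        ],
    )
    def test_bands(self, rho, expected):
        assert classify_regime(rho) == expected

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            classify_regime(-0.1)


class TestPartition:
    def test_irreversible_far_from_saturation(self, fixture_fixed, fixed_scan):
        # acetoin efflux at high phiN: substrate far below Km
        idx = len(fixed_scan.values) - 1
        st = fixed_scan.states[idx]
        part = partition_elasticity(
            fixture_fixed, "v10", "Acet", st,
            parameter_overrides={"phiN": float(fixed_scan.values[idx])},
        )
        assert part.mass_action == pytest.approx(1.0)
        assert part.binding == pytest.approx(0.0, abs=0.01)
        assert part.total == pytest.approx(1.0, abs=0.01)
        assert part.regime == "kinetic_fwd"

    def test_saturating_substrate_low_phiN(self, fixture_fixed, fixed_scan):
        # acetoin saturates reaction 11 at the lowest phiN: binding term -1,
        # mass-action term 1, total ~ 0
        st = fixed_scan.states[0]
        part = partition_elasticity(
            fixture_fixed, "v11", "Acet", st,
            parameter_overrides={"phiN": float(fixed_scan.values[0])},
        )
        assert part.binding == pytest.approx(-1.0, abs=0.05)
        assert part.mass_action == pytest.approx(1.0 / (1.0 - part.rho), rel=1e-9)
        assert part.rho < 0.1

    def test_additivity_across_scan(self, fixture_fixed, fixed_scan):
        elas = symbolic_elasticities(fixture_fixed)
        for val, st in list(zip(fixed_scan.values, fixed_scan.states))[::7]:
            ov = {"phiN": float(val)}
            for rid, sid in [
                ("v11", "Acet"), ("v2", "Pyr"), ("v8", "Aclac"),
                ("v5", "Acp"), ("v6", "phiC"),
            ]:
                p = partition_elasticity(
                    fixture_fixed, rid, sid, st, elas, parameter_overrides=ov
                )
                assert p.additive_residual <= 1e-9 * abs(p.total) + 1e-12

    def test_closed_forms_match_symbolic(self):
        # reversible uni-uni at 50 seeded random states
        rng = np.random.default_rng(42)
        m = sc.generate(sc.GeneratorSpec(topology="two_step", rate_law="rev_mm", seed=8))
        elas = symbolic_elasticities(m)
        for _ in range(50):
            x = float(rng.uniform(0.05, 5.0))
            st = SteadyState({"X": x}, {}, 0.0, True)
            for rid, species, role, coef in [
                ("v1", "X", "product", 1),
                ("v2", "X", "substrate", 1),
            ]:
                part = partition_elasticity(m, rid, species, st, elas)
                expected = closed_form_mass_action(coef, part.rho, role)
                assert part.mass_action == pytest.approx(expected, rel=1e-9)

    def test_mass_action_diverges_at_equilibrium(self):
        m = sc.generate(sc.GeneratorSpec(topology="two_step", rate_law="rev_mm", seed=8))
        S = m.species_by_id("S").initial_value
        keq = m.parameters["Keqv1"]
        st = SteadyState({"X": S * keq}, {}, 0.0, True)  # Gamma == Keq
        part = partition_elasticity(m, "v1", "X", st)
        assert part.rho == pytest.approx(1.0)
        assert math.isinf(part.mass_action)
        assert part.regime == "near_equilibrium"

    def test_near_equilibrium_blowup_from_below(self):
        # substrate elasticity of v2 (X -> P) diverges to +inf as rho -> 1-
        m = sc.generate(sc.GeneratorSpec(topology="two_step", rate_law="rev_mm", seed=8))
        P = m.species_by_id("P").initial_value
        keq = m.parameters["Keqv2"]
        vals = []
        for eps in (1e-2, 1e-4, 1e-6):
            st = SteadyState({"X": P / keq * (1 + eps)}, {}, 0.0, True)
            vals.append(partition_elasticity(m, "v2", "X", st).mass_action)
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 1e5

    def test_unfactorable_rate_law_errors(self):
        m = parse_model(
            "MODEL m\nSPECIES\n  X 1.0\nFIXED\n  S 1.0\nPARAMETERS\n  k 1.0\n"
            "REACTIONS\n  v1: S = X\n  v2: X ->\nRATES\n  v1: k*(S - X/5)\n  v2: k*X\n"
        )
        st = find_steady_state(m)
        with pytest.raises(PartitionError, match="partition"):
            partition_elasticity(m, "v1", "X", st)


def test_irreversible_substrate_elasticity_bounded():
    # substrate elasticity of an irreversible MM law lies in [0, n]
    rng = np.random.default_rng(0)
    m = sc.generate(sc.GeneratorSpec(topology="linear_chain", n=2, rate_law="irrev_mm", seed=13))
    elas = symbolic_elasticities(m)
    for _ in range(25):
        st = SteadyState({"s1": float(rng.uniform(1e-3, 1e3))}, {}, 0.0, True)
        val = elas.evaluate(st)[("v2", "s1")]
        assert 0.0 <= val <= 1.0


def test_rho_tracks_scan_parameter(fixture_fixed, fixed_scan):
    # J11 reverses exactly where rho11 crosses 1
    rhos, j11 = [], []
    for val, st in zip(fixed_scan.values, fixed_scan.states):
        _, rho = disequilibrium_ratio(fixture_fixed, "v11", st, {"phiN": float(val)})
        rhos.append(rho)
        j11.append(st.fluxes["v11"])
    sign_flux = np.sign(j11)
    sign_thermo = np.sign(1 - np.array(rhos))
    assert (sign_flux == sign_thermo).all()
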