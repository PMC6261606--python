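import dataclasses

import pytest

import symcontrol as sc
from symcontrol.model_core import apply_ratio_transform


def transformed_fixture(mode_phiN: str) -> sc.KineticModel:
    """Pyruvate-branch fixture with all three ratio transforms applied."""
    model = sc.load_fixture()
    for name in ("phiA", "phiC"):
        rts = {r.ratio_symbol: r for r in model.ratios}
        model = apply_ratio_transform(model, rts[name])
    rts = {r.ratio_symbol: r for r in model.ratios}
    return apply_ratio_transform(
        model, dataclasses.replace(rts["phiN"], mode=mode_phiN)
    )


@pytest.fixture(scope="session")
def fixture_raw():
    return sc.load_fixture()


@pytest.fixture(scope="session")
def fixture_fixed():
    return transformed_fixture("fixed")


@pytest.fixture(scope="session")
def fixture_free():
    return transformed_fixture("free")


@pytest.fixture(scope="session")
def fixed_state(fixture_fixed):
    state = sc.find_steady_state(fixture_fixed)
    assert state.converged
    return state


@pytest.fixture(scope="session")
def fixed_expr(fixture_fixed, fixed_state):
    return sc.control_coefficient_expression(
        fixture_fixed, flux="v6", reaction="v3", state=fixed_state
    )


@pytest.fixture(scope="session")
def fixed_scan(fixture_fixed):
    grid = sc.log_grid(2e-4, 1.77, 60)
    return sc.parameter_scan(fixture_fixed, "phiN", grid)


@pytest.fixture(scope="session")
def fixed_factorizations(fixture_fixed, fixed_expr):
    from symcontrol.patterns import allocate_subpattern_coefficients, factorize_pattern

    return allocate_subpattern_coefficients(
        {
            p.id: factorize_pattern(fixture_fixed, p, "v6", "v3")
            for p in fixed_expr.patterns
        }
    )


@pytest.fixture(scope="session")
def two_step():
    return sc.generate(sc.GeneratorSpec(topology="two_step", seed=3))


@pytest.fixture(scope="session")
def branched():
    return sc.generate(sc.GeneratorSpec(topology="branched_fig1", seed=11))


@pytest.fixture(scope="session")
def cofactor():
    return sc.generate(sc.GeneratorSpec(topology="cofactor_cycle", seed=5))
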