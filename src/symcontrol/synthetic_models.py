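"""Generators for toy kinetic models with known control properties, and the
transcribed pyruvate-branch fixture loader.

Topologies:

* ``two_step`` — S = X = P with fixed ends; the flux-control coefficients
  have the closed forms e2/(e2-e1) and -e1/(e2-e1).
* ``linear_chain(n)`` — a reversible chain with n reactions and n-1
  internal species.
* ``branched_fig1`` — six reactions: a four-step backbone with three
  internal species and two single-reaction branches draining the middle
  species; every flux-control pattern of the first reaction factors into
  one backbone and one multiplier.
* ``cofactor_cycle`` — a two-species conserved pair (A/B) coupling a
  producing reaction to a recycling demand step; exercises conservation
  detection and the moiety-ratio transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import KineticModel, ModelError, parse_model

__all__ = ["GeneratorSpec", "generate", "generate_text", "load_fixture"]

_TOPOLOGIES = ("two_step", "linear_chain", "branched_fig1", "cofactor_cycle")


@dataclass
class GeneratorSpec:
    topology: str
    n: int = 3  # chain length for linear_chain
    rate_law: str = "mass_action"  # mass_action | rev_mm | irrev_mm
    seed: int = 0
    k_range: tuple[float, float] = (0.2, 5.0)
    keq_range: tuple[float, float] = (2.0, 50.0)
    km_range: tuple[float, float] = (0.1, 10.0)

    def __post_init__(self):
        if self.topology not in _TOPOLOGIES:
            raise ModelError(f"unknown topology {self.topology!r}")
        if self.topology == "linear_chain" and self.n < 2:
            raise ModelError("linear_chain needs n >= 2")


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


class _Builder:
    def __init__(self) -> None:
        self.species: list[str] = []
        self.fixed: list[str] = []
        self.params: list[str] = []
        self.reactions: list[str] = []
        self.rates: list[str] = []
        self.ratios: list[str] = []

    def text(self, name: str) -> str:
        out = [f"MODEL {name}"]
        for block, lines in (
            ("SPECIES", self.species),
            ("FIXED", self.fixed),
            ("PARAMETERS", self.params),
            ("REACTIONS", self.reactions),
            ("RATES", self.rates),
            ("RATIOS", self.ratios),
        ):
            if lines:
                out.append(block)
                out.extend(f"  {l}" for l in lines)
        return "\n".join(out) + "\n"


def _rate(kind: str, rid: str, sub: str, prod: str, b: _Builder, rng) -> None:
    """Emit parameters and a rate law for a uni-uni step sub -> prod."""
    if kind == "mass_action":
        k = _loguniform(rng, 0.2, 5.0)
        keq = _loguniform(rng, 2.0, 50.0)
        b.params += [f"k{rid} {k!r}", f"Keq{rid} {keq!r}"]
        b.rates.append(f"{rid}: k{rid}*({sub} - {prod}/Keq{rid})")
    elif kind == "rev_mm":
        v = _loguniform(rng, 1.0, 20.0)
        keq = _loguniform(rng, 2.0, 50.0)
        ks = _loguniform(rng, 0.1, 10.0)
        kp = _loguniform(rng, 0.1, 10.0)
        b.params += [
            f"V{rid} {v!r}",
            f"Keq{rid} {keq!r}",
            f"Ks{rid} {ks!r}",
            f"Kp{rid} {kp!r}",
        ]
        b.rates.append(
            f"{rid}: V{rid}/Ks{rid}*({sub} - {prod}/Keq{rid})"
            f"/(1 + {sub}/Ks{rid} + {prod}/Kp{rid})"
        )
    elif kind == "irrev_mm":
        v = _loguniform(rng, 1.0, 20.0)
        ks = _loguniform(rng, 0.1, 10.0)
        b.params += [f"V{rid} {v!r}", f"Ks{rid} {ks!r}"]
        b.rates.append(f"{rid}: V{rid}*{sub}/(Ks{rid} + {sub})")
    else:
        raise ModelError(f"unknown rate-law kind {kind!r}")


def generate_text(spec: GeneratorSpec) -> str:
    """Deterministic model text for a spec; identical (spec, seed) gives
    byte-identical output."""
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    kind = spec.rate_law

    if spec.topology == "two_step":
        b.fixed += ["S 2.0", "P 0.5"]
        b.species.append("X 1.0")
        b.reactions += ["v1: S = X", "v2: X = P"]
        keq_mod = " ! keq=Keqv1", " ! keq=Keqv2"
        _rate(kind if kind != "irrev_mm" else "mass_action", "v1", "S", "X", b, rng)
        _rate(kind if kind != "irrev_mm" else "mass_action", "v2", "X", "P", b, rng)
        b.reactions = [r + m for r, m in zip(b.reactions, keq_mod)]
        return b.text("two_step")

    if spec.topology == "linear_chain":
        n = spec.n
        b.fixed += ["X0 2.0", f"X{n} 0.2"]
        names = ["X0"] + [f"s{i}" for i in range(1, n)] + [f"X{n}"]
        for i in range(1, n):
            b.species.append(f"s{i} {1.0!r}")
        for i in range(n):
            rid = f"v{i + 1}"
            irrev = kind == "irrev_mm"
            arrow = "->" if irrev else "="
            tail = "" if irrev else f" ! keq=Keq{rid}"
            b.reactions.append(f"{rid}: {names[i]} {arrow} {names[i + 1]}{tail}")
            _rate(kind, rid, names[i], names[i + 1], b, rng)
        return b.text(f"linear_chain_{n}")

    if spec.topology == "branched_fig1":
        b.fixed += ["X0 5.0", "X1 0.1", "X2 0.1", "X3 0.1"]
        b.species += ["s1 1.0", "s2 1.0", "s3 1.0"]
        chain = [("v1", "X0", "s1"), ("v2", "s1", "s2"), ("v3", "s2", "s3"),
                 ("v4", "s3", "X1"), ("v5", "s2", "X2"), ("v6", "s2", "X3")]
        for rid, s, p in chain:
            b.reactions.append(f"{rid}: {s} = {p} ! keq=Keq{rid}")
            _rate("mass_action" if kind == "irrev_mm" else kind, rid, s, p, b, rng)
        return b.text("branched_fig1")

    if spec.topology == "cofactor_cycle":
        b.fixed += ["S 5.0", "P 0.1"]
        b.species += ["X 1.0", "A 1.0", "B 1.0"]
        b.reactions += [
            "v1: S + A = X + B ! keq=Keqv1",
            "v2: X = P ! keq=Keqv2",
            "v3: B = A ! keq=Keqv3",
        ]
        k1 = _loguniform(rng, 0.2, 5.0)
        k2 = _loguniform(rng, 0.2, 5.0)
        k3 = _loguniform(rng, 0.2, 5.0)
        b.params += [
            f"k1 {k1!r}", f"k2 {k2!r}", f"k3 {k3!r}",
            "Keqv1 20.0", "Keqv2 10.0", "Keqv3 8.0",
        ]
        b.rates += [
            "v1: k1*(S*A - X*B/Keqv1)",
            "v2: k2*(X - P/Keqv2)",
            "v3: k3*(B - A/Keqv3)",
        ]
        b.ratios.append("phi: A / B")
        return b.text("cofactor_cycle")

    raise ModelError(f"unknown topology {spec.topology!r}")  # pragma: no cover


def generate(spec: GeneratorSpec) -> KineticModel:
    return parse_model(generate_text(spec))


def load_fixture(name: str = "pyruvate_branch") -> KineticModel:
    """Load a transcribed model that ships with the package.

    The pyruvate-branch fixture is a transcription of the *L. lactis*
    pyruvate-metabolism model (14 reactions; conserved ATP/ADP,
    acetyl-CoA/CoA and NADH/NAD+ pairs declared in its RATIOS block).
    """
    from importlib import resources

    res = resources.files("symcontrol.data").joinpath(f"{name}.model")
    if not res.is_file():
        raise ModelError(
            f"fixture {name!r} not found; transcribe the model description "
            "files from the original model distribution into "
            f"src/symcontrol/data/{name}.model"
        )
    return parse_model(res.read_text())
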