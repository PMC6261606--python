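# Model dialect

Plain-text, line-oriented kinetic model description. `#` starts a comment
anywhere on a line; blank lines are ignored. A file consists of a `MODEL`
header followed by named blocks.

```
MODEL two_step
SPECIES                # variable species: id and initial concentration
  X 1.0
FIXED                  # fixed (clamped) species, treated as parameters
  S 2.0
  P 0.5
PARAMETERS
  k1 1.0
  Keq1 20.0
REACTIONS
  v1: S = X ! keq=Keq1 core=mass_action
  v2: X -> P
RATES
  v1: k1*(S - X/Keq1)
  v2: k2*X
RATIOS                 # conserved pairs representable as a ratio variable
  phi: A / B total=2.0
```

## Blocks

* **SPECIES / FIXED / PARAMETERS** — `name value` pairs, one per line.
  Identifiers match `[A-Za-z_][A-Za-z0-9_]*` and must be unique across
  species and parameters.
* **REACTIONS** — `id: lhs = rhs` (reversible) or `id: lhs -> rhs`
  (irreversible). Sides are `+`-separated terms `coefficient species` with
  integer coefficients (omitted coefficient = 1). A side may be empty
  (boundary step). Optional trailing modifiers after `!`:
  * `keq=<parameter>` — the equilibrium-constant parameter used by the
    thermodynamic analysis (mass-action ratio, disequilibrium ratio,
    elasticity partition). Never inferred from Haldane relationships.
  * `core=<name>` — rate-law family tag (`mass_action`, `irrev_mm`,
    `rev_mm`, `rev_hill`, ...); informational, used by tooling and tests.
* **RATES** — `id: expression`. Expressions are parsed by sympy; every
  symbol must be a declared species or parameter. Every reaction needs a
  rate law.
* **RATIOS** — `phi: numerator / denominator [total=<x>]` declares that the
  two species form a moiety-conserved pair that may be replaced by the
  ratio variable `phi` (`apply_ratio_transform`). When `total` is omitted
  it defaults to the sum of the two initial values.

## Errors

Undeclared symbols, duplicate identifiers, malformed stoichiometry and
missing rate laws raise `ParseError` carrying the 1-based line number.

## Round trip

`parse_model(serialize_model(m))` reproduces the model field by field;
the serializer emits blocks in a fixed order and entries in declared order.
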