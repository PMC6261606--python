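# symcontrol

Symbolic metabolic control analysis as a reusable pipeline: from a
plain-text kinetic model to symbolic control-coefficient expressions, their
decomposition into control patterns and backbone/multiplier subpatterns,
quantification of pattern importance over steady-state parameter scans, and
partitioning of elasticity coefficients into binding and mass-action
components with thermodynamic classification.

The package ships a transcription of the *L. lactis* pyruvate-branch model
(14 reactions, three moiety-conserved cofactor pairs) as its principal
fixture, plus generators for toy models with known control properties, so
every stage is testable offline. See `docs/model-dialect.md` for the model
format and `docs/fixture-provenance.md` for fixture provenance.

## What it does

* **model_core** — parse/serialize the model dialect; moiety-ratio
  transformation (replace a conserved pair by its ratio φ, in `free` or
  `fixed` mode).
* **stoichiometry** — exact rational N, reduced N_r, link matrix L, flux
  kernel K and conservation relations.
* **steady_state** — hybrid integrate-then-Newton steady states,
  continuation parameter scans.
* **elasticities** — symbolic scaled elasticities with structural zeros;
  partition ε = ε^Θ (binding) + ε^ma (mass action); disequilibrium-ratio
  regime classification.
* **symca** — the control matrix equation C·E = I; sparse exact symbolic
  inversion producing the common denominator Σ and one control pattern per
  numerator monomial; numeric matrix-inversion and finite-difference
  oracles; summation/connectivity theorem checks.
* **patterns** — absolute-percentage pattern importance over a scan;
  two-cut-off dominant-pattern grid selection; backbone/multiplier
  factorization on the pathway graph; dominance grouping.
* **pipeline** — full-analysis runs from a YAML config, the
  equilibrium-constant perturbation experiment, and the fixed- vs
  free-ratio comparison (driving the free ratio through the demand
  reaction's Vmax).

## CLI

```bash
symcontrol info --model fixture:pyruvate_branch
symcontrol generate --topology branched_fig1 --seed 1 --out toy.model
symcontrol scan --model toy.model --param Vv1 --from 0.1 --to 10 --points 50
symcontrol symca --model fixture:pyruvate_branch --fix phiN --coefficient J6:v3 --out out/
symcontrol run --config config.yaml --out runs/analysis
symcontrol perturb --param Keq11 --factor 1000
symcontrol compare-fixed-free --driver V13 --isolated v13
```

`symcontrol run` writes, per run directory: the resolved config, scan CSV,
per-pattern values/percentages CSV, selection grid CSV, the control
coefficient expression JSON, subpattern factorizations JSON, theorem-check
report and a summary JSON.

## Library example

```python
import symcontrol as sc

model = sc.load_fixture()                       # raw model, ratios declared
for rt in list(model.ratios):
    rt.mode = "fixed" if rt.ratio_symbol == "phiN" else "free"
    model = sc.apply_ratio_transform(model, rt)

state = sc.find_steady_state(model)
expr = sc.control_coefficient_expression(model, flux="v6", reaction="v3", state=state)
print(expr.n_patterns)                          # 76

scan = sc.parameter_scan(model, "phiN", sc.log_grid(2e-4, 1.77, 200))
contribs = sc.quantify_patterns(expr, scan)
selection = sc.select_dominant(contribs)
```
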