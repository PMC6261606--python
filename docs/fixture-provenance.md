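# Pyruvate-branch fixture: provenance and calibration

`src/symcontrol/data/pyruvate_branch.model` is a transcription of the
*Lactococcus lactis* pyruvate-branch kinetic model (Hoefnagel et al.),
originally distributed through the JWS Online model database and as
model-description files accompanying later analyses of it.

## What is exact

The network **structure** is transcribed directly from the published
pathway scheme and analysis:

* 14 reactions with the published numbering; 1-to-1 stoichiometry except
  glycolysis (`Glc + 2 ADP + 2 NAD -> 2 Pyr + 2 ATP + 2 NADH`) and
  acetolactate synthase (`2 Pyr = Aclac`).
* Three moiety-conserved pairs (ATP/ADP, acetyl-CoA/CoA, NADH/NAD+)
  declared as ratio candidates.
* Rate-law families per reaction: reversible Hill for acetolactate
  synthase (with cooperative product binding, h = 2.4), irreversible
  Michaelis–Menten for acetoin efflux and the lumped glycolysis step,
  reversible Michaelis–Menten forms elsewhere, mass action for the
  non-enzymatic acetolactate decarboxylation.
* The rate-law dependency structure (which species appear in which rate
  law) was validated symbolically: the fixed-ratio variant yields exactly
  76 control patterns for the flux-control coefficient of reaction 3 on
  J6, matching the published count.
* `Keq11 = 1.4e3` as published.

## What is calibrated

The numeric kinetic parameters of the original model files could not be
retrieved in this offline build.
The values in the fixture are a best-effort reconstruction: orders of
magnitude follow the published model family where remembered, and the
remaining freedom was calibrated **only against qualitative facts of the published analysis**
(flux reversals, regime boundaries, saturation behaviour), never against
the dominance-selection outcomes:

* the model converges over the whole stated scan range (phi_N from 2e-4 to
  1.77) in both the fixed- and free-ratio variants;
* the free-ratio variant's realized phi_N, driven by the NADH-oxidase
  Vmax, spans that same interval (ceiling ≈ 1.8 at vanishing oxidase
  activity);
* J6 reverses direction exactly once across the scan, together with the
  sign change of the control coefficient;
* J11 reverses where the disequilibrium ratio of reaction 11 crosses 1,
  with acetoin saturating reaction 11 at low phi_N (binding elasticity
  -1 rising to 0) and reaction 10 far from saturation at high phi_N;
* flux shifts from the acetoin branch toward lactate as phi_N rises, and
  J1 falls through NADH product inhibition.

Quantities that depend on the numeric parameter values (dominant-pattern
selection cut-offs and set sizes) are therefore reproduced only
approximately; structural quantities (pattern counts, subpattern census)
are exact. Checksum of the shipped fixture:

```
sha256  badd90c1e78fbbd0ccc77fc8e186346c86fac723232c74bd01948410bdea665a
```
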