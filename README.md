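# combonull

Null models for two-drug combination effects: **Loewe**, **Tallarida**
(both orderings and their lower/upper envelope), **Hand**, **Bliss** and
**HSA**, built on four-parameter Hill dose-effect curves — with isobole
extraction, synergy classification of checkerboard assays, cross-model
comparison and a synthetic-screen generator with known ground truth.

It is written for people who analyse combination drug screens (oncology,
anaesthesiology, immunology) and for methodologists comparing non-interaction
references: synergy and antagonism are only meaningful *relative to a null
model*, and the models disagree systematically.

## The models

Monotherapies are Hill curves

```
f_A(a) = E_min + (E_max,A − E_min) / (1 + (EC50,A / a)^n_A)
```

with inverse `f_A⁻¹(x) = EC50,A · ((x − E_min)/(E_max,A − x))^(1/n_A)`.
Given `f_A`, `f_B`, each null model predicts a reference surface `E(a, b)`
with `E(a, 0) = f_A(a)`, `E(0, b) = f_B(b)`:

| model | definition | sham | commutes | partial agents |
|---|---|---|---|---|
| Loewe | unique `x` solving `a/f_A⁻¹(x) + b/f_B⁻¹(x) = 1` (straight isoboles) | yes | yes | only below `b = f_B⁻¹(E_max,A)` |
| Tallarida A→B | `f_B(b + f_B⁻¹(f_A(a)))` (sequential dose equivalence) | yes | no | yes |
| Hand | combined curve solves `f'_AB(f_AB⁻¹(x)) = λ s_A(x) + (1−λ) s_B(x)`, `λ = a/(a+b)` | yes | yes | yes |
| Bliss | `f_A + f_B − f_A·f_B` (normalised effects) | no | yes | yes |
| HSA | `max(f_A, f_B)` | no | yes | yes |

Here `s_A(x) = f'_A(f_A⁻¹(x))` is the *effect-sensitivity curve* — the slope
of the dose-effect curve expressed as a function of the effect level.  The
Hand model averages sensitivities with the mixture weights, i.e. both agents
contribute linearly to the instantaneous gain in effect; it is the N → ∞
limit of alternately applying N-th portions of each dose through the
Tallarida construction, which resolves that model's order ambiguity.  Hand
isoboles are convex, so wherever both are defined the references obey

```
HSA ≤ Loewe ≤ Hand,   HSA ≤ Bliss,   Tallarida_LB ≤ Tallarida_UB.
```

## Worked example

```python
import pandas as pd
from combonull import CurvePair, HillCurve, NullModelSurface, classify

pair = CurvePair(HillCurve(0, 1, 1.0, 1.0), HillCurve(0, 1, 2.0, 2.5))
a, b = 0.6, 1.2
for name in ("hsa", "tallarida_lb", "loewe", "bliss", "hand", "tallarida_ub"):
    print(f"{name:13s} reference = {NullModelSurface(name, pair).effect(a, b):.4f}")

board = pd.DataFrame({"dose_a": [a], "dose_b": [b], "effect": [0.62]})
surfaces = [NullModelSurface(m, pair) for m in ("hsa", "loewe", "hand")]
print(classify(board, surfaces, delta=0.01)[["model", "reference", "verdict"]])
```

prints

```
hsa           reference = 0.3750
tallarida_lb  reference = 0.4678
loewe         reference = 0.5659
bliss         reference = 0.5113
hand          reference = 0.6309
tallarida_ub  reference = 0.7044
model  reference      verdict
  hsa   0.375000  synergistic
loewe   0.565857  synergistic
 hand   0.630893 antagonistic
```

The same measured effect (0.62) is *synergistic* against HSA and Loewe but
*antagonistic* against the more conservative Hand reference — the choice of
null model decides the verdict.

Estimator-style access (scikit-learn conventions) is available too:
`HillCurveRegressor` fits a titration, `NullModelReference(model="hand")`
fits the two monotherapy curves from the axis rows of a combination design
and predicts reference effects, and `SynergyClassifier` emits per-point
verdicts.  A CLI mirrors the library: `combonull reference`,
`combonull synergize`, `combonull simulate`.

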