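# Methods

## Scope and model conventions

All dose-effect curves are assumed strictly increasing with the baseline
`e_min` describing the untreated condition, hence shared between the two
drugs of a pair (enforced to relative 1e-9 by `CurvePair`).  Decreasing
readouts (viability) are handled by the documented pre-transformation
`effect -> top − effect` (`to_increasing`), not natively.  The drug with the
strictly lower maximal effect is the *partial agent*; maximal effects are
considered equal within relative 1e-9 of the effect span, which is the
switch between the equal-range and full/partial code paths.

Hill evaluation at dose 0 returns `e_min` by the limit convention (the
closed form is indeterminate there).  The inverse is the algebraic inverse
of the Hill form, `EC50·((x−e_min)/(e_max−x))^(1/n)`; it raises a
structured error distinguishing the two boundaries because the
`above_max` case is what triggers partial-agent logic downstream.  The
effect-sensitivity curve

```
s(x) = n/(EC50·(e_max−e_min)) · (x−e_min)^(1−1/n) · (e_max−x)^(1+1/n)
```

is zero-extended outside `[e_min, e_max]` and never raises, so the Hand
integrands below are total functions.  At `x = e_min` it is 0 for n > 1,
`n·Δ/EC50`-finite for n = 1 and +inf for n < 1 (the one-sided limit).

## Loewe evaluation and its domain

The Loewe reference is the root of the strictly decreasing function
`g(x) = a/f_A⁻¹(x) + b/f_B⁻¹(x) − 1` on `(e_min, min(e_max))`, found by
Brent with an effect tolerance of `1e-10·range` inside a bracket inset by
`1e-12·range`.  Definedness is decided *exactly*, from the limit of `g` as
`x` approaches `min(e_max)`: a curve that attains the limit level only
asymptotically contributes 0 there, a curve whose maximum lies strictly
above contributes its finite term.  Consequently a full/partial pair is
defined precisely on the strip `b < f_B⁻¹(E_max,A)` (with A partial), and a
dose pair whose root lies within the bracket inset of the limit level
returns the inset value rather than raising.  Undefined regions raise
`LoeweUndefinedError` carrying the limiting level — they are scientific
content (the model genuinely assigns nothing there), never silent NaNs;
the `loewe_hsa` surface fills them with the HSA value, which is continuous
across the horizontal limit isobole.

## Hand engine

The combined curve of the fixed-ratio mixture `C_λ` is defined by the ODE
`f'_AB(f_AB⁻¹(x)) = λ s_A(x) + (1−λ) s_B(x)` with `f_AB(0) = e_min`-level
initial condition.  The forward ODE is degenerate at the baseline whenever
both Hill coefficients exceed 1 (the right-hand side vanishes at the
initial condition), so the primary route is the equivalent integral for the
inverse curve,

```
f_AB⁻¹(x) = ∫ dy / (λ s_A(y) + (1−λ) s_B(y))    from e_min to x,
```

whose integrand has integrable power-law singularities at the baseline and
(for equal maxima) at the attainable supremum.

Numerics (`CombinedCurve`):

* **Node ladders.** The effect axis is covered by geometric
  (factor-of-two) node ladders clustered toward both endpoints, one
  16-point Gauss–Legendre panel per segment.  On a factor-two segment a
  power-law integrand is analytic well inside the Bernstein ellipse, so
  per-panel error is at rounding level.
* **Baseline sliver.** Below the deepest node the integrand is extrapolated
  as a single power law fitted from two nodes and integrated in closed
  form.  Because the integrand is really a *mixture* of power laws (one
  exponent per curve) whose composition drifts all the way to the baseline,
  this extrapolation is only asymptotically exact; the ladder therefore
  runs deep (default depth 110, sliver width ~`range·2⁻¹¹¹`) so the
  sliver's absolute contribution — and with it the extrapolation error —
  is far below the 1e-6 tolerances used in the ordering tests (measured
  ~1e-11 against tight adaptive quadrature).  Ladder nodes that are not
  representable above a non-zero baseline are dropped; with a non-zero
  `e_min` the attainable sliver depth is limited by float spacing and
  worst-case accuracy degrades to ~1e-7.
* **Supremum side.** For equal maximal effects the ladder toward the
  asymptotic supremum is extended on demand (doses grow without bound as
  the effect approaches it; extension stops at float resolution and
  returns the supremum-adjacent value).  For a full/partial pair the
  integral ends at the partial maximum `E_max,A`, a regular endpoint
  handled by the same sliver machinery.
* **Evaluation.** `f_AB(c)` is recovered by Brent inversion within the
  bracketing table segment (tolerance `1e-13·range`), not by interpolation;
  `f_AB⁻¹(x)` adds a single panel from the nearest node.  Both are exact on
  the axes (`λ ∈ {0, 1}` delegates to the single curve).
* **Partial-agent tail.** Beyond `c*(λ) = f_AB⁻¹(E_max,A)` the combined
  curve is driven by the full agent alone and uses the closed form
  `f_B(f_B⁻¹(E_max,A) + (1−λ)(c − c*))`.  The limit isobole is
  `(a*, b*) = (λ c*, (1−λ) c*)`; `b*` is continuous, strictly decreasing
  and vanishes as `λ → 1` (`c*` is flagged infinite for the pure partial
  agent).
* The engine is written against a minimal curve protocol rather than Hill
  curves, so combined curves can themselves be pair members; that is how
  the associative property (mixtures of mixtures) is exercised numerically.
  The forward-ODE route is retained as an independent cross-check in the
  tests (integration from a small offset).

`tallarida_iterated` implements the N-piece alternating dose-equivalence
scheme that links the Tallarida and Hand models: `N = 1` reproduces the
directional Tallarida value bit-for-bit, and the error against the Hand
value decays like 1/N.  When a curve is saturated at the current level the
step is taken with zero gain, mirroring the sensitivity zero-extension, so
the scheme is total for partial agents.  The monotone-decay property is a
statement about the regime where both curves share the attainable effect
range (where the first-order limit argument applies); under the capping
convention on full/partial pairs the signed error can cross zero at small
N, so the convergence suite asserts monotone decay on full-range instances
and plain convergence on partial ones.

## Isoboles, classification, comparison

Isoboles are traced by ray angle `λ = a/(a+b)` (every surface here is
increasing along rays): per ray, the dose solving `E(λc, (1−λ)c) = x` is
found by bracketed root search, or taken directly from the combined-curve
inverse for the Hand surface, where the ray cut *is* the combined curve.
Rays on which the level is unreachable, or the model undefined, yield
truncated polylines with explicit flags.  The convexity diagnostic uses
increments of successive chord slopes of `b` as a function of `a`
(non-negative for a convex polyline), compared against `−tol·scale` with
`scale = max(1, max |slope|)`, piecewise over contiguous valid runs.

Synergy calls compare the replicate-averaged measured effect against each
reference within an additive band of half-width δ (default 0.01 effect
units; δ = 0 gives the strict synergistic/antagonistic dichotomy).
Undefined references yield the verdict `undefined`, never a silent drop;
the Loewe surface can optionally be HSA-extended first, and both modes are
exposed because either is defensible for screen-wide comparisons.
Cross-model comparison reports signed pairwise differences
(mean/quantiles/fraction positive) and Spearman rank correlations —
rank-based because the relations between references are monotone but
nonlinear.

Bliss is only evaluated on the normalised scale (`e_min = 0`, larger
`e_max = 1`); by default an unnormalised pair is an error, and the `auto`
mode rescales internally and maps back, because silent rescaling changes
verdicts.

## Fitting and model selection

`HillCurveRegressor` minimises squared error with EC50 and n on the log
scale (positivity) from 10 Latin-hypercube starts (seeded; deterministic
under `random_state`), start boxes informed by the data span and dose
range.  Requires ≥ 4 distinct doses; optimizer non-convergence is surfaced
as `converged_ = False`, not silent.  The Gaussian noise model is an
assumption of this package.  BIC-based selection against the flat
`ZeroEffectRegressor` counts the noise variance for both models
(k = 4+1 vs 1+1), lower BIC wins, ties break toward the flat model.
`NullModelReference` / `SynergyClassifier` fit the two monotherapies
independently from the axis rows of a combination design and then impose
the shared-baseline assumption by replacing both fitted `e_min` values
with their record-weighted average.

Parameter-recovery accuracy is quantified with errors relative to the true
value for EC50 and n, and relative to the true effect *range* for `e_min`
and `e_max` (a baseline of exactly 0 has no meaningful relative error).

## Synthetic screens

`generate_checkerboard` emulates the design of large combination screens:
4×4 log-spaced combination doses anchored at each drug's EC50
(`EC50·2^{−2..1}`), 7-dose monotherapy titrations (`EC50·2^{−3..3}`),
3 replicates, additive Gaussian noise with sd 0.02 on the normalised
effect scale, and a ground-truth null model with an optional interaction:
multiplicative `κ` on the reference measured about the baseline (clipped
to the attainable range) or an additive offset.  `κ = 1` means the
expected measurement equals the reference, so classification under the
generating model is a closed-loop test.  The seed fixes the output
bitwise.  Cells where the generating model is undefined are emitted
flagged with NaN effects, not fabricated.

What the generator does **not** emulate: plate/edge effects, heteroscedastic
or correlated noise, dose-dependent error, row/column normalisation
artefacts, or off-target non-monotone responses.  Passing tests therefore
certify the mathematics and the pipeline, not robustness to real-screen
noise structure.

## Problem sizes and known limitations

The property suites run at desk scale: 500 random pairs × 8×8 grids for
the ordering chain, 200 instances × N up to 4096 for the convergence
study, 100 pairs × 5 levels × 50 rays for isobole convexity, 100 seeded
replicates for fit recovery — a few minutes in total.

Limitations: two drugs only; Hill (or protocol-compatible) monotone
curves; no statistical significance testing of synergy calls or
combination indices; convexity/associativity are verified numerically,
not proven; very aggressive Hill coefficients (n ≫ 6) push the fit
start boxes and the quadrature exponents outside their tuned range.
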