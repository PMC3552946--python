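# Methods

## Model

`forestpi` implements the normal–normal random-effects (RE) hierarchy

    θᵢ ~ N(θ, τ²),      yᵢ | θᵢ ~ N(θᵢ, seᵢ²),      i = 1, …, k,

where yᵢ is study *i*'s effect estimate on a linear analysis scale and
seᵢ its (assumed known) standard error. For ratio measures the analysis
scale is the log scale, where the normal approximation is defensible;
ratios are exponentiated only at presentation time. The fixed-effect (FE)
model is the τ² = 0 special case, and the code treats it as such:
`pool_random` with τ̂² forced to 0 is bit-identical to `pool_fixed`.

### Estimators

* **Pooling** is inverse-variance: weights wᵢ = 1/seᵢ² (FE) or
  wᵢ* = 1/(seᵢ² + τ̂²) (RE); θ̂ = Σwy/Σw, SE(θ̂) = (Σw)^(−1/2).
* **Cochran's Q** = Σ wᵢ (yᵢ − θ̂_FE)² on k − 1 df, with FE weights.
* **τ̂²** is the DerSimonian–Laird moment estimator
  max(0, (Q − (k−1)) / (S₁ − S₂/S₁)), S₁ = Σwᵢ, S₂ = Σwᵢ²; truncation at
  zero is applied, as is standard. REML, Paule–Mandel etc. are out of
  scope.
* **I²** = max(0, (Q − df)/Q), i.e. computed from Q rather than from
  τ̂²/(τ̂² + typical variance).
* **CI of θ̂** is Wald with the normal quantile z₁₋α/₂. No
  Knapp–Hartung adjustment: the published summaries this package is used
  to reproduce are z-based, and mixing a KH confidence interval with a
  t-based prediction interval would conflate two different small-k
  corrections.

### Prediction interval

The PI for the true effect of a single new study is

    θ̂ ∓ t₍₁₋α/₂; k−₂₎ · √(τ̂² + SE(θ̂)²),

with exactly k − 2 degrees of freedom; k < 3 is a hard error rather than
a silent fallback to a normal quantile. `pi_from_summary` drives this
from a published summary (pooled ratio, its CI, τ̂, k) by back-deriving
SE(θ̂) = (ln U − ln L)/(2 z₁₋α/₂) from the printed CI — so reported
meta-analyses can be augmented with a PI without access to study-level
data. `PredictionInterval` deliberately exposes no p-value: significance
statements belong to the CI of the pooled effect, not to the PI.

### 2×2 tables

Log odds ratio ln(ad/bc) with SE √(1/a + 1/b + 1/c + 1/d). Zero cells:
Haldane–Anscombe +0.5 added to all four cells of affected tables only
(default), or a strict mode that raises. Double-zero rows/columns carry
no information about the OR and always raise, naming the study. Other
effect measures enter as precomputed effect/SE pairs; their formulas are
out of scope.

## Forest plots

A `ForestSpec` is a declarative, JSON-round-trippable description of the
plot: study rows (label, effect, CI, normalized weight), summary rows
(glyph + extents), axis (log/linear, reference line at 1 or 0, 1–2–5
ticks on log axes), and a heterogeneity annotation printing τ̂ (not τ̂²),
I² as a percentage, and Q with its df. Three PI presentations:

* `rectangle` (default): a separate row labelled "95% prediction
  interval" carrying a grey rectangle spanning the PI, 0.6 of a row tall,
  with no centre tick — the glyph emphasises a region, not a point, and
  makes no distributional assumption.
* `hollow_diamond`: an additional unfilled diamond spanning the PI.
* `extended_diamond`: one summary row whose diamond spans the CI and
  whose horizontal lines extend to the PI bounds.

The rectangle is the recommended style because the PI glyph should never
share a symbol class with the CI diamond; the other two exist for
comparison figures. `rectangle_rationale_demo` shrinks every study SE by
a factor while holding τ̂² at its original estimate: study CIs collapse
toward points and the PI stabilizes at θ̂ ∓ t·τ̂·√(1+1/k) (the pooled SE
has a floor of τ̂/√k under RE weighting), which is the merged-squares
picture that motivates the rectangle.

Rendering (matplotlib, SVG 1.1/PNG) is deterministic for a given spec and
format: fixed figure metrics (8 in wide, 0.45 in per row, dpi 100, fixed
fonts), a fixed `svg.hashsalt`, and date-free SVG metadata, so SVG output
is golden-file stable. Glyphs carry stable SVG `id`s
(`pi-rectangle`, `summary-diamond`, `study-square-i`, `plot-area`), which
the tests use to verify geometry in data coordinates by inverting the
plot-area transform. Study squares are drawn with side ∝ √weight (area ∝
weight) in typographic points, converted to display space after the axis
limits are frozen so they stay square on log axes. Axis limits are
computed from the plotted extents with 8% padding in transform space and
stored in the spec, making every plot reproducible from its JSON.
Unplottable specs (a non-positive value on a log axis) raise before any
file is written.

## Simulation

`simulate_meta` draws seᵢ from a configurable sampler — default
U(0.1, 0.5), a realistic precision range for trial-level log odds ratios
— then θᵢ and yᵢ from the hierarchy above. Effects are simulated directly
on the linear scale (no binomial layer): that is the model the estimators
assume, so simulation checks the estimators, not the adequacy of the
normal approximation to binomial data. A single seed drives everything;
replicates use `SeedSequence.spawn` substreams, so results are
reproducible and order-independent.

`coverage_experiment` repeats: simulate, fit RE + PI, draw a new true
effect θ_new ~ N(θ, τ²), and record whether θ_new ∈ PI and θ ∈ CI, with
binomial Monte-Carlo standard errors √(p(1−p)/n). The covered target is
the *true* effect of the new study, not its estimate. A `use_z` variant
replaces the t quantile with z to quantify what the t correction buys.

Problem sizes in the shipped tests — 2000 replicates for the k = 10
coverage and k = 50 τ²-recovery experiments, 600–800 for secondary
checks — keep each experiment's Monte-Carlo SE below ~0.01 while the full
suite runs in seconds.

## Validation

* Closed-form oracles: all statistics on a two-study toy match hand
  computation to 1e-12.
* Independent route: the 3-study fixture is checked against R `metafor`
  (`rma(..., method = "DL")`, PI with k − 2 df), frozen to 1e-9.
* The published amantadine summary (OR 0.34, CI 0.22–0.53, τ̂ = 0.4,
  k = 8) reproduces the printed 95% PI of (0.11, 1.04).
* Generator self-consistency: in the coverage simulation, the interval
  built from the *true* τ² and the z quantile covers θ_new at the nominal
  rate (0.948 at k = 10, τ² = 0.1, n = 2000, seed 1).

## Known limitations

* **Plug-in PI undercoverage at small k / moderate heterogeneity.** The
  t-based PI substitutes the noisy DL estimate for τ². τ̂² is
  right-skewed (its median sits below τ²; a fraction of replicates
  truncate to 0), so the plug-in interval is too narrow more often than
  too wide, and the t₍k−₂₎ quantile only partly compensates. In the
  package's own experiment at k = 10, τ² = 0.1, se ~ U(0.1, 0.5)
  (I² ≈ 50%), 2000 replicates, the PI covers θ_new ~0.89 rather than
  0.95 — while the same simulation with the true τ² covers nominally,
  and the z-based variant is worse (~0.84). Coverage approaches nominal
  when heterogeneity dominates the within-study variance (e.g. ~0.95 at
  k = 20, τ² = 0.25). Users should read the PI as an approximate summary
  of dispersion, especially in small meta-analyses.
* Normal random-effects distribution only; no Bayesian or non-normal PI.
* No Knapp–Hartung CI, REML/PM/SJ τ² estimators, meta-regression or
  subgroup pooling.
* The simulator does not emulate binomial sampling, zero cells,
  publication bias or correlated estimates; passing coverage tests speak
  to the estimators under the assumed hierarchy, not to real-data
  robustness.
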