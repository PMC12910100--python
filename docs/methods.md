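# Methods

## The question the simulator answers

A gradient study estimates a response curve `y = f(x)` along a continuous
environmental driver by regression. With a fixed budget of `N` samples the
designer must trade the number of distinct sampling locations `L` against
the number of replicates `r` per location (`N = L·r`), and must decide
where along the gradient the locations go. `gradsim` quantifies how these
choices, together with the noise level, the shape of the true response,
a-priori knowledge of that shape, and coverage of the gradient ends,
determine prediction accuracy.

## Simulation model

**True responses.** Six deterministic shapes on the domain `[1, 100]`
(arbitrary units), scaled so responses span ≈`[0, 100]`: linear `f(x)=x`;
centred hump `100 − (x−50.5)²·100/49.5²` (an exact quadratic); skewed hump
(Ricker) `100·(x/20)·e^(1−x/20)`; saturating `100·ln(x)/ln(100)`;
exponential `100·(e^(0.05x)−e^(0.05))/(e^5−e^(0.05))`; logistic
`100/(1+e^(−0.15(x−50.5)))`. The domain is strictly positive so
log-spaced placement is defined. Every shape carries its analytic
derivative; numerical differentiation is used only as a test oracle. All
forms and constants are overridable through the shape registry.

**Sampling procedures.** Budgets `N ∈ {6, 12, 24, 48, 96}` with every
factorization `N = L·r` satisfying `L ≥ 3` and `r ≤ 32` — 30 procedures in
total, spanning the extremes `(3 loc × 32 rep)` to `(96 loc × 1 rep)`.
The exact budget grid within the 6–96 range is a package choice; results
are aggregates over it.

**Strategies.** Systematic (equidistant), log-systematic (equidistant in
`log x`), random (uniform over a 1000-point candidate grid), and three
preferential strategies that draw locations without replacement with
probability proportional to a *criticality*: the local slope `|f′|`, the
extremeness `|f − (min f + max f)/2|`, or the equal-weight mean of the two
(each min–max standardized). After standardization, weights are floored at
10⁻³ of their maximum so no candidate has zero probability — otherwise
slope-preferential sampling of the hump could never observe the apex and
the quadratic fit would systematically degenerate. Weighted sampling
without replacement uses the generator's native draw-and-remove scheme and
is seed-deterministic.

**Predictor-extremes scenarios.** "With extremes": both gradient ends are
always sampled — systematic placements include them by construction;
random/preferential draws have their smallest and largest points replaced
by the endpoints, keeping `L` constant. "Without extremes": systematic
placements sit at the centres of `L` equal-(log-)width bins and the
endpoints are removed from the candidate grid. The replacement mechanics
are a package decision; only the scenario itself (ends always sampled or
not) is externally prescribed.

**Noise.** Observations are `y = f(x) + ε`, `ε ~ N(0, σ)` with
`σ = max(noise_level·|f(x)|, sd_floor)` — proportional, heteroscedastic,
untruncated. Study levels are 20% (close to noise levels reported for
real ecological measurements) and 100% (an extreme scenario). The floor
`noise_level·0.01·range(f)` prevents exactly-zero scatter where `f(x)=0`
(the hump's ends, the linear shape's origin), which would otherwise create
artificial noise-free anchor points.

**Fitting and selection.** OLS polynomials of order 1–4 on the driver
centred and scaled to `[−1, 1]` (coefficients reported on the raw scale);
replicates enter as repeated rows, so the locations-vs-replicates
trade-off bites through the design-matrix rank (`order+1` distinct
locations required). With the shape *unknown*, the order minimizing
`AIC = n·ln(RSS/n) + 2(order+2)` is selected among all feasible orders,
ties broken toward the lowest order; RSS is floored at 10⁻¹² inside the
log so noiseless fits select the most parsimonious exact order. With the
shape *known*, a fixed nominal order is used: the smallest order whose fit
to the noiseless dense curve reaches R² ≥ 0.995 (the best-R² order if none
does; capped at feasibility). For the default registry this gives
linear→1, hump→2, exponential→3, logistic→3, skewed hump→4, saturating→4.
Note that minimal-AIC selection retains an irreducible overfitting
probability of roughly 16% per extra candidate order (one spurious
parameter costs 2 AIC points and `P(χ²₁ > 2) ≈ 0.157`); exact-order
recovery therefore plateaus near 84%, which the tests assert rather than a
near-certain recovery.

**Scoring.** Predictions are evaluated on 1000 equidistant grid points
spanning the *full* domain — deliberately including regions never sampled,
which is how restricted gradient coverage hurts. Three measures:
multiple R² (squared Pearson correlation of predicted vs. true;
affine-invariant), prediction success of the fixed identity model
(`1 − Σ(ŷ−y)²/Σ(y−ȳ)²`; 1 only on exact match, may be negative), and
negative RMSE. A flat prediction scores multiple R² = 0 by convention; a
constant truth makes prediction success undefined (NaN, logged) — neither
raises mid-experiment.

## Analysis model

Accuracy is analyzed with four linear mixed-effect models (REML), each
with the replicate count as a numeric fixed effect, optionally interacting
with one scenario factor, and the remaining factors as random intercepts
(response shape always among them when it varies):

1. `accuracy ~ replicates | total, extremes, knowledge`
2. `accuracy ~ replicates × extremes | total, knowledge`
3. `accuracy ~ replicates × knowledge | total, extremes`
4. `accuracy ~ replicates × total | knowledge, extremes`

Crossed random intercepts are encoded in statsmodels `MixedLM` as variance
components on a single grouping; fixed-effect inference is Wald-z (at the
row counts involved the difference from Satterthwaite degrees of freedom
is negligible). A Huber-reweighting variant is available behind a flag but
the standard analysis is the plain REML fit. Variance components at the
boundary are floored at zero and flagged.

**What enters the models.** For the explained-variance analyses (the
four-model sensitivity table and the variation partitioning) the response
is the *Monte-Carlo mean* accuracy per factor combination (cell), not the
individual repetitions. Repetition-level scatter is simulation noise, not
a property of a design; leaving it in the response lets it dominate the
residual variance and makes explained-variance summaries shrink as the
noise level grows — the opposite of the structural signal of interest.
With mean accuracies the models describe how the *expected* accuracy of a
design responds to replication. The per-case effect classification, by
contrast, asks whether replication affects accuracy at all and therefore
uses every repetition, which maximizes the power of the per-case slope
test. `fit_lmm` itself is agnostic: it models whatever table it is given,
and `aggregate=False` switches the higher-level analyses to raw rows.

**Explained variance.** Marginal R² = `var(Xβ) / (var(Xβ) + Σσ²_random +
σ²_resid)`; conditional R² adds the random-intercept variances to the
numerator. If the response has no variance at all both are reported as 0
(nothing to explain).

**Variation partitioning.** For two predictors A and B with a common
random structure: `unique_A = R²(joint) − R²(B)`, `unique_B = R²(joint) −
R²(A)`, `shared = R²(A) + R²(B) − R²(joint)`, all on marginal R². The
joint model includes the A×B interaction, mirroring the interacting fixed
effects of the accuracy models, so "shared" includes the interaction's
contribution. The three terms sum to R²(joint) identically; negative
shared fractions (suppression) are reported as-is and flagged.

**Per-case classification.** For every case (shape × strategy × knowledge
× extremes, per metric and noise level) the repetition-level accuracy is
regressed on the replicate count with a random intercept for the total
sample size; the slope is classified negative/positive at Wald `p < 0.05`,
else nonsignificant. Cases with fewer than two replicate levels are
excluded and counted, and a case whose metric is numerically constant
(e.g. multiple R² for the known linear shape, identically 1 by affine
invariance) is classified nonsignificant rather than letting a
zero-variance regression declare a sign.

**Model comparison.** One-way ANOVA with post hoc Tukey HSD across groups
of sub-fit R² values, summarized as a compact letter display: letters are
assigned to the maximal cliques of the nonsignificance graph, ordered by
descending group mean, so the display is invariant to input order.

## Seeding and determinism

One master seed; each (cell, repetition) pair derives its own
`SeedSequence(master, spawn_key=(cell_index, rep))`, so any single run is
reproducible in isolation, the grid is identical across platforms for a
given configuration, and an interrupted run resumes bit-identically
(completed cells are recognized in the output CSV by factor key and row
count). The per-row `seed` column records a 31-bit integer derived from
that sequence.

## Problem sizes

The reference analysis uses 1000 repetitions per cell (the `RunConfig`
default). The bundled acceptance script and the heavyweight tests run the
same full factor crossing at 100 repetitions per cell — 8640 cells,
864 000 simulated fits — which reproduces the headline aggregates with
proportionally wider Monte-Carlo bands; lighter tests use single cells or
reduced factor sets chosen to isolate one property each.

## What the generator does and does not emulate

The generator produces independent, Gaussian, proportionally
heteroscedastic scatter around deterministic one-factor response curves.
Real gradient data additionally carry autocorrelated residuals, non-
Gaussian errors, observation-level covariates, multi-factor interactions
and drivers measured with error — none of which are modelled. Passing
tests therefore demonstrate properties of the sampling-design question
under the idealized error model, not performance guarantees for any
particular field dataset.

## Known limitations

* Only balanced replication (equal `r` at every location) is supported.
* Prediction models are polynomials; the true nonlinear forms are never
  fit even in the known-shape scenario, so "known" means "known shape
  class", operationalized as a fixed polynomial order.
* The preferential strategies presume exact knowledge of the true curve
  when computing criticality; they bound what preferential sampling could
  achieve, not what a pilot study would deliver.
* Mixed models with two-level random factors (extremes, knowledge) are
  weakly identified and often estimate a zero variance component; this is
  expected and flagged, not an error.
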