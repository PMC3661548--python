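# Methods

This note records the statistical model, the estimation and classification
procedures, the synthetic-data generator, and the numerical and design
choices behind morphmix. It is written for a user who wants to know exactly
what the package computes and what its tests do and do not demonstrate.

## The facing-gamma mixture

A male-dimorphic trait is modelled as a two-component finite mixture whose
components are *facing* (mirrored, bound-shifted) gamma densities. Writing
`G(z; λ, θ) = z^(λ−1) e^(−z/θ) / (Γ(λ) θ^λ)` for the gamma density,

- homeomorphic (minor) males: `f₁(x) = G(x − L; λ₁, θ₁)` for `x ≥ L` — a
  lower-bounded density skewed toward higher values;
- heteromorphic (major) males: `f₂(x) = G(U − x; λ₂, θ₂)` for `x ≤ U` — an
  upper-bounded density skewed toward lower values;
- mixture: `f(x) = π f₁(x) + (1 − π) f₂(x)`, `π ∈ (0, 1)`.

Component identity is fixed by orientation (the lower-bounded component is
always "homeomorphic"), which removes label-switching ambiguity without any
ordering heuristic on means. Means are `L + λ₁θ₁` and `U − λ₂θ₂`; CDFs are
regularized incomplete gamma functions, and quantiles come from the gamma
inverse-CDF (machine-precision inversion; the CDF/quantile pair round-trips
to 1e-9, which the test suite asserts at a grid of probabilities).

Parameters of the reference trait (units mm): homeomorphic λ₁ = 1.91,
θ₁ = 0.163, L = 0.48; heteromorphic λ₂ = 2.88, θ₂ = 0.201, U = 2.25. The
mixing weight of the source analysis is unreported; the package treats
π = 0.5 as the neutral default in synthetic work, and every reproduction
check is constructed to be π-free (component quantiles do not involve π).

## Maximum-likelihood estimation

The observed-data log-likelihood is maximized directly (EM has no
closed-form M-step for shifted gammas). The search runs over an
unconstrained reparameterization:

- `logit π` — weight in (0, 1);
- `log(λ − 1)` — shapes kept ≥ 1 so the density cannot spike *at* a bound;
- `log θ` — positive scales, with a floor `θ ≥ 1e-3 × data span` that keeps
  the optimizer away from the classical one-point degeneracy of
  location-scale mixtures (a bound placed just below a data point with
  θ → 0 sends the likelihood to infinity);
- `L` and `U` free, subject only to `L < U`.

The bounds are deliberately *not* constrained to the data range. The two
supports `[L, ∞)` and `(−∞, U]` jointly cover every observation whenever
`L < U`, and an extreme lower-tail draw from the upper-bounded component
can legitimately fall below the true `L` (in a 5000-draw sample at the
reference parameters the sample minimum can sit near 0.04 mm while
L = 0.48 mm). Forcing `L ≤ min(x)` in that situation drags the lower bound
— and with it the homeomorphic shape and scale — to a wrong optimum; with
free bounds the fit recovers all seven parameters and its log-likelihood
always dominates the generating parameters' (both are asserted in tests).

Optimization uses eight deterministic starts built from data-quantile
splits (each side moment-matched to a shifted gamma; later starts get small
seeded jitters), Nelder–Mead with a 1e-8 function tolerance followed by an
L-BFGS-B polish, best result kept. Fitting requires n ≥ 10: seven
parameters below that are not meaningfully estimable, and a two-male sample
must be rejected with a clear error rather than fitted.

Model comparison fits a one-component lower-bounded gamma (3 parameters,
bound constrained below the sample minimum, which *is* correct for a single
component that must cover all data) against the mixture (7 parameters) and
ranks by AIC; AICc is available by flag. The source analysis reports no
comparison procedure, so AIC is the least-assumption default; the
likelihood-ratio test is avoided because mixture boundary conditions make
its null distribution nonstandard.

At the reference conditions (n = 5000) the shape estimators are unbiased
but information-limited: across seeds the homeomorphic shape shows a
relative spread of roughly ±10% (the bound–shape–scale coupling of
three-parameter gamma components is the known cause), the heteromorphic
shape about ±6%. Single-seed recoveries therefore usually, but not always,
land within 10% of truth.

## Classification

Two rules are implemented, and they are not equivalent:

- **component_quantile** (default): cutoff_low is the heteromorphic
  component's 5th percentile, cutoff_high the homeomorphic component's 95th
  percentile; males below cutoff_low are homeomorphic, above cutoff_high
  heteromorphic, between them unassigned, ties unassigned. At the reference
  parameters these cutoffs are 1.02 mm and 1.23 mm. This rule is π-free and
  reproduces the published cutoff values exactly from the component
  parameters, which is why it is the default.
- **posterior**: threshold the posterior morph probability
  `P(hetero | x) = (1−π) f₂(x) / f(x)` at the confidence level. This is the
  rule whose stated 95% confidence transfers directly to accuracy: among
  males it assigns, ≥95% carry their true generating morph (the
  component-quantile rule achieves ≈94–95%, since e.g. among all males
  below 1.02 mm a ≈6% heteromorphic minority remains). It depends on π and
  does not reproduce both published cutoffs under any single π.

The ambiguity between the two rules is documented, not resolved: accuracy
claims in the end-to-end tests use the posterior rule; cutoff-value
reproduction uses the quantile rule. When the two assertion regions cross
(cutoff_low > cutoff_high, which happens under extreme component
separation, not mild overlap), the result is flagged and the doubly-claimed
band is left unassigned.

## Screening statistics

Bimodality is screened with a Gaussian-kernel KDE on a 512-point grid
spanning the data ± 3 bandwidths; the automatic bandwidth is the
rule-of-thumb `0.9 · min(sd, IQR/1.34) · n^(−1/5)`. Modes are strict local
maxima with prominence ≥ 5% of the peak density (plateaus merged, endpoint
maxima counted); the threshold suppresses grid-level ripple and is
configurable. This screen motivates the mixture fit; it is not itself a
test of multimodality.

Trait variabilities are compared as mean-standardized variances, var/mean
(units mm); var/mean² (squared CV) is available behind a flag since either
reading is consistent with the magnitudes being emulated. For a dimorphic
male trait against body size this ratio is ≫ 1 (order 20 under the
reference conditions); for monomorphic females it is < 1 (order 0.5).

## SMA allometry

Per-group scaling is fitted by standardized major axis regression on the
natural mm scale (no log transform — the source coefficients, including
negative intercepts, are on natural scale; log-log is behind a flag):
`b = sign(r) · sd(y)/sd(x)`, `a = ȳ − b x̄`, slope CI from
`B = F(1−α; 1, n−2)(1−r²)/(n−2)` as `b(√(B+1) ± √B)`, intercept limits
propagated from the slope limits through the centroid. Slope differences
between groups are judged by CI overlap only — a slope is "steeper" only
when its whole interval clears the other's — matching how the published
comparison was made; no common-slope test is performed.

Unassigned males enter neither morph's fit. Groups under n = 3 are skipped
with a warning, and comparisons involving them are omitted.

## Synthetic-data generator

The generator emulates the study population so every stage is testable:
45 males and 17 females by default; male patella from the reference mixture
(π = 0.5); prosoma on the published per-sex ranges; per-group allometric
lines with intercepts/slopes from the published coefficients and residual
sd 0.05 mm (males) / 0.02 mm (females), chosen so simulated CI widths are
of the same order as the published ones (residual variance is unreported).
Generating morph labels travel as hidden truth metadata for scoring, and
are dropped on CSV export unless requested.

Two modes exist because the exact mixture marginal and the exact linear
structure cannot hold simultaneously: `trait_only` (default) draws male
patella from the mixture with prosoma independent — exact facing-gamma
marginals for mixture-recovery tests, but no real male allometry — while
`allometric` assigns a morph by π and sets patella = morph line + noise —
exact lines for allometry tests, with the bimodality emerging from the two
lines' separation.

Prosoma is drawn, by default, from a normal centred mid-range with
sd = range/4, truncated to the published range; `uniform` is available by
flag. Published ranges are sample extremes, not plateau edges: a uniform
spread pushed through the female line produces a flat female trait marginal
whose small-sample KDE is frequently multimodal, contradicting the
unimodal female distribution the generator exists to emulate, and implying
female trait values well outside the published female range. The truncated
normal reproduces the central clustering the published female range
implies. The published female range and female line remain jointly
unsatisfiable over the full prosoma range under any noise-on-line scheme;
validation against the published ranges reports such tail excursions
honestly rather than hiding them.

What passing tests show — and do not show. The generator's males are exact
draws from the assumed mixture, so recovery tests validate the estimator,
not the model's fit to real animals; real traits carry measurement error,
possible prosoma–morph correlation (not modelled; kept independent by
default) and finite-population structure that the generator omits.

## Problem sizes and determinism

Test and reproduction sizes were chosen as the smallest that make each
property stable: mixture recovery at n = 5000 (the reference size) in the
acceptance checks and n = 2000 in the unit suite; oracle-equivalence grid
search at n = 200; SMA recovery at n = 500; variance-ratio envelope over
50 seeded replicates at the study's own n = 45/17; end-to-end at 500 males
/ 189 females (the study's sex ratio scaled up ~11×, where KDE mode counts
are stable). Every random draw flows from an explicit seed; fits are
deterministic given data and configuration (fixed multi-start schedule),
and repeated pipeline runs produce identical reports modulo timestamps.

## Known limitations

- No bootstrap or asymptotic CIs on mixture parameters; point estimates and
  log-likelihoods only.
- Only two-component facing-gamma mixtures; no ≥3-component fits and no
  alternative kernels beyond the one-component gamma baseline.
- The posterior/quantile rule discrepancy is inherent to the method
  definition and is surfaced, not hidden; users comparing against published
  cutoff values should use the quantile rule, users wanting calibrated
  assignment confidence the posterior rule.
- SMA intercept CIs use the centroid propagation from the slope limits;
  exact likelihood-based intervals are not implemented.
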