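# morphmix

Discrimination of discrete male morphs from a continuous trait, and the
allometric consequences: facing-gamma mixture models, 95%-confidence morph
classification, and standardized major axis (SMA) allometry.

## The problem

In many arthropods, males come in two discrete forms ("male dimorphism"):
minor (homeomorphic) males with a modestly sized trait and major
(heteromorphic) males with a greatly elongated one — here, the pedipalpal
patella of cave-dwelling short-tailed whipscorpions (Schizomida), with
prosoma length as the body-size proxy. Deciding objectively which males
belong to which morph, and how each morph's trait scales with body size,
is the core analysis this package implements for anyone studying
alternative male phenotypes from specimen measurements.

## The model

The male trait density is a two-component mixture of *facing gamma
distributions*: a lower-bounded gamma skewed toward higher values for
homeomorphic males and its mirror image — an upper-bounded gamma skewed
toward lower values — for heteromorphic males,

```
f(x) = π · G(x − L; λ₁, θ₁) + (1 − π) · G(U − x; λ₂, θ₂),
```

where `G(·; λ, θ)` is the gamma density with shape λ and scale θ, `L` is the
homeomorphic lower bound and `U` the heteromorphic upper bound (all lengths
in mm). All seven parameters `(π, λ₁, θ₁, L, λ₂, θ₂, U)` are estimated by
direct maximum likelihood with deterministic multi-starts. Males are
classified at a 95% confidence level either from component quantiles (below
the heteromorphic 5th percentile → homeomorphic; above the homeomorphic
95th percentile → heteromorphic; between → unassigned) or from posterior
membership probabilities. Per-group trait-on-size lines are then fitted by
SMA regression (`|slope| = sd(y)/sd(x)`), with classical confidence
intervals and CI-overlap slope comparisons.

A seeded synthetic-data generator emulates the dimorphic study population
(bimodal males, unimodal females, per-group allometric lines), so the whole
pipeline runs and is tested without access to raw specimen data.

## Worked example

```python
import numpy as np
from morphmix import (MixtureModel, right_facing, left_facing,
                      fit_mixture, classification_cutoffs, FitConfig)

truth = MixtureModel(0.5, right_facing(1.91, 0.163, 0.48),
                     left_facing(2.88, 0.201, 2.25))
xs = truth.sample(500, np.random.default_rng(1))
fit = fit_mixture(xs, FitConfig(seed=1))
lo, hi = classification_cutoffs(fit, level=0.95)
print(f"{lo:.2f} {hi:.2f}")
```

prints `0.96 1.22`: with this 500-male sample the refitted mixture puts the
homeomorphic assertion cutoff at 0.96 mm and the heteromorphic one at
1.22 mm — males below 0.96 mm are homeomorphic and above 1.22 mm
heteromorphic, each at ≥95% within-component confidence. Evaluated at the
generating component parameters instead of the refit, the same quantiles
are 1.02 mm and 1.23 mm.

The `examples/` directory holds one narrative script per capability
(simulation, mixture fitting and classification, SMA allometry, full
pipeline); each prints the numbers it computes and says what they mean.
A thin CLI wraps the same library calls:

```
morphmix simulate --seed 1 --out population.csv
morphmix analyze --input population.csv --out results/
morphmix fit-mixture --input population.csv --out model.json
morphmix sma --input population.csv --out sma.tsv
```

`analyze` writes a schema-validated `report.json` plus a TSV of SMA
coefficients per group.

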