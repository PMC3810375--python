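# growthcorr

Detecting **positive growth autocorrelation** in cohorts of *unmarked*
individuals from the pattern of increasing size variance through time.

## The problem

A cohort of same-aged individuals usually spreads out in body size as it
grows ("growth depensation"). Two process classes produce this spread:

- **within-individual variation** — uncorrelated step-to-step noise in
  each individual's growth rate; and
- **among-individual variation** (positive growth autocorrelation) —
  persistent differences in growth rate between individuals, e.g.
  consistent behaviour types or microhabitat quality.

Telling them apart normally requires marking individuals and following
them. Many systems make marking infeasible or harmful. This package
implements a method that needs only *repeated cross-sectional size
samples*: the trajectory of the cohort's size variance identifies how
much of the growth-rate variance is persistent.

## The model

Individual sizes follow, on a time axis scaled so the observation window
is [0, 1],

```
x_i(t + δ) = x_i(t) + (g + ε_i) δ + η_i(t),
ε_i  ~ N(0, ρ² σ²)          (permanent, per individual)
η_i(t) ~ N(0, (1 − ρ²) σ² δ)  (independent each step)
```

so the cohort variance is quadratic in time:

```
V(t) = σ₀² + σ² (ρ² t² + (1 − ρ²) t).
```

`ρ² ∈ [0, 1]` is the fraction of growth-rate variance attributable to
permanent among-individual differences; `σ²` is the total increase in
cohort variance over the window. Between-step changes in the observed
sample variance are modelled as independent normals around
`ΔV(t, δ) = σ² (ρ² (2tδ + δ²) + (1 − ρ²) δ)` with a constant nuisance
scale τ; `ρ̂` is the MLE and its 95% confidence interval comes from
profile likelihood (χ²₁ cutoff). `ρ = 0` is rejected when the CI
excludes zero.

The package also provides:

- a **cohort simulator** (with optional logistic size-dependent
  mortality and a saturating-exponential observation scale),
- a **linearization** step (fit `size = c(1 − e^{−(b+dt)})` to occasion
  means, transform through `−log(1 − size/ĉ)`, censor sizes above `ĉ`),
- a **repeated-measures comparator** for marked data (random-intercept
  LMM on growth increments; bootstrap restricted LR test of ρ = 0),
- a **Monte-Carlo study harness** for power, coverage, CI width,
  minimum sample sizes, and mortality-induced bias.

## Worked example

```python
from growthcorr import GrowthParams, simulate_cohort, fit, test_rho_positive

params = GrowthParams(rho=0.7, sigma2=16.0, n_t=16)      # true rho^2 = 0.49
cohort = simulate_cohort(params, n_individuals=200, seed=42)
result = fit(cohort.variance_trajectory())
print(result.rho_hat, result.rho_ci, test_rho_positive(result))
```

prints (run as `examples/01_fit_single_cohort.py`):

```
rho_hat    = 0.816   (true 0.700)
rho^2_hat  = 0.666   (true 0.490)
sigma^2    = 16.41    (true 16)
95% CI rho = (0.654, 0.964)
reject rho=0: True
```

The point estimate overshoots a little in this particular cohort, but
the 95% profile interval comfortably contains the true ρ = 0.7, and its
lower bound above zero means uncorrelated growth noise alone cannot
explain how the variance accelerated through time.

The `examples/` directory has one short script per capability (single
fit, power-based design, mortality bias, nonlinear growth, comparison
with marked-individual analysis). A thin CLI mirrors the same
operations:

```sh
growthcorr simulate --rho 0.7 --sigma2 16 --n-individuals 200 --seed 1 --out cohort.csv
growthcorr fit cohort.csv
growthcorr min-n --rho2 0.64 --seed 1 --replicates 200
```

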