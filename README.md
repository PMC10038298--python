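# bbsurvey

Hierarchical Bayesian modelling of weekly food-consumption frequency
surveys, for food-security analysts who want more from a consumption module
than a single aggregate score.

Humanitarian agencies monitor food insecurity with household surveys that
record, for each of J standard food groups, the number of days (0–7) in the
previous week on which the household consumed that group.  These counts are
usually collapsed into aggregate indicators — the Food Consumption Score
(FCS, a weighted sum over 8 groups with weights summing to 16 and maximum
112) or the Household Dietary Diversity Score (HDDS) — which hide the
variability across households, the dispersion of each food group, and the
correlations between groups that drive the shape of the indicator
distributions.

## The model

Each household's count vector is modelled jointly.  For household *i* and
food group *j* (m = 7 recall days):

```
Y_ij | κ_i  ~  Beta-Binomial(m, γ_ij, θ_j)
γ_ij        =  logit⁻¹( logit(p_j) + κ_ij )
κ_i         ~  N(0, Σ),   Σ = D Ω D,   D = diag(σ_1, …, σ_J)
```

* `p_j` — population daily consumption probability for group *j*;
* `θ_j` — dispersion: the count variance is `m p (1−p) (1 + (m−1)/(θ+1))`,
  so small θ means mass piling up at 0 and 7 days and large θ recovers the
  plain binomial;
* `σ_j` — across-household spread of consumption propensity;
* `Ω` — correlation matrix of the household effects: positive `ρ_jk` means
  households eating more of group *j* also eat more of group *k*.

Baseline rounds are fitted with diffuse priors (`p_j ~ Beta(1,1)`,
`θ_j ~ Gamma(5,1)`, `σ_j ~ Half-Cauchy(0,2)`, `Ω ~ LKJ(2)`).  For a smaller
follow-up (emergency) round, weighted informative priors carry the baseline
forward: `p_j ~ Beta(a p̂₀ⱼ, a (1−p̂₀ⱼ))`, `θ_j ~ Gamma(α θ̂₀ⱼ, α)`, and
truncated-normal priors on the correlations, with weights (default a = 50,
α = 5) chosen by closed-form and normal-approximation planning tools so the
prior informs without swamping the new data.  Fit quality is checked by
posterior-predictive simulation: per-group Wilcoxon rank-sum and
Fligner–Killeen tests and Kolmogorov–Smirnov tests on the FCS and
frequency-weighted HDDS distributions, with Benjamini–Hochberg adjustment.

Fitting uses a hand-written adaptive Metropolis-within-Gibbs sampler with
interweaved centered/non-centered updates (no external probabilistic
programming framework is required); split-R̂ and effective-sample-size
diagnostics come from `arviz`.

## Worked example

```python
import numpy as np
from bbsurvey import (ConsumptionModel, compute_indicators, generate_survey,
                      prevalence, scenario_library)

# a 480-household synthetic survey from the Ibb-2014 fixture parameters
params = scenario_library()["ibb_2014"]
survey = generate_survey(params, n=480, seed=42)

table = compute_indicators(survey)
severe, below = prevalence(table["fcs"])
print(f"share FCS <= 28       {severe:.3f}")       # 0.267
print(f"share FCS <= 42       {below:.3f}")        # 0.504
print(f"median weighted HDDS  {table['hdds_weighted'].median():.2f}")  # 5.43

# fit a 3-group sub-model and inspect the posterior
sub = survey.subset_groups(["vegetables", "pulses", "dairy"])
results = ConsumptionModel(sub).fit(chains=2, iterations=1500, warmup=500, seed=1)
print(results.summary().table[["mean", "hpd_lower", "hpd_upper"]].round(3))
```

```
                           mean  hpd_lower  hpd_upper
p[vegetables]             0.349      0.298      0.409
theta[vegetables]         5.548      2.329      9.698
sigma[vegetables]         2.083      1.585      2.588
p[pulses]                 0.131      0.080      0.196
...
Omega[vegetables,pulses]  0.612      0.461      0.782
```

About a quarter of the simulated households fall at or below the severe
FCS cutoff of 28 and half below the acceptable cutoff of 42.  The fitted
daily probabilities straddle the generating values (vegetables 0.40, pulses
0.11, dairy 0.23 in the fixture), and the correlation estimates recover the
exchangeable 0.5 structure the survey was generated under.  `results`
also exposes `simulate()` for posterior-predictive surveys, `gof()` for the
goodness-of-fit report, `compare()` for HPD-overlap change flags between
rounds, and `baseline_summary()` to feed
`bbsurvey.updating.make_updated_priors` for a follow-up fit.

A command line mirrors the pipeline: `bbsurvey simulate | fit-baseline |
fit-update | indicators | gof | compare` (see `bbsurvey --help`).

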