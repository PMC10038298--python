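# Methods

## Model

A household's weekly consumption module is a vector of J bounded counts,
`Y_ij ∈ {0,…,7}`.  Conditional on a household-level random effect vector
`κ_i`, the counts are independent beta-binomials in the mean/dispersion
parametrization (`α = pθ`, `β = (1−p)θ`):

    Y_ij | κ_i ~ Beta-Bin(7, γ_ij, θ_j),
    γ_ij = logit⁻¹(logit(p_j) + κ_ij),
    κ_i ~ N(0, Σ),  Σ = D Ω D,  D = diag(σ).

Assumptions worth stating explicitly:

* meals are communal, so one count per household per group is meaningful;
* the recall window length m = 7 is carried as a field, so other windows
  are possible, but all defaults assume 7;
* random effects are Gaussian on the logit scale and constant within the
  week; there is no temporal structure beyond the two-round prior updating;
* no survey design weights: the two-stage cluster design of the source
  surveys is ignored, matching how the models are fitted in practice;
* no household covariates and no zero-inflation.

The marginal count distribution (integrating κ) is a logit-normal mixture
of beta-binomials.  Its key identification property, and the model's main
scientific payoff, is the separation of *within*-household dispersion
(θ_j: U-shaped vs binomial-shaped conditional counts) from
*across*-household heterogeneity (σ_j) and co-movement (Ω).  At m = 7 this
separation is real but weak; posterior intervals for θ_j are wide even at
n = 480, and θ beyond roughly 50 is operationally indistinguishable from
the binomial.

## Priors

Baseline (diffuse): `p_j ~ Beta(1,1)` (uniform), `θ_j ~ Gamma(5,1)`
(right-skewed, mean 5, 99% of mass below 11.6), `σ_j ~ Half-Cauchy(0,2)`,
`Ω ~ LKJ(2)`.

Follow-up (weighted updating): a baseline fit is condensed into the sample
proportions `p̂₀ⱼ = Σ_i X_ij / (7 n₀)` and posterior means
`(θ̂₀ⱼ, σ̂₀ⱼ, ρ̂₀ⱼₖ)`.  The conjugate Beta posterior of a proportion under a
binomial likelihood, `Beta(1 + 7n₀p̂₀ⱼ, 1 + 7n₀(1−p̂₀ⱼ))`, has sd below 0.02
already at n₀ = 100 — too narrow to serve as a prior without drowning the
follow-up data.  The carried-forward priors are therefore down-weighted:

    p_j ~ Beta(a p̂₀ⱼ, a (1−p̂₀ⱼ))        (mean p̂₀ⱼ, weight a)
    θ_j ~ Gamma(α θ̂₀ⱼ, α)               (mean θ̂₀ⱼ, variance θ̂₀ⱼ/α)
    ρ_jk ~ N(ρ̂₀ⱼₖ, 1) truncated to (−1,1)
    σ_j ~ Half-Cauchy(0,2)               (unchanged)

Defaults a = 50, α = 5, correlation prior sd 1.  Degenerate baseline
proportions (exactly 0 or 1) are clamped to `1/(7n₀+2)` — the resolution of
the conjugate posterior mean — with a logged warning.

The truncated-normal correlation priors are applied elementwise to the
entries of Ω through its Cholesky parametrization (canonical partial
correlations), which preserves positive definiteness by construction; the
change-of-variables Jacobian from partial correlations to Ω entries is
included exactly.

## Planning the weights

Two tools quantify what a weight choice implies for a follow-up round of
n_d households:

1. **Closed form for p.**  The updated Beta posterior has
   `mean = (a p̂₀ + 7 n_d p̂_d)/(a + 7 n_d)` and
   `var = mean · (1−mean-type term) / (a + 7 n_d + 1)`.  The 95% half-width
   `1.96 σ` maximized over all proportion pairs is 0.0193 at a = 50,
   n_d = 360 (attained at p̂₀ = p̂_d = 0.5), i.e. within ±0.025 regardless
   of dispersion.  This is the planning bound reported by the acceptance
   script.
2. **Normal approximation for (p, θ) jointly.**  For a single group without
   random effects, the posterior mode of (p, θ) is located numerically
   (BFGS on logit/log scales) and the covariance taken as the inverse
   central-difference Hessian (step 1e-4 on the transformed scales, mapped
   back by the delta method).  Data enter either as observed counts or as
   expected cell counts `n_d · P(y | p_d, θ_d)` for a deterministic
   scenario grid.  The approximation is accurate for n_d ≥ 250.  The θ
   half-widths from this tool motivate the weight α; they depend strongly
   on the scenario grid (≈1.7 for θ ≤ 5, rising towards ≈2.5 near θ = 10),
   and at small θ with mid-range p the joint-posterior p half-width exceeds
   the closed-form value in (1), because overdispersed counts genuinely
   carry less information about p than the binomial-likelihood conjugate
   calculation assumes.  The package treats (1) as the p-planning bound and
   (2) as the θ-planning and diagnostic tool.

## Inference

No probabilistic-programming backend is used; the sampler is a purpose
-built adaptive Metropolis-within-Gibbs scheme on unconstrained scales
(logit p, log θ, log σ, atanh canonical partial correlations for Ω).
Under LKJ(η) the partial correlations are independent shifted-Beta
variables, giving an exact and cheap prior in the sampling parametrization.
Each iteration sweeps:

1. joint random-walk updates of each household's κ row, pre-conditioned by
   the current Cholesky factor of Σ, with per-household adaptive step sizes
   (target acceptance 0.25);
2. an exact translation move `(logit p_j, κ·j) → (logit p_j + d, κ·j − d)`
   per group — the likelihood is invariant, so this cheaply decorrelates
   p_j from the mean random effect;
3. scalar random-walk updates of logit p_j, log θ_j, log σ_j, and each
   partial correlation (centered parametrization; target acceptance 0.44);
4. the same σ and Ω updates in the *non-centered* parametrization (whitened
   effects held fixed, κ rescaled), interweaved with step 3, plus a joint
   (θ_j, σ_j, κ·j) move along the dispersion trade-off direction.  The
   interweaving is what makes the weakly identified θ/σ split mix; with
   centered updates alone the chain's R̂ for these parameters stays near 2.

Initialization is data-informed: κ starts at 0.8 × the logit residual of
each count around the group sample proportion, and σ at the implied column
spread.  Proposal scales adapt by Robbins–Monro during warmup only.

Defaults mirror the reporting protocol: 4 chains × 4000 iterations with
1000 discarded as warmup.  Convergence guards are split-R̂ < 1.05 and bulk
ESS > 100 per parameter, logged as warnings rather than errors — with the
default budget the slowest parameters (θ, σ of strongly dispersed groups)
typically sit at R̂ ≈ 1.1–1.4, which is adequate for posterior means and
95% HPD endpoints but worth increasing for publication-grade interval
estimates of θ.

HPD intervals are the shortest contiguous window over the sorted draws
containing the requested mass (exhaustive window search).  Cross-round
comparison flags a parameter as changed ("increase"/"decrease") exactly
when the two 95% HPD intervals are disjoint.

Parameters can be pinned (`fixed={"theta": 1e6, "sigma": 0.0}`), which
reduces the model to a binomial with a Beta prior and is used to verify the
sampler against the conjugate closed form.

## Indicators

FCS: survey groups are aggregated into the 8 FCS groups (sum of days,
capped at 7), then weighted: Starches 2, Pulses 3, Vegetables 1, Fruit 1,
Meat 4, Dairy 4, Fats 0.5, Sugar 0.5.  Thresholds are inclusive: ≤ 28
severe, ≤ 42 below acceptable.  The default 13-group mapping sends bread,
potatoes and rice to Starches; eggs, meat and fish to the animal-protein
group; condiments carry no FCS weight.  HDDS counts how many of the 12
standard groups saw any consumption; the frequency-weighted HDDS divides
each group's capped days by 7 before summing.  The cap-at-7 aggregation
rule keeps both scores within their stated maxima (112 and 12); a worked
"fast-food diet" illustration in the source literature is consistent only
with scoring starch subgroups separately (yielding 91 rather than the 77
the capped rule gives) — the package keeps the capped rule, which is the
one compatible with the stated maximum of 112.

## Goodness of fit

A fitted model is checked by simulating a survey-scale dataset (default
12,000 households) and comparing it with the observed one: per group,
Wilcoxon rank-sum (center) and Fligner–Killeen (spread); at the indicator
level, two-sample Kolmogorov–Smirnov on FCS and weighted HDDS.  P-values
are Benjamini–Hochberg adjusted within one family per test type; a
multi-region analysis concatenates the per-region reports and re-adjusts.
Simulation integrates over the posterior by default (one posterior draw
per simulated household); simulation from the posterior-mean parameters is
available as a mode.  A decorrelated simulator (identity Ω, same
marginals) isolates the contribution of the correlation structure: under
positively correlated high-weight groups the correlated FCS distribution
is wider and more right-skewed than the decorrelated one.

Numerical caveats: the K-S test on FCS values is applied to heavily tied
discrete scores; and Fligner–Killeen is anticonservative (≈10% rejection
at nominal 5%) for skewed, heavily tied count marginals at unequal sample
sizes — observed on iid samples from the same marginal, so it is a property
of the test, not of the model code.  Decisions in reports should therefore
be read at the BH-adjusted level, which absorbs this inflation.

## Synthetic data

The generator draws from the generative model itself, so model fits to its
output are parameter-recovery exercises by construction.  Fixture
parameter sets transcribe published two-decimal marginal estimates (p, θ,
σ) for six region-rounds (Ibb, Shabwa, Ad Daleh × 2014, 2016).  Printed
probabilities of 1.00/0.00 are clamped to 0.995/0.005 — inside their
printed 95% intervals — because the logit link requires the open interval.
Correlation matrices were published only graphically, so fixtures pair the
tabulated marginals with documented synthetic scenarios: identity,
exchangeable(r) (default r = 0.5), and a "luxury block" with the
high-value foods (fruit, pulses, eggs, dairy, meat) mutually correlated at
0.6.  What passing recovery tests on these fixtures shows is that the
estimation machinery works at realistic parameter values and sample sizes;
it does not validate the model against real survey idiosyncrasies
(heaping at particular day counts, multimodal response profiles,
assistance-driven shifts), which real data exhibit and the generator does
not emulate.  Design effects of cluster sampling are also not emulated.

## Problem sizes and runtime

The test suite and the acceptance script scale the published protocol to
routine hardware: the recovery acceptance run fits 5 groups × 480
households with 4 chains × 2000 iterations (600 warmup), about one minute
on one core; the round-trip recovery test uses 3 groups × 2000 households
with 2 × 1500 iterations.  Posterior means of p are stable to well under
0.01 across seeds at these budgets.  Full-protocol fits (13 groups, 4 ×
4000) take a few minutes per region.

## Known limitations

* θ_j is weakly identified at m = 7; its posterior mean shrinks noticeably
  toward the prior mean at n ≤ 2000 and its intervals are wide.
* R̂ warnings at the default budget for the most dispersed groups (see
  above); raise iterations when interval endpoints for θ/σ matter.
* Groups with p̂ near 1 (bread, oil, sugar) are fitted as-is; no boundary
  special-casing.
* Elementwise truncated-normal correlation priors are a modelling choice;
  a joint prior respecting the constraint set differently could behave
  differently for J large and strong prior correlations.
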