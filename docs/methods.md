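# Methods

## The relative-phenology time axis

Soybean development is staged on the ordinal Fehr scale, which cannot serve
as a model time axis.  All curves here run on a continuous, dimensionless
relative-phenology scale: 0 at emergence (VE), 1 at beginning pod (R3),
2 at beginning physiological maturity (R7), extending to 2.5 at R8.  The
mapping is defined by an anchor table of (stage, value) pairs; the packaged
default is the union of the stage values printed for the source field
studies, with the densest schedule's value preferred where schedules
disagree (V4 → 0.44, V6 → 0.62).  Stages between anchors interpolate
linearly in stage number.  Two conventions close the map on realistic
inputs: V1 interpolates from VE treated as node 0, and V stages past the
last tabulated V anchor approach R1's value linearly over five nodes
(with the default table this is exact: V8 and R1 both anchor at 0.70).
The V2–V3 segment is flat (both 0.40), so interpolation there is
degenerate and returns 0.40 by construction.  Stages beyond the last
anchor raise rather than extrapolate.

## Ndfa and fixed-N

The natural-abundance estimator is (δref − δsoy)/(δref − B) with B the
δ¹⁵N of a fully fixation-dependent soybean (default −2.54 ‰, overridable
per dataset).  The dilution estimator is exposed in two forms because the
excess ratio (soy − atm)/(soil − atm) printed in parts of the field
literature is, under standard dilution logic, the fraction of plant N
traced to the *labeled soil pool*; its complement is the conventional
Ndfa.  `ndfa_dilution(as_printed=...)` makes the choice explicit, the
long-format reducer defaults to the conventional complement, and the three
abundances may be on any self-consistent scale (atom% or δ).  Raw Ndfa
outside [0, 1] — routine with field-scale δ¹⁵N noise — is clipped with a
warning rather than rejected, since the beta observation model requires
values in (0, 1).  The soil-pool enrichment decay with soil mineral N is a
pluggable callable (default family a + b·e^(−cx)); its coefficients are
site calibrations the user must supply.

## Process and observation models

Cumulative fixed-N follows the increasing Gompertz curve
β₁·exp(−exp(−β₃(t − β₂))): β₁ is the season asymptote (kg ha⁻¹), β₂ the
time of maximum fixation rate (the inflection), β₃ a dimensionless rate
multiplier.  Ndfa follows the zero-intercept bell
α₁·exp(−((t − α₂)/(α₃·t))²), which rises from 0 at emergence to peak α₁ at
t = α₂; smaller α₃ gives sharper rise and decay.  Observations are linked
by moment-matched likelihoods: fixed-N ~ Gamma(shape z²/σ², rate z/σ²)
(mean z, SD σ) and Ndfa ~ Beta(zφ, (1 − z)φ) (mean z, variance
z(1 − z)/(1 + φ)).

Derived season functionals are computed per posterior draw, in closed form
where one exists:

- total fixed-N = curve value at season end t_end (default 2.0, i.e. R7;
  configurable since some schedules run to R8);
- t50 = β₂ − log(log 2 + e^(−β₃(t_end−β₂)))/β₃, the time to half the
  season-end value (a variant referenced to the asymptote β₁ is also
  provided; the season-end reference is the default);
- t_max_rate = β₂ exactly;
- AUC on [0, t_end] by composite Simpson on a fixed 401-node grid, which
  agrees with adaptive quadrature to better than 1e-6 relative error for
  all parameter values in the prior box (tested);
- for the Ndfa curve: peak α₁, peak time α₂, half-rise time
  α₂/(1 + α₃√log 2), and AUC.

## Priors

All priors are bounded and flat, encoding biological range rather than
shape: β₁ ~ U(0, 500) kg ha⁻¹, β₂ ~ U(0.25, 1.75), β₃ ~ U(1, 10),
σ ~ U(1, 300) kg ha⁻¹; α₁ ~ Beta(1, 1) on (0, 1), α₂ ~ U(0.2, 2),
α₃ ~ U(0.1, 2), φ ~ U(1, 300).  The "uninformative beta" on the Ndfa peak
is taken as Beta(1, 1); other shapes can be supplied and their density is
then included in the posterior.

## Sampler

Sampling is adaptive random-walk Metropolis-within-Gibbs: one Gaussian
random-walk update per scalar parameter per sweep, with proposals folded
back into the support by reflection (so every retained draw respects the
bounds by construction, and the proposal stays symmetric).  Proposal
scales start at 10% of each support range and adapt toward a 44%
acceptance rate by Robbins–Monro recursion (step t^(−0.6)) during warmup
only; after warmup the scales are frozen, so the retained chain is a valid
time-homogeneous Markov chain.  Chains (default 4) are vectorized in
numpy, initialized from independent prior draws, and all randomness
derives from the mandatory seed via `numpy.random.SeedSequence` — same
seed, same data, bit-identical draws.  "Retained draws" counts across
chains (default 15,000 = 4 × 3,750, configurable with thinning).
Convergence is reported per parameter as split R-hat and bulk ESS (via
arviz); R-hat ≥ 1.05 flags the fit with a warning rather than failing,
1.01–1.05 is logged as imperfect mixing.  Defaults (warmup 2,000) give
clean single-study fits in under a second; an independent ensemble-sampler
(emcee) cross-check of the posterior is part of the test suite.

An eligibility rule mirrors the synthesis inclusion criterion: a study
must contribute at least five distinct sampling times.  Ndfa observations
exactly at 0 or 1 are nudged by 1e-6 into the open interval; nonpositive
fixed-N observations are dropped with a logged warning.

### Pooled hierarchical fit

In the pooled model each study's process parameters are drawn from
truncated-normal population distributions restricted to the flat-prior
supports; population means carry flat hyperpriors over the same supports
and population SDs half-normal hyperpriors with scale one quarter of each
support range.  Noise parameters (σ, φ) remain study-level with flat
priors — the sources give no basis for pooling measurement error across
protocols.  The sampler updates all studies' copies of a parameter
simultaneously (they are conditionally independent given the population
layer), then the population means and SDs.  The centered parametrization
has the usual funnel — when the population SD is small the study
parameters are pinned to the mean and neither can move — so each sweep
also proposes a joint translation of a population mean together with all
its study-level values; only the likelihood and the truncation normalizer
change under that move, and it restores mixing (split R-hat drops from
~1.3 to ~1.1 at equal cost).  A single-study input falls back to the
independent fit with a warning.

## Environmental covariate screen

The covariate table holds one row per study: clay, SOM, pH, maturity
group, season length, sowing day of year, latitude, and
precipitation/radiation/temperature/VPD summarized over the vegetative
(VE–R1) and reproductive (R1–R7) periods.  Covariates are standardized to
mean 0, SD 1 (n−1 denominator; zero-variance columns excluded with a
warning).  Before regression, pairs with Pearson |r| ≥ 0.75 are pruned
greedily — the non-exempt member with the larger mean absolute correlation
is dropped — except that the period-summarized weather variables are never
dropped, so their vegetative/reproductive contrast stays inspectable.

Each functional is regressed on one covariate at a time, per posterior
draw index: the length-n_studies vector of draw d's functional values is
fit by OLS, giving a slope and r² per draw.  The slope distribution blends
posterior and between-study sampling uncertainty; it is summarized by the
median and the 2.5/97.5 percentiles, with significance defined as that
interval excluding zero.  Studies are fit independently, so pairing draws
across studies by index is arbitrary; when studies carry unequal draw
counts they are subsampled to the common minimum with a seeded generator,
making the pairing reproducible.  Permuting study order leaves all
summaries unchanged (tested).

## Synthetic generator

The generator emulates the structure of a 15-study field synthesis:

- **Covariates** are independent uniforms within the documented observed
  range of each variable (e.g. clay 23.8–34.2%, season length 96–119 d,
  rVPD 0.38–0.85 kPa).  An optional Gaussian-copula knob induces rank
  correlation between covariates (marginals stay uniform) to exercise the
  pruning rule; the real studies' joint covariate structure is not
  recoverable from published summaries, so independence is the default.
- **True parameters** default to β₁ = 130 kg ha⁻¹, β₂ = 1.0, β₃ = 5,
  σ = 20 kg ha⁻¹ and α₁ = 0.58, α₂ = 1.15, α₃ = 0.8, φ = 30 — a season
  totalling ~130 kg N ha⁻¹ fixed with peak Ndfa 58% shortly after R3, and
  noise consistent with field-scale scatter.  Per-study parameters may add
  covariate effects (slope per SD of a covariate) and Gaussian study
  noise, truncated to the prior supports with a warning (truncation
  distorts planted effects, so it is surfaced).
- **Observations** follow the exact gamma/beta observation models around
  the true curves at a stage-based schedule (default: the densest printed
  17-stage schedule, V2–R8; a 9-stage mid-density schedule is also
  packaged), with a configurable replicate count (default 4).  A
  deterministic mode emits the process values exactly.

One modeling consequence of the constant-σ gamma model deserves note:
early in the season the curve mean is orders of magnitude below σ, the
implied gamma shape is ≪ 1, and a large fraction of draws fall below the
smallest representable positive double.  Such a value is below any
measurable quantity, and coercing it to an arbitrary floor provably
distorts inference (a floored value rewards inflated early-season means;
in development this biased asymptote estimates by ~+13%).  The generator
therefore simply omits those fixed-N rows; every emitted value is an exact
draw from the stated model, and every study retains at least five distinct
sampling times.

### What passing tests do and do not show

The generator shares its curve and noise code with the fitter, so recovery
tests validate the inference machinery and the pipeline's internal
consistency — not the model's adequacy for real fields.  Real data bring
features the generator omits: temporally correlated replicate errors,
stage-assignment error in the phenology mapping, reference-plant and
B-value uncertainty in Ndfa, non-gamma heteroscedasticity, and covariates
measured with error.  Conclusions about real drivers of fixation require
the real multi-study data.

## Validation experiments (test suite)

- Functional oracles: inflection argmax vs β₂ within 1e-6; Simpson AUC vs
  adaptive quadrature within 1e-6 relative; closed-form t50 vs bisection
  within 1e-8; bell peak/zero-limit identities.
- Observation-model moments at 10⁵ draws within 3 Monte-Carlo SEs
  (SEs from the exact fourth central moments).
- Parameter recovery: 25 default-truth studies, independent fits at
  4 chains × 1,000 retained (warmup 3,000, thin 5): β₁ medians within 15%
  of truth in ≥ 80% of studies, β₂ 95%-CI coverage within [85%, 100%].
- Pipeline closure: a planted +15 kg ha⁻¹-per-SD season-length effect on
  β₁ (equal to one population SD, as no other between-study variance is
  added) is recovered by the covariate screen — positive slope median with
  a 95% interval excluding zero — in ≥ 9 of 10 seeded replicates.

Problem sizes (25 studies; 10 closure replicates of 15 studies at
4 chains × 500 retained) keep the full suite around two minutes on one
CPU while leaving the binomial pass margins comfortable.

## Known limitations

- The pooled model assumes truncated-normal population layers; the real
  between-study distribution of curve parameters is unknown.
- Draw pairing across independently fitted studies is arbitrary by
  construction; only summaries that are invariant to within-study draw
  order (medians, quantiles) should be interpreted.
- The 9-point sampling design is intrinsically slightly overconfident for
  β₂ (measured ~80% coverage of the 95% interval with converged,
  cross-checked posteriors); denser schedules restore near-nominal
  coverage.
- No model comparison (WAIC/LOO) and no covariate interactions are
  provided, by scope.
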