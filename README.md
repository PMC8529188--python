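# soyfix

Seasonal dynamics of biological nitrogen fixation (BNF) in soybean
(*Glycine max*): a reusable Python implementation of the full analysis
chain from raw isotope measurements to environmental drivers of the
seasonal fixation curve.

Soybean satisfies most of its large nitrogen demand through symbiotic
fixation, yet most field studies report a single late-season measurement.
Characterizing the *seasonal pattern* — when the fixation rate peaks, when
the plant's reliance on fixation (Ndfa) is maximal, and how much N is fixed
over the whole season — requires repeated in-season sampling and a model
that can compare seasons and sites on a common time axis.  `soyfix` is
aimed at agronomists and crop physiologists synthesizing such multi-study
¹⁵N datasets.

## What it computes

**Time axis.** Fehr growth stages (VE, V*n*, R1–R8) are mapped onto a
continuous relative-phenology scale *t* with 0 = emergence, 1 = R3
(beginning pod), 2 = R7 (physiological maturity), via an anchor table with
linear interpolation (`soyfix.phenology`).

**Ndfa and fixed-N.** From δ¹⁵N natural abundance,

    Ndfa = (δ¹⁵N_ref − δ¹⁵N_soy) / (δ¹⁵N_ref − B),    B = −2.54 ‰ default,

or from ¹⁵N dilution of a labeled soil pool (both the printed excess-ratio
form and its conventional complement are exposed).  Fixed-N (kg ha⁻¹) is
aboveground N — biomass · N concentration · plant density — times Ndfa
(`soyfix.isotopes`).

**Seasonal curves.** Cumulative fixed-N follows an increasing Gompertz
curve z(t) = β₁ exp(−exp(−β₃(t − β₂))) with asymptote β₁, maximum fixation
rate at t = β₂; observations are Gamma(mean z, SD σ).  Ndfa follows a
zero-intercept bell z(t) = α₁ exp(−((t − α₂)/(α₃t))²) peaking at α₁ when
t = α₂; observations are Beta(mean z, precision φ) (`soyfix.models`).

**Bayesian fits.** Per-study independent fits and a pooled hierarchical fit
(truncated-normal population layers) under bounded flat priors, sampled by
an adaptive Metropolis-within-Gibbs with reflection at the support bounds;
15,000 retained draws by default, split R-hat/ESS diagnostics, and per-draw
derived functionals — AUC, total fixed-N at season end, time to 50% of
total, inflection time (`soyfix.inference`).

**Environmental regression.** Posterior functionals across studies are
regressed, draw by draw, on centered-and-scaled soil/season/weather
covariates (one at a time, after |r| ≥ 0.75 correlation pruning that spares
the vegetative/reproductive weather summaries); slopes are summarized by
median and 95% credible interval (`soyfix.envreg`).

**Synthetic data.** A generator emulates a 15-study synthesis — covariates
within documented observed ranges, true curve parameters optionally linked
to covariates, stage-based sampling schedules, and noise from the exact
observation models — so the whole pipeline can be validated by parameter
recovery and effect-recovery closure (`soyfix.synthetic`).

## Worked example

Simulate a 15-study season with a planted season-length effect on the
fixed-N asymptote, fit every study, and screen covariates:

```python
from soyfix import envreg, inference, synthetic

cfg = synthetic.GeneratorConfig(seed=42,
                                covariate_effects={("beta1", "season_length"): 15.0})
ds = synthetic.generate_dataset(cfg)

obs = ds.observations[ds.observations.variable == "fixed_n"]
draws = {}
for k, (sid, grp) in enumerate(obs.groupby("study_id")):
    settings = inference.McmcSettings(seed=100 + k, chains=4, warmup=3000,
                                      retained_total=2000, thin=5)
    fit = inference.fit_study(grp, model="fixed_n", settings=settings, study=sid)
    draws[sid] = inference.derive_draws(fit).samples

print(draws["S01"][["beta1", "beta2", "total_fixed_n", "t50", "auc"]].median().round(2))

table = envreg.regress_functionals(draws, ds.covariates,
                                   functionals=["total_fixed_n"], seed=0)
print(table[table.covariate == "season_length"].iloc[0])
```

Output:

```
beta1            140.41
beta2              1.02
total_fixed_n    139.23
t50                1.10
auc              120.57
```

and for the season-length screen: slope median 13.1 kg ha⁻¹ per SD of
season length, 95% credible interval (10.9, 15.3), r² median 0.86,
significant.  Study S01's curve plateaus near 140 kg N ha⁻¹ with the
fastest fixation at t ≈ 1.0 (around R3) and half the season's fixation
accumulated by t ≈ 1.1; across studies the planted positive season-length
effect (+15 kg ha⁻¹ per SD) is recovered with an interval that excludes
zero.

The same pipeline runs from a shell:

```sh
soyfix simulate --seed 42 --out data/
soyfix fit --observations data/observations.csv --model fixed_n --seed 1 --out fits/
soyfix envreg --draws-dir fits/ --covariates data/covariates.csv --out slopes.csv
```

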