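"""Sampler contracts: prior support, determinism, eligibility, derived
draws, and small-scale posterior recovery (with an emcee cross-check)."""

import warnings

import numpy as np
import pandas as pd
import pytest

from soyfix import inference, models, synthetic
from soyfix.inference import (
    EligibilityError,
    FIXED_N_PRIORS,
    McmcSettings,
    NDFA_PRIORS,
    derive_draws,
    fit_pooled,
    fit_study,
    sample_prior,
)


def _study_obs(ds, sid, variable="fixed_n"):
    obs = ds.observations
    return obs[(obs.study_id == sid) & (obs.variable == variable)]


class TestSamplePrior:
    def test_draws_respect_support(self):
        draws = sample_prior(FIXED_N_PRIORS, 5000, seed=1)
        assert draws["beta1"].between(0, 500).all()
        assert draws["beta2"].between(0.25, 1.75).all()
        assert draws["beta3"].between(1, 10).all()
        assert draws["sigma"].between(1, 300).all()
        nd = sample_prior(NDFA_PRIORS, 5000, seed=1)
        assert nd["alpha1"].between(0, 1).all()
        assert nd["alpha3"].between(0.1, 2).all()

    def test_uniform_midpoint(self):
        draws = sample_prior(FIXED_N_PRIORS, 40000, seed=2)
        assert draws["beta2"].mean() == pytest.approx(1.0, abs=0.01)

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            sample_prior(FIXED_N_PRIORS, 0, seed=1)


class TestEligibility:
    def test_too_few_sampling_times(self, fast_settings):
        df = pd.DataFrame({"t": [0.5, 0.8, 1.2, 1.6], "value": [5.0, 30, 80, 110]})
        with pytest.raises(EligibilityError):
            fit_study(df, settings=fast_settings)

    def test_zero_observations(self, fast_settings):
        with pytest.raises(EligibilityError):
            fit_study(pd.DataFrame({"t": [], "value": []}), settings=fast_settings)

    def test_nonpositive_fixed_n_dropped(self, fast_settings, caplog):
        df = pd.DataFrame(
            {
                "t": [0.6, 0.8, 1.0, 1.2, 1.4, 1.7, 2.0] * 2,
                "value": [1.0, 10, 40, 80, 100, 120, 130] + [0.0] * 7,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_study(df, settings=fast_settings)
        assert d.diagnostics.n_obs == 7


class TestDeterminismAndSupport:
    def test_same_seed_same_draws(self, small_dataset, fast_settings):
        obs = _study_obs(small_dataset, "S01")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_study(obs, settings=fast_settings)
            b = fit_study(obs, settings=fast_settings)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_different_seed_differs(self, small_dataset, fast_settings):
        obs = _study_obs(small_dataset, "S01")
        other = McmcSettings(seed=99, chains=2, warmup=400, retained_total=400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_study(obs, settings=fast_settings)
            b = fit_study(obs, settings=other)
        assert not a.samples.equals(b.samples)

    def test_all_draws_inside_prior_support(self, small_dataset, fast_settings):
        obs = _study_obs(small_dataset, "S02")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_study(obs, settings=fast_settings)
        for name, prior in FIXED_N_PRIORS.items():
            col = d.samples[name]
            assert col.between(prior.lo, prior.hi).all()

    def test_retained_total_honored(self, small_dataset, fast_settings):
        obs = _study_obs(small_dataset, "S01")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_study(obs, settings=fast_settings)
        assert len(d.samples) == fast_settings.retained_total
        assert d.samples["chain"].nunique() == fast_settings.chains


class TestDeriveDraws:
    def test_constant_draws_give_oracle_functionals(self):
        df = pd.DataFrame(
            {
                "chain": [0] * 4,
                "draw": range(4),
                "beta1": [100.0] * 4,
                "beta2": [1.0] * 4,
                "beta3": [5.0] * 4,
                "sigma": [20.0] * 4,
            }
        )
        d = inference.PosteriorDraws(df, "fixed_n", ["beta1", "beta2", "beta3", "sigma"])
        out = derive_draws(d)
        np.testing.assert_allclose(out.samples["auc"], 88.59021898, atol=1e-5)
        np.testing.assert_allclose(out.samples["t50"], 1.07137, atol=1e-5)
        assert (out.samples["t_max_rate"] == out.samples["beta2"]).all()
        assert (out.samples["total_fixed_n"] <= out.samples["beta1"]).all()

    def test_ndfa_derivations(self):
        df = pd.DataFrame(
            {
                "chain": [0, 0],
                "draw": [0, 1],
                "alpha1": [0.58, 0.5],
                "alpha2": [1.15, 1.0],
                "alpha3": [0.8, 0.5],
                "phi": [30.0, 30.0],
            }
        )
        d = inference.PosteriorDraws(df, "ndfa", ["alpha1", "alpha2", "alpha3", "phi"])
        out = derive_draws(d)
        assert (out.samples["peak_ndfa"] == out.samples["alpha1"]).all()
        assert (out.samples["t_peak"] == out.samples["alpha2"]).all()
        np.testing.assert_allclose(
            out.samples["t_half_rise"],
            models.bell_half_rise(df["alpha2"].to_numpy(), df["alpha3"].to_numpy()),
        )


class TestRecovery:
    def test_single_study_beta1_recovery(self):
        """Posterior median of the asymptote lands near the generating
        value on a nine-timepoint, four-replicate design."""
        cfg = synthetic.GeneratorConfig(
            seed=21, n_studies=1, schedule=list(synthetic.NINE_STAGE_SCHEDULE)
        )
        ds = synthetic.generate_dataset(cfg)
        obs = _study_obs(ds, "S01")
        st = McmcSettings(seed=5, chains=4, warmup=2000, retained_total=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_study(obs, settings=st)
        assert d.samples["beta1"].median() == pytest.approx(130.0, rel=0.15)

    def test_matches_emcee_posterior(self):
        """Independent ensemble-sampler oracle agrees on posterior medians."""
        emcee = pytest.importorskip("emcee")
        cfg = synthetic.GeneratorConfig(
            seed=21, n_studies=1, schedule=list(synthetic.NINE_STAGE_SCHEDULE)
        )
        ds = synthetic.generate_dataset(cfg)
        obs = _study_obs(ds, "S01")
        t, y = inference._prepare_observations(obs, "fixed_n")
        lo = np.array([0, 0.25, 1, 1.0])
        hi = np.array([500, 1.75, 10, 300.0])

        def logpost(th):
            if np.any(th <= lo) or np.any(th >= hi):
                return -np.inf
            return float(inference._gamma_loglik(y, t, th[None, :])[0])

        rng = np.random.default_rng(0)
        p0 = np.column_stack(
            [rng.uniform(l, h, 24) for l, h in zip([80, 0.8, 2, 10], [250, 1.2, 7, 60])]
        )
        sam = emcee.EnsembleSampler(24, 4, logpost)
        sam.run_mcmc(p0, 3000, progress=False)
        ref = np.median(sam.get_chain(discard=1500, thin=5, flat=True), axis=0)

        st = McmcSettings(seed=5, chains=4, warmup=2000, retained_total=4000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_study(obs, settings=st)
        ours = d.samples[["beta1", "beta2", "beta3", "sigma"]].median().to_numpy()
        np.testing.assert_allclose(ours, ref, rtol=0.10)

    def test_rmse_decreases_with_sampling_density(self):
        """At the noise floor, denser stage schedules recover the asymptote
        more accurately; a three-timepoint design is not even eligible."""
        three = ["R3", "R5", "R7"]
        six = ["V6", "R2", "R3.5", "R5", "R6", "R7"]
        twelve = [
            "V5", "V6", "R1", "R2", "R3", "R3.5", "R4", "R4.5", "R5", "R5.5", "R6", "R7",
        ]
        st = McmcSettings(seed=5, chains=4, warmup=1500, retained_total=2000)

        def rmse(schedule):
            errs = []
            for s in range(4):
                cfg = synthetic.GeneratorConfig(
                    seed=300 + s, n_studies=1, schedule=schedule, truth={"sigma": 1.0}
                )
                ds = synthetic.generate_dataset(cfg)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    d = fit_study(_study_obs(ds, "S01"), settings=st)
                errs.append(d.samples["beta1"].median() - 130.0)
            return float(np.sqrt(np.mean(np.square(errs))))

        cfg3 = synthetic.GeneratorConfig(seed=300, n_studies=1, schedule=three)
        with pytest.raises(EligibilityError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_study(_study_obs(synthetic.generate_dataset(cfg3), "S01"), settings=st)
        assert rmse(twelve) < rmse(six)


class TestPooled:
    def test_population_mean_recovery(self):
        """Studies sharing one true inflection time: the population-mean
        posterior concentrates near it."""
        cfg = synthetic.GeneratorConfig(
            seed=31, n_studies=6, schedule=list(synthetic.NINE_STAGE_SCHEDULE)
        )
        ds = synthetic.generate_dataset(cfg)
        all_obs = {
            sid: g
            for sid, g in ds.observations[ds.observations.variable == "fixed_n"].groupby(
                "study_id"
            )
        }
        st = McmcSettings(seed=13, chains=4, warmup=3000, retained_total=2000, thin=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_pooled(all_obs, settings=st)
        assert d.samples["mu_beta2"].median() == pytest.approx(1.0, abs=0.1)
        assert {"mu_beta1", "tau_beta1", "beta1[S01]", "sigma[S06]"} <= set(d.samples.columns)

    def test_heterogeneous_studies_inflate_population_sd(self):
        cfg = synthetic.GeneratorConfig(
            seed=33,
            n_studies=6,
            schedule=list(synthetic.NINE_STAGE_SCHEDULE),
            param_noise_sd={"beta1": 60.0},
        )
        ds = synthetic.generate_dataset(cfg)
        all_obs = {
            sid: g
            for sid, g in ds.observations[ds.observations.variable == "fixed_n"].groupby(
                "study_id"
            )
        }
        st = McmcSettings(seed=13, chains=4, warmup=3000, retained_total=2000, thin=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = fit_pooled(all_obs, settings=st)
        assert np.quantile(d.samples["tau_beta1"], 0.025) > 5.0

    def test_single_study_falls_back(self, small_dataset, fast_settings):
        obs = _study_obs(small_dataset, "S01")
        with pytest.warns(UserWarning, match="falling back"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                d = fit_pooled({"S01": obs}, settings=fast_settings)
        assert d.study == "S01"


class TestPersistence:
    def test_write_read_round_trip(self, small_dataset, fast_settings, tmp_path):
        obs = _study_obs(small_dataset, "S01")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = derive_draws(fit_study(obs, settings=fast_settings, study="S01"))
        csv = tmp_path / "draws.csv"
        sidecar = tmp_path / "draws.json"
        d.write(csv, sidecar)
        again = inference.PosteriorDraws.read(csv, model="fixed_n", study="S01")
        pd.testing.assert_frame_equal(again.samples, d.samples)
        import json

        meta = json.loads(sidecar.read_text())
        assert meta["settings"]["seed"] == fast_settings.seed
        assert "rhat" in meta["diagnostics"]
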