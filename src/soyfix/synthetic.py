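"""Synthetic multi-study datasets with the structure the analysis assumes.

The generator emulates a synthesis of 15 field studies, each contributing
one seasonal curve sampled at a stage-based schedule with replicated
measurements.  For every study it draws environmental covariates within the
documented observed ranges, sets true curve parameters (optionally linked to
covariates, with study-level noise), and simulates noisy observations from
the same gamma / beta observation models the inference module fits — so
parameter recovery and full pipeline-closure experiments are exact
self-consistency checks of the analysis chain.

Defaults encode the study conditions of the source synthesis: 15 studies,
4 replicates, the densest printed sampling schedule (17 stages from V2 to
R8), season-end fixed-N averaging 130 kg ha-1 and peak Ndfa 0.58 near
relative phenology 1.15.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import envreg, inference, models, phenology

__all__ = [
    "TABLE_BOUNDS",
    "DENSE_SCHEDULE",
    "NINE_STAGE_SCHEDULE",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_covariates",
    "generate_curve_params",
    "generate_observations",
    "generate_dataset",
]

#: observed (min, max) per covariate across the emulated studies.
TABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "clay": (23.8, 34.2),  # %
    "som": (1.7, 3.1),  # g kg-1
    "ph": (5.7, 6.1),
    "maturity_group": (2.2, 3.9),
    "season_length": (96.0, 119.0),  # days
    "sowing_doy": (120.0, 155.0),
    "latitude": (39.0, 43.0),  # decimal degrees
    "v_precipitation": (97.0, 232.0),  # mm
    "v_radiation": (437.0, 909.0),  # MJ m-2
    "v_temperature": (17.9, 23.5),  # deg C
    "v_vpd": (0.15, 0.33),  # kPa
    "r_precipitation": (206.0, 358.0),
    "r_radiation": (1236.0, 1648.0),
    "r_temperature": (22.0, 24.7),
    "r_vpd": (0.38, 0.85),
}

#: densest printed schedule (17 stages, V2 through R8).
DENSE_SCHEDULE = [
    "V2", "V3", "V4", "V5", "V6", "R1", "R2", "R3", "R3.5", "R4", "R4.5",
    "R5", "R6", "R6.5", "R7", "R7.5", "R8",
]

#: nine-stage schedule (V6 through R7), the mid-density printed design.
NINE_STAGE_SCHEDULE = ["V6", "V8", "R2", "R3", "R4", "R5", "R5.5", "R6", "R7"]

_PARAM_PRIOR = {**inference.FIXED_N_PRIORS, **inference.NDFA_PRIORS}

#: true-parameter baselines: season-end fixed-N near 130 kg ha-1 and a peak
#: Ndfa of 0.58 reached at relative phenology 1.15.
_DEFAULT_TRUTH = {
    "beta1": 130.0,
    "beta2": 1.0,
    "beta3": 5.0,
    "sigma": 20.0,
    "alpha1": 0.58,
    "alpha2": 1.15,
    "alpha3": 0.8,
    "phi": 30.0,
}



class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic multi-study generator.

    ``covariate_effects`` maps (parameter, covariate) -> slope per 1 SD of
    the covariate; ``param_noise_sd`` adds study-level Gaussian scatter to a
    parameter.  ``covariate_correlation`` optionally supplies a Gaussian-
    copula correlation matrix (covariate order = ``covariate_bounds`` keys)
    to generate correlated covariates.  ``seed`` is mandatory.
    """

    seed: int
    n_studies: int = 15
    reps: int = 4
    schedule: list[str] = field(default_factory=lambda: list(DENSE_SCHEDULE))
    covariate_bounds: dict = field(default_factory=lambda: dict(TABLE_BOUNDS))
    truth: dict = field(default_factory=lambda: dict(_DEFAULT_TRUTH))
    covariate_effects: dict = field(default_factory=dict)
    param_noise_sd: dict = field(default_factory=dict)
    covariate_correlation: list | None = None
    noise: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("an integer seed is mandatory")
        self.truth = {**_DEFAULT_TRUTH, **self.truth}
        for name, (lo, hi) in self.covariate_bounds.items():
            if not lo < hi:
                raise ConfigError(f"covariate {name}: bounds must satisfy min < max")
        for p, v in self.truth.items():
            pr = _PARAM_PRIOR[p]
            open_support = pr.dist == "beta"  # the peak-Ndfa prior lives on (0, 1)
            inside = pr.lo < v < pr.hi if open_support else pr.lo <= v <= pr.hi
            if not inside:
                raise ConfigError(f"baseline {p}={v} outside the prior support ({pr.lo}, {pr.hi})")
        for (p, c) in self.covariate_effects:
            if p not in self.truth:
                raise ConfigError(f"covariate effect targets unknown parameter {p!r}")
            if c not in self.covariate_bounds:
                raise ConfigError(f"covariate effect references unknown covariate {c!r}")

    def as_dict(self):
        d = asdict(self)
        d["covariate_effects"] = {f"{p}:{c}": v for (p, c), v in self.covariate_effects.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        eff = d.pop("covariate_effects", {}) or {}
        parsed = {}
        for key, v in eff.items():
            p, c = key.split(":") if isinstance(key, str) else key
            parsed[(p, c)] = float(v)
        return cls(covariate_effects=parsed, **d)


@dataclass
class SyntheticDataset:
    covariates: pd.DataFrame
    truth: pd.DataFrame
    observations: pd.DataFrame
    config: GeneratorConfig

    def provenance(self) -> dict:
        return {"config": self.config.as_dict(), "config_digest": self.config.digest(),
                "seed": self.config.seed}

    def write(self, outdir):
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        self.observations.to_csv(out / "observations.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance(), fh, indent=2)


def _study_ids(n):
    return [f"S{i + 1:02d}" for i in range(n)]


def generate_covariates(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Per-study covariates, uniform within the configured bounds.

    With ``covariate_correlation`` set, values are drawn through a Gaussian
    copula so marginals stay uniform within bounds while pairwise rank
    correlation follows the supplied matrix.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    names = list(config.covariate_bounds)
    n = config.n_studies
    if config.covariate_correlation is not None:
        corr = np.asarray(config.covariate_correlation, dtype=float)
        if corr.shape != (len(names), len(names)):
            raise ConfigError("covariate_correlation must be square over all covariates")
        z = rng.multivariate_normal(np.zeros(len(names)), corr, size=n, method="cholesky")
        from scipy.special import ndtr

        u = ndtr(z)
    else:
        u = rng.random((n, len(names)))
    data = {"study_id": _study_ids(n)}
    for k, name in enumerate(names):
        lo, hi = config.covariate_bounds[name]
        data[name] = lo + (hi - lo) * u[:, k]
    return pd.DataFrame(data)


def generate_curve_params(cov: pd.DataFrame, config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """True per-study curve parameters: baseline + covariate effects (per SD
    of the covariate) + optional study noise, truncated to the prior
    support (truncation is warned about, since it distorts planted
    effects)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    std = envreg.center_scale(cov) if config.covariate_effects else None
    n = len(cov)
    out = {"study_id": cov["study_id"].tolist()}
    for p, base in config.truth.items():
        vals = np.full(n, float(base))
        for (pp, c), slope in config.covariate_effects.items():
            if pp == p:
                vals = vals + slope * std.table[c].to_numpy()
        sd = config.param_noise_sd.get(p, 0.0)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, n)
        pr = _PARAM_PRIOR[p]
        # only the open-interval (beta-family) priors need an interior margin
        margin = 1e-9 * (pr.hi - pr.lo) if pr.dist == "beta" else 0.0
        clipped = np.clip(vals, pr.lo + margin, pr.hi - margin)
        n_trunc = int(np.sum(np.abs(clipped - vals) > 2 * margin))
        if n_trunc == n:
            raise ConfigError(f"covariate effects push every study's {p} outside the prior support")
        if n_trunc:
            warnings.warn(
                f"{n_trunc} studies' {p} truncated to the prior support", UserWarning, stacklevel=2
            )
        out[p] = clipped
    return pd.DataFrame(out)


def generate_observations(
    params: pd.DataFrame,
    schedule: list[str] | None = None,
    config: GeneratorConfig | None = None,
    rng=None,
    anchors: phenology.StageAnchorTable | None = None,
) -> pd.DataFrame:
    """Simulate the long observation table from true curve parameters.

    For each study, scheduled stage and replicate, fixed-N is drawn from the
    gamma observation model around the Gompertz curve and Ndfa from the beta
    model around the bell curve.  With ``config.noise`` false the process
    values are returned exactly (deterministic mode).

    Early in the season the gamma model's mean sits far below its SD, and a
    draw can fall below the smallest representable positive double; such a
    value is below any measurable quantity, so its fixed-N row is simply not
    emitted (the Ndfa row is kept).  The table therefore stays strictly
    positive without distorting the observation model.
    """
    if config is None:
        config = GeneratorConfig(seed=0)
    if schedule is None:
        schedule = config.schedule
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    t_vals = np.array([phenology.stage_to_relative(s, anchors) for s in schedule])
    rows = []
    for _, p in params.iterrows():
        z_fix = models.gompertz(t_vals, p["beta1"], p["beta2"], p["beta3"])
        z_ndfa = models.bell_zero(t_vals, p["alpha1"], p["alpha2"], p["alpha3"])
        z_ndfa = np.clip(z_ndfa, 1e-9, 1.0 - 1e-9)
        for i, (stage, t) in enumerate(zip(schedule, t_vals)):
            for rep in range(1, config.reps + 1):
                if config.noise:
                    shape, rate = models.gamma_obs_params(max(z_fix[i], 1e-12), p["sigma"])
                    y_fix = rng.gamma(shape, 1.0 / rate)
                    a, b = models.beta_obs_params(z_ndfa[i], p["phi"])
                    y_ndfa = rng.beta(a, b)
                else:
                    y_fix, y_ndfa = z_fix[i], z_ndfa[i]
                y_ndfa = float(np.clip(y_ndfa, 1e-9, 1.0 - 1e-9))
                base = dict(study_id=p["study_id"], rep=rep, stage=stage, t=float(t))
                if y_fix > 0.0:
                    rows.append(dict(base, variable="fixed_n", value=float(y_fix)))
                rows.append(dict(base, variable="ndfa", value=y_ndfa))
    return pd.DataFrame(rows)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Covariates, true parameters and observations in one reproducible
    pass; all randomness flows from ``config.seed``."""
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)]
    cov = generate_covariates(config, rng=streams[0])
    truth = generate_curve_params(cov, config, rng=streams[1])
    obs = generate_observations(truth, config.schedule, config, rng=streams[2])
    return SyntheticDataset(covariates=cov, truth=truth, observations=obs, config=config)
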