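"""Seasonal process curves, observation-model parametrizations, and derived
curve functionals.

Two deterministic process functions describe the season on the relative
phenology axis t (0 = emergence, 1 = R3, 2 = R7):

* cumulative fixed-N follows an increasing Gompertz curve
  ``beta1 * exp(-exp(-beta3 * (t - beta2)))`` with asymptote beta1 (kg ha-1),
  inflection — the moment of maximum fixation rate — at t = beta2, and rate
  multiplier beta3;
* Ndfa follows a zero-intercept bell curve
  ``alpha1 * exp(-((t - alpha2) / (alpha3 * t))**2)`` that rises from 0 at
  emergence to a peak alpha1 at t = alpha2 and decays with shape alpha3.

Observations are linked to the process by moment-matched likelihoods: a
gamma for fixed-N, parametrized by mean z and standard deviation sigma, and
a beta for Ndfa, parametrized by mean z and precision phi.

All functions are numpy-vectorized in both t and the parameters, so the same
code serves scalar evaluation, forward simulation, and per-draw posterior
functionals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import integrate

__all__ = [
    "GompertzParams",
    "BellParams",
    "DerivedQuantities",
    "gompertz",
    "bell_zero",
    "gamma_obs_params",
    "beta_obs_params",
    "gompertz_t50",
    "gompertz_auc",
    "derive_gompertz",
    "bell_half_rise",
    "bell_auc",
    "derive_bell",
    "AUC_NODES",
    "SEASON_END",
]

#: default integration endpoint: R7 (beginning physiological maturity).
SEASON_END = 2.0
#: nodes of the fixed composite-Simpson grid used for AUC.
AUC_NODES = 401


@dataclass(frozen=True)
class GompertzParams:
    """Fixed-N process parameters: asymptote (kg ha-1), inflection time
    (relative phenology), rate multiplier, and observation SD (kg ha-1)."""

    beta1: float
    beta2: float
    beta3: float
    sigma: float

    def as_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class BellParams:
    """Ndfa process parameters: peak fraction, time of peak (relative
    phenology), decay shape, and beta-likelihood precision."""

    alpha1: float
    alpha2: float
    alpha3: float
    phi: float

    def as_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class DerivedQuantities:
    """Season-level functionals of a fitted fixed-N curve."""

    auc: float  # kg ha-1 * relative-phenology units
    total_fixed_n: float  # curve value at season end, kg ha-1
    t50: float  # time to 50% of season-end fixed-N
    t_max_rate: float  # inflection time (= beta2)

    def as_dict(self):
        return asdict(self)


def gompertz(t, beta1, beta2, beta3):
    """Increasing Gompertz curve; strictly increasing in t with asymptote
    beta1 and maximum slope at t = beta2."""
    t = np.asarray(t, dtype=float)
    return beta1 * np.exp(-np.exp(-beta3 * (t - beta2)))


def bell_zero(t, alpha1, alpha2, alpha3):
    """Zero-intercept bell curve: 0 at t = 0 (limit convention), unique
    maximum alpha1 at t = alpha2."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (t - alpha2) / (alpha3 * t)
        out = alpha1 * np.exp(-np.square(z))
    out = np.where(t == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def gamma_obs_params(z, sigma):
    """Gamma (shape, rate) with mean z and standard deviation sigma."""
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(z <= 0) or np.any(sigma <= 0):
        raise ValueError("gamma observation model requires z > 0 and sigma > 0")
    var = sigma**2
    return z**2 / var, z / var


def beta_obs_params(z, phi):
    """Beta (a, b) = (z*phi, (1-z)*phi): mean z, variance z(1-z)/(1+phi)."""
    z = np.asarray(z, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(z <= 0) or np.any(z >= 1):
        raise ValueError("beta observation model requires z in the open interval (0, 1)")
    if np.any(phi <= 0):
        raise ValueError("beta observation model requires phi > 0")
    return z * phi, (1.0 - z) * phi


# ---------------------------------------------------------------------------
# derived functionals


def gompertz_t50(beta2, beta3, t_end=SEASON_END, of_asymptote=False):
    """Time at which the Gompertz curve reaches half its reference value.

    By default the reference is the curve value at ``t_end`` (season-end
    accumulation); with ``of_asymptote=True`` it is the asymptote beta1.
    Closed form: the half-crossing of beta1*exp(-exp(-beta3*(t - beta2)))
    against 0.5*exp(-exp(-beta3*(t_end - beta2))) solves to

        t50 = beta2 - log(log 2 + exp(-beta3*(t_end - beta2))) / beta3

    and against 0.5 (asymptote reference) to beta2 - log(log 2)/beta3.
    """
    beta2 = np.asarray(beta2, dtype=float)
    beta3 = np.asarray(beta3, dtype=float)
    if of_asymptote:
        return beta2 - np.log(np.log(2.0)) / beta3
    return beta2 - np.log(np.log(2.0) + np.exp(-beta3 * (t_end - beta2))) / beta3


def gompertz_auc(beta1, beta2, beta3, t_end=SEASON_END, nodes=AUC_NODES):
    """Area under the Gompertz curve on [0, t_end] by composite Simpson on a
    fixed grid; vectorized over parameter arrays."""
    grid = np.linspace(0.0, t_end, nodes)
    b1, b2, b3 = np.broadcast_arrays(
        np.asarray(beta1, float), np.asarray(beta2, float), np.asarray(beta3, float)
    )
    vals = gompertz(grid, b1[..., None], b2[..., None], b3[..., None])
    out = integrate.simpson(vals, x=grid, axis=-1)
    return out if np.ndim(beta1) else float(out)


def derive_gompertz(p: GompertzParams, t_end: float = SEASON_END) -> DerivedQuantities:
    """Season functionals of a fixed-N curve: AUC on [0, t_end], total
    fixed-N (value at t_end), time to 50% of total, and inflection time."""
    return DerivedQuantities(
        auc=float(gompertz_auc(p.beta1, p.beta2, p.beta3, t_end)),
        total_fixed_n=float(gompertz(t_end, p.beta1, p.beta2, p.beta3)),
        t50=float(gompertz_t50(p.beta2, p.beta3, t_end)),
        t_max_rate=p.beta2,
    )


def bell_half_rise(alpha2, alpha3):
    """Time on the rising limb at which the bell curve reaches half its
    peak: alpha2 / (1 + alpha3 * sqrt(log 2))."""
    alpha2 = np.asarray(alpha2, dtype=float)
    alpha3 = np.asarray(alpha3, dtype=float)
    return alpha2 / (1.0 + alpha3 * np.sqrt(np.log(2.0)))


def bell_auc(alpha1, alpha2, alpha3, t_end=SEASON_END, nodes=AUC_NODES):
    """Area under the bell curve on [0, t_end], composite Simpson."""
    grid = np.linspace(0.0, t_end, nodes)
    a1, a2, a3 = np.broadcast_arrays(
        np.asarray(alpha1, float), np.asarray(alpha2, float), np.asarray(alpha3, float)
    )
    vals = bell_zero(grid, a1[..., None], a2[..., None], a3[..., None])
    out = integrate.simpson(vals, x=grid, axis=-1)
    return out if np.ndim(alpha1) else float(out)


def derive_bell(p: BellParams, t_end: float = SEASON_END) -> dict:
    """Season functionals of an Ndfa curve: AUC, peak Ndfa, time of peak,
    and half-rise time."""
    return {
        "auc": float(bell_auc(p.alpha1, p.alpha2, p.alpha3, t_end)),
        "peak_ndfa": p.alpha1,
        "t_peak": p.alpha2,
        "t_half_rise": float(bell_half_rise(p.alpha2, p.alpha3)),
    }
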