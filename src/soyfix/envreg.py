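"""Regression of posterior seasonal functionals on environmental covariates.

Each study contributes a posterior distribution of seasonal functionals
(AUC, total fixed-N, inflection time beta2) and one row of environmental
descriptors (soil texture and chemistry, season structure, and weather
summarized over the vegetative VE-R1 and reproductive R1-R7 periods).  For
every posterior draw index the functional values across studies are
regressed by ordinary least squares on one centered-and-scaled covariate at
a time; the resulting slope distribution blends posterior and sampling
uncertainty and is summarized by its median and equal-tailed 95% credible
interval, with significance declared when that interval excludes zero.

Covariates with pairwise Pearson |r| above a threshold (default 0.75) are
pruned greedily before regression, except the vegetative/reproductive
weather pairs, which are always retained so that their period-specific
associations stay inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATE_COLUMNS",
    "WEATHER_COVARIATES",
    "StandardizedCovariates",
    "SlopeSummary",
    "center_scale",
    "prune_correlated",
    "slope_distribution",
    "regress_functionals",
]

#: covariate schema: one row per study, keyed by study_id.
COVARIATE_COLUMNS = [
    "clay",
    "som",
    "ph",
    "maturity_group",
    "season_length",
    "sowing_doy",
    "latitude",
    "v_precipitation",
    "v_radiation",
    "v_temperature",
    "v_vpd",
    "r_precipitation",
    "r_radiation",
    "r_temperature",
    "r_vpd",
]

#: period-summarized weather variables, exempt from correlation pruning.
WEATHER_COVARIATES = [c for c in COVARIATE_COLUMNS if c.startswith(("v_", "r_"))]


@dataclass
class StandardizedCovariates:
    """Centered/scaled covariate table with the transform stored for
    invertibility."""

    table: pd.DataFrame  # standardized values, indexed by study_id
    mean: pd.Series
    sd: pd.Series

    def original(self) -> pd.DataFrame:
        return self.table * self.sd + self.mean


@dataclass
class SlopeSummary:
    covariate: str
    median: float
    lo: float  # 2.5th percentile
    hi: float  # 97.5th percentile
    r2_median: float
    significant: bool

    def as_dict(self):
        return {
            "covariate": self.covariate,
            "slope_median": self.median,
            "slope_q025": self.lo,
            "slope_q975": self.hi,
            "r2_median": self.r2_median,
            "significant": self.significant,
        }


def _covariate_frame(cov: pd.DataFrame) -> pd.DataFrame:
    df = cov.set_index("study_id") if "study_id" in cov.columns else cov.copy()
    return df.select_dtypes(include=[np.number])


def center_scale(cov: pd.DataFrame) -> StandardizedCovariates:
    """Standardize each covariate to mean 0 and SD 1 (n-1 denominator).

    Zero-variance covariates cannot be scaled and are excluded with a
    warning.  Requires at least three studies.
    """
    df = _covariate_frame(cov)
    if len(df) < 3:
        raise ValueError(f"standardization requires >= 3 studies, got {len(df)}")
    sd = df.std(ddof=1)
    dead = sd[sd == 0.0].index.tolist()
    if dead:
        warnings.warn(f"excluding zero-variance covariates: {dead}", UserWarning, stacklevel=2)
        df = df.drop(columns=dead)
        sd = sd.drop(dead)
    mean = df.mean()
    return StandardizedCovariates(table=(df - mean) / sd, mean=mean, sd=sd)


def prune_correlated(
    cov: pd.DataFrame,
    threshold: float = 0.75,
    exempt: list[str] | None = None,
) -> list[str]:
    """Greedy correlation pruning; returns the retained covariate names.

    While any pair with |Pearson r| >= threshold has a non-exempt member,
    drop the non-exempt member with the larger mean absolute correlation
    against all remaining covariates.  Exempt covariates (by default the
    vegetative/reproductive weather summaries) are never dropped, even from
    pairs that exceed the threshold.
    """
    df = _covariate_frame(cov)
    if len(df) < 3:
        raise ValueError("correlation pruning requires >= 3 studies")
    if exempt is None:
        exempt = [c for c in WEATHER_COVARIATES if c in df.columns]
    exempt = set(exempt)
    kept = list(df.columns)
    while True:
        corr = df[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst, worst_pair = threshold, None
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a in exempt and b in exempt:
                    continue
                r = corr.loc[a, b]
                if r >= worst:
                    worst, worst_pair = r, (a, b)
        if worst_pair is None:
            return kept
        droppable = [c for c in worst_pair if c not in exempt]
        victim = max(droppable, key=lambda c: corr.loc[c, kept].mean())
        kept.remove(victim)


def _align_draws(response_draws: dict[str, np.ndarray], rng=None) -> np.ndarray:
    """Stack per-study draw vectors into an (n_draws, n_studies) matrix,
    subsampling each study to the common minimum length when they differ."""
    lengths = {s: len(v) for s, v in response_draws.items()}
    m = min(lengths.values())
    cols = []
    for s, v in response_draws.items():
        v = np.asarray(v, dtype=float)
        if len(v) > m:
            if rng is None:
                rng = np.random.default_rng(0)
            v = v[np.sort(rng.choice(len(v), size=m, replace=False))]
        cols.append(v)
    return np.column_stack(cols)


def slope_distribution(
    response_draws: dict[str, np.ndarray],
    covariate: pd.Series | np.ndarray,
    name: str = "covariate",
    rng=None,
) -> SlopeSummary:
    """Draw-wise OLS of a posterior functional on one standardized covariate.

    ``response_draws`` maps study -> posterior draw vector of the functional;
    ``covariate`` holds one standardized value per study in the same order
    (or indexed by study when a Series).  For each draw index the length-
    n_studies response vector is regressed on the covariate; the slope and
    r-squared distributions over draw indices are summarized by median and
    2.5/97.5 percentiles.
    """
    studies = list(response_draws)
    if len(studies) < 3:
        raise ValueError("slope regression requires >= 3 studies")
    if isinstance(covariate, pd.Series):
        x = covariate.loc[studies].to_numpy(dtype=float)
    else:
        x = np.asarray(covariate, dtype=float)
    Y = _align_draws(response_draws, rng=rng)  # (n_draws, n_studies)
    xc = x - x.mean()
    sxx = np.sum(xc**2)
    yc = Y - Y.mean(axis=1, keepdims=True)
    slopes = yc @ xc / sxx
    ss_tot = np.sum(yc**2, axis=1)
    ss_reg = slopes**2 * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / ss_tot, 0.0)
    lo, med, hi = np.quantile(slopes, [0.025, 0.5, 0.975])
    return SlopeSummary(
        covariate=name,
        median=float(med),
        lo=float(lo),
        hi=float(hi),
        r2_median=float(np.median(r2)),
        significant=bool(lo > 0.0 or hi < 0.0),
    )


def regress_functionals(
    draws_by_study: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
    functionals: list[str] = ("auc", "total_fixed_n", "t_max_rate"),
    threshold: float = 0.75,
    seed: int = 0,
) -> pd.DataFrame:
    """Full covariate screen: prune correlated covariates, standardize, and
    regress each functional's posterior draws on each retained covariate.

    ``draws_by_study`` maps study -> derived draws frame (must contain the
    functional columns); ``covariates`` follows the COVARIATE_COLUMNS schema
    with a study_id column aligned to the draw keys.  Returns one tidy row
    per (functional, covariate).
    """
    cov_ids = set(map(str, covariates["study_id"]))
    draw_ids = set(map(str, draws_by_study))
    if cov_ids != draw_ids:
        raise ValueError(
            f"study ids differ between draws and covariates: "
            f"only-in-draws={sorted(draw_ids - cov_ids)}, only-in-covariates={sorted(cov_ids - draw_ids)}"
        )
    kept = prune_correlated(covariates, threshold=threshold)
    std = center_scale(covariates)
    kept = [c for c in kept if c in std.table.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for fn in functionals:
        responses = {str(s): df[fn].to_numpy() for s, df in draws_by_study.items()}
        for c in kept:
            x = std.table[c]
            x.index = std.table.index.map(str)
            summ = slope_distribution(responses, x, name=c, rng=rng)
            rows.append(dict({"functional": fn}, **summ.as_dict()))
    return pd.DataFrame(rows)
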