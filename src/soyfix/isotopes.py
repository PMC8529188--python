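"""Ndfa and fixed-N computation from nitrogen-isotope measurements.

Ndfa (the fraction of plant N derived from the atmosphere by symbiotic
fixation) is estimated either from natural-abundance delta-15N of soybean
versus a non-fixing reference plant, or by dilution of an applied 15N-labeled
soil pool.  Fixed-N (kg ha-1) is aboveground N times Ndfa, with aboveground
N the product of per-plant biomass, tissue N concentration and plant
density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import phenology

__all__ = [
    "NaturalAbundanceSample",
    "DilutionSample",
    "PlantSample",
    "IsotopeError",
    "NdfaClippedWarning",
    "ATMOSPHERE_ATOM_PCT_15N",
    "DEFAULT_B_VALUE",
    "ndfa_natural_abundance",
    "ndfa_dilution",
    "aboveground_n",
    "fixed_n",
    "soil_pool_decay",
    "read_measurements",
    "measurements_to_long",
]

#: atom% 15N of atmospheric N2, the international standard.
ATMOSPHERE_ATOM_PCT_15N = 0.3663

#: delta-15N (per mil) of a fully fixation-dependent soybean; corrects
#: isotopic fractionation in the natural-abundance method.
DEFAULT_B_VALUE = -2.54


class IsotopeError(ValueError):
    """Invalid isotope or plant-sample inputs."""


class NdfaClippedWarning(UserWarning):
    """Raw Ndfa fell outside [0, 1] and was clipped."""


@dataclass(frozen=True)
class NaturalAbundanceSample:
    d15n_reference: float
    d15n_soybean: float
    b_value: float = DEFAULT_B_VALUE


@dataclass(frozen=True)
class DilutionSample:
    atomp_soybean: float
    atomp_soilpool: float
    atomp_atmosphere: float = ATMOSPHERE_ATOM_PCT_15N


@dataclass(frozen=True)
class PlantSample:
    biomass_per_plant: float  # g
    n_concentration: float  # g g-1
    plant_density: float  # plants ha-1
    ndfa: float = np.nan  # fraction

    def __post_init__(self):
        if min(self.biomass_per_plant, self.n_concentration, self.plant_density) < 0:
            raise IsotopeError("plant sample fields must be nonnegative")
        if self.n_concentration > 1:
            raise IsotopeError("N concentration is a mass fraction and cannot exceed 1")


def _clip_fraction(raw: float, what: str) -> float:
    if raw < -1e-12 or raw > 1.0 + 1e-12:  # no warning for float-epsilon excursions
        warnings.warn(
            f"raw {what} = {raw:.4f} outside [0, 1]; clipped", NdfaClippedWarning, stacklevel=3
        )
    return float(min(1.0, max(0.0, raw)))


def ndfa_natural_abundance(sample: NaturalAbundanceSample) -> float:
    """Ndfa fraction by the natural-abundance method.

    (ref - soy) / (ref - B): zero when the soybean matches the reference
    plant (no fixation) and one when it matches the B-value (all N fixed).
    Values outside [0, 1], which routine field delta-15N noise can produce,
    are clipped with a warning.
    """
    denom = sample.d15n_reference - sample.b_value
    if denom == 0.0:
        raise IsotopeError("reference delta-15N equals the B-value; Ndfa is undefined")
    raw = (sample.d15n_reference - sample.d15n_soybean) / denom
    return _clip_fraction(raw, "Ndfa (natural abundance)")


def ndfa_dilution(sample: DilutionSample, as_printed: bool = True) -> float:
    """Ndfa fraction by the 15N-dilution method.

    With ``as_printed=True`` returns (soy - atm) / (soil - atm), the excess
    enrichment of the plant relative to the labeled soil pool.  Under the
    standard dilution logic that ratio is the fraction of plant N traced to
    the *soil* pool; ``as_printed=False`` returns its complement
    1 - (soy - atm)/(soil - atm), the conventional Ndfa.  Both forms are
    exposed because the source literature prints the former under the Ndfa
    name.  Works on any self-consistent abundance scale (atom% or delta).
    """
    denom = sample.atomp_soilpool - sample.atomp_atmosphere
    if denom == 0.0:
        raise IsotopeError("soil pool abundance equals atmosphere; Ndfa is undefined")
    ratio = (sample.atomp_soybean - sample.atomp_atmosphere) / denom
    raw = ratio if as_printed else 1.0 - ratio
    return _clip_fraction(raw, "Ndfa (dilution)")


def aboveground_n(sample: PlantSample) -> float:
    """Aboveground N in kg ha-1 from per-plant biomass (g), N concentration
    (g g-1) and plant density (plants ha-1)."""
    grams_per_ha = sample.biomass_per_plant * sample.n_concentration * sample.plant_density
    return grams_per_ha / 1000.0


def fixed_n(aboveground_n_kg_ha: float, ndfa: float) -> float:
    """Fixed-N (kg ha-1) = aboveground N times the Ndfa fraction."""
    if not 0.0 <= ndfa <= 1.0:
        raise IsotopeError(f"ndfa must be a fraction in [0, 1], got {ndfa}")
    return aboveground_n_kg_ha * ndfa


def soil_pool_decay(a: float, b: float, c: float) -> Callable[[float], float]:
    """Three-parameter exponential-decay model of the soil inorganic pool's
    atom% 15N as a function of soil mineral N content: a + b*exp(-c*x).

    The coefficients are site calibrations supplied by the user; only the
    functional family is fixed here, and any callable of soil mineral N may
    be substituted.
    """

    def pool(x: float) -> float:
        return a + b * np.exp(-c * x)

    return pool


# ---------------------------------------------------------------------------
# tabular interface

_WIDE_COLUMNS = ["study_id", "rep", "stage"]


def read_measurements(path) -> pd.DataFrame:
    """Read a wide per-sample measurement CSV.

    Expected columns: study_id, rep, stage, biomass_g, n_conc, density and
    either (d15n_soy, d15n_ref) for the natural-abundance method or
    (atomp_soy, atomp_soil) for the dilution method; an optional ndfa column
    short-circuits the isotope computation.
    """
    df = pd.read_csv(path)
    missing = [c for c in _WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise IsotopeError(f"measurement table missing required columns: {missing}")
    return df


def measurements_to_long(
    df: pd.DataFrame,
    anchors: phenology.StageAnchorTable | None = None,
    b_value: float = DEFAULT_B_VALUE,
    dilution_as_printed: bool = False,
) -> pd.DataFrame:
    """Reduce a wide measurement table to long observations for inference.

    Returns a frame with columns (study_id, rep, stage, t, variable, value)
    holding one ``ndfa`` row (fraction) and, where biomass data permit, one
    ``fixed_n`` row (kg ha-1) per input sample.
    """
    rows = []
    for _, r in df.iterrows():
        t = phenology.stage_to_relative(str(r["stage"]), anchors)
        if "ndfa" in df.columns and pd.notna(r.get("ndfa")):
            eta = _clip_fraction(float(r["ndfa"]), "Ndfa (direct)")
        elif {"d15n_soy", "d15n_ref"} <= set(df.columns) and pd.notna(r.get("d15n_soy")):
            eta = ndfa_natural_abundance(
                NaturalAbundanceSample(float(r["d15n_ref"]), float(r["d15n_soy"]), b_value)
            )
        elif {"atomp_soy", "atomp_soil"} <= set(df.columns) and pd.notna(r.get("atomp_soy")):
            eta = ndfa_dilution(
                DilutionSample(float(r["atomp_soy"]), float(r["atomp_soil"])),
                as_printed=dilution_as_printed,
            )
        else:
            raise IsotopeError(
                f"no Ndfa source for study {r['study_id']} rep {r['rep']} stage {r['stage']}"
            )
        base = dict(study_id=r["study_id"], rep=r["rep"], stage=str(r["stage"]), t=t)
        rows.append(dict(base, variable="ndfa", value=eta))
        if {"biomass_g", "n_conc", "density"} <= set(df.columns) and pd.notna(r.get("biomass_g")):
            agn = aboveground_n(
                PlantSample(float(r["biomass_g"]), float(r["n_conc"]), float(r["density"]))
            )
            rows.append(dict(base, variable="fixed_n", value=fixed_n(agn, eta)))
    return pd.DataFrame(rows)
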