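"""Power calculations and smoking-specific bias corrections for DLW TEE.

Two families of desk calculations accompany the cohort analysis:

* sample-size arithmetic — the standard error of a two-group TEE difference
  and the smallest difference detectable at a given significance level and
  power (normal approximation);
* smoking corrections — (a) the projected TEE increment from a transient
  post-cigarette elevation of resting metabolic rate, and (b) the
  overestimation of DLW-measured CO2 production caused by inhaling CO2 from
  burning tobacco, expressed in mol/day, as a percentage of true CO2
  production, and in kcal/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from . import constants as c
from .dlw import weir_tee
from .errors import InvalidInputError

__all__ = [
    "PowerSpec",
    "CorrectionParams",
    "se_difference",
    "minimal_detectable_difference",
    "rmr_projection",
    "inhaled_co2_mol",
    "co2_overestimate_pct",
    "co2_energy_correction",
    "pct_of_tee_correction",
]


@dataclass(frozen=True)
class PowerSpec:
    """Two-sided test at level ``alpha`` with target ``power`` for a
    difference whose standard error is ``se_diff`` (kcal/day)."""

    se_diff: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise InvalidInputError("alpha and power must be in (0, 1)")
        if self.se_diff <= 0:
            raise InvalidInputError("se_diff must be positive")


@dataclass(frozen=True)
class CorrectionParams:
    """Constants of the cigarette CO2 and RMR-elevation models.

    Defaults: 0.7 g combustible material per cigarette of which 40% is
    carbon, two-thirds of the produced CO2 inhaled; RMR elevated by 5% for
    1 hour after each cigarette on a 1200 kcal/day resting rate.
    """

    g_combustible_per_cig: float = 0.7
    inhaled_fraction: float = 2.0 / 3.0
    carbon_mass_fraction: float = 0.40
    rq: float = c.DEFAULT_RQ
    rmr_kcal_d: float = 1200.0
    elevation_fraction: float = 0.05
    elevated_hours_per_cig: float = 1.0

    def __post_init__(self) -> None:
        for name in ("inhaled_fraction", "carbon_mass_fraction", "elevation_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if self.g_combustible_per_cig < 0:
            raise InvalidInputError("combustible grams must be >= 0")


def se_difference(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Standard error of a difference of two independent group means:
    sqrt(sd1^2/n1 + sd2^2/n2)."""
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("group sizes must be >= 2")
    if sd1 < 0 or sd2 < 0:
        raise InvalidInputError("SDs must be >= 0")
    return math.sqrt(sd1**2 / n1 + sd2**2 / n2)


def minimal_detectable_difference(spec: PowerSpec) -> float:
    """Smallest mean difference detectable at the spec's alpha and power,
    normal approximation: (z_{1-alpha/2} + z_{power}) * se_diff."""
    return float((norm.ppf(1 - spec.alpha / 2) + norm.ppf(spec.power)) * spec.se_diff)


def rmr_projection(params: CorrectionParams, cigs_per_day: float) -> float:
    """Projected daily TEE increment from transient post-cigarette RMR
    elevation: fraction x hourly RMR x hours per cigarette x cigarettes."""
    if cigs_per_day < 0:
        raise InvalidInputError("cigarettes per day must be >= 0")
    if cigs_per_day * params.elevated_hours_per_cig > 24.0:
        raise InvalidInputError("elevated time exceeds 24 h/day")
    return (params.elevation_fraction * (params.rmr_kcal_d / 24.0)
            * params.elevated_hours_per_cig * cigs_per_day)


def inhaled_co2_mol(params: CorrectionParams, cigs_per_day: float) -> float:
    """Moles of cigarette-derived CO2 absorbed per day: combusted carbon
    converted to CO2, times the inhaled fraction."""
    if cigs_per_day < 0:
        raise InvalidInputError("cigarettes per day must be >= 0")
    carbon_g = cigs_per_day * params.g_combustible_per_cig * params.carbon_mass_fraction
    return carbon_g / c.MOLAR_MASS_CARBON_G * params.inhaled_fraction


def co2_overestimate_pct(mol_err: float, rco2_mol_d: float) -> float:
    """Inhaled CO2 as a percentage of true CO2 production."""
    if rco2_mol_d <= 0:
        raise InvalidInputError("rCO2 must be positive")
    return 100.0 * mol_err / rco2_mol_d


def co2_energy_correction(mol_err: float, rq: float = c.DEFAULT_RQ) -> float:
    """Energy equivalent (kcal/day) of an inhaled-CO2 error, via the Weir
    per-mole equivalent at the given RQ."""
    if mol_err < 0:
        raise InvalidInputError("CO2 error must be >= 0")
    return weir_tee(mol_err, rq)


def pct_of_tee_correction(pct: float, tee_kcal_d: float) -> float:
    """Companion helper: a CO2 overestimate of ``pct`` percent translated to
    kcal/day on a given TEE (pct/100 x TEE)."""
    if pct < 0 or tee_kcal_d < 0:
        raise InvalidInputError("inputs must be >= 0")
    return pct / 100.0 * tee_kcal_d
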