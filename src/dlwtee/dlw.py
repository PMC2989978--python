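"""Doubly-labeled-water calculation engine.

Converts an isotope dose and a timed urine-enrichment series into elimination
rates, dilution spaces, total body water (TBW), fat-free mass (FFM), CO2
production and total energy expenditure (TEE).

The method: after an oral dose of 2H- and 18O-labeled water, deuterium leaves
the body only as water while 18O leaves as water and CO2, so the difference in
the two mono-exponential elimination rates measures CO2 production.  TEE then
follows from the modified Weir equation at a fixed respiratory quotient.

Unit conventions (see :mod:`dlwtee.constants`): enrichments are atom-fraction
excess above the pre-dose baseline; the 2H dose excess is expressed in
water-equivalent moles (moles of dose water x atom-fraction excess per
hydrogen site) so that ``dilution_space`` returns moles of body water for both
isotopes with the same identity N = dose / e0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import constants as c
from .errors import InvalidInputError

__all__ = [
    "IsotopeDose",
    "EnrichmentSample",
    "EnrichmentSeries",
    "DlwResult",
    "compute_dose",
    "fit_elimination",
    "dilution_space",
    "tbw_ffm",
    "rco2",
    "weir_tee",
    "process_subject",
]

# Flags attached to a DlwResult. "Fatal" flags invalidate the subject's TEE;
# warning flags do not.
FLAG_SPACE_RATIO = "space_ratio_out_of_band"          # warning
FLAG_NONPOSITIVE_KD = "nonpositive_kd"                # fatal
FLAG_NONPOSITIVE_KO = "nonpositive_ko"                # fatal
FLAG_NONPOSITIVE_RCO2 = "nonpositive_rco2"            # fatal
FATAL_FLAGS = {FLAG_NONPOSITIVE_KD, FLAG_NONPOSITIVE_KO, FLAG_NONPOSITIVE_RCO2}

# Elimination rates below this (1/day) mean no measurable decay over the
# two-week protocol (physiological kD is ~0.05-0.15/day); they are treated as
# zero when flagging, which also absorbs float noise from exactly flat series.
MIN_ELIMINATION_RATE = 1e-6


@dataclass(frozen=True)
class IsotopeDose:
    """An administered DLW dose.

    ``o18_excess_mol`` and ``d2_excess_mol`` are moles of tracer above natural
    abundance (2H in water-equivalent moles, see module docstring).
    """

    o18_water_g: float
    d2_water_g: float
    o18_excess_mol: float
    d2_excess_mol: float

    def __post_init__(self) -> None:
        for name in ("o18_water_g", "d2_water_g", "o18_excess_mol", "d2_excess_mol"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"dose field {name} must be >= 0")


@dataclass(frozen=True)
class EnrichmentSample:
    time_days: float
    d2_excess: float
    o18_excess: float
    discarded: bool = False


@dataclass(frozen=True)
class EnrichmentSeries:
    """Timed post-dose urine enrichments for one subject.

    Times are fractional days since dose (3 h = 0.125 d).  The five-specimen
    protocol collects urine at 2, 3 and 4 h post dose (the 2 h specimen is
    discarded as potentially pre-equilibration) and twice ~14 days later.
    """

    subject_id: str
    samples: tuple[EnrichmentSample, ...]

    def __post_init__(self) -> None:
        times = [s.time_days for s in self.samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidInputError(
                f"subject {self.subject_id}: sample times must be strictly increasing"
            )
        kept = self.retained()
        if len(kept) < 2:
            raise InvalidInputError(
                f"subject {self.subject_id}: need >=2 non-discarded samples, got {len(kept)}"
            )
        for s in kept:
            if s.d2_excess <= 0 or s.o18_excess <= 0:
                raise InvalidInputError(
                    f"subject {self.subject_id}: non-positive enrichment at t={s.time_days} d"
                )

    def retained(self) -> tuple[EnrichmentSample, ...]:
        return tuple(s for s in self.samples if not s.discarded)


@dataclass(frozen=True)
class DlwResult:
    """Full output of the DLW computation for one subject.

    kD/kO in 1/day, pools in mol of water, tbw/ffm in kg, rco2 in mol/day,
    TEE in kcal/day.
    """

    subject_id: str
    kd_per_d: float
    ko_per_d: float
    nd_mol: float
    no_mol: float
    n_mol: float
    tbw_kg: float
    ffm_kg: float
    rco2_mol_d: float
    tee_kcal_d: float
    rq: float
    flags: tuple[str, ...] = field(default=())

    @property
    def valid(self) -> bool:
        return not (set(self.flags) & FATAL_FLAGS)


def compute_dose(estimated_tbw_kg: float) -> IsotopeDose:
    """Dose for a subject: 2 g of 10 atom% H2(18)O and 0.12 g of 99.9 atom%
    2H-labeled water per kg of estimated total body water.

    Excess moles are computed against natural abundances using the molar mass
    of each enriched water.
    """
    if estimated_tbw_kg <= 0:
        raise InvalidInputError("estimated TBW must be positive")
    o18_g = c.O18_DOSE_G_PER_KG_TBW * estimated_tbw_kg
    d2_g = c.D2_DOSE_G_PER_KG_TBW * estimated_tbw_kg

    mw_o18 = c.MOLAR_MASS_WATER_G + c.ATOM_FRACTION_18O_DOSE * (c.MASS_18O - c.MASS_16O)
    mw_d2 = c.MOLAR_MASS_WATER_G + 2.0 * c.ATOM_FRACTION_2H_DOSE * (c.MASS_2H - c.MASS_1H)

    o18_excess = (o18_g / mw_o18) * (c.ATOM_FRACTION_18O_DOSE - c.NATURAL_ABUNDANCE_18O)
    # per-H-site excess times one water equivalent (2 sites cancel against the
    # 2 H per molecule of body water)
    d2_excess = (d2_g / mw_d2) * (c.ATOM_FRACTION_2H_DOSE - c.NATURAL_ABUNDANCE_2H)
    return IsotopeDose(o18_g, d2_g, o18_excess, d2_excess)


def fit_elimination(samples: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Log-linear least-squares fit of an elimination curve.

    ``samples`` are (time_days, excess) pairs with excess > 0.  Returns
    ``(k, e0)`` where ``k`` is the elimination rate (1/day, = minus the slope
    of ln(excess) vs time) and ``e0`` the back-extrapolated excess at t = 0.
    With exactly two points this is the exact two-point solution.  A
    non-positive ``k`` is returned as-is; callers flag it as physiologically
    invalid.
    """
    pts = list(samples)
    if len(pts) < 2:
        raise InvalidInputError("elimination fit needs at least 2 points")
    t = np.asarray([p[0] for p in pts], dtype=float)
    e = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(e <= 0):
        raise InvalidInputError("enrichments must be positive for log-linear fit")
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("sample times must be strictly increasing")
    slope, intercept = np.polyfit(t, np.log(e), 1)
    return -float(slope), float(math.exp(intercept))


def dilution_space(dose_excess_mol: float, e0: float) -> float:
    """Isotope-dilution pool size N = dose excess / initial excess (mol water)."""
    if dose_excess_mol <= 0:
        raise InvalidInputError("dose excess must be positive")
    if e0 <= 0:
        raise InvalidInputError("back-extrapolated enrichment must be positive")
    return dose_excess_mol / e0


def space_ratio_in_band(nd_mol: float, no_mol: float) -> bool:
    lo, hi = c.SPACE_RATIO_BAND
    return lo <= nd_mol / no_mol <= hi


def tbw_ffm(nd_mol: float, no_mol: float) -> tuple[float, float]:
    """Total body water and fat-free mass from the two dilution spaces.

    The mean body-water pool corrects each space for isotope exchange:
    N = (ND/1.041 + NO/1.007)/2; TBW converts N to kg of water and FFM
    assumes a hydration fraction of 0.732.
    """
    if nd_mol <= 0 or no_mol <= 0:
        raise InvalidInputError("dilution spaces must be positive")
    n = (nd_mol / c.KD_FRACTIONATION + no_mol / c.KO_FRACTIONATION) / 2.0
    tbw_kg = n * c.MOLAR_MASS_WATER_G / 1000.0
    ffm_kg = tbw_kg / c.HYDRATION_OF_FFM
    return tbw_kg, ffm_kg


def mean_pool(nd_mol: float, no_mol: float) -> float:
    """Fractionation-corrected mean body-water pool N (mol)."""
    return (nd_mol / c.KD_FRACTIONATION + no_mol / c.KO_FRACTIONATION) / 2.0


def rco2(n_mol: float, ko_per_d: float, kd_per_d: float) -> float:
    """CO2 production rate from the elimination-rate difference.

    rCO2 = 0.4554 * N * (1.007*kO - 1.041*kD) mol/day.  Non-positive output
    means the fitted kinetics are unphysiological; callers flag the subject.
    """
    if ko_per_d <= 0 or kd_per_d <= 0:
        raise InvalidInputError("elimination rates must be positive")
    return c.RCO2_COEFFICIENT * n_mol * (
        c.KO_FRACTIONATION * ko_per_d - c.KD_FRACTIONATION * kd_per_d
    )


def weir_tee(rco2_mol_d: float, rq: float = c.DEFAULT_RQ) -> float:
    """Modified Weir equation at fixed RQ.

    TEE = 22.4 * rCO2 * (3.941/RQ + 1.106) kcal/day; at RQ 0.86 one mole of
    CO2 is worth ~127.42 kcal.
    """
    lo, hi = c.RQ_BAND
    if not (lo <= rq <= hi):
        raise InvalidInputError(f"respiratory quotient {rq} outside [{lo}, {hi}]")
    if rco2_mol_d < 0:
        raise InvalidInputError("rCO2 must be non-negative")
    return rco2_mol_d * c.kcal_per_mol_co2(rq)


def process_subject(
    dose: IsotopeDose,
    series: EnrichmentSeries,
    rq: float = c.DEFAULT_RQ,
) -> DlwResult:
    """Run the full DLW computation for one subject.

    Fits each isotope's elimination on the non-discarded samples, derives the
    dilution spaces from the back-extrapolated intercepts, and chains TBW/FFM,
    rCO2 and the Weir equation.  Subjects with unphysiological kinetics are
    returned flagged (``result.valid`` is False), never silently dropped.
    """
    kept = series.retained()
    kd, e0d = fit_elimination([(s.time_days, s.d2_excess) for s in kept])
    ko, e0o = fit_elimination([(s.time_days, s.o18_excess) for s in kept])

    flags: list[str] = []
    if kd < MIN_ELIMINATION_RATE:
        flags.append(FLAG_NONPOSITIVE_KD)
    if ko < MIN_ELIMINATION_RATE:
        flags.append(FLAG_NONPOSITIVE_KO)

    nd = dilution_space(dose.d2_excess_mol, e0d)
    no = dilution_space(dose.o18_excess_mol, e0o)
    if not space_ratio_in_band(nd, no):
        flags.append(FLAG_SPACE_RATIO)

    n = mean_pool(nd, no)
    tbw_kg, ffm_kg = tbw_ffm(nd, no)

    if not flags or set(flags) == {FLAG_SPACE_RATIO}:
        r = rco2(n, ko, kd)
    else:
        r = c.RCO2_COEFFICIENT * n * (
            c.KO_FRACTIONATION * ko - c.KD_FRACTIONATION * kd
        )
    if r <= 0:
        flags.append(FLAG_NONPOSITIVE_RCO2)
        tee = 0.0
    else:
        tee = weir_tee(r, rq)

    return DlwResult(
        subject_id=series.subject_id,
        kd_per_d=kd,
        ko_per_d=ko,
        nd_mol=nd,
        no_mol=no,
        n_mol=n,
        tbw_kg=tbw_kg,
        ffm_kg=ffm_kg,
        rco2_mol_d=r,
        tee_kcal_d=tee,
        rq=rq,
        flags=tuple(flags),
    )
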