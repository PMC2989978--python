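"""Synthetic cohort generator emulating a large DLW field study.

Generates subject tables (sex, age, anthropometry, smoking history, physical
activity, fat-free mass) cell by cell for the four sex x smoking-status
groups of the emulated sample (158 males: 20 current / 138 never smokers;
146 females: 27 / 119), assigns each subject a latent "true" total energy
expenditure from a per-sex linear model, and simulates the five-specimen
urine enrichment series that the DLW engine would observe.

Covariates are drawn independently within each cell from truncated normals
(inverse-CDF sampling on a per-cell substream, so enlarging a cell never
reshuffles earlier subjects).  The latent TEE model is

    TEE = b0 + b_FFM*FFM + b_age*age + b_PA*PA + b_smoke*1[current] + eps

with per-sex coefficients and a normal residual; intercepts are calibrated so
the expected never-smoker mean at the cell's covariate means hits a target
(2854 kcal/d males, 2330 kcal/d females by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.stats import truncnorm

from . import constants as c
from .dlw import EnrichmentSample, EnrichmentSeries, IsotopeDose, compute_dose
from .errors import InvalidInputError, KineticsError

__all__ = [
    "CellSpec",
    "TeeModel",
    "CohortConfig",
    "classify_smoking",
    "apply_eligibility",
    "generate_covariates",
    "assign_true_tee",
    "simulate_enrichments",
    "generate_study",
    "DEFAULT_PROTOCOL_TIMES_D",
    "DEFAULT_DISCARDED",
]

SEXES = ("male", "female")
STATUSES = ("current", "never", "former")
# stable cell ordering and integer tags for substream derivation
CELL_ORDER = [
    ("male", "current"),
    ("male", "never"),
    ("female", "current"),
    ("female", "never"),
    ("male", "former"),
    ("female", "former"),
]
_CELL_TAG = {cell: i for i, cell in enumerate(CELL_ORDER)}

# Five-specimen protocol: 2, 3, 4 h post dose (2 h discarded) and two late
# collections ~14 days later.  Times in fractional days.
DEFAULT_PROTOCOL_TIMES_D = (2.0 / 24.0, 3.0 / 24.0, 4.0 / 24.0, 13.5, 14.0)
DEFAULT_DISCARDED = (True, False, False, False, False)


@dataclass(frozen=True)
class CellSpec:
    """Covariate distribution for one sex x smoking-status cell: (mean, SD)."""

    n: int
    age_y: tuple[float, float]
    height_cm: tuple[float, float]
    weight_kg: tuple[float, float]
    ffm_kg: tuple[float, float]
    pa_met_min_wk: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidInputError("cell n must be >= 0")
        for name in ("age_y", "height_cm", "weight_kg", "ffm_kg", "pa_met_min_wk"):
            if getattr(self, name)[1] < 0:
                raise InvalidInputError(f"{name} SD must be >= 0")


@dataclass(frozen=True)
class TeeModel:
    """Per-sex latent TEE model coefficients (kcal/d per unit of each term)."""

    beta_smoking: float
    beta_ffm: float
    beta_age: float
    beta_pa: float
    intercept: float
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise InvalidInputError("residual SD must be >= 0")


def calibrate_intercept(
    target_never_mean: float,
    beta_ffm: float,
    beta_age: float,
    beta_pa: float,
    never_cell: CellSpec,
) -> float:
    """Intercept such that a never smoker at the cell's covariate means has
    expected TEE equal to ``target_never_mean``."""
    return target_never_mean - (
        beta_ffm * never_cell.ffm_kg[0]
        + beta_age * never_cell.age_y[0]
        + beta_pa * never_cell.pa_met_min_wk[0]
    )


# Default cell specs: the emulated study's subject-characteristics table.
_DEFAULT_CELLS: dict[tuple[str, str], CellSpec] = {
    ("male", "current"): CellSpec(
        n=20, age_y=(50.6, 8.7), height_cm=(177.4, 7.7), weight_kg=(87.7, 18.9),
        ffm_kg=(60.0, 11.4), pa_met_min_wk=(1128.0, 1154.0)),
    ("male", "never"): CellSpec(
        n=138, age_y=(53.4, 8.3), height_cm=(176.3, 7.9), weight_kg=(85.4, 13.9),
        ffm_kg=(58.0, 7.9), pa_met_min_wk=(1558.0, 1411.0)),
    ("female", "current"): CellSpec(
        n=27, age_y=(53.6, 8.1), height_cm=(164.6, 6.6), weight_kg=(71.8, 16.0),
        ffm_kg=(42.8, 7.1), pa_met_min_wk=(1467.0, 1679.0)),
    ("female", "never"): CellSpec(
        n=119, age_y=(52.2, 7.9), height_cm=(162.3, 6.7), weight_kg=(74.1, 18.3),
        ffm_kg=(42.4, 6.7), pa_met_min_wk=(1516.0, 1387.0)),
}

# Default per-sex TEE coefficients (multiple-regression scale) and residual
# SDs chosen so the marginal never-smoker TEE SD is ~468/415 kcal/d.
_DEFAULT_BETAS = {
    "male": dict(beta_smoking=111.9, beta_ffm=43.6, beta_age=-13.3, beta_pa=0.05,
                 resid_sd=288.0, never_mean=2854.0),
    "female": dict(beta_smoking=-81.8, beta_ffm=45.0, beta_age=-3.5, beta_pa=0.01,
                   resid_sd=284.0, never_mean=2330.0),
}

AGE_RANGE = (40.0, 69.0)
_TRUNC_SD = 4.0  # non-age covariates truncated at +/- 4 SD (and >= 0 for PA)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a reproducible synthetic study."""

    cells: Mapping[tuple[str, str], CellSpec]
    tee_models: Mapping[str, TeeModel]
    noise_cv: float = 0.01
    space_ratio: float = c.DEFAULT_SPACE_RATIO
    rq: float = c.DEFAULT_RQ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise CV must be >= 0")
        if not (c.SPACE_RATIO_BAND[0] <= self.space_ratio <= c.SPACE_RATIO_BAND[1]):
            raise InvalidInputError("space ratio outside sanity band")

    @classmethod
    def study_defaults(cls, seed: int = 0, noise_cv: float = 0.01) -> "CohortConfig":
        tee_models = {}
        for sex, b in _DEFAULT_BETAS.items():
            never = _DEFAULT_CELLS[(sex, "never")]
            tee_models[sex] = TeeModel(
                beta_smoking=b["beta_smoking"], beta_ffm=b["beta_ffm"],
                beta_age=b["beta_age"], beta_pa=b["beta_pa"],
                intercept=calibrate_intercept(
                    b["never_mean"], b["beta_ffm"], b["beta_age"], b["beta_pa"], never),
                resid_sd=b["resid_sd"],
            )
        return cls(cells=dict(_DEFAULT_CELLS), tee_models=tee_models,
                   noise_cv=noise_cv, seed=seed)

    def scaled(self, factor: float) -> "CohortConfig":
        """Same distributions, cell sizes multiplied by ``factor``."""
        cells = {k: replace(v, n=int(round(v.n * factor))) for k, v in self.cells.items()}
        return replace(self, cells=cells)

    def null_smoking(self) -> "CohortConfig":
        """Exact no-smoking-effect null: zero smoking coefficient and
        identical covariate distributions in current- and never-smoker cells
        (smoking becomes a pure label)."""
        cells = dict(self.cells)
        for sex in SEXES:
            if (sex, "never") in cells and (sex, "current") in cells:
                never = cells[(sex, "never")]
                cells[(sex, "current")] = replace(never, n=cells[(sex, "current")].n)
        tee_models = {s: replace(m, beta_smoking=0.0) for s, m in self.tee_models.items()}
        return replace(self, cells=cells, tee_models=tee_models)


def classify_smoking(lifetime_cigarettes: int, currently_smoking: bool) -> str:
    """Questionnaire rule: fewer than 100 lifetime cigarettes -> never smoker;
    100 or more -> current if still smoking else former (the boundary count
    of exactly 100 is classified on the smoker side)."""
    if lifetime_cigarettes < 0:
        raise InvalidInputError("lifetime cigarette count must be >= 0")
    if lifetime_cigarettes < 100:
        return "never"
    return "current" if currently_smoking else "former"


def apply_eligibility(
    cohort: pd.DataFrame, tee_col: str | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only never and current smokers with TEE data.

    Returns the analysis cohort (covariate values untouched) and a log of
    exclusion counts by reason.  ``tee_col`` defaults to the measured TEE
    column if present, else the latent one.
    """
    if tee_col is None:
        tee_col = "tee_kcal_d" if "tee_kcal_d" in cohort.columns else "true_tee_kcal_d"
    log = {"former": 0, "missing_smoking": 0, "missing_tee": 0}
    status = cohort["smoking_status"]
    missing_smoking = status.isna()
    former = status.eq("former") & ~missing_smoking
    has_tee = cohort[tee_col].notna() if tee_col in cohort.columns else pd.Series(
        False, index=cohort.index)
    missing_tee = ~has_tee & ~missing_smoking & ~former
    keep = ~(missing_smoking | former | missing_tee)
    log["missing_smoking"] = int(missing_smoking.sum())
    log["former"] = int(former.sum())
    log["missing_tee"] = int(missing_tee.sum())
    return cohort.loc[keep].copy(), log


def _tnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF truncated-normal transform (one uniform per draw, so the
    stream position is independent of acceptance, unlike rejection sampling)."""
    if sd == 0:
        return np.full_like(u, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _cell_rng(seed: int, tag: int, stream: int) -> Generator:
    return default_rng(SeedSequence([int(seed), int(stream), int(tag)]))


def generate_covariates(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw subject covariates (no TEE yet) for every configured cell.

    Deterministic under a fixed seed; each cell has its own substream and a
    fixed number of uniforms per subject, so growing a cell appends subjects
    without altering existing ones.
    """
    seed = config.seed if seed is None else seed
    frames = []
    for cell in CELL_ORDER:
        if cell not in config.cells:
            continue
        sex, status = cell
        spec = config.cells[cell]
        if spec.n == 0:
            continue
        rng = _cell_rng(seed, _CELL_TAG[cell], 100)
        u = rng.random((spec.n, 7))

        age = _tnorm_ppf(u[:, 0], *spec.age_y, *AGE_RANGE)
        m, s = spec.height_cm
        height = _tnorm_ppf(u[:, 1], m, s, m - _TRUNC_SD * s, m + _TRUNC_SD * s)
        m, s = spec.weight_kg
        weight = _tnorm_ppf(u[:, 2], m, s, m - _TRUNC_SD * s, m + _TRUNC_SD * s)
        m, s = spec.ffm_kg
        ffm = _tnorm_ppf(u[:, 3], m, s, max(10.0, m - _TRUNC_SD * s), m + _TRUNC_SD * s)
        m, s = spec.pa_met_min_wk
        pa = _tnorm_ppf(u[:, 4], m, s, max(0.0, m - _TRUNC_SD * s), m + _TRUNC_SD * s)
        # body composition sanity: FFM cannot exceed body mass; the FFM
        # marginal is kept exact and weight is bumped where needed
        weight = np.maximum(weight, ffm / 0.95)

        if status == "never":
            lifetime = np.floor(u[:, 5] * 100.0).astype(int)
            currently = np.zeros(spec.n, dtype=bool)
            cigs_per_day = np.zeros(spec.n, dtype=int)
        else:
            lifetime = (100.0 + u[:, 5] * 400_000.0).astype(int)
            currently = np.full(spec.n, status == "current")
            cigs_per_day = np.where(
                currently,
                np.rint(_tnorm_ppf(u[:, 6], 18.0, 8.0, 1.0, 60.0)).astype(int),
                0,
            )

        frames.append(pd.DataFrame({
            "id": [f"{sex[0].upper()}{status[0].upper()}{i:04d}" for i in range(spec.n)],
            "sex": sex,
            "age_y": age,
            "height_cm": height,
            "weight_kg": weight,
            "bmi_kg_m2": weight / (height / 100.0) ** 2,
            "lifetime_cigarettes": lifetime,
            "currently_smoking": currently,
            "smoking_status": [classify_smoking(lc, cs) for lc, cs in zip(lifetime, currently)],
            "cigs_per_day": cigs_per_day,
            "pa_met_min_wk": pa,
            "ffm_kg": ffm,
        }))
    if not frames:
        return _empty_cohort()
    return pd.concat(frames, ignore_index=True)


def _empty_cohort() -> pd.DataFrame:
    cols = ["id", "sex", "age_y", "height_cm", "weight_kg", "bmi_kg_m2",
            "lifetime_cigarettes", "currently_smoking", "smoking_status",
            "cigs_per_day", "pa_met_min_wk", "ffm_kg"]
    return pd.DataFrame(columns=cols)


def assign_true_tee(cohort: pd.DataFrame, config: CohortConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Attach the latent true TEE from the per-sex linear model plus a normal
    residual (per-cell substream, one draw per subject)."""
    seed = config.seed if seed is None else seed
    out = cohort.copy()
    out["true_tee_kcal_d"] = np.nan
    for cell in CELL_ORDER:
        sex, status = cell
        mask = (out["sex"] == sex) & (out["smoking_status"] == status)
        n = int(mask.sum())
        if n == 0 or sex not in config.tee_models:
            continue
        m = config.tee_models[sex]
        rng = _cell_rng(seed, _CELL_TAG[cell], 200)
        resid = rng.standard_normal(n) * m.resid_sd
        sub = out.loc[mask]
        out.loc[mask, "true_tee_kcal_d"] = (
            m.intercept
            + m.beta_ffm * sub["ffm_kg"].to_numpy()
            + m.beta_age * sub["age_y"].to_numpy()
            + m.beta_pa * sub["pa_met_min_wk"].to_numpy()
            + m.beta_smoking * float(status == "current")
            + resid
        )
    return out


def _solve_spaces(n_mol: float, ratio: float) -> tuple[float, float]:
    """ND, NO with ND/NO = ratio and fractionation-corrected mean exactly n_mol."""
    no = 2.0 * n_mol / (ratio / c.KD_FRACTIONATION + 1.0 / c.KO_FRACTIONATION)
    return ratio * no, no


def simulate_enrichments(
    subject: Mapping[str, object],
    dose: IsotopeDose,
    protocol_times_d: tuple[float, ...] = DEFAULT_PROTOCOL_TIMES_D,
    discarded: tuple[bool, ...] = DEFAULT_DISCARDED,
    noise_cv: float = 0.0,
    rng: Generator | int | None = None,
    space_ratio: float = c.DEFAULT_SPACE_RATIO,
    rq: float = c.DEFAULT_RQ,
    max_retries: int = 10,
) -> EnrichmentSeries:
    """Simulate the urine enrichment series the DLW engine would observe.

    Inverts the engine: body water from FFM at 0.732 hydration, target rCO2
    from the Weir equation at the subject's true TEE, deuterium elimination
    from a water-turnover model (~3-4 L/day for a typical adult, scaled to
    pool size), and kO solved from the rCO2 identity.  With ``noise_cv`` = 0
    the engine recovers the true TEE exactly (to float precision).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = default_rng(rng)
    ffm = float(subject["ffm_kg"])
    tee = float(subject["true_tee_kcal_d"])
    sid = str(subject.get("id", "anon"))
    if ffm <= 0:
        raise InvalidInputError(f"subject {sid}: FFM must be positive")
    if tee <= 0:
        raise KineticsError(f"subject {sid}: true TEE must be positive")

    tbw_kg = c.HYDRATION_OF_FFM * ffm
    n_mol = tbw_kg * 1000.0 / c.MOLAR_MASS_WATER_G
    nd, no = _solve_spaces(n_mol, space_ratio)
    rco2_target = tee / c.kcal_per_mol_co2(rq)

    kd = ko = None
    for _ in range(max_retries):
        # water turnover ~ N(0.085, 0.010) L per kg TBW per day, truncated
        turnover_l_per_kg = float(
            _tnorm_ppf(rng.random(1), 0.085, 0.010, 0.055, 0.115)[0])
        rh2o_mol = turnover_l_per_kg * tbw_kg * 1000.0 / c.MOLAR_MASS_WATER_G
        kd_try = rh2o_mol / nd
        ko_try = (rco2_target / (c.RCO2_COEFFICIENT * n_mol)
                  + c.KD_FRACTIONATION * kd_try) / c.KO_FRACTIONATION
        if ko_try > kd_try * c.KD_FRACTIONATION / c.KO_FRACTIONATION:
            kd, ko = kd_try, ko_try
            break
    if kd is None:
        raise KineticsError(f"subject {sid}: could not find physiological kinetics")

    e0d = dose.d2_excess_mol / nd
    e0o = dose.o18_excess_mol / no
    samples = []
    for t, disc in zip(protocol_times_d, discarded):
        ed = e0d * math.exp(-kd * t)
        eo = e0o * math.exp(-ko * t)
        if noise_cv > 0:
            fd, fo = 1.0 + noise_cv * rng.standard_normal(2)
            ed *= max(fd, 0.05)
            eo *= max(fo, 0.05)
        samples.append(EnrichmentSample(t, ed, eo, disc))
    return EnrichmentSeries(subject_id=sid, samples=tuple(samples))


def generate_study(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the full synthetic study: cohort table, per-subject doses and
    long-format enrichment records ready for the DLW engine.

    Returns ``(cohort, doses, enrichments)``; enrichment rows have columns
    subject_id, time_days, isotope (2H|18O), excess, discarded.
    """
    seed = config.seed if seed is None else seed
    cohort = assign_true_tee(generate_covariates(config, seed), config, seed)

    dose_rows = []
    enr_rows = []
    for idx, row in enumerate(cohort.itertuples(index=False)):
        tbw_est = c.HYDRATION_OF_FFM * row.ffm_kg
        dose = compute_dose(tbw_est)
        rng = default_rng(SeedSequence([int(seed), 300, idx]))
        series = simulate_enrichments(
            {"id": row.id, "ffm_kg": row.ffm_kg, "true_tee_kcal_d": row.true_tee_kcal_d},
            dose, noise_cv=config.noise_cv, rng=rng,
            space_ratio=config.space_ratio, rq=config.rq)
        dose_rows.append({
            "subject_id": row.id,
            "o18_water_g": dose.o18_water_g, "d2_water_g": dose.d2_water_g,
            "o18_excess_mol": dose.o18_excess_mol, "d2_excess_mol": dose.d2_excess_mol,
        })
        for s in series.samples:
            for iso, exc in (("2H", s.d2_excess), ("18O", s.o18_excess)):
                enr_rows.append({
                    "subject_id": row.id, "time_days": s.time_days,
                    "isotope": iso, "excess": exc, "discarded": int(s.discarded),
                })
    doses = pd.DataFrame(dose_rows, columns=[
        "subject_id", "o18_water_g", "d2_water_g", "o18_excess_mol", "d2_excess_mol"])
    enr = pd.DataFrame(enr_rows, columns=[
        "subject_id", "time_days", "isotope", "excess", "discarded"])
    return cohort, doses, enr
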