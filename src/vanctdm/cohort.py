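"""Seeded virtual ICU cohorts for exercising the TDM pipeline.

Every patient carries *true* one-compartment kinetics (clearance, volume of
distribution) alongside the demographic covariates that drive them, so that
downstream estimators can be checked against known ground truth.  The
generative choices emulate the statistical structure of a real vancomycin
TDM cohort of critically ill adults:

* demographics drawn from truncated normals calibrated to the study-type
  population (mean age ~50 y, ideal body weight ~65 kg, baseline serum
  creatinine ~0.95 mg/dl);
* baseline GFR is *computed* from the drawn age/weight/creatinine via
  Cockcroft-Gault — never drawn independently — which builds in the strong
  negative creatinine<->GFR coupling seen clinically;
* eligibility mirrors an ICU TDM protocol: adults 18-85 y with GFR >= 45
  ml/min (patients failing the renal criterion are redrawn);
* vancomycin clearance is proportional to GFR with lognormal
  between-patient noise (the drug is ~80-90% renally eliminated), and the
  volume of distribution is lognormal around 0.7 L/kg of ideal body weight;
* the acute-kidney-injury outcome is an exposure-driven Bernoulli process
  whose logistic intercept is tuned so cohort prevalence matches a target
  (default 17%).

Randomness is keyed per patient: patient ``i`` under master seed ``s`` uses
independent streams derived from ``(s, i, tag)``, so cohorts are bit-stable
under reordering and a patient's samples do not depend on cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit, ndtr, ndtri

from .pk import ConcentrationProfile, Regimen, cockcroft_gault, forward_profile

__all__ = [
    "AKIModelParams",
    "CohortConfig",
    "TruePatient",
    "generate_cohort",
    "simulate_samples",
    "assign_aki",
    "default_schedule",
    "cohort_to_frames",
]

# sub-stream tags under the master seed
_STREAM_COVARIATES = 0
_STREAM_SAMPLES = 1
_STREAM_AKI = 2

_MAX_REDRAWS = 1000


class AKIModelParams(BaseModel):
    """Logistic exposure-toxicity process for the simulated AKI outcome.

    P(AKI) = logistic(intercept + slope_exposure * exposure).  When
    ``intercept`` is None it is tuned by bisection so the cohort's expected
    prevalence matches ``target_prevalence`` (within 0.005).
    """

    model_config = ConfigDict(extra="forbid")

    intercept: float | None = None
    slope_exposure: float = Field(default=0.15, ge=0.0)
    exposure_metric: Literal["mean_trough", "auc24"] = "mean_trough"
    target_prevalence: float = Field(default=0.17, gt=0.0, lt=1.0)


class CohortConfig(BaseModel):
    """Knobs of the virtual-cohort generator, with study-typical defaults."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(ge=1)
    seed: int = 0
    age_mean_sd: tuple[float, float] = (50.25, 19.12)
    age_bounds: tuple[float, float] = (18.0, 85.0)
    ibw_mean_sd: tuple[float, float] = (65.52, 10.16)
    ibw_bounds: tuple[float, float] = (44.0, 95.0)
    height_mean_sd: tuple[float, float] = (166.62, 9.72)
    height_bounds: tuple[float, float] = (140.0, 185.0)
    scr_mean_sd: tuple[float, float] = (0.95, 0.32)
    scr_bounds: tuple[float, float] = (0.5, 2.2)
    female_fraction: float = Field(default=0.472, ge=0.0, le=1.0)
    #: maintenance regimens as (dose mg/kg IBW, interval h, infusion h)
    regimen_menu: list[tuple[float, float, float]] = Field(
        default_factory=lambda: [(15.0, 12.0, 1.0), (17.5, 12.0, 1.0), (20.0, 12.0, 1.0)]
    )
    dose_increment_mg: float = 250.0
    #: clearance-GFR link: Cl (L/h) = cl_per_gfr * GFR (ml/min) * lognormal noise
    cl_per_gfr: float = 0.06
    cl_lognorm_sd: float = 0.25
    vd_per_kg: float = 0.7
    vd_lognorm_sd: float = 0.5
    min_gfr: float = 45.0
    nephrotoxin_fraction: float = Field(default=0.245, ge=0.0, le=1.0)
    assay_cv: float = Field(default=0.10, ge=0.0, le=0.5)
    aki_model: AKIModelParams = Field(default_factory=AKIModelParams)

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for name in ("age", "ibw", "height", "scr"):
            mean, sd = getattr(self, f"{name}_mean_sd")
            lo, hi = getattr(self, f"{name}_bounds")
            if sd < 0:
                raise ValueError(f"{name} SD must be non-negative")
            if lo >= hi:
                raise ValueError(f"{name} bounds are infeasible: [{lo}, {hi}]")
            if sd == 0 and not (lo <= mean <= hi):
                raise ValueError(f"{name} mean {mean} outside bounds with SD 0")
        if not self.regimen_menu:
            raise ValueError("regimen_menu must not be empty")
        return self


@dataclass
class TruePatient:
    """One simulated patient with ground-truth kinetics."""

    patient_id: int
    age: float  # years
    sex: str  # "F" or "M"
    ibw: float  # kg, ideal body weight
    height: float  # cm
    baseline_scr: float  # mg/dl
    baseline_gfr: float  # ml/min, Cockcroft-Gault
    true_cl: float  # L/h
    true_vd: float  # L
    true_k: float  # 1/h
    regimen: Regimen
    nephrotoxin_cotreat: bool
    aki: bool | None = None


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    # inverse-CDF sampling: uniform on [Phi(a), Phi(b)] mapped back through
    # the normal quantile function
    if sd == 0:
        return mean
    pa = ndtr((lo - mean) / sd)
    pb = ndtr((hi - mean) / sd)
    u = pa + (pb - pa) * rng.random()
    return float(mean + sd * ndtri(u))


def _round_dose(dose: float, increment: float) -> float:
    return max(increment, round(dose / increment) * increment)


def _draw_patient(pid: int, config: CohortConfig) -> TruePatient:
    rng = np.random.default_rng([config.seed, pid, _STREAM_COVARIATES])
    sex = "F" if rng.random() < config.female_fraction else "M"
    height = _trunc_normal(rng, *config.height_mean_sd, *config.height_bounds)
    ibw = _trunc_normal(rng, *config.ibw_mean_sd, *config.ibw_bounds)

    # redraw (age, SCr) until the renal inclusion criterion is met
    for _ in range(_MAX_REDRAWS):
        age = _trunc_normal(rng, *config.age_mean_sd, *config.age_bounds)
        scr = _trunc_normal(rng, *config.scr_mean_sd, *config.scr_bounds)
        gfr = cockcroft_gault(age, ibw, scr, is_female=(sex == "F"))
        if gfr >= config.min_gfr:
            break
    else:
        raise RuntimeError(
            f"patient {pid}: could not satisfy GFR >= {config.min_gfr} "
            f"in {_MAX_REDRAWS} redraws; check configured distributions"
        )

    cl = config.cl_per_gfr * gfr * math.exp(rng.normal(0.0, config.cl_lognorm_sd))
    vd = config.vd_per_kg * ibw * math.exp(rng.normal(0.0, config.vd_lognorm_sd))
    mgkg, tau, tinf = config.regimen_menu[rng.integers(len(config.regimen_menu))]
    regimen = Regimen(
        dose_mg=_round_dose(mgkg * ibw, config.dose_increment_mg),
        interval_h=tau,
        infusion_h=tinf,
    )
    return TruePatient(
        patient_id=pid,
        age=age,
        sex=sex,
        ibw=ibw,
        height=height,
        baseline_scr=scr,
        baseline_gfr=gfr,
        true_cl=cl,
        true_vd=vd,
        true_k=cl / vd,
        regimen=regimen,
        nephrotoxin_cotreat=bool(rng.random() < config.nephrotoxin_fraction),
    )


def generate_cohort(config: CohortConfig) -> list[TruePatient]:
    """Generate a deterministic cohort of :class:`TruePatient` records."""
    return [_draw_patient(pid, config) for pid in range(1, config.n_patients + 1)]


def default_schedule(regimen: Regimen) -> tuple[float, ...]:
    """The sparse sampling design generalized to any interval.

    (0, end-of-infusion, mid-interval, tau) — for the canonical 12-h
    interval with a 1-h infusion this is the (0, 1, 6, 12) h design.
    """
    return (0.0, regimen.infusion_h, regimen.interval_h / 2.0, regimen.interval_h)


def simulate_samples(
    patient: TruePatient,
    schedule: Sequence[float] | None = None,
    assay_cv: float = 0.10,
    seed: int = 0,
) -> ConcentrationProfile:
    """Noisy sampled concentrations for one patient at steady state.

    The noiseless value is the forward one-compartment steady-state profile;
    measurement noise is mean-one multiplicative lognormal with coefficient
    of variation ``assay_cv`` (so ``assay_cv=0`` returns the exact model
    values, and concentrations can never go negative).
    """
    if schedule is None:
        schedule = default_schedule(patient.regimen)
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must contain at least one time")
    if np.any(schedule < 0) or np.any(schedule > patient.regimen.interval_h):
        raise ValueError("schedule times must lie within one dosing interval")
    conc = forward_profile(patient.true_cl, patient.true_vd, patient.regimen, schedule)
    if assay_cv > 0:
        rng = np.random.default_rng([seed, patient.patient_id, _STREAM_SAMPLES])
        sigma = math.sqrt(math.log1p(assay_cv**2))
        noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=conc.size))
        conc = conc * noise
    return ConcentrationProfile(
        patient_id=patient.patient_id,
        times=schedule,
        concentrations=conc,
        regimen=patient.regimen,
    )


def _tune_intercept(exposures: np.ndarray, slope: float, target: float,
                    tol: float = 0.005) -> float:
    """Bisection on the logistic intercept for a target expected prevalence."""

    def prevalence(b0: float) -> float:
        return float(np.mean(expit(b0 + slope * exposures)))

    lo, hi = -50.0 - slope * float(np.max(exposures, initial=0.0)), 50.0
    mid = (lo + hi) / 2.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if abs(prevalence(mid) - target) <= tol / 10.0:
            break
        if prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    return mid


def assign_aki(
    patients: list[TruePatient],
    exposures: Sequence[float],
    params: AKIModelParams,
    seed: int = 0,
) -> list[TruePatient]:
    """Draw the AKI outcome from the logistic exposure-toxicity process.

    ``exposures`` is one value per patient on the scale named by
    ``params.exposure_metric``.  Patients are mutated in place (and also
    returned).  A negative exposure slope is rejected: the simulated
    toxicity process is increasing in exposure by construction.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.size != len(patients):
        raise ValueError("need exactly one exposure value per patient")
    if params.slope_exposure < 0:
        raise ValueError("slope_exposure must be non-negative")
    intercept = params.intercept
    if intercept is None:
        intercept = _tune_intercept(
            exposures, params.slope_exposure, params.target_prevalence
        )
    probs = expit(intercept + params.slope_exposure * exposures)
    for patient, p in zip(patients, probs):
        rng = np.random.default_rng([seed, patient.patient_id, _STREAM_AKI])
        patient.aki = bool(rng.random() < p)
    return patients


def cohort_to_frames(
    patients: list[TruePatient],
    profiles: Sequence[ConcentrationProfile] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Flatten a cohort (and optional sample profiles) to tidy DataFrames."""
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex,
                "ibw_kg": p.ibw,
                "height_cm": p.height,
                "baseline_scr_mgdl": p.baseline_scr,
                "baseline_gfr_mlmin": p.baseline_gfr,
                "dose_mg": p.regimen.dose_mg,
                "interval_h": p.regimen.interval_h,
                "infusion_h": p.regimen.infusion_h,
                "nephrotoxin_cotreat": int(p.nephrotoxin_cotreat),
                "aki": int(p.aki) if p.aki is not None else pd.NA,
            }
        )
    patients_df = pd.DataFrame(rows)
    samples_df = None
    if profiles is not None:
        samples_df = pd.DataFrame(
            [
                {"patient_id": prof.patient_id, "time_h": t, "conc_ugml": c}
                for prof in profiles
                for t, c in zip(prof.times, prof.concentrations)
            ]
        )
    return patients_df, samples_df
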