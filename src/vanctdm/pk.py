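"""One-compartment intermittent-infusion vancomycin kinetics.

Forward steady-state concentration profiles, trapezoidal AUC over a dosing
interval from sparse timed samples, and the individualized parameter
estimators used in routine therapeutic drug monitoring:

    Cl   = X0 / AUCtau                (dose over interval AUC)
    Vd   = X0 / (Cmax - Cmin)         (peak-trough swing)
    k    = Cl / Vd                    (first-order elimination constant)
    t1/2 = 0.693 / k                  (elimination half-life)

plus the Cockcroft-Gault creatinine-clearance estimate of GFR used for
eligibility screening and the renal link in simulation.

Units throughout: concentrations in ug/ml (identical to mg/L), volumes in L,
times in h, doses in mg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Regimen",
    "ConcentrationProfile",
    "PKEstimate",
    "cockcroft_gault",
    "forward_profile",
    "trapezoid_auc_tau",
    "auc24_from_auc_tau",
    "clearance_from_auc",
    "vd_from_peak_trough",
    "elimination_constant",
    "half_life",
    "steady_state_check",
    "estimate_pk",
    "report_round",
    "HALF_LIFE_CONSTANT",
]

#: Constant used in the half-life report (clinical convention rounds ln 2
#: to 0.693; the exact value is available via ``use_ln2=True``).
HALF_LIFE_CONSTANT = 0.693


@dataclass(frozen=True)
class Regimen:
    """An intermittent intravenous infusion schedule.

    Parameters
    ----------
    dose_mg : float
        Dose administered in each dosing interval (X0), mg.
    interval_h : float
        Dosing interval tau, h.
    infusion_h : float
        Duration of the constant-rate infusion T, h. Must satisfy
        0 < T <= tau.
    doses_given : int
        Number of doses administered so far (sampling is performed around
        the fifth dose, by which time steady state is assumed).
    """

    dose_mg: float
    interval_h: float
    infusion_h: float
    doses_given: int = 5

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError(f"dose_mg must be positive, got {self.dose_mg}")
        if self.interval_h <= 0:
            raise ValueError(f"interval_h must be positive, got {self.interval_h}")
        if not (0 < self.infusion_h <= self.interval_h):
            raise ValueError(
                "infusion_h must satisfy 0 < T <= tau, got "
                f"T={self.infusion_h}, tau={self.interval_h}"
            )

    @property
    def infusion_rate(self) -> float:
        """Constant infusion rate k0 = X0/T in mg/h."""
        return self.dose_mg / self.infusion_h


@dataclass
class ConcentrationProfile:
    """Timed plasma concentrations over one dosing interval at steady state.

    The nominal sparse schedule is (0, 1, 6, 12) h for a 12-h interval:
    trough 1 immediately pre-dose, peak at the end of the 1-h infusion, an
    intermediate sample, and trough 2 immediately before the next dose.
    """

    patient_id: int | str
    times: np.ndarray
    concentrations: np.ndarray
    regimen: Regimen

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.size != self.concentrations.size:
            raise ValueError("times and concentrations must have equal length")
        if self.times.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.times[0] != 0:
            raise ValueError("first sample must be the pre-dose trough (t=0)")
        if not math.isclose(self.times[-1], self.regimen.interval_h):
            raise ValueError(
                f"last sample must fall at the end of the interval "
                f"(t={self.regimen.interval_h}), got {self.times[-1]}"
            )
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def trough1(self) -> float:
        return float(self.concentrations[0])

    @property
    def trough2(self) -> float:
        return float(self.concentrations[-1])

    @property
    def peak(self) -> float:
        """Concentration at the first sample at or after the end of infusion."""
        idx = int(np.searchsorted(self.times, self.regimen.infusion_h))
        idx = min(idx, self.times.size - 1)
        return float(self.concentrations[idx])


@dataclass
class PKEstimate:
    """Individualized steady-state PK parameters for one patient."""

    patient_id: int | str
    auc_tau: float  # ug*h/ml over one interval
    auc_24h: float  # ug*h/ml scaled to 24 h
    cl: float  # L/h
    vd: float  # L
    k: float  # 1/h
    t_half: float  # h
    trough1: float  # ug/ml
    peak: float  # ug/ml
    trough2: float  # ug/ml
    mean_trough: float = field(init=False)
    steady_state: bool = True

    def __post_init__(self) -> None:
        self.mean_trough = (self.trough1 + self.trough2) / 2.0


def report_round(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding for report tables.

    Clinical reports round the *displayed* decimal value half-up (so
    0.693/0.28 prints as 2.48), whereas ``round`` applies banker's
    rounding to the binary float.  The value is first quantized at six
    guard digits to recover the displayed decimal, then rounded half-up.
    """
    from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

    d = Decimal(repr(float(value)))
    d = d.quantize(Decimal(1).scaleb(-(decimals + 6)), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def cockcroft_gault(
    age: float, weight_kg: float, scr_mgdl: float, is_female: bool
) -> float:
    """Cockcroft-Gault creatinine clearance in ml/min.

    ((140 - age) * weight) / (72 * SCr), multiplied by 0.85 for women.
    Ages at or beyond 140 put the formula outside its clinical domain
    (the estimate hits zero); a warning is emitted rather than an error.
    """
    if age < 18:
        raise ValueError(f"adult formula requires age >= 18, got {age}")
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if scr_mgdl <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr_mgdl}")
    if age >= 140:
        warnings.warn(
            f"age {age} is outside the clinical domain of Cockcroft-Gault",
            stacklevel=2,
        )
    gfr = ((140.0 - age) * weight_kg) / (72.0 * scr_mgdl)
    if is_female:
        gfr *= 0.85
    return max(gfr, 0.0)


def forward_profile(
    cl: float, vd: float, regimen: Regimen, times: np.ndarray | list[float]
) -> np.ndarray:
    """Steady-state plasma concentration at ``times`` within one interval.

    Closed-form superposition solution for repeated constant-rate infusions
    of duration T every tau hours.  Writing k = cl/vd, k0 = X0/T and
    r = exp(-k*tau), the steady-state trough (t = 0, immediately pre-dose) is

        C_trough = (k0/(vd*k)) * (1 - e^{-kT}) * e^{-k(tau-T)} / (1 - r)

    during the infusion (0 <= t <= T)

        C(t) = C_trough * e^{-kt} + (k0/(vd*k)) * (1 - e^{-kt})

    and after it (T <= t <= tau) the peak C(T) decays mono-exponentially.
    The profile is periodic: C(0) == C(tau).
    """
    if cl <= 0 or vd <= 0:
        raise ValueError("cl and vd must be positive")
    t = np.asarray(times, dtype=float)
    tau, T = regimen.interval_h, regimen.infusion_h
    if np.any(t < 0) or np.any(t > tau):
        raise ValueError(f"times must lie within [0, tau={tau}]")

    k = cl / vd
    k0 = regimen.infusion_rate
    scale = k0 / (vd * k)
    one_minus_ekT = -math.expm1(-k * T)
    accumulation = 1.0 / (-math.expm1(-k * tau))
    c_trough = scale * one_minus_ekT * math.exp(-k * (tau - T)) * accumulation
    c_peak = c_trough * math.exp(-k * T) + scale * one_minus_ekT

    conc = np.where(
        t <= T,
        c_trough * np.exp(-k * t) + scale * (-np.expm1(-k * t)),
        c_peak * np.exp(-k * (t - T)),
    )
    return conc


def trapezoid_auc_tau(profile: ConcentrationProfile) -> float:
    """Linear trapezoidal AUC over one dosing interval, ug*h/ml.

    Uses every available sample; the nominal schedule has four, and a
    warning is logged when fewer are present since the sparse-sampling
    error bound was characterized for the 4-point design.
    """
    if profile.times.size < 4:
        warnings.warn(
            f"profile for patient {profile.patient_id} has only "
            f"{profile.times.size} samples; AUC computed from available points",
            stacklevel=2,
        )
    return float(np.trapezoid(profile.concentrations, profile.times))


def auc24_from_auc_tau(auc_tau: float, tau: float) -> float:
    """Scale an interval AUC to 24 h: AUC24 = AUCtau * 24/tau.

    For the 12-h interval this is exact doubling.
    """
    if auc_tau < 0:
        raise ValueError("auc_tau must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return auc_tau * (24.0 / tau)


def clearance_from_auc(dose_mg: float, auc_tau: float) -> float:
    """Systemic clearance Cl = X0 / AUCtau, in L/h (dose mg, AUC mg*h/L)."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if auc_tau <= 0:
        raise ValueError("AUCtau must be positive")
    return dose_mg / auc_tau


def vd_from_peak_trough(dose_mg: float, cmax: float, cmin: float) -> float:
    """Apparent volume of distribution Vd = X0 / (Cmax - Cmin), in L.

    Cmin is the pre-dose trough and Cmax the end-of-infusion peak, so the
    concentration swing brackets exactly one administered dose.  A peak at
    or below the trough signals an assay or sampling problem and raises.
    """
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    if cmin < 0:
        raise ValueError("trough must be non-negative")
    if cmax <= cmin:
        raise ValueError(
            f"peak ({cmax}) must exceed trough ({cmin}); "
            "volume of distribution is undefined for this profile"
        )
    return dose_mg / (cmax - cmin)


def elimination_constant(cl: float, vd: float) -> float:
    """First-order elimination constant k = Cl / Vd, in 1/h."""
    if cl <= 0 or vd <= 0:
        raise ValueError("cl and vd must be positive")
    return cl / vd


def half_life(k: float, use_ln2: bool = False) -> float:
    """Elimination half-life t1/2 = 0.693/k (or ln2/k), in h."""
    if k <= 0:
        raise ValueError("k must be positive")
    return (math.log(2) if use_ln2 else HALF_LIFE_CONSTANT) / k


def steady_state_check(
    trough1: float, trough2: float, tolerance: float = 0.25
) -> tuple[bool, float]:
    """Per-patient steady-state check from the two bracketing troughs.

    Returns ``(confirmed, relative_difference)`` where the relative
    difference is |t2 - t1| over the trough mean.  Two zero troughs are
    indeterminate (the drug may simply be undetectable) and flagged as not
    confirmed with a NaN difference.
    """
    if trough1 < 0 or trough2 < 0:
        raise ValueError("troughs must be non-negative")
    mean = (trough1 + trough2) / 2.0
    if mean == 0:
        return False, float("nan")
    rel = abs(trough2 - trough1) / mean
    return rel <= tolerance, rel


def estimate_pk(profile: ConcentrationProfile) -> PKEstimate:
    """Full individualized estimate from one sparse steady-state profile."""
    auc_tau = trapezoid_auc_tau(profile)
    tau = profile.regimen.interval_h
    auc24 = auc24_from_auc_tau(auc_tau, tau)
    cl = clearance_from_auc(profile.regimen.dose_mg, auc_tau)
    vd = vd_from_peak_trough(profile.regimen.dose_mg, profile.peak, profile.trough1)
    k = elimination_constant(cl, vd)
    confirmed, _ = steady_state_check(profile.trough1, profile.trough2)
    return PKEstimate(
        patient_id=profile.patient_id,
        auc_tau=auc_tau,
        auc_24h=auc24,
        cl=cl,
        vd=vd,
        k=k,
        t_half=half_life(k),
        trough1=profile.trough1,
        peak=profile.peak,
        trough2=profile.trough2,
        steady_state=confirmed,
    )
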