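import numpy as np
import pytest

from vanctdm.cohort import CohortConfig
from vanctdm.pk import Regimen


@pytest.fixture
def regimen_q12() -> Regimen:
    """Canonical regimen: 1000 mg over a 1-h infusion every 12 h."""
    return Regimen(dose_mg=1000.0, interval_h=12.0, infusion_h=1.0)


@pytest.fixture
def small_cohort_config() -> CohortConfig:
    return CohortConfig(n_patients=53, seed=42)


def brute_force_superposition(cl, vd, regimen, times, n_doses):
    """Independent oracle: sum single-dose infusion responses over n doses.

    The single-dose response at time t since its own start is
    (k0/(Vd k)) (1 - e^{-kt}) during the infusion and decays
    mono-exponentially afterwards; steady state is the superposition of
    all previous doses.
    """
    k = cl / vd
    k0 = regimen.dose_mg / regimen.infusion_h
    T, tau = regimen.infusion_h, regimen.interval_h
    t = np.asarray(times, dtype=float)
    total = np.zeros_like(t)
    for n in range(n_doses):
        ts = t + n * tau  # elapsed time since the dose given n intervals ago
        single = np.where(
            ts < T,
            (k0 / (vd * k)) * (1.0 - np.exp(-k * ts)),
            (k0 / (vd * k)) * (1.0 - np.exp(-k * T)) * np.exp(-k * (ts - T)),
        )
        total += single
    return total


def pair_count_auroc(values, flags):
    """Independent oracle: AUROC as concordant-pair fraction U/(n1*n2),
    counting case-control ties one half."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    cases = values[flags]
    controls = values[~flags]
    wins = 0.0
    for c in cases:
        wins += np.sum(c > controls) + 0.5 * np.sum(c == controls)
    return wins / (cases.size * controls.size)
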