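"""End-to-end run: simulate -> estimate -> classify -> stats -> ROC.

``run_pipeline`` composes the cohort generator, the sparse-sampling PK
model and the nephrotoxicity analysis into one deterministic run and
assembles a :class:`CohortReport` whose tables mirror the standard TDM
report surfaces: a demographics summary, the PK parameter summary,
association and correlation tables, exposure-band frequencies with
chi-square, the on-target trough distribution, and the ROC cut-off table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    CohortConfig,
    assign_aki,
    cohort_to_frames,
    generate_cohort,
    simulate_samples,
)
from .dosing import TargetSpec
from .io import RunConfig, write_table
from .models import NephrotoxicityModel, NephrotoxicityResults, SparsePKModel, SparsePKResults
from .pk import forward_profile, report_round

__all__ = ["CohortReport", "simulate_cohort_tables", "run_pipeline"]


@dataclass
class CohortReport:
    config: RunConfig
    patients: pd.DataFrame
    samples: pd.DataFrame
    pk_results: SparsePKResults
    tox_results: NephrotoxicityResults
    demographics: pd.DataFrame
    pk_summary: pd.DataFrame

    def machine_summary(self) -> dict:
        """Flat, JSON-serializable digest of the headline numbers."""
        tox = self.tox_results
        cut = tox.cutoff_table.set_index("parameter")
        under_over = tox.underdosed_overdosed("trough1")
        under_over_auc = tox.underdosed_overdosed("auc_24h")
        return {
            "n_patients": int(len(self.patients)),
            "n_patients_analyzed": int(tox.n),
            "n_samples": int(len(self.samples)),
            "aki_prevalence_pct": round(100.0 * tox.prevalence, 4),
            "trough1_underdosed_pct": round(under_over["underdosed_pct"], 4),
            "trough1_overdosed_pct": round(under_over["overdosed_pct"], 4),
            "auc24_underdosed_pct": round(under_over_auc["underdosed_pct"], 4),
            "auc24_overdosed_pct": round(under_over_auc["overdosed_pct"], 4),
            "mean_trough_cutoff_ugml": round(float(cut.loc["mean_trough", "cutoff"]), 4),
            "mean_trough_auroc": round(float(cut.loc["mean_trough", "auroc"]), 4),
            "auc_tau_cutoff_ughml": round(float(cut.loc["auc_tau", "cutoff"]), 4),
            "auc_tau_auroc": round(float(cut.loc["auc_tau", "auroc"]), 4),
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.patients, outdir / "patients.csv")
        write_table(self.samples, outdir / "samples.csv")
        write_table(self.pk_results.estimates, outdir / "pk_estimates.csv")
        write_table(self.demographics, outdir / "demographics.csv")
        write_table(self.pk_summary, outdir / "pk_summary.csv")
        write_table(self.tox_results.associations, outdir / "associations.csv")
        write_table(self.tox_results.correlations, outdir / "correlations.csv")
        bands = []
        for metric, table in self.tox_results.band_tables.items():
            t = table.copy()
            t.insert(0, "metric", metric)
            t["chi_square_p"] = self.tox_results.chi_square[metric].p_value
            bands.append(t)
        write_table(pd.concat(bands, ignore_index=True), outdir / "exposure_bands.csv")
        write_table(self.tox_results.cutoff_table, outdir / "roc_cutoffs.csv")
        for marker, curve in self.tox_results.roc_curves.items():
            write_table(curve.as_frame(), outdir / f"roc_curve_{marker}.csv")
        (outdir / "summary.json").write_text(
            json.dumps(self.machine_summary(), indent=2, sort_keys=True) + "\n"
        )


def _demographics_table(patients: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    rows = []
    for col in ["age", "ibw_kg", "height_cm", "baseline_scr_mgdl",
                "baseline_gfr_mlmin"]:
        v = patients[col]
        rows.append(
            {
                "characteristic": col,
                "min": report_round(float(v.min()), decimals),
                "max": report_round(float(v.max()), decimals),
                "mean": report_round(float(v.mean()), decimals),
                "sd": report_round(float(v.std(ddof=1)), decimals)
                if len(v) > 1 else 0.0,
            }
        )
    n = len(patients)
    n_female = int((patients["sex"] == "F").sum())
    rows.append({"characteristic": "female_pct", "min": np.nan, "max": np.nan,
                 "mean": report_round(100.0 * n_female / n, decimals), "sd": np.nan})
    rows.append({"characteristic": "nephrotoxin_cotreat_pct", "min": np.nan,
                 "max": np.nan,
                 "mean": report_round(100.0 * patients["nephrotoxin_cotreat"].mean(),
                               decimals),
                 "sd": np.nan})
    return pd.DataFrame(rows)


def simulate_cohort_tables(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort with outcomes and return (patients, samples) tables.

    The AKI exposure is the *true* (noiseless) steady-state exposure on the
    configured metric, so the outcome process is driven by the patient's
    actual kinetics rather than by measurement noise.
    """
    patients = generate_cohort(config)
    exposures = []
    for p in patients:
        trough = float(
            forward_profile(p.true_cl, p.true_vd, p.regimen, [0.0])[0]
        )
        if config.aki_model.exposure_metric == "mean_trough":
            exposures.append(trough)  # trough1 == trough2 at steady state
        else:  # auc24: interval AUC is dose/Cl exactly at steady state
            auc_tau = p.regimen.dose_mg / p.true_cl
            exposures.append(auc_tau * 24.0 / p.regimen.interval_h)
    assign_aki(patients, exposures, config.aki_model, seed=config.seed)
    profiles = [
        simulate_samples(p, assay_cv=config.assay_cv, seed=config.seed)
        for p in patients
    ]
    patients_df, samples_df = cohort_to_frames(patients, profiles)
    return patients_df, samples_df


def run_pipeline(config: RunConfig) -> CohortReport:
    """Deterministic end-to-end run from a :class:`RunConfig`."""
    cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
    patients_df, samples_df = simulate_cohort_tables(cohort_cfg)

    pk_results = SparsePKModel(patients_df, samples_df).fit()
    targets = TargetSpec(
        trough_band=config.trough_band,
        auc_tau_band=config.auc_tau_band,
        auc24_band=config.auc24_band,
    )
    tox_results = NephrotoxicityModel.from_results(
        pk_results, patients_df, targets
    ).fit()

    decimals = config.report.decimals
    return CohortReport(
        config=config,
        patients=patients_df,
        samples=samples_df,
        pk_results=pk_results,
        tox_results=tox_results,
        demographics=_demographics_table(patients_df, decimals),
        pk_summary=pk_results.summary(decimals),
    )
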