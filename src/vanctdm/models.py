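"""Model / Results objects tying the pipeline stages together.

Two fitted-model surfaces in the statsmodels idiom:

``SparsePKModel``
    Built from a patient table and a timed-sample table; ``fit()`` applies
    the individualized one-compartment estimators to every patient's
    sparse steady-state profile and returns :class:`SparsePKResults` — a
    per-patient estimate frame, a cohort parameter summary, a cohort-level
    paired steady-state test, and dose-recommendation helpers.

``NephrotoxicityModel``
    Built from the PK estimates joined with patient covariates and the AKI
    outcome; ``fit()`` runs the full association battery (two-group tests,
    renal-function correlations, exposure-band chi-square, on-target
    trough distribution, ROC cut-offs, logistic adjustment) and returns
    :class:`NephrotoxicityResults` with table-shaped accessors and a
    ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dosing, toxicity
from .pk import ConcentrationProfile, Regimen, estimate_pk, report_round

__all__ = [
    "SparsePKModel",
    "SparsePKResults",
    "NephrotoxicityModel",
    "NephrotoxicityResults",
    "PK_PARAMETER_COLUMNS",
]

#: estimate-frame columns summarized in the cohort parameter table
PK_PARAMETER_COLUMNS = [
    "trough1", "peak", "trough2", "mean_trough",
    "auc_tau", "auc_24h", "vd", "cl", "k", "t_half",
]

#: ROC markers and their toxicity orientation (k inverts: slow elimination
#: means accumulation, so *lower* k indicates risk)
ROC_MARKERS: list[tuple[str, bool]] = [
    ("trough1", True),
    ("trough2", True),
    ("mean_trough", True),
    ("auc_tau", True),
    ("auc_24h", True),
    ("k", False),
]


class SparsePKModel:
    """Individualized PK estimation for a cohort of sparse profiles."""

    def __init__(self, patients: pd.DataFrame, samples: pd.DataFrame):
        required_p = {"patient_id", "dose_mg", "interval_h", "infusion_h"}
        required_s = {"patient_id", "time_h", "conc_ugml"}
        if missing := required_p - set(patients.columns):
            raise ValueError(f"patients table missing columns: {sorted(missing)}")
        if missing := required_s - set(samples.columns):
            raise ValueError(f"samples table missing columns: {sorted(missing)}")
        if patients["patient_id"].duplicated().any():
            raise ValueError("duplicate patient_id in patients table")
        self.patients = patients.reset_index(drop=True)
        self.samples = samples

    @classmethod
    def from_csv(cls, patients_path, samples_path) -> "SparsePKModel":
        from .io import read_patients, read_samples

        return cls(read_patients(patients_path), read_samples(samples_path))

    def profiles(self) -> list[ConcentrationProfile]:
        out = []
        grouped = self.samples.groupby("patient_id", sort=False)
        for _, prow in self.patients.iterrows():
            pid = prow["patient_id"]
            try:
                grp = grouped.get_group(pid)
            except KeyError:
                raise ValueError(f"no samples for patient {pid}") from None
            grp = grp.sort_values("time_h")
            regimen = Regimen(
                dose_mg=float(prow["dose_mg"]),
                interval_h=float(prow["interval_h"]),
                infusion_h=float(prow["infusion_h"]),
            )
            out.append(
                ConcentrationProfile(
                    patient_id=pid,
                    times=grp["time_h"].to_numpy(),
                    concentrations=grp["conc_ugml"].to_numpy(),
                    regimen=regimen,
                )
            )
        return out

    def fit(self, on_error: str = "skip") -> "SparsePKResults":
        """Estimate every patient; profiles with undefined estimates (e.g. a
        measured trough at or above the measured peak, an assay/sampling
        problem) are dropped with a warning when ``on_error="skip"`` or
        re-raised when ``on_error="raise"``."""
        if on_error not in ("skip", "raise"):
            raise ValueError("on_error must be 'skip' or 'raise'")
        rows = []
        dropped: list = []
        for prof in self.profiles():
            try:
                est = estimate_pk(prof)
            except ValueError as exc:
                if on_error == "raise":
                    raise
                dropped.append(prof.patient_id)
                warnings.warn(
                    f"patient {prof.patient_id}: estimate undefined and "
                    f"dropped ({exc})",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "patient_id": est.patient_id,
                    "trough1": est.trough1,
                    "peak": est.peak,
                    "trough2": est.trough2,
                    "mean_trough": est.mean_trough,
                    "auc_tau": est.auc_tau,
                    "auc_24h": est.auc_24h,
                    "vd": est.vd,
                    "cl": est.cl,
                    "k": est.k,
                    "t_half": est.t_half,
                    "steady_state": est.steady_state,
                }
            )
        if not rows:
            raise ValueError("no patient yielded a defined PK estimate")
        return SparsePKResults(self, pd.DataFrame(rows), dropped=dropped)


@dataclass
class SparsePKResults:
    """Per-patient estimates plus cohort-level views.

    ``dropped`` lists patient ids whose profiles yielded undefined
    estimates and were excluded from the cohort tables.
    """

    model: SparsePKModel
    estimates: pd.DataFrame
    dropped: list = field(default_factory=list)

    def summary(self, decimals: int = 2) -> pd.DataFrame:
        """Cohort parameter table: min-max range and mean +/- SD."""
        rows = []
        for col in PK_PARAMETER_COLUMNS:
            v = self.estimates[col]
            rows.append(
                {
                    "parameter": col,
                    "min": report_round(float(v.min()), decimals),
                    "max": report_round(float(v.max()), decimals),
                    "mean": report_round(float(v.mean()), decimals),
                    "sd": report_round(float(v.std(ddof=1)), decimals)
                    if len(v) > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)

    def steady_state_test(self) -> dict:
        """Cohort-level paired comparison of the two bracketing troughs.

        A non-significant difference supports the steady-state assumption
        (and hence the interval-AUC doubling to 24 h).
        """
        t1 = self.estimates["trough1"].to_numpy()
        t2 = self.estimates["trough2"].to_numpy()
        res = stats.ttest_rel(t1, t2)
        return {
            "mean_trough1": float(np.mean(t1)),
            "mean_trough2": float(np.mean(t2)),
            "p_value": float(res.pvalue),
            "n": int(t1.size),
            "fraction_confirmed": float(self.estimates["steady_state"].mean()),
        }

    def exposure_bands(self) -> pd.DataFrame:
        """Band classification of every patient for each exposure metric."""
        est = self.estimates
        out = est[["patient_id"]].copy()
        for col, metric in [
            ("trough1", "trough"), ("trough2", "trough"),
            ("auc_tau", "auc_tau"), ("auc_24h", "auc24"),
        ]:
            out[f"{col}_band"] = [
                dosing.classify_exposure(v, metric).label for v in est[col]
            ]
        return out

    def recommend_doses(
        self, targets: dosing.TargetSpec | None = None,
        method: str = "auc_scaling",
        increment_mg: float = 250.0,
    ) -> pd.DataFrame:
        """AUC-scaling or target-trough re-dosing for every patient."""
        targets = targets or dosing.TargetSpec()
        patients = self.model.patients.set_index("patient_id")
        rows = []
        for _, est in self.estimates.iterrows():
            pid = est["patient_id"]
            prow = patients.loc[pid]
            regimen = Regimen(
                float(prow["dose_mg"]), float(prow["interval_h"]),
                float(prow["infusion_h"]),
            )
            if method == "auc_scaling":
                target_auc = targets.auc_tau_midpoint * regimen.interval_h / 12.0
                raw = dosing.scale_dose_to_auc(
                    regimen.dose_mg, est["auc_tau"], target_auc
                )
                rec = dosing.DoseRecommendation(
                    patient_id=pid, method="auc_scaling",
                    current_dose_mg=regimen.dose_mg,
                    new_dose_mg=dosing.round_to_increment(raw, increment_mg),
                    current_auc=float(est["auc_tau"]), target_auc=target_auc,
                )
            elif method == "target_trough":
                rec = dosing.recommend_dose_trough(
                    pid, targets.trough_midpoint,
                    float(est["cl"]), float(est["vd"]), regimen,
                )
            else:
                raise ValueError(f"unknown dosing method {method!r}")
            rows.append(rec.__dict__)
        return pd.DataFrame(rows)


class NephrotoxicityModel:
    """Exposure-toxicity analysis over a cohort of PK estimates."""

    def __init__(
        self,
        estimates: pd.DataFrame,
        patients: pd.DataFrame,
        targets: dosing.TargetSpec | None = None,
    ):
        required = {"patient_id", "aki", "baseline_scr_mgdl", "baseline_gfr_mlmin"}
        if missing := required - set(patients.columns):
            raise ValueError(f"patients table missing columns: {sorted(missing)}")
        data = estimates.merge(patients, on="patient_id", validate="one_to_one")
        if data["aki"].isna().any():
            raise ValueError("AKI outcome missing for some patients")
        flags = data["aki"].astype(bool)
        if flags.all() or not flags.any():
            raise ValueError("both AKI outcomes must be present in the cohort")
        self.data = data
        self.targets = targets or dosing.TargetSpec()

    @classmethod
    def from_results(
        cls, results: SparsePKResults, patients: pd.DataFrame,
        targets: dosing.TargetSpec | None = None,
    ) -> "NephrotoxicityModel":
        return cls(results.estimates, patients, targets)

    def fit(self) -> "NephrotoxicityResults":
        data = self.data
        flags = data["aki"].astype(bool).to_numpy()

        assoc_params = (
            ["baseline_scr_mgdl", "baseline_gfr_mlmin"] + PK_PARAMETER_COLUMNS
        )
        associations = pd.DataFrame(
            [
                toxicity.association_test(
                    data[c].to_numpy(), flags, parameter=c
                ).__dict__
                for c in assoc_params
            ]
        )

        corr_rows = []
        for baseline in ("baseline_scr_mgdl", "baseline_gfr_mlmin"):
            others = [c for c in assoc_params if c != baseline]
            for c in others:
                r, p = toxicity.pearson_corr(data[baseline], data[c])
                corr_rows.append(
                    {"baseline": baseline, "parameter": c, "r": r, "p_value": p}
                )
        correlations = pd.DataFrame(corr_rows)

        band_tables = {}
        chi_square = {}
        for col, metric in [
            ("trough1", "trough"), ("trough2", "trough"),
            ("auc_tau", "auc_tau"), ("auc_24h", "auc24"),
        ]:
            labels = [
                dosing.classify_exposure(v, metric).label for v in data[col]
            ]
            order = dosing.band_labels(metric)
            counts = pd.Series(labels).value_counts()
            band_tables[col] = pd.DataFrame(
                {
                    "band": order,
                    "count": [int(counts.get(b, 0)) for b in order],
                    "percent": [
                        100.0 * counts.get(b, 0) / len(data) for b in order
                    ],
                }
            )
            chi_square[col] = toxicity.chi_square_bands(labels, flags)

        trough_in_target = {
            "auc_tau": toxicity.trough_distribution_in_target_auc(
                data, "trough1", "auc_tau", self.targets.auc_tau_band
            ),
            "auc_24h": toxicity.trough_distribution_in_target_auc(
                data, "trough1", "auc_24h", self.targets.auc24_band
            ),
        }

        roc_curves = {}
        cutoffs = []
        for marker, higher in ROC_MARKERS:
            curve, cut = toxicity.roc_and_cutoff(
                data[marker].to_numpy(), flags, parameter=marker,
                higher_is_toxic=higher,
            )
            roc_curves[marker] = curve
            cutoffs.append(cut.__dict__)
        cutoff_table = pd.DataFrame(cutoffs)

        adjustment = None
        if "nephrotoxin_cotreat" in data.columns:
            try:
                adjustment = toxicity.adjusted_association(
                    data["mean_trough"].to_numpy(), flags,
                    covariates=data[["nephrotoxin_cotreat"]].astype(float),
                )
            except RuntimeError:
                adjustment = None

        return NephrotoxicityResults(
            model=self,
            n=len(data),
            prevalence=float(flags.mean()),
            associations=associations,
            correlations=correlations,
            band_tables=band_tables,
            chi_square=chi_square,
            trough_in_target=trough_in_target,
            roc_curves=roc_curves,
            cutoff_table=cutoff_table,
            adjustment=adjustment,
        )


@dataclass
class NephrotoxicityResults:
    model: NephrotoxicityModel
    n: int
    prevalence: float
    associations: pd.DataFrame
    correlations: pd.DataFrame
    band_tables: dict[str, pd.DataFrame]
    chi_square: dict[str, toxicity.ChiSquareResult]
    trough_in_target: dict[str, toxicity.TroughDistributionResult]
    roc_curves: dict[str, toxicity.ROCCurve]
    cutoff_table: pd.DataFrame
    adjustment: toxicity.LogisticAdjustment | None = None
    _summary_cache: str | None = field(default=None, repr=False)

    def underdosed_overdosed(self, metric_column: str = "trough1") -> dict:
        """Fractions below / above the therapeutic band, in percent."""
        metric = {"trough1": "trough", "trough2": "trough",
                  "auc_tau": "auc_tau", "auc_24h": "auc24"}[metric_column]
        table = self.band_tables[metric_column]
        band_pct = dict(zip(table["band"], table["percent"]))
        return {
            "underdosed_pct": dosing.subtherapeutic_pct(band_pct, metric),
            "overdosed_pct": dosing.supratherapeutic_pct(band_pct, metric),
        }

    def summary(self, decimals: int = 2) -> str:
        lines = [
            f"Nephrotoxicity analysis: n={self.n}, "
            f"AKI prevalence {100 * self.prevalence:.1f}%",
            "",
            "Association with AKI (two-group tests):",
            self.associations[
                ["parameter", "test_used", "p_value"]
            ].round(4).to_string(index=False),
            "",
            "ROC cut-offs (Youden):",
            self.cutoff_table[
                ["parameter", "cutoff", "auroc", "sensitivity_pct",
                 "specificity_pct"]
            ].round(decimals).to_string(index=False),
        ]
        if self.adjustment is not None:
            adj = self.adjustment
            lines += [
                "",
                "Nephrotoxin-adjusted exposure odds ratio "
                f"(per ug/ml mean trough): {adj.odds_ratio:.3f} "
                f"(95% CI {adj.conf_int[0]:.3f}-{adj.conf_int[1]:.3f}, "
                f"p={adj.p_value:.4f})",
            ]
        return "\n".join(lines)
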