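"""Nephrotoxicity association statistics and ROC cut-off derivation.

The analysis battery applied to a cohort of individualized PK estimates
with a binary acute-kidney-injury (AKI) outcome:

* normality-gated two-group comparisons — Student t when both outcome
  groups pass a Lilliefors-type Kolmogorov-Smirnov normality test at
  alpha = 0.05, Mann-Whitney U otherwise;
* Pearson correlation between baseline renal function and PK parameters;
* Pearson chi-square association of AKI across exposure bands (with a
  small-expected-count warning and, for 2x2 tables, a Fisher fallback);
* empirical ROC curves with the cut-off chosen by the Youden index
  (J = sensitivity + specificity - 1), ties resolved toward the more
  sensitive (lower) threshold;
* a multivariate logistic adjustment of the exposure-AKI association for
  concomitant-nephrotoxin co-treatment and other covariates.

No multiple-testing correction is applied by default (each table reports
raw p-values); a Holm adjustment helper is available for users who want
family-wise control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import Logit
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalityResult",
    "AssociationResult",
    "ChiSquareResult",
    "ROCCurve",
    "CutoffResult",
    "TroughDistributionResult",
    "LogisticAdjustment",
    "ks_normality",
    "association_test",
    "pearson_corr",
    "chi_square_bands",
    "trough_distribution_in_target_auc",
    "roc_curve_points",
    "roc_and_cutoff",
    "adjusted_association",
    "holm_adjust",
]


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    reason: str = ""


@dataclass
class AssociationResult:
    parameter: str
    test_used: str  # "t_test" | "mann_whitney"
    p_value: float
    aki_summary: float  # group mean (t-test) or median (Mann-Whitney)
    no_aki_summary: float
    n_aki: int
    n_no_aki: int


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    low_expected: bool = False
    fisher_p: float | None = None


@dataclass
class ROCCurve:
    """Empirical ROC of a continuous marker for a binary outcome.

    Thresholds are the midpoints between sorted unique marker values plus
    -inf/+inf sentinels; a subject is called positive when the (oriented)
    marker is >= threshold.  Sensitivity is therefore 1 at the -inf end
    and specificity 1 at the +inf end.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    higher_is_toxic: bool = True

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


@dataclass
class CutoffResult:
    parameter: str
    cutoff: float
    auroc: float
    sensitivity_pct: float
    specificity_pct: float
    youden_j: float
    defined: bool = True


@dataclass
class TroughDistributionResult:
    """Trough-band mix among patients whose AUC hit the target band."""

    n_selected: int
    frequencies: pd.DataFrame | None  # columns: band, count, percent
    empty: bool = field(init=False)

    def __post_init__(self) -> None:
        self.empty = self.n_selected == 0


@dataclass
class LogisticAdjustment:
    odds_ratio: float
    coef: float
    p_value: float
    conf_int: tuple[float, float]
    covariates_used: list[str]
    dropped: list[str]


def ks_normality(values, alpha: float = 0.05) -> NormalityResult:
    """Kolmogorov-Smirnov normality check with estimated parameters.

    The reference normal uses the sample mean and SD, so Lilliefors-type
    critical values (approximated by simulation/table in statsmodels) are
    required rather than the classical KS distribution.  Constant input
    fails with an explicit reason.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("normality testing needs at least 4 observations")
    if np.ptp(x) == 0:
        return NormalityResult(np.nan, 0.0, False, reason="constant input")
    stat, p = lilliefors(x, dist="norm")
    return NormalityResult(float(stat), float(p), bool(p > alpha))


def association_test(values, aki_flags, parameter: str = "") -> AssociationResult:
    """Two-group comparison of a PK parameter between AKI and non-AKI.

    Student t (independent samples, pooled variance) when both groups pass
    the normality gate; Mann-Whitney U otherwise.  Groups too small for a
    normality check (n < 4) fall back to Mann-Whitney with a warning.
    """
    x = np.asarray(values, dtype=float)
    flags = np.asarray(aki_flags, dtype=bool)
    if x.size != flags.size:
        raise ValueError("values and aki_flags must have equal length")
    g1, g0 = x[flags], x[~flags]
    if g1.size == 0 or g0.size == 0:
        raise ValueError("both outcome classes must be non-empty")

    small = min(g1.size, g0.size) < 4
    if small:
        warnings.warn(
            f"{parameter or 'parameter'}: a group has fewer than 4 patients; "
            "using Mann-Whitney without a normality check",
            stacklevel=2,
        )
        both_normal = False
    else:
        both_normal = ks_normality(g1).normal and ks_normality(g0).normal

    if both_normal:
        res = stats.ttest_ind(g1, g0)
        return AssociationResult(
            parameter, "t_test", float(res.pvalue),
            float(np.mean(g1)), float(np.mean(g0)), g1.size, g0.size,
        )
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided")
    return AssociationResult(
        parameter, "mann_whitney", float(res.pvalue),
        float(np.median(g1)), float(np.median(g0)), g1.size, g0.size,
    )


def pearson_corr(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def chi_square_bands(band_labels, aki_flags) -> ChiSquareResult:
    """Pearson chi-square on the exposure-band x AKI contingency table.

    No continuity correction.  Expected counts below 5 trigger a warning;
    for 2x2 tables a Fisher exact p-value is attached as a fallback.
    """
    bands = pd.Series(band_labels, name="band")
    flags = pd.Series(np.asarray(aki_flags, dtype=int), name="aki")
    if bands.size != flags.size:
        raise ValueError("band_labels and aki_flags must have equal length")
    table = pd.crosstab(bands, flags)
    if table.size == 0:
        raise ValueError("empty contingency table")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 exposure bands")
    if table.shape[1] < 2:
        raise ValueError("both outcomes must be present in the cohort")
    stat, p, df, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    low = bool(np.any(expected < 5))
    fisher_p = None
    if low:
        warnings.warn(
            "expected counts below 5 in the band x AKI table; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
        if table.shape == (2, 2):
            fisher_p = float(stats.fisher_exact(table.to_numpy())[1])
    return ChiSquareResult(float(stat), int(df), float(p), table, low, fisher_p)


def trough_distribution_in_target_auc(
    estimates: pd.DataFrame,
    trough_column: str = "trough1",
    auc_column: str = "auc_tau",
    target_band: tuple[float, float] = (200.0, 300.0),
) -> TroughDistributionResult:
    """Trough-band frequencies among patients whose AUC is on target.

    Answers whether a trough-only monitoring rule would have recognized
    the patients who actually achieved the target AUC band.  Percentages
    sum to 100 over the selection; an empty selection is an explicit
    empty result, not a table of zeros.
    """
    from .dosing import band_labels as _band_labels, classify_exposure

    lo, hi = target_band
    sel = estimates[(estimates[auc_column] >= lo) & (estimates[auc_column] < hi)]
    if sel.empty:
        return TroughDistributionResult(n_selected=0, frequencies=None)
    labels = [classify_exposure(v, "trough").label for v in sel[trough_column]]
    counts = pd.Series(labels).value_counts()
    rows = []
    for band in _band_labels("trough"):
        c = int(counts.get(band, 0))
        rows.append({"band": band, "count": c, "percent": 100.0 * c / len(sel)})
    return TroughDistributionResult(
        n_selected=len(sel), frequencies=pd.DataFrame(rows)
    )


def roc_curve_points(values, aki_flags, higher_is_toxic: bool = True) -> ROCCurve:
    """Empirical ROC with midpoint thresholds and +/-inf sentinels.

    The trapezoidal area under the resulting curve equals the
    Mann-Whitney U statistic divided by n1*n2 (ties counted one half).
    Markers for which *lower* values indicate toxicity (e.g. the
    elimination constant k) are handled by orientation; reported
    thresholds stay on the original scale.
    """
    x = np.asarray(values, dtype=float)
    flags = np.asarray(aki_flags, dtype=bool)
    if x.size != flags.size:
        raise ValueError("values and aki_flags must have equal length")
    if not flags.any() or flags.all():
        raise ValueError("both outcome classes must be non-empty")

    oriented = x if higher_is_toxic else -x
    uniq = np.unique(oriented)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    cases = np.sort(oriented[flags])
    controls = np.sort(oriented[~flags])
    # positive call: oriented value >= threshold
    sens = 1.0 - np.searchsorted(cases, thresholds, side="left") / cases.size
    spec = np.searchsorted(controls, thresholds, side="left") / controls.size

    fpr = 1.0 - spec
    auroc = float(-np.trapezoid(sens, fpr))  # fpr decreases along thresholds

    out_thresholds = thresholds if higher_is_toxic else -thresholds
    return ROCCurve(out_thresholds, sens, spec, auroc, higher_is_toxic)


def roc_and_cutoff(
    values, aki_flags, parameter: str = "", higher_is_toxic: bool = True
) -> tuple[ROCCurve, CutoffResult]:
    """ROC curve plus the Youden-optimal cut-off.

    The cut-off maximizes J = sensitivity + specificity - 1; ties go to
    the lower (more sensitive) threshold.  A constant marker yields AUROC
    0.5 and an undefined cut-off flag.
    """
    curve = roc_curve_points(values, aki_flags, higher_is_toxic)
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        return curve, CutoffResult(
            parameter, float("nan"), 0.5, float("nan"), float("nan"),
            float("nan"), defined=False,
        )
    j = curve.sensitivity + curve.specificity - 1.0
    finite = np.isfinite(curve.thresholds)
    j_masked = np.where(finite, j, -np.inf)
    # oriented thresholds ascend with index; the lowest oriented threshold
    # is the most sensitive, so pick the first argmax
    best = int(np.argmax(j_masked))
    return curve, CutoffResult(
        parameter=parameter,
        cutoff=float(curve.thresholds[best]),
        auroc=curve.auroc,
        sensitivity_pct=100.0 * float(curve.sensitivity[best]),
        specificity_pct=100.0 * float(curve.specificity[best]),
        youden_j=float(j[best]),
    )


def adjusted_association(
    exposure, aki_flags, covariates: pd.DataFrame | None = None
) -> LogisticAdjustment:
    """Exposure odds ratio adjusted for covariates by logistic regression.

    Maximum-likelihood fit of AKI on exposure plus covariates with an
    intercept.  Constant covariate columns are dropped with a warning.
    Perfect separation is reported as an explicit failure (a penalized
    refit is a deliberate user decision, never applied silently).
    """
    y = np.asarray(aki_flags, dtype=float)
    x = np.asarray(exposure, dtype=float)
    design = pd.DataFrame({"const": 1.0, "exposure": x})
    dropped: list[str] = []
    used: list[str] = []
    if covariates is not None:
        for col in covariates.columns:
            v = np.asarray(covariates[col], dtype=float)
            if np.ptp(v) == 0:
                dropped.append(col)
                warnings.warn(
                    f"covariate {col!r} is constant and was dropped",
                    stacklevel=2,
                )
                continue
            design[col] = v
            used.append(col)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = Logit(y, design).fit(disp=False, maxiter=200)
    except Exception as exc:  # includes PerfectSeparationError
        raise RuntimeError(
            "logistic adjustment failed (possible perfect separation); "
            "consider collapsing exposure or a penalized fit: " + str(exc)
        ) from exc
    if not np.all(np.isfinite(fit.bse)):
        raise RuntimeError(
            "logistic adjustment is degenerate (infinite standard errors; "
            "likely separation)"
        )
    coef = float(fit.params["exposure"])
    ci = fit.conf_int().loc["exposure"]
    return LogisticAdjustment(
        odds_ratio=float(np.exp(coef)),
        coef=coef,
        p_value=float(fit.pvalues["exposure"]),
        conf_int=(float(np.exp(ci[0])), float(np.exp(ci[1]))),
        covariates_used=used,
        dropped=dropped,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down family-wise adjustment (opt-in; raw p by default)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
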