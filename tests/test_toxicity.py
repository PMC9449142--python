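"""Association statistics, ROC construction, and the Youden cut-off."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from vanctdm.toxicity import (
    adjusted_association,
    association_test,
    chi_square_bands,
    holm_adjust,
    ks_normality,
    pearson_corr,
    roc_and_cutoff,
    roc_curve_points,
    trough_distribution_in_target_auc,
)

from conftest import pair_count_auroc


class TestNormality:
    def test_normal_sample_passes(self):
        x = np.random.default_rng(0).normal(10, 2, size=500)
        assert ks_normality(x).normal

    def test_null_pass_rate_near_alpha(self):
        passes = sum(
            ks_normality(np.random.default_rng(s).normal(size=500)).normal
            for s in range(200)
        )
        assert 0.90 <= passes / 200 <= 0.99

    def test_heavy_tailed_mixture_fails(self):
        fails = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = np.where(
                rng.random(500) < 0.1, rng.normal(0, 10, 500), rng.normal(0, 1, 500)
            )
            fails += not ks_normality(x).normal
        assert fails >= 95

    def test_constant_input_fails_with_reason(self):
        res = ks_normality(np.full(50, 3.0))
        assert not res.normal
        assert "constant" in res.reason

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestAssociationTest:
    def test_type_one_error_control(self):
        """Identical distributions: p > 0.05 in at least 90% of seeds."""
        keep = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.normal(10, 3, size=400)
            flags = np.zeros(400, dtype=bool)
            flags[:200] = True
            keep += association_test(x, flags).p_value > 0.05
        assert keep >= 90

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)  # 3 pooled SDs apart
        res = association_test(
            np.concatenate([a, b]),
            np.concatenate([np.zeros(200, bool), np.ones(200, bool)]),
        )
        assert res.p_value < 0.001

    def test_gate_selects_mann_whitney_for_skewed_data(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(1, 1.2, size=400)
        flags = rng.random(400) < 0.3
        res = association_test(x, flags)
        assert res.test_used == "mann_whitney"

    def test_tiny_group_warns_and_computes(self):
        x = np.arange(50, dtype=float)
        flags = np.zeros(50, dtype=bool)
        flags[0] = True
        with pytest.warns(UserWarning, match="fewer than 4"):
            res = association_test(x, flags)
        assert 0 <= res.p_value <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            association_test(np.arange(10.0), np.zeros(10, bool))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(20.0)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        x = np.arange(20.0)
        r, _ = pearson_corr(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))


class TestChiSquare:
    @staticmethod
    def _from_table(table):
        """Expand a bands x outcome count table into label/flag vectors."""
        labels, flags = [], []
        for i, row in enumerate(table):
            for j, count in enumerate(row):
                labels += [f"band{i}"] * count
                flags += [bool(j)] * count
        return labels, flags

    def test_perfect_independence(self):
        labels, flags = self._from_table([[10, 10], [10, 10]])
        res = chi_square_bands(labels, flags)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_no_continuity_correction(self):
        # hand value: Pearson chi-square of [[20,0],[0,20]] is exactly 40
        # (expected counts are all 10, so no small-count fallback)
        labels, flags = self._from_table([[20, 0], [0, 20]])
        res = chi_square_bands(labels, flags)
        assert res.statistic == pytest.approx(40.0)
        assert res.fisher_p is None

    def test_small_expected_counts_trigger_fisher_fallback(self):
        labels, flags = self._from_table([[4, 2], [3, 3]])
        with pytest.warns(UserWarning, match="expected counts"):
            res = chi_square_bands(labels, flags)
        assert res.low_expected
        assert res.fisher_p is not None

    def test_all_cases_in_top_band(self):
        labels, flags = self._from_table([[10, 0], [10, 0], [10, 0], [0, 10]])
        with pytest.warns(UserWarning):
            res = chi_square_bands(labels, flags)
        assert res.p_value < 0.01

    def test_invariant_to_band_reordering(self):
        rng = np.random.default_rng(3)
        labels = rng.choice(["a", "b", "c"], size=300).tolist()
        flags = (rng.random(300) < 0.4).tolist()
        stat1 = chi_square_bands(labels, flags).statistic
        relabel = {"a": "z", "b": "y", "c": "x"}
        stat2 = chi_square_bands([relabel[l] for l in labels], flags).statistic
        assert stat1 == pytest.approx(stat2)

    def test_single_band_rejected(self):
        with pytest.raises(ValueError):
            chi_square_bands(["a"] * 20, [True] * 10 + [False] * 10)


class TestTroughDistribution:
    def _frame(self, troughs, aucs):
        return pd.DataFrame(
            {"trough1": troughs, "auc_tau": aucs,
             "patient_id": range(len(troughs))}
        )

    def test_on_target_fraction(self):
        # 12 on-target patients, 4 with trough in 10-15
        troughs = [12.0] * 4 + [17.0] * 4 + [22.0] * 4
        aucs = [250.0] * 12
        res = trough_distribution_in_target_auc(self._frame(troughs, aucs))
        assert res.n_selected == 12
        freq = res.frequencies.set_index("band")["percent"]
        assert freq["10-15"] == pytest.approx(33.33, abs=0.01)
        assert freq.sum() == pytest.approx(100.0)

    def test_single_band_dominates(self):
        res = trough_distribution_in_target_auc(
            self._frame([12.0] * 6, [250.0] * 6)
        )
        assert res.frequencies.set_index("band")["percent"]["10-15"] == 100.0

    def test_empty_selection_is_explicit(self):
        res = trough_distribution_in_target_auc(
            self._frame([12.0] * 5, [100.0] * 5)
        )
        assert res.empty
        assert res.frequencies is None


class TestROC:
    def test_small_instance_pair_counting(self):
        values = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        flags = np.array([False, False, False, True, True])
        curve, cut = roc_and_cutoff(values, flags)
        assert curve.auroc == pytest.approx(5.0 / 6.0)

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(10, 60)
            values = rng.normal(size=n).round(1)  # force some ties
            flags = rng.random(n) < 0.4
            if flags.all() or not flags.any():
                continue
            curve = roc_curve_points(values, flags)
            assert curve.auroc == pytest.approx(
                roc_auc_score(flags, values), abs=1e-12
            )

    def test_perfect_separation(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0])
        flags = np.array([False, False, False, True, True])
        curve, cut = roc_and_cutoff(values, flags)
        assert curve.auroc == 1.0
        assert cut.sensitivity_pct == 100.0
        assert cut.specificity_pct == 100.0
        assert 3.0 < cut.cutoff <= 10.0

    def test_null_auroc_near_half(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=2000)
        flags = rng.permutation([True] * 400 + [False] * 1600)
        curve = roc_curve_points(values, flags)
        assert abs(curve.auroc - 0.5) < 0.03

    def test_sentinel_ends(self):
        rng = np.random.default_rng(13)
        curve = roc_curve_points(rng.normal(size=50), rng.random(50) < 0.5)
        assert curve.sensitivity[0] == 1.0  # -inf threshold calls everyone
        assert curve.specificity[-1] == 1.0  # +inf threshold calls no one

    def test_monotone_sensitivity(self):
        rng = np.random.default_rng(17)
        curve = roc_curve_points(rng.normal(size=200), rng.random(200) < 0.3)
        assert np.all(np.diff(curve.sensitivity) <= 0)
        assert np.all(np.diff(1.0 - curve.specificity) <= 0)

    def test_lower_is_toxic_orientation(self):
        """Markers where small values mean risk (elimination constant k)."""
        rng = np.random.default_rng(19)
        k = np.concatenate([rng.normal(0.04, 0.01, 50),  # cases: slow
                            rng.normal(0.10, 0.02, 150)])
        flags = np.array([True] * 50 + [False] * 150)
        curve, cut = roc_and_cutoff(k, flags, higher_is_toxic=False)
        assert curve.auroc > 0.9
        assert 0.03 < cut.cutoff < 0.1  # reported on the original scale

    def test_constant_marker_undefined_cutoff(self):
        flags = np.array([True] * 5 + [False] * 5)
        curve, cut = roc_and_cutoff(np.ones(10), flags)
        assert curve.auroc == pytest.approx(0.5)
        assert not cut.defined

    def test_tie_break_toward_sensitive_threshold(self):
        # two thresholds share the maximal Youden J; the lower one wins
        values = np.array([1.0, 2.0, 3.0, 4.0])
        flags = np.array([False, False, True, True])
        _, cut = roc_and_cutoff(values, flags)
        assert cut.cutoff == pytest.approx(2.5)


class TestAdjustedAssociation:
    def test_independent_covariate_leaves_or_unchanged(self):
        rng = np.random.default_rng(23)
        n = 5000
        x = rng.normal(15, 5, n)
        z = rng.random(n) < 0.25  # independent of both exposure and outcome
        p = 1.0 / (1.0 + np.exp(-(-4.0 + 0.2 * x)))
        y = rng.random(n) < p
        adj = adjusted_association(x, y, pd.DataFrame({"z": z.astype(float)}))
        una = adjusted_association(x, y)
        assert adj.odds_ratio == pytest.approx(una.odds_ratio, rel=0.10)
        assert adj.covariates_used == ["z"]

    def test_null_exposure_ci_coverage(self):
        """Exposure truly inert: the 95% CI covers OR=1 at ~95% of seeds."""
        covered = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            x = rng.normal(15, 5, 400)
            y = rng.random(400) < 0.3
            adj = adjusted_association(x, y)
            covered += adj.conf_int[0] <= 1.0 <= adj.conf_int[1]
        assert 0.90 <= covered / 200 <= 0.99

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(29)
        x = rng.normal(15, 5, 300)
        y = rng.random(300) < 0.3
        with pytest.warns(UserWarning, match="constant"):
            adj = adjusted_association(
                x, y, pd.DataFrame({"zeros": np.zeros(300)})
            )
        assert adj.dropped == ["zeros"]

    def test_perfect_separation_is_explicit_failure(self):
        x = np.concatenate([np.zeros(20), np.ones(20) * 100.0])
        y = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        with pytest.raises(RuntimeError, match="separation"):
            adjusted_association(x, y)


def test_holm_adjustment_is_monotone_and_conservative():
    p = np.array([0.001, 0.01, 0.04, 0.2])
    adj = holm_adjust(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
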