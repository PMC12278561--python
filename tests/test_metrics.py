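"""Metric suite: library-oracle equivalence, closed forms, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clabsi_forest.metrics import (
    auprc,
    auroc,
    brier_skill,
    calibration_slope,
    eci,
    eo_ratio,
    landmark_metrics,
    loess_smooth,
    metric_suite,
    summarize,
)


def random_preds_labels(rng, n=200, ties=True):
    preds = rng.random(n).round(1) if ties else rng.random(n)
    labels = (rng.random(n) < 0.3).astype(float)
    if labels.sum() in (0, n):
        labels[:2] = [0, 1]
    return preds, labels


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_predictions_are_chance(self):
        assert auroc([0.5] * 6, [1, 0, 0, 1, 0, 0]) == 0.5

    def test_single_class_is_missing(self):
        assert np.isnan(auroc([0.1, 0.2], [0, 0]))

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(30):
            p, y = random_preds_labels(rng)
            assert auroc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_complement_identities(self, rng):
        p, y = random_preds_labels(rng, ties=False)
        assert auroc(1 - p, y) == pytest.approx(1 - auroc(p, y), abs=1e-12)
        assert auroc(1 - p, 1 - y) == pytest.approx(auroc(p, y), abs=1e-12)


class TestAUPRC:
    def test_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_predictions_equal_prevalence(self):
        assert auprc([0.4] * 10, [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(30):
            p, y = random_preds_labels(rng)
            assert auprc(p, y) == pytest.approx(average_precision_score(y, p), abs=1e-12)


class TestBrierSkill:
    def test_prevalence_prediction_has_zero_skill(self):
        y = np.array([1, 0, 0, 0])
        assert brier_skill(np.full(4, 0.25), y, 0.25) == pytest.approx(0.0)

    def test_perfect_prediction_has_full_skill(self):
        y = np.array([1.0, 0.0, 0.0])
        assert brier_skill(y, y, 1 / 3) == pytest.approx(1.0)

    def test_worse_than_prevalence_is_negative(self):
        y = np.array([1, 0, 0, 0])
        assert brier_skill(1 - y, y, 0.25) < 0

    def test_ratio_form_available(self):
        y = np.array([1, 0, 0, 0])
        assert brier_skill(np.full(4, 0.25), y, 0.25, form="ratio") == pytest.approx(1.0)

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            brier_skill([0.5], [1], 1.0)


class TestEORatio:
    def test_arithmetic(self):
        assert eo_ratio([0.02, 0.02], [0, 0.02]) == pytest.approx(2.0)

    def test_calibrated_means_give_one(self):
        y = np.array([1, 0, 0, 0])
        assert eo_ratio(np.full(4, 0.25), y) == pytest.approx(1.0)

    def test_no_events_is_missing(self):
        assert np.isnan(eo_ratio([0.1], [0]))


class TestCalibrationSlope:
    def test_recovers_unity_for_calibrated_predictions(self):
        rng = np.random.default_rng(1)
        p = rng.beta(1, 20, size=50_000)
        y = (rng.random(50_000) < p).astype(float)
        assert calibration_slope(p, y) == pytest.approx(1.0, abs=0.06)

    def test_underconfident_predictions_have_slope_above_one(self):
        rng = np.random.default_rng(2)
        p_true = rng.beta(2, 10, size=50_000)
        y = (rng.random(50_000) < p_true).astype(float)
        prev = p_true.mean()
        squashed = prev + 0.3 * (p_true - prev)  # shrink spread toward prevalence
        assert calibration_slope(squashed, y) > 1.5

    def test_matches_newton_mle_oracle(self, rng):
        """Independent IRLS logistic fit agrees to 1e-8."""
        for _ in range(10):
            p, y = random_preds_labels(rng, n=400, ties=False)
            p = 0.02 + 0.5 * p
            lp = np.log(p / (1 - p))
            X = np.column_stack([np.ones_like(lp), lp])
            beta = np.zeros(2)
            for _ in range(50):
                mu = 1 / (1 + np.exp(-X @ beta))
                W = mu * (1 - mu)
                step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - mu))
                beta = beta + step
                if np.abs(step).max() < 1e-12:
                    break
            assert calibration_slope(p, y) == pytest.approx(beta[1], abs=1e-8)

    def test_single_class_is_missing(self):
        assert np.isnan(calibration_slope([0.2, 0.4], [0, 0]))


class TestECI:
    def test_constant_predictions_reduce_to_squared_gap(self):
        """With constant predictions the smoother collapses to the mean and
        ECI = 100 * (c - prevalence)^2."""
        y = np.r_[np.ones(10), np.zeros(40)]
        c = 0.5
        out = eci(np.full(50, c), y)
        assert out == pytest.approx(100 * (c - 0.2) ** 2, abs=1e-9)

    def test_near_zero_for_calibrated_predictions(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.05, 0.95, size=4000)
        y = (rng.random(4000) < p).astype(float)
        assert eci(p, y) < 0.1

    def test_row_order_invariant(self, rng):
        p, y = random_preds_labels(rng, n=300)
        perm = rng.permutation(300)
        assert eci(p, y) == pytest.approx(eci(p[perm], y[perm]), abs=1e-12)

    def test_degenerate_inputs_are_missing(self):
        assert np.isnan(eci([0.5] * 5, [1, 0, 1, 0, 1]))  # < 10 rows

    def test_loess_recovers_a_smooth_trend(self):
        x = np.linspace(0, 1, 500)
        y = x**2
        fit = loess_smooth(x, y, span=0.3)
        assert np.max(np.abs(fit - y)) < 0.01


class TestLandmarkMetrics:
    def test_single_stratum_matches_overall(self, rng):
        p, y = random_preds_labels(rng, n=300)
        lm = np.zeros(300, dtype=int)
        out = landmark_metrics(p, y, lm)
        overall = metric_suite(p, y)
        got = dict(zip(out["metric"], out["value"]))
        for k in ("AUROC", "AUPRC", "EO"):
            assert got[k] == pytest.approx(overall[k], abs=1e-12)

    def test_sparse_stratum_reported_missing(self, rng):
        p = rng.random(60)
        y = np.zeros(60)
        y[:30][:2] = 1  # landmark 0: 2 events (< 5); landmark 1: none
        lm = np.r_[np.zeros(30, int), np.ones(30, int)]
        out = landmark_metrics(p, y, lm)
        assert out["value"].isna().all()

    def test_disjoint_strata_reproduce_subset_auroc(self, rng):
        p, y = random_preds_labels(rng, n=400, ties=False)
        y[:200] = (rng.random(200) < 0.3).astype(float)
        lm = np.r_[np.zeros(200, int), np.ones(200, int)]
        out = landmark_metrics(p, y, lm, min_events=1)
        a0 = out[(out.landmark == 0) & (out.metric == "AUROC")]["value"].iloc[0]
        assert a0 == pytest.approx(auroc(p[:200], y[:200]), abs=1e-12)


class TestSummarize:
    def test_quartile_convention(self):
        df = pd.DataFrame(
            {"model": "m", "landmark": "all", "metric": "AUROC", "value": [1.0, 2.0, 3.0]}
        )
        out = summarize(df)
        assert out.loc[0, "median"] == 2.0
        assert out.loc[0, "q25"] == 1.5
        assert out.loc[0, "q75"] == 2.5

    def test_single_split_has_zero_iqr_width(self):
        df = pd.DataFrame({"model": "m", "landmark": "all", "metric": "EO", "value": [1.1]})
        out = summarize(df)
        assert out.loc[0, "q25"] == out.loc[0, "q75"] == 1.1

    def test_missing_excluded_with_count(self):
        df = pd.DataFrame(
            {"model": "m", "landmark": "all", "metric": "ECI", "value": [np.nan, 2.0, 4.0]}
        )
        out = summarize(df)
        assert out.loc[0, "n"] == 2
        assert out.loc[0, "median"] == 3.0


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_metrics_invariant_to_joint_permutation(seed):
    rng = np.random.default_rng(seed)
    p, y = random_preds_labels(rng, n=80)
    perm = rng.permutation(80)
    for fn in (auroc, auprc, eo_ratio):
        a, b = fn(p, y), fn(p[perm], y[perm])
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)
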