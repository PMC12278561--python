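"""Split statistics and terminal estimators against hand computations and
independent survival-library oracles."""

import numpy as np
import pandas as pd
import pytest

from clabsi_forest.forest import (
    _aj_cif,
    _km_risk,
    score_split_gini,
    score_split_logrank,
    score_split_logrank_cr,
    score_split_logrank_cs,
)
from conftest import random_cr_node, random_survival_node


class TestGini:
    def test_two_class_parent_impurity(self):
        """Parent {1,0,0,0}: G = 2 * 0.25 * 0.75 = 0.375; a pure split
        recovers the full parent impurity."""
        score = score_split_gini([1], [0, 0, 0], n_classes=2)
        assert score == pytest.approx(0.375)

    def test_single_class_node_scores_zero(self):
        assert score_split_gini([1, 1], [1], n_classes=2) == pytest.approx(0.0)

    def test_uninformative_split_scores_zero(self):
        assert score_split_gini([1, 0], [1, 0], n_classes=2) == pytest.approx(0.0)

    def test_multiclass_matches_direct_formula(self, rng):
        for _ in range(50):
            y = rng.integers(0, 4, size=rng.integers(4, 30))
            k = rng.integers(1, len(y))
            left, right = y[:k], y[k:]

            def gini(v):
                p = np.bincount(v, minlength=4) / len(v)
                return 1 - (p**2).sum()

            expected = gini(y) - len(left) / len(y) * gini(left) - len(right) / len(y) * gini(right)
            assert score_split_gini(left, right, 4) == pytest.approx(expected, abs=1e-12)


def brute_logrank(left, right):
    """Loop-based two-sample log-rank |U|/sqrt(V), independent of the engine."""
    both = list(left) + list(right)
    days = sorted({t for t, s in both if s == 1})
    U = V = 0.0
    for tk in days:
        dk = sum(1 for t, s in both if t == tk and s == 1)
        dkl = sum(1 for t, s in left if t == tk and s == 1)
        Yk = sum(1 for t, _ in both if t >= tk)
        Ykl = sum(1 for t, _ in left if t >= tk)
        U += dkl - dk * Ykl / Yk
        if Yk > 1:
            V += dk * (Ykl / Yk) * (1 - Ykl / Yk) * (Yk - dk) / (Yk - 1)
    return abs(U) / np.sqrt(V) if V > 0 else 0.0


def brute_weighted(left, right, weights, modified_risk_set=False, admin_censor=7):
    """Loop-based cause-weighted statistic; with ``modified_risk_set`` a
    subject with a prior competing event stays at risk until the
    administrative-censoring day (the Gray-type rule)."""
    both = list(left) + list(right)
    U = V = 0.0
    for j, w in enumerate(weights, start=1):
        if w == 0:
            continue

        def exit_day(t, c):
            if modified_risk_set and c not in (0, j):
                return admin_censor
            return t

        days = sorted({t for t, c in both if c == j})
        for tk in days:
            dk = sum(1 for t, c in both if t == tk and c == j)
            dkl = sum(1 for t, c in left if t == tk and c == j)
            Yk = sum(1 for t, c in both if exit_day(t, c) >= tk)
            Ykl = sum(1 for t, c in left if exit_day(t, c) >= tk)
            U += w * (dkl - dk * Ykl / Yk)
            if Yk > 1:
                V += w * w * dk * (Ykl / Yk) * (1 - Ykl / Yk) * (Yk - dk) / (Yk - 1)
    return abs(U) / np.sqrt(V) if V > 0 else 0.0


class TestLogrank:
    def test_hand_computed_balanced_node_is_zero(self):
        """left {(1,event),(2,cens)}, right {(1,cens),(2,event)}: the two
        daughter nodes balance and U = 0."""
        assert score_split_logrank([(1, 1), (2, 0)], [(1, 0), (2, 1)]) == pytest.approx(0.0)

    def test_identical_multisets_score_zero(self):
        node = [(1, 1), (3, 0), (5, 1)]
        assert score_split_logrank(node, node) == pytest.approx(0.0, abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            score_split_logrank([(3, 0)], [(5, 0)])

    def test_matches_lifelines_two_sample_statistic(self, rng):
        """score^2 equals the chi-squared log-rank statistic of lifelines."""
        from lifelines.statistics import logrank_test

        checked = 0
        while checked < 25:
            lt, ls = random_survival_node(rng)
            rt, rs = random_survival_node(rng)
            if ls.sum() + rs.sum() == 0:
                continue
            score = score_split_logrank(list(zip(lt, ls)), list(zip(rt, rs)))
            res = logrank_test(lt, rt, event_observed_A=ls, event_observed_B=rs)
            assert score**2 == pytest.approx(res.test_statistic, rel=1e-8, abs=1e-10)
            checked += 1


class TestCauseSpecific:
    def test_weight_degeneracy_reduces_to_logrank(self, rng):
        """Weights (1,0,0) equal the plain log-rank with competing causes
        treated as censored."""
        for _ in range(20):
            lt, lc = random_cr_node(rng)
            rt, rc = random_cr_node(rng)
            if (lc == 1).sum() + (rc == 1).sum() == 0:
                continue
            cs = score_split_logrank_cs(list(zip(lt, lc)), list(zip(rt, rc)), (1, 0, 0))
            lr = score_split_logrank(
                list(zip(lt, (lc == 1).astype(int))), list(zip(rt, (rc == 1).astype(int)))
            )
            assert cs == pytest.approx(lr, abs=1e-12)

    def test_single_cause_equals_logrank(self, rng):
        lt, ls = random_survival_node(rng, n=12)
        rt, rs = random_survival_node(rng, n=9)
        if ls.sum() + rs.sum() == 0:
            ls[0] = 1
        cs = score_split_logrank_cs(list(zip(lt, ls)), list(zip(rt, rs)), (1, 1, 1))
        assert cs == pytest.approx(score_split_logrank(list(zip(lt, ls)), list(zip(rt, rs))), abs=1e-12)


class TestGrayType:
    def test_no_competing_events_equals_cause_specific(self, rng):
        for _ in range(10):
            lt, ls = random_survival_node(rng)
            rt, rs = random_survival_node(rng)
            if ls.sum() + rs.sum() == 0:
                continue
            l = list(zip(lt, ls))
            r = list(zip(rt, rs))
            assert score_split_logrank_cr(l, r, (1, 0, 0), 7) == pytest.approx(
                score_split_logrank_cs(l, r, (1, 0, 0)), abs=1e-12
            )

    def test_modified_risk_set_keeps_discharged_subject(self):
        """Node {(2, discharge), (5, CLABSI)}: under the Gray rule the
        discharged subject is still at risk at day 5 (Y* = 2), giving a
        hand-computable score of 1."""
        left = [(2, 3)]
        right = [(5, 1)]
        # cause-specific: only the CLABSI row is at risk at day 5 -> U=0
        assert score_split_logrank_cs(left, right, (1, 0, 0)) == pytest.approx(0.0)
        # Gray-type: Y*_5 = 2, Y*_L = 1 -> U = -1/2, V = 1/4 -> score 1
        assert score_split_logrank_cr(left, right, (1, 0, 0), 7) == pytest.approx(1.0)


class TestOracleEquivalence:
    """Engine scores vs brute-force loop implementations on random nodes."""

    def test_logrank_brute_force(self, rng):
        for _ in range(100):
            lt, ls = random_survival_node(rng)
            rt, rs = random_survival_node(rng)
            if ls.sum() + rs.sum() == 0:
                continue
            l, r = list(zip(lt, ls)), list(zip(rt, rs))
            assert score_split_logrank(l, r) == pytest.approx(brute_logrank(l, r), abs=1e-10)

    def test_cause_specific_brute_force(self, rng):
        for _ in range(100):
            lt, lc = random_cr_node(rng)
            rt, rc = random_cr_node(rng)
            w = tuple(rng.random(3).round(2))
            l, r = list(zip(lt, lc)), list(zip(rt, rc))
            if sum(wj * sum(c == j for _, c in l + r) for j, wj in enumerate(w, 1)) == 0:
                continue
            assert score_split_logrank_cs(l, r, w) == pytest.approx(
                brute_weighted(l, r, w), abs=1e-10
            )

    def test_gray_type_brute_force(self, rng):
        for _ in range(100):
            lt, lc = random_cr_node(rng)
            rt, rc = random_cr_node(rng)
            w = tuple(rng.random(3).round(2))
            l, r = list(zip(lt, lc)), list(zip(rt, rc))
            if sum(wj * sum(c == j for _, c in l + r) for j, wj in enumerate(w, 1)) == 0:
                continue
            assert score_split_logrank_cr(l, r, w, 7) == pytest.approx(
                brute_weighted(l, r, w, modified_risk_set=True, admin_censor=7), abs=1e-10
            )


class TestTerminalEstimators:
    def test_aj_equals_empirical_fraction_with_complete_data(self):
        """{(1,CLABSI),(2,discharge),(3,CLABSI),(5,discharge)}: AJ CIF of
        CLABSI at day 7 is the plain fraction 2/4."""
        time = np.array([1, 2, 3, 5])
        cause = np.array([1, 3, 1, 3])
        cif = _aj_cif(time, cause, 7)
        assert cif[0] == pytest.approx(0.5)
        assert cif.sum() == pytest.approx(1.0)

    def test_km_with_horizon_censoring_equals_binary_fraction(self):
        """{(3,CLABSI),(7,cens),(7,cens)}: 1 - KM(7) = 1/3."""
        assert _km_risk(np.array([3, 7, 7]), np.array([1, 0, 0]), 7) == pytest.approx(1 / 3)

    def test_km_no_events_is_zero(self):
        assert _km_risk(np.array([2, 5]), np.array([0, 0]), 7) == 0.0

    def test_km_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        for _ in range(20):
            t, s = random_survival_node(rng, n=30)
            if s.sum() == 0:
                continue
            kmf = KaplanMeierFitter().fit(t, s)
            expected = 1 - float(kmf.predict(7))
            assert _km_risk(t, s, 7) == pytest.approx(expected, abs=1e-10)

    def test_aj_matches_scikit_survival(self, rng):
        """The leaf CIF equals scikit-survival's Aalen-Johansen estimator
        (which, unlike lifelines, handles tied discrete times exactly)."""
        from sksurv.nonparametric import cumulative_incidence_competing_risks

        for _ in range(20):
            t, c = random_cr_node(rng, n=40)
            if any((c == j).sum() == 0 for j in range(1, 4)):
                continue  # the oracle requires every risk to appear
            times, cif = cumulative_incidence_competing_risks(c, t.astype(float))
            for j in range(1, 4):
                at7 = float(cif[j][times <= 7][-1]) if (times <= 7).any() else 0.0
                assert _aj_cif(t, c, 7)[j - 1] == pytest.approx(at7, abs=1e-10)
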