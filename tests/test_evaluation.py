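import numpy as np
import pandas as pd
import pytest

from crc_riskval import (
    age_rule_sensitivity,
    auc,
    calibration_table,
    harrell_c,
    metrics_from_rates,
    threshold_metrics,
)


def brute_force_auc(scores, outcomes):
    """Pairwise concordance over all case-control pairs; ties count half."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    pos, neg = s[y == 1], s[y == 0]
    diff = pos[:, None] - neg[None, :]
    return ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (len(pos) * len(neg))


def brute_force_harrell(scores, time, event):
    """Exhaustive enumeration of comparable pairs."""
    conc = ties = comp = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if not event[i]:
                continue
            if time[i] < time[j] or (time[i] == time[j] and not event[j]):
                comp += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    ties += 1
    return (conc + 0.5 * ties) / comp


class TestAuc:
    def test_identical_scores_give_half(self):
        r = auc(np.ones(20), [1] * 5 + [0] * 15)
        assert r.auc == 0.5

    def test_perfect_separation(self):
        r = auc([3, 4, 1, 2], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert (r.ci_low, r.ci_high) == (1.0, 1.0)  # degenerate interval

    def test_worked_five_record_example(self):
        # cases {0.9, 0.4} vs controls {0.5, 0.3, 0.1}: 5 of 6 pairs concordant
        r = auc([0.9, 0.4, 0.5, 0.3, 0.1], [1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.integers(0, 8, n).astype(float)  # heavy ties
        outcomes = rng.random(n) < 0.3
        if outcomes.all() or not outcomes.any():
            outcomes[0] = ~outcomes[0]
        r = auc(scores, outcomes.astype(int))
        assert r.auc == pytest.approx(brute_force_auc(scores, outcomes), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        scores = rng.normal(size=500)
        outcomes = (rng.random(500) < 0.1).astype(int)
        assert auc(scores, outcomes).auc == pytest.approx(
            roc_auc_score(outcomes, scores), abs=1e-12)

    def test_delong_ci_matches_independent_implementation(self):
        # expected interval computed with R pROC::ci.auc(method="delong")
        # on this exact data set: 0.6986426110 — 0.8892248062
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 80)
        s = np.round(rng.random(80) + 0.3 * y, 2)
        r = auc(s, y)
        assert r.auc == pytest.approx(0.7939337086, abs=1e-9)
        assert r.ci_low == pytest.approx(0.6986426110, abs=1e-9)
        assert r.ci_high == pytest.approx(0.8892248062, abs=1e-9)

    def test_hanley_fallback_close_to_delong(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=300)
        y = (rng.random(300) < 0.25).astype(int)
        d = auc(s, y)
        h = auc(s, y, ci_method="hanley")
        assert h.auc == d.auc
        assert h.se == pytest.approx(d.se, rel=0.25)


class TestHarrellC:
    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2, 3], [5, 6, 7], [0, 0, 0])

    def test_perfect_rank_alignment(self):
        # shorter time <=> higher score, all uncensored
        time = np.array([1.0, 2.0, 3.0, 4.0])
        scores = -time
        assert harrell_c(scores, time, [1, 1, 1, 1]) == 1.0

    def test_four_record_censored_worked_example(self):
        scores = np.array([2.0, 1.0, 3.0, 2.0])
        time = np.array([1.0, 2.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1])
        assert harrell_c(scores, time, event) == pytest.approx(
            brute_force_harrell(scores, time, event))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 100))
        scores = rng.integers(0, 5, n).astype(float)
        time = np.round(rng.exponential(5, n), 1)
        event = (rng.random(n) < 0.5).astype(int)
        if not event.any():
            event[0] = 1
        assert harrell_c(scores, time, event) == pytest.approx(
            brute_force_harrell(scores, time, event), abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines.utils import concordance_index

        rng = np.random.default_rng(8)
        n = 400
        scores = rng.normal(size=n)
        time = rng.exponential(5, n)
        event = (rng.random(n) < 0.4).astype(int)
        # lifelines orients scores as predicted survival time (higher = later)
        expected = concordance_index(time, -scores, event)
        assert harrell_c(scores, time, event) == pytest.approx(expected, abs=1e-12)


class TestThresholdMetrics:
    def test_two_top_ranked_events(self):
        # 20 records, 2 events holding the two highest scores, q = 0.1
        scores = np.arange(20, dtype=float)
        outcomes = np.zeros(20, int)
        outcomes[[18, 19]] = 1
        tm = threshold_metrics(scores, outcomes, 0.10)
        assert (tm.tp, tm.fp, tm.fn, tm.tn) == (2, 0, 0, 18)
        assert tm.sensitivity == 100.0
        assert tm.ppv == 100.0

    def test_flagged_count_is_round_qn_even_with_ties(self):
        rng = np.random.default_rng(2)
        for n, q in [(100, 0.1), (103, 0.2), (57, 0.8)]:
            scores = rng.integers(0, 3, n).astype(float)  # massive ties
            outcomes = (rng.random(n) < 0.2).astype(int)
            tm = threshold_metrics(scores, outcomes, q)
            assert tm.tp + tm.fp == int(np.rint(q * n))

    def test_lr_identity(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=500)
        outcomes = (rng.random(500) < 0.1).astype(int)
        tm = threshold_metrics(scores, outcomes, 0.2)
        assert tm.lr_plus == pytest.approx(
            tm.sensitivity / (100.0 - tm.specificity), abs=1e-12)
        assert tm.lr_minus == pytest.approx(
            (100.0 - tm.sensitivity) / tm.specificity, abs=1e-12)

    def test_npv_algebraic_bound(self):
        # NPV >= 100 * (1 - prevalence / (1 - q)) whenever round(q n) flagged
        rng = np.random.default_rng(6)
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 400
            scores = r.normal(size=n)
            outcomes = (r.random(n) < 0.05).astype(int)
            prev = outcomes.mean()
            tm = threshold_metrics(scores, outcomes, 0.1)
            assert tm.npv >= 100.0 * (1.0 - prev / 0.9) - 1e-9

    def test_specificity_identity_at_top_decile(self):
        # with exactly n/10 flagged: spec = (0.9 - p + p s) / (1 - p)
        rng = np.random.default_rng(9)
        n = 1000
        scores = rng.normal(size=n)
        outcomes = (rng.random(n) < 0.05).astype(int)
        tm = threshold_metrics(scores, outcomes, 0.1)
        p = outcomes.mean()
        s = tm.sensitivity / 100.0
        assert tm.specificity / 100.0 == pytest.approx(
            (0.9 - p + p * s) / (1.0 - p), abs=1e-12)

    def test_boundary_q_one_permissive(self):
        scores = np.arange(10, dtype=float)
        outcomes = np.array([0] * 8 + [1] * 2)
        tm = threshold_metrics(scores, outcomes, 1.0, permissive=True)
        assert tm.sensitivity == 100.0
        assert tm.specificity == 0.0
        assert tm.ppv == pytest.approx(100.0 * outcomes.mean())
        with pytest.raises(ValueError):
            threshold_metrics(scores, outcomes, 1.0)

    def test_too_small_q_rejected(self):
        with pytest.raises(ValueError):
            threshold_metrics([1.0, 2.0], [0, 1], 0.1)


class TestMetricsFromRates:
    def test_reconstruction_matches_direct_computation(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=2000)
        outcomes = (rng.random(2000) < 0.04).astype(int)
        direct = threshold_metrics(scores, outcomes, 0.1)
        rebuilt = metrics_from_rates(direct.sensitivity, direct.specificity,
                                     2000, int(outcomes.sum()))
        assert (rebuilt.tp, rebuilt.fp, rebuilt.tn, rebuilt.fn) == (
            direct.tp, direct.fp, direct.tn, direct.fn)
        assert rebuilt.ppv == pytest.approx(direct.ppv)


class TestCalibration:
    def test_perfectly_calibrated_groups(self):
        # observed proportion equals mean predicted in both groups
        pred = np.array([0.1] * 100 + [0.3] * 100)
        out = np.array([1] * 10 + [0] * 90 + [1] * 30 + [0] * 70)
        res = calibration_table(pred, out)
        assert res.hl_chi2 == pytest.approx(0.0, abs=1e-20)
        assert res.hl_p == pytest.approx(1.0)

    def test_two_group_hand_computed_chi2(self):
        # (O-E)^2/(E(1-p)): (15-10)^2/(10*0.9) + (25-30)^2/(30*0.7)
        pred = np.array([0.1] * 100 + [0.3] * 100)
        out = np.array([1] * 15 + [0] * 85 + [1] * 25 + [0] * 75)
        res = calibration_table(pred, out)
        assert res.hl_df == 2
        assert res.hl_chi2 == pytest.approx(25 / 9 + 25 / 21, rel=1e-12)
        assert res.hl_chi2 == pytest.approx(3.9683, abs=5e-5)

    def test_inflated_predictions_increase_chi2(self):
        rng = np.random.default_rng(13)
        pred = rng.uniform(0.05, 0.3, 5000)
        out = (rng.random(5000) < pred).astype(int)
        base = calibration_table(pred, out).hl_chi2
        inflated = calibration_table(np.clip(2 * pred, 0, 1), out).hl_chi2
        assert inflated > base

    def test_group_sizes_near_equal_for_distinct_predictions(self):
        rng = np.random.default_rng(14)
        pred = rng.uniform(0.001, 0.2, 1003)
        out = (rng.random(1003) < pred).astype(int)
        res = calibration_table(pred, out)
        sizes = res.groups["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 1003

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            calibration_table(np.zeros(100), np.zeros(100, int), g=2)


class TestAgeRule:
    def _cohort(self):
        return pd.DataFrame({
            "sex": ["male"] * 6 + ["female"] * 4,
            "age": [55, 62, 65, 58, 70, 61, 59, 66, 63, 52],
            "event": [0, 1, 1, 0, 0, 0, 0, 1, 0, 1],
        })

    def test_cutoff_below_all_ages(self):
        res = age_rule_sensitivity(self._cohort(), 40)
        assert (res["sensitivity"] == 100.0).all()
        assert (res["flagged_fraction"] == 1.0).all()

    def test_cutoff_above_all_ages(self):
        res = age_rule_sensitivity(self._cohort(), 90)
        assert (res["sensitivity"] == 0.0).all()

    def test_manual_count_at_sixty(self):
        res = age_rule_sensitivity(self._cohort(), 60).set_index("sex")
        # male events at ages 62, 65 -> both flagged; female events at 66, 52
        assert res.loc["male", "sensitivity"] == 100.0
        assert res.loc["female", "sensitivity"] == 50.0
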