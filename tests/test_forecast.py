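import math

import numpy as np
import pytest
from scipy import stats

from rulestrat import (
    Condition,
    ConfigError,
    DataError,
    Rule,
    RuleSet,
    calibration,
    confusion_metrics,
    evaluate_forecast,
    forecast_score,
    lr_plus_from_rates,
    posttest_probability,
    rank_sum_test,
    roc_auc,
    score_samples,
    youden_from_rates,
)
from rulestrat.forecast import _decile_bins, brier_score
from tests.conftest import make_table


def toy_ruleset():
    """3 case-rules + 2 control-rules over 5 binary features (A/B values)."""
    rules = [
        Rule(1, (Condition("f1", "A"),), "case", 30.0, 4.0),
        Rule(2, (Condition("f2", "A"), Condition("f3", "A")), "case", 20.0, 2.0),
        Rule(3, (Condition("f4", "A"),), "case", 10.0, 5.0),
        Rule(4, (Condition("f2", "B"), Condition("f5", "B")), "control", 25.0, 3.0),
        Rule(5, (Condition("f3", "B"),), "control", 15.0, 1.0),
    ]
    return RuleSet(rules)


ALL_CASE_SAMPLE = {"f1": "A", "f2": "A", "f3": "A", "f4": "A", "f5": "A"}
ALL_CONTROL_SAMPLE = {"f1": "B", "f2": "B", "f3": "B", "f4": "B", "f5": "B"}


class TestForecastScore:
    @pytest.mark.parametrize("weighting", ["covering", "uniform"])
    def test_all_case_rules_met_scores_one(self, weighting):
        assert forecast_score(toy_ruleset(), ALL_CASE_SAMPLE, weighting) == 1.0

    @pytest.mark.parametrize("weighting", ["covering", "uniform"])
    def test_all_control_rules_met_scores_zero(self, weighting):
        assert forecast_score(toy_ruleset(), ALL_CONTROL_SAMPLE, weighting) == 0.0

    def test_no_rule_met_stays_at_half(self):
        sample = {f: "C" for f in ("f1", "f2", "f3", "f4", "f5")}
        assert forecast_score(toy_ruleset(), sample) == 0.5

    def test_empty_ruleset_rejected(self):
        with pytest.raises(DataError):
            forecast_score(RuleSet([]), ALL_CASE_SAMPLE)

    def test_monotone_in_rules_met(self):
        """Meeting one more case-rule never lowers the score; one more
        control-rule never raises it."""
        rs = toy_ruleset()
        base = dict(ALL_CONTROL_SAMPLE)
        s0 = forecast_score(rs, base)
        base["f4"] = "A"  # now additionally meets case-rule 3
        assert forecast_score(rs, base) >= s0
        worse = dict(ALL_CASE_SAMPLE)
        s1 = forecast_score(rs, worse)
        worse["f3"] = "B"  # loses case-rule 2, gains control-rule 5
        assert forecast_score(rs, worse) <= s1

    def test_vectorized_matches_scalar(self):
        rs = toy_ruleset()
        cols = {
            "f1": ["A", "B", "C"],
            "f2": ["A", "B", "C"],
            "f3": ["A", "B", "C"],
            "f4": ["A", "B", "C"],
            "f5": ["A", "B", "C"],
        }
        t = make_table(cols, ["case", "control", "control"])
        scores = score_samples(rs, t)
        for i, row in enumerate(np.array(list(cols.values())).T):
            sample = dict(zip(cols, row))
            assert scores[i] == pytest.approx(forecast_score(rs, sample))


class TestConfusionMetrics:
    def test_published_rates_give_youden_and_lr(self):
        sens, spec = 0.28, 0.93
        assert youden_from_rates(sens, spec) == pytest.approx(0.21)
        assert lr_plus_from_rates(sens, spec) == pytest.approx(4.0)

    def test_counts_and_derived_metrics(self):
        pred = [True, True, False, False, True]
        truth = [True, False, True, False, False]
        m = confusion_metrics(pred, truth)
        assert (m.tp, m.fp, m.fn, m.tn) == (1, 2, 1, 1)
        assert m.accuracy == pytest.approx(0.4)
        assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1)

    def test_perfect_prediction(self):
        truth = [True, True, False, False]
        m = confusion_metrics(truth, truth)
        assert m.mcc == pytest.approx(1.0)
        assert m.youden_j == pytest.approx(1.0)
        assert math.isnan(m.lr_plus)  # spec = 1 -> undefined

    def test_empty_raises(self):
        with pytest.raises(DataError):
            confusion_metrics([], [])


class TestPosttest:
    def test_increment_reproduces_worked_example(self):
        # pretest 2%, LR+ 4.0 -> +25 points -> 27%
        assert posttest_probability(0.02, 4.0, "increment") == pytest.approx(0.27)

    def test_bayes_update(self):
        # odds 0.0204 * 4 = 0.0816 -> p = 0.0755
        assert posttest_probability(0.02, 4.0, "bayes") == pytest.approx(0.07547, abs=1e-4)

    @pytest.mark.parametrize("method", ["bayes", "increment"])
    def test_lr_one_changes_nothing(self, method):
        assert posttest_probability(0.3, 1.0, method) == pytest.approx(0.3)

    @pytest.mark.parametrize("lr,delta", [(2, 15), (5, 30), (10, 45)])
    def test_increment_lookup_points(self, lr, delta):
        assert posttest_probability(0.10, lr, "increment") == pytest.approx(0.10 + delta / 100)

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            posttest_probability(0.0, 4.0)
        with pytest.raises(ConfigError):
            posttest_probability(0.5, -1.0)


class TestRocAuc:
    def test_constant_scores_give_half(self):
        auc, _ci = roc_auc([0.5] * 10, [True] * 5 + [False] * 5)
        assert auc == pytest.approx(0.5)

    def test_perfect_separation(self):
        auc, ci = roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == pytest.approx(1.0)
        assert ci[1] <= 1.0

    def test_frozen_examples(self):
        auc, _ = roc_auc([0.9, 0.8, 0.7, 0.1], [True, True, False, False])
        assert auc == pytest.approx(1.0)
        auc, _ = roc_auc([0.9, 0.3, 0.7, 0.1], [True, True, False, False])
        assert auc == pytest.approx(0.75)

    def test_matches_pairwise_concordance(self):
        """Oracle: mean over all case-control pairs of 1/0.5/0 for
        concordant/tied/discordant, on inputs up to 50 samples."""
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            truth = np.zeros(n, bool)
            truth[: int(rng.integers(1, n))] = True
            rng.shuffle(truth)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # ties likely
            pos, neg = scores[truth], scores[~truth]
            oracle = np.mean(
                [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
            )
            auc, _ = roc_auc(scores, truth)
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.random(80)
        truth = rng.random(80) < 0.4
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], [True, True])


class TestCalibration:
    def test_constant_predictor_brier_is_bernoulli_variance(self):
        truth = [True] * 3 + [False] * 7
        _table, brier, _ci = calibration([0.5] * 10, truth, n_boot=50, seed=0)
        assert brier == pytest.approx(0.3 * 0.7)

    def test_perfect_risks_give_zero_brier(self):
        truth = np.array([True] * 5 + [False] * 5)
        scores = truth.astype(float)  # separation -> falls back to raw 0/1
        _table, brier, _ci = calibration(scores, truth, n_boot=50, seed=0)
        assert brier == pytest.approx(0.0)

    def test_hand_computed_brier(self):
        assert brier_score([0.8, 0.8, 0.2, 0.2], [1, 0, 0, 0]) == pytest.approx(0.19)

    def test_decile_ties_go_to_lower_bin(self):
        risks = np.array([0.1] * 4 + [0.2] * 6)
        bins = _decile_bins(risks, 5)
        assert set(bins[:4]) == {0}
        assert set(bins[4:]) == {2}  # first position of the 0.2 group

    def test_calibration_table_tracks_observed_risk(self):
        rng = np.random.default_rng(6)
        n = 500
        score = rng.random(n)
        truth = rng.random(n) < score  # well-calibrated by construction
        table, brier, ci = calibration(score, truth, n_boot=200, seed=1)
        assert table["n"].sum() == n
        gap = (table["mean_predicted"] - table["observed_fraction"]).abs().max()
        assert gap < 0.15
        assert ci[0] <= brier <= ci[1]


class TestRankSum:
    def test_exact_p_for_complete_separation(self):
        # 5 vs 5, all cases above all controls: one-sided p = 1/C(10,5) = 1/252
        p = rank_sum_test([6, 7, 8, 9, 10], [1, 2, 3, 4, 5], alternative="greater")
        assert p == pytest.approx(1 / 252)

    def test_label_swap_leaves_two_sided_p(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(15), rng.random(20)
        assert rank_sum_test(x, y) == pytest.approx(rank_sum_test(y, x))

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(200):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            ps.append(rank_sum_test(x, y))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_raises(self):
        with pytest.raises(DataError):
            rank_sum_test([], [1.0])


def test_evaluate_forecast_bundle_consistency():
    rng = np.random.default_rng(10)
    truth = rng.random(120) < 0.4
    scores = np.clip(truth * 0.3 + rng.random(120) * 0.7, 0, 1)
    m = evaluate_forecast(scores, truth, n_boot=100, seed=3)
    assert m.tp + m.fp + m.fn + m.tn == 120
    assert m.accuracy == pytest.approx((m.tp + m.tn) / 120)
    assert m.youden_j == pytest.approx(m.sensitivity + m.specificity - 1)
    assert 0 <= m.auc <= 1 and m.auc_ci[0] <= m.auc <= m.auc_ci[1]
    d = m.to_dict()
    assert d["auc"] == m.auc and len(d["calibration"]) <= 10


def test_threshold_tie_goes_to_control():
    # an empty-evidence cohort (all scores exactly 0.5) predicts all-control
    m = evaluate_forecast(np.full(20, 0.5), [True] * 8 + [False] * 12, n_boot=10)
    assert m.tp == 0 and m.fp == 0
    assert m.tn == 12 and m.fn == 8
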