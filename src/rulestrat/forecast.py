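"""Forecast scoring and discrimination/calibration metrics.

Per-sample *forecast score*, anchored at 0.5 and bounded in [0, 1]:

    score = 0.5 + 0.5 * (W+_met / W+_tot) - 0.5 * (W-_met / W-_tot)

where W+ sums the weights of the case-predicting rules the sample meets
(numerator) and of all case-predicting rules (denominator), and W- does the
same for control-predicting rules.  With covering-based weights, stronger
rules move the score more; a class with no rules contributes 0 to its term.
A sample that meets every case rule and no control rule scores exactly 1, the
mirror sample exactly 0, and a sample meeting no rule stays at 0.5.

The metric bundle covers the standard confusion-matrix statistics, the
rank-statistic AUC with a DeLong-type confidence interval, a decile
calibration table after a one-predictor logistic recalibration, the Brier
score with a bootstrap CI, and a two-sample rank-sum comparison of the score
distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .genotype_io import AlleleFeatureTable
from .rule_induction import CASE, CONTROL, Rule, RuleSet, rule_match_mask

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _rule_weights(rules: Sequence[Rule], weighting: str) -> np.ndarray:
    if weighting == "covering":
        return np.array([r.covering for r in rules], dtype=float)
    if weighting == "uniform":
        return np.ones(len(rules))
    raise ConfigError(f"unknown weighting {weighting!r} (use 'covering' or 'uniform')")


def score_samples(
    ruleset: RuleSet,
    table: AlleleFeatureTable,
    weighting: str = "covering",
    return_met: bool = False,
):
    """Vectorized forecast score for every sample of a table."""
    if not ruleset.rules:
        raise DataError("cannot score with an empty ruleset")
    n = table.n_samples
    met = np.column_stack([rule_match_mask(r, table) for r in ruleset.rules])
    score = np.full(n, 0.5)
    for klass, sign in ((CASE, +0.5), (CONTROL, -0.5)):
        idx = [i for i, r in enumerate(ruleset.rules) if r.klass == klass]
        if not idx:
            continue
        w = _rule_weights([ruleset.rules[i] for i in idx], weighting)
        tot = w.sum()
        if tot <= 0:
            continue
        score = score + sign * (met[:, idx] @ w) / tot
    score = np.clip(score, 0.0, 1.0)
    if return_met:
        return score, met
    return score


def forecast_score(
    ruleset: RuleSet, sample: Mapping[str, str], weighting: str = "covering"
) -> float:
    """Forecast score of a single sample given as a feature -> value mapping."""
    if not ruleset.rules:
        raise DataError("cannot score with an empty ruleset")
    score = 0.5
    for klass, sign in ((CASE, +0.5), (CONTROL, -0.5)):
        rules = ruleset.by_class(klass)
        if not rules:
            continue
        w = _rule_weights(rules, weighting)
        tot = w.sum()
        if tot <= 0:
            continue
        met = np.array(
            [all(sample.get(c.feature) == c.value for c in r.conditions) for r in rules]
        )
        score += sign * float(met @ w) / tot
    return float(np.clip(score, 0.0, 1.0))


def forecast_table(
    ruleset: RuleSet,
    table: AlleleFeatureTable,
    weighting: str = "covering",
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-sample forecast: score, predicted label (score > threshold -> case;
    an exact tie at the threshold is called control), rules satisfied."""
    score, met = score_samples(ruleset, table, weighting, return_met=True)
    rule_ids = [r.id for r in ruleset.rules]
    satisfied = [
        ";".join(str(rule_ids[j]) for j in np.flatnonzero(met[i]))
        for i in range(table.n_samples)
    ]
    return pd.DataFrame(
        {
            "iid": table.samples["iid"],
            "score": score,
            "predicted": np.where(score > threshold, CASE, CONTROL),
            "rules_met": satisfied,
        }
    )


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricBundle:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mcc: float
    youden_j: float
    lr_plus: float
    auc: float = math.nan
    auc_ci: tuple[float, float] = (math.nan, math.nan)
    brier: float = math.nan
    brier_ci: tuple[float, float] = (math.nan, math.nan)
    calibration: pd.DataFrame | None = None
    rank_sum_p: float = math.nan
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x

        d = {
            k: clean(getattr(self, k))
            for k in (
                "tp", "fp", "fn", "tn", "accuracy", "sensitivity", "specificity",
                "ppv", "npv", "mcc", "youden_j", "lr_plus", "auc", "brier",
                "rank_sum_p", "degenerate",
            )
        }
        d["auc_ci"] = [clean(v) for v in self.auc_ci]
        d["brier_ci"] = [clean(v) for v in self.brier_ci]
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict(orient="records")
        d.update(self.extras)
        return d


def youden_from_rates(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def lr_plus_from_rates(sensitivity: float, specificity: float) -> float:
    """Positive likelihood ratio = sensitivity / (1 - specificity);
    NaN when specificity = 1 (undefined)."""
    denom = 1.0 - specificity
    return sensitivity / denom if denom > 0 else math.nan


def confusion_metrics(predicted, truth) -> MetricBundle:
    """Discrimination metrics of binary predictions (True = case).

    Zero denominators yield NaN rather than raising.
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.size == 0:
        raise DataError("empty input")
    if predicted.shape != truth.shape:
        raise DataError("predicted and truth lengths differ")
    tp = int((predicted & truth).sum())
    fp = int((predicted & ~truth).sum())
    fn = int((~predicted & truth).sum())
    tn = int((~predicted & ~truth).sum())

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    acc = (tp + tn) / predicted.size
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan
    return MetricBundle(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=acc, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        mcc=mcc,
        youden_j=youden_from_rates(sens, spec),
        lr_plus=lr_plus_from_rates(sens, spec),
    )


# ---------------------------------------------------------------------------
# post-test risk
# ---------------------------------------------------------------------------

#: increment heuristic: a positive test adds ~19*ln(LR+) percentage points,
#: rounded to the nearest 5 (so LR+ of 2/4/5/10 -> +15/+25/+30/+45 points)
def posttest_probability(pretest: float, lr_plus: float, method: str = "bayes") -> float:
    """Post-test disease probability from a pre-test probability and LR+.

    ``bayes`` applies the odds-form Bayes update; ``increment`` applies the
    published likelihood-ratio rule of thumb (add 19*ln(LR+) percentage
    points, rounded to the nearest 5), clipped to [0, 1].
    """
    if not 0 < pretest < 1:
        raise ConfigError("pretest probability must be in (0, 1)")
    if lr_plus <= 0:
        raise ConfigError("LR+ must be positive")
    if method == "bayes":
        odds = pretest / (1 - pretest) * lr_plus
        return odds / (1 + odds)
    if method == "increment":
        delta_points = 5 * round(19 * math.log(lr_plus) / 5)
        return float(np.clip(pretest + delta_points / 100.0, 0.0, 1.0))
    raise ConfigError(f"unknown method {method!r} (use 'bayes' or 'increment')")


# ---------------------------------------------------------------------------
# ROC / AUC (rank statistic + DeLong-type CI)
# ---------------------------------------------------------------------------

def roc_auc(scores, truth, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC by the Mann-Whitney rank statistic (midranks for ties) with an
    asymptotic DeLong-type confidence interval."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pos = scores[truth]
    neg = scores[~truth]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DataError("ROC needs both classes present")
    allv = np.concatenate([pos, neg])
    rk = stats.rankdata(allv)  # midranks
    auc = (rk[:m].sum() - m * (m + 1) / 2) / (m * n)
    # placement values (structural components)
    v10 = (rk[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (rk[m:] - stats.rankdata(neg)) / m
    if m > 1 and n > 1:
        var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
        se = math.sqrt(var)
        z = stats.norm.ppf(1 - alpha / 2)
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    else:
        ci = (math.nan, math.nan)
    return float(auc), ci


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def brier_score(risks, truth) -> float:
    """Mean squared error of probabilistic predictions."""
    risks = np.asarray(risks, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return float(np.mean((risks - truth) ** 2))


def _logistic_recalibrate(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Predicted risks from a one-predictor logistic model of status on the
    forecast score (Newton, tol 1e-8).  A zero-variance score collapses to the
    intercept-only model (risk = prevalence); a failed or separated fit falls
    back to the raw scores."""
    if np.std(scores) == 0:
        return np.full(len(scores), y.mean())
    try:
        import statsmodels.api as sm

        X = sm.add_constant(scores)
        res = sm.Logit(y.astype(float), X).fit(
            method="newton", maxiter=100, tol=1e-8, disp=0
        )
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("Newton iterations did not converge")
        return np.asarray(res.predict(X), dtype=float)
    except Exception as exc:  # separation, singular Hessian, non-convergence
        log.warning("logistic recalibration failed (%s); using raw scores as risks", exc)
        return scores.astype(float)


def _decile_bins(risks: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bins 0..n_bins-1 of the predicted risks; samples tied on
    the same risk value all go to the lower (first-occupied) bin."""
    n = len(risks)
    order = np.argsort(risks, kind="stable")
    bins = np.empty(n, dtype=int)
    bins[order] = np.arange(n) * n_bins // n
    # collapse ties to the minimum bin of their value group
    df = pd.DataFrame({"r": risks, "b": bins})
    bins = df.groupby("r")["b"].transform("min").to_numpy()
    return bins


def calibration(
    scores,
    truth,
    n_bins: int = 10,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, tuple[float, float]]:
    """Decile calibration table and Brier score with a bootstrap CI.

    Risks come from :func:`_logistic_recalibrate`; the table compares the mean
    predicted risk per decile with the observed case fraction.  The Brier CI
    is a seeded percentile bootstrap over (risk, outcome) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if len(scores) < n_bins:
        raise DataError(f"need at least {n_bins} samples for {n_bins} bins")
    risks = _logistic_recalibrate(scores, y)
    bins = _decile_bins(risks, n_bins)
    rows = []
    for b in range(n_bins):
        sel = bins == b
        if not sel.any():
            continue
        rows.append(
            {
                "decile": b + 1,
                "n": int(sel.sum()),
                "mean_predicted": float(risks[sel].mean()),
                "observed_fraction": float(y[sel].mean()),
            }
        )
    table = pd.DataFrame(rows)

    brier = brier_score(risks, y)
    rng = np.random.default_rng(seed)
    n = len(risks)
    reps = np.empty(n_boot)
    sq = (risks - y) ** 2
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        reps[i] = sq[idx].mean()
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return table, brier, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# rank-sum comparison of score distributions
# ---------------------------------------------------------------------------

def rank_sum_test(
    scores_cases, scores_controls, alternative: str = "two-sided"
) -> float:
    """Two-sample Wilcoxon/Mann-Whitney rank-sum p-value.

    The two groups are independent, so the two-sample rank-sum test applies
    (not the paired signed-rank test).  Exact enumeration is used when both
    groups have <= 10 tie-free observations, otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def evaluate_forecast(
    scores,
    truth,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
    degenerate: bool = False,
) -> MetricBundle:
    """Full metric bundle from per-sample scores and true labels."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    bundle = confusion_metrics(scores > threshold, truth)
    bundle.degenerate = degenerate
    if truth.any() and not truth.all():
        bundle.auc, bundle.auc_ci = roc_auc(scores, truth)
        bundle.rank_sum_p = rank_sum_test(scores[truth], scores[~truth])
    if len(scores) >= 10:
        try:
            bundle.calibration, bundle.brier, bundle.brier_ci = calibration(
                scores, truth, n_boot=n_boot, seed=seed
            )
        except DataError:
            pass
    else:
        bundle.brier = brier_score(scores, truth)
    return bundle
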