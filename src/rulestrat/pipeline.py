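"""End-to-end orchestration: cross-validation, hyperparameter grid, final
model training and cross-cohort forecasting.

The workflow mirrors a two-cohort design: on the training cohort, feature
selection and rule induction run inside a stratified k-fold loop (selection is
re-run on each fold's training part by default, to avoid optimistic bias; a
``selection="global"`` switch reproduces the alternative reading where a
single selection precedes the cross-validation); held-out scores are pooled
into one metric bundle per hyperparameter configuration.  The chosen
configuration is refit on the full training cohort, and the resulting ruleset
is adapted to the validation cohort before forecasting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .feature_selection import SelectionConfig, select_features
from .forecast import MetricBundle, evaluate_forecast, forecast_table, score_samples
from .genotype_io import AlleleFeatureTable
from .rule_induction import InductionConfig, RuleSet, fit_ruleset
from .rule_transfer import AdaptationReport, adapt_ruleset

log = logging.getLogger(__name__)


def derive_seed(master: int, label: str) -> int:
    """Deterministically fan a master seed out to per-stage seeds (< 2^31)."""
    h = hashlib.blake2b(f"{master}:{label}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31)


def stratified_folds(
    status: np.ndarray, folds: int, seed: int, max_tries: int = 10
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (round-robin within each
    shuffled class).  Refolds with a new derived seed if a fold misses a class
    (only possible when a class has fewer samples than folds)."""
    status = np.asarray(status, dtype=bool)
    for attempt in range(max_tries):
        rng = np.random.default_rng(derive_seed(seed, f"folds{attempt}"))
        assign = np.empty(len(status), dtype=int)
        for cls in (True, False):
            idx = np.flatnonzero(status == cls)
            rng.shuffle(idx)
            assign[idx] = np.arange(len(idx)) % folds
        ok = all(
            status[assign == k].any() and (~status[assign == k]).any()
            for k in range(folds)
        )
        if ok:
            return [np.flatnonzero(assign == k) for k in range(folds)]
        log.warning("fold %d missed a class; refolding", attempt)
    raise DataError(f"could not build {folds} stratified folds with both classes")


@dataclass
class CVResult:
    scores: np.ndarray
    truth: np.ndarray
    metrics: MetricBundle
    fold_sizes: list[int]
    rules_per_fold: list[int]


def cross_validate(
    table: AlleleFeatureTable,
    sel_cfg: SelectionConfig,
    ind_cfg: InductionConfig,
    folds: int = 10,
    seed: int = 0,
    selection: str = "per_fold",
    weighting: str = "covering",
) -> CVResult:
    """Stratified k-fold: per fold, feature selection + rule fit on the
    training part, forecast on the held-out part; held-out predictions are
    pooled into one metric bundle."""
    if selection not in ("per_fold", "global"):
        raise ConfigError("selection must be 'per_fold' or 'global'")
    status = table.status_bool
    if min(status.sum(), (~status).sum()) < folds:
        raise DataError(f"need >= {folds} samples per class for {folds} folds")
    fold_idx = stratified_folds(status, folds, seed)
    table.codes()  # encode once; sample subsets reuse the cache

    global_feats = None
    if selection == "global":
        global_feats, _ranked = select_features(table, sel_cfg)

    scores = np.full(table.n_samples, np.nan)
    rules_per_fold = []
    for k, test_idx in enumerate(fold_idx):
        train_idx = np.setdiff1d(np.arange(table.n_samples), test_idx)
        train = table.subset_samples(train_idx)
        feats = global_feats
        if feats is None:
            feats, _ranked = select_features(train, sel_cfg)
        ruleset = fit_ruleset(train.subset_features(feats), ind_cfg)
        rules_per_fold.append(len(ruleset))
        test = table.subset_samples(test_idx)
        if len(ruleset):
            scores[test_idx] = score_samples(ruleset, test, weighting)
        else:
            scores[test_idx] = 0.5
    metrics = evaluate_forecast(
        scores, status, seed=derive_seed(seed, "cv-boot")
    )
    return CVResult(
        scores=scores,
        truth=status,
        metrics=metrics,
        fold_sizes=[len(i) for i in fold_idx],
        rules_per_fold=rules_per_fold,
    )


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    ruleset: RuleSet
    selected_features: list[str]
    training_table: AlleleFeatureTable
    sel_cfg: SelectionConfig
    ind_cfg: InductionConfig


def train_final(
    table: AlleleFeatureTable, sel_cfg: SelectionConfig, ind_cfg: InductionConfig
) -> ModelBundle:
    """Fit the final ruleset on the full training cohort."""
    feats, _ranked = select_features(table, sel_cfg)
    ruleset = fit_ruleset(table.subset_features(feats), ind_cfg)
    return ModelBundle(ruleset, feats, table, sel_cfg, ind_cfg)


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    t_values: tuple[float, ...] = (0.7, 0.8, 0.9)
    size_pairs: tuple[tuple[int, int], ...] = ((100, 30),)  # (npresel, nsel)
    errmax_values: tuple[float, ...] = (0.05,)
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_values and self.size_pairs and self.errmax_values):
            raise ConfigError("grid axes must be non-empty")

    def points(self) -> list[dict]:
        """Reproducible enumeration order: t, then (npresel, nsel), then errmax."""
        return [
            {"t": t, "npresel": np_, "nsel": ns, "errmax": em}
            for t in self.t_values
            for np_, ns in self.size_pairs
            for em in self.errmax_values
        ]


@dataclass
class RunRecord:
    config: dict
    metrics: dict
    n_rules_median: float = 0.0
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "metrics": self.metrics,
            "n_rules_median": self.n_rules_median,
            "error": self.error,
        }


def _config_key(config: dict) -> str:
    return json.dumps(config, sort_keys=True)


_RECORD_METRICS = (
    "accuracy", "sensitivity", "specificity", "ppv", "npv", "mcc",
    "youden_j", "lr_plus", "auc", "brier",
)


def grid_search(
    table: AlleleFeatureTable,
    grid: GridSpec,
    out_path=None,
    selection: str = "per_fold",
) -> list[RunRecord]:
    """Cross-validate every grid point; records are appended incrementally to
    ``out_path`` (JSON lines) so a completed grid reruns as a no-op."""
    done: dict[str, RunRecord] = {}
    if out_path is not None and Path(out_path).exists():
        with open(out_path) as fh:
            for line in fh:
                d = json.loads(line)
                done[_config_key(d["config"])] = RunRecord(**d)

    records: list[RunRecord] = []
    for config in grid.points():
        key = _config_key(config)
        if key in done:
            records.append(done[key])
            continue
        try:
            cv = cross_validate(
                table,
                SelectionConfig(t=config["t"], npresel=config["npresel"], nsel=config["nsel"]),
                InductionConfig(errmax=config["errmax"], seed=grid.seed),
                folds=grid.folds,
                seed=grid.seed,
                selection=selection,
            )
            full = cv.metrics.to_dict()
            rec = RunRecord(
                config=config,
                metrics={k: full.get(k) for k in _RECORD_METRICS},
                n_rules_median=float(np.median(cv.rules_per_fold)),
            )
        except (DataError, ConfigError) as exc:  # record and continue
            log.warning("grid point %s failed: %s", config, exc)
            rec = RunRecord(config=config, metrics={}, error=str(exc))
        records.append(rec)
        if out_path is not None:
            with open(out_path, "a") as fh:
                fh.write(json.dumps(rec.to_dict()) + "\n")
    return records


def select_best_config(
    records: list[RunRecord], accuracy_band: float = 0.05, ppv_band: float = 0.05
) -> RunRecord:
    """Pick the configuration maximizing specificity with a good balance of
    accuracy and precision: among records within ``accuracy_band`` of the best
    accuracy and ``ppv_band`` of the best PPV, take the highest specificity;
    ties fall to Youden's J, then to enumeration order."""
    valid = [
        r
        for r in records
        if r.error is None and r.metrics.get("specificity") is not None
    ]
    if not valid:
        raise DataError("no grid record carries usable metrics")

    def _get(r, k):
        v = r.metrics.get(k)
        return -np.inf if v is None else v

    max_acc = max(_get(r, "accuracy") for r in valid)
    ppvs = [_get(r, "ppv") for r in valid if _get(r, "ppv") > -np.inf]
    max_ppv = max(ppvs) if ppvs else None
    eligible = [
        r
        for r in valid
        if _get(r, "accuracy") >= max_acc - accuracy_band
        and (max_ppv is None or _get(r, "ppv") >= max_ppv - ppv_band)
    ]
    if not eligible:
        eligible = valid
    best = eligible[0]
    for r in eligible[1:]:
        if (_get(r, "specificity"), _get(r, "youden_j")) > (
            _get(best, "specificity"),
            _get(best, "youden_j"),
        ):
            best = r
    return best


# ---------------------------------------------------------------------------
# cross-cohort forecast
# ---------------------------------------------------------------------------

@dataclass
class ForecastOutput:
    per_sample: "object"  # DataFrame: iid, score, predicted, rules_met
    metrics: MetricBundle
    adaptation: AdaptationReport
    adapted_ruleset: RuleSet = field(repr=False, default=None)


def run_forecast(
    bundle: ModelBundle,
    validation_table: AlleleFeatureTable,
    seed: int = 0,
    weighting: str = "covering",
    out_dir=None,
) -> ForecastOutput:
    """Adapt the final ruleset to the validation cohort and score it.

    An empty adapted ruleset degenerates to all-0.5 scores with the metric
    bundle flagged accordingly.
    """
    adapted, report = adapt_ruleset(bundle.ruleset, bundle.training_table, validation_table)
    truth = validation_table.status_bool
    if len(adapted):
        per_sample = forecast_table(adapted, validation_table, weighting)
        scores = per_sample["score"].to_numpy()
        degenerate = False
    else:
        import pandas as pd

        scores = np.full(validation_table.n_samples, 0.5)
        per_sample = pd.DataFrame(
            {
                "iid": validation_table.samples["iid"],
                "score": scores,
                "predicted": "control",
                "rules_met": "",
            }
        )
        degenerate = True
    metrics = evaluate_forecast(
        scores, truth, seed=derive_seed(seed, "forecast-boot"), degenerate=degenerate
    )
    out = ForecastOutput(per_sample, metrics, report, adapted)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_sample.to_csv(out_dir / "forecast.tsv", sep="\t", index=False)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2)
        report.to_json(out_dir / "adaptation.json")
        adapted.to_json(out_dir / "ruleset_adapted.json")
    return out
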