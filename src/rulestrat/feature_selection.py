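"""Correlation-aware feature selection.

Tens of thousands of allele-slot features are reduced to at most ``nsel``
weakly inter-correlated inputs by a three-stage filter:

1. *mode filter* — drop features whose most frequent value exceeds a fraction
   of the non-missing observations (default 0.95);
2. *univariate ranking* — Cramér's V of each feature against the case/control
   status;
3. *greedy forward selection* — walk the ranking, accepting a feature only if
   its Cramér's V with every already-accepted feature stays at or below the
   cap ``t``.

No wrapper-style (model-driven) selection is performed: the filter looks only
at direct correlations, so the downstream rule learner is evaluated on its own
multivariate merits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genotype_io import MISSING, SPECIAL_FEATURES, AlleleFeatureTable, _pearson_chi2


@dataclass(frozen=True)
class SelectionConfig:
    mode_threshold: float = 0.95
    t: float = 0.8  # inter-feature Cramér's V cap
    npresel: int = 200  # top-ranked features entering the greedy stage
    nsel: int = 40  # max features selected

    def __post_init__(self) -> None:
        if not 0 < self.t <= 1:
            raise ConfigError("t must be in (0, 1]")
        if self.nsel > self.npresel:
            raise ConfigError("nsel must not exceed npresel")
        if self.nsel < 1:
            raise ConfigError("nsel must be >= 1")


@dataclass(frozen=True)
class RankedFeature:
    feature: str
    cramers_v: float
    rank: int  # 1-based, strictly ordered by descending V (ties: feature id)


# ---------------------------------------------------------------------------
# Cramér's V
# ---------------------------------------------------------------------------

def _encode(arr: np.ndarray) -> np.ndarray:
    """Factorize an object vector; missing ("0", None, NaN) -> -1."""
    out = np.empty(len(arr), dtype=np.int64)
    mapping: dict[str, int] = {}
    for i, v in enumerate(arr):
        if v is None or v == MISSING or (isinstance(v, float) and np.isnan(v)):
            out[i] = -1
            continue
        key = str(v)
        out[i] = mapping.setdefault(key, len(mapping))
    return out


def _cramers_v_codes(xc: np.ndarray, yc: np.ndarray) -> float:
    """V on pre-encoded integer vectors (missing = -1, pairwise-excluded)."""
    keep = (xc >= 0) & (yc >= 0)
    x, y = xc[keep], yc[keep]
    n = x.size
    if n == 0:
        return 0.0
    kx = int(x.max()) + 1
    ky = int(y.max()) + 1
    obs = np.bincount(x * ky + y, minlength=kx * ky).reshape(kx, ky)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    r, c = obs.shape
    if r < 2 or c < 2:
        return 0.0  # single observed category carries no association
    chi2 = _pearson_chi2(obs)
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def cramers_v(x, y) -> float:
    """Cramér's V between two categorical vectors.

    V = sqrt(chi2 / (N * min(r-1, c-1))) with the Pearson chi-square (no
    continuity correction) on the r x c contingency table.  Pairs with a
    missing value in either vector are excluded; single-category input gives 0.
    """
    x = np.asarray(x, dtype=object)
    y = np.asarray(y, dtype=object)
    if len(x) != len(y):
        raise DataError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise DataError("need at least 2 observations")
    return _cramers_v_codes(_encode(x), _encode(y))


# ---------------------------------------------------------------------------
# filter stages
# ---------------------------------------------------------------------------

def mode_filter(
    table: AlleleFeatureTable, mode_threshold: float = 0.95
) -> AlleleFeatureTable:
    """Drop near-constant features.

    A feature is removed when its most frequent non-missing value accounts for
    *strictly more* than ``mode_threshold`` of its non-missing observations
    (a feature at exactly the threshold is kept).  ``Sex`` and ``HLA_ordinal``
    are exempt.  Features with no non-missing values are dropped.
    """
    X, _cats = table.codes()
    keep: list[str] = []
    for j, f in enumerate(table.feature_ids):
        if f in SPECIAL_FEATURES:
            keep.append(f)
            continue
        col = X[:, j]
        col = col[col >= 0]
        if col.size == 0:
            continue
        frac = np.bincount(col).max() / col.size
        if frac <= mode_threshold:
            keep.append(f)
    if not keep:
        raise DataError(
            "mode filter removed every feature; lower mode_threshold "
            f"(currently {mode_threshold})"
        )
    return table.subset_features(keep)


def rank_by_cramers_v(table: AlleleFeatureTable) -> list[RankedFeature]:
    """Rank all features by Cramér's V against the case/control status,
    descending; ties broken lexicographically by feature id."""
    X, _cats = table.codes()
    y = table.status_bool.astype(np.int64)
    scored = [
        (f, _cramers_v_codes(X[:, j], y)) for j, f in enumerate(table.feature_ids)
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [RankedFeature(f, v, i + 1) for i, (f, v) in enumerate(scored)]


def greedy_forward_select(
    ranked: list[RankedFeature],
    table: AlleleFeatureTable,
    cfg: SelectionConfig,
) -> list[str]:
    """Correlation-capped greedy forward selection.

    Candidates are scanned in rank order (equivalent to re-picking the
    highest-V remaining feature at each step, since V against the output never
    changes).  A candidate is accepted iff its Cramér's V with every
    already-selected feature is <= ``cfg.t``; selection stops at ``cfg.nsel``
    accepted features.  Returns features in acceptance order.
    """
    X, _cats = table.codes()
    col = {f: j for j, f in enumerate(table.feature_ids)}
    selected: list[str] = []
    for rf in ranked[: cfg.npresel]:
        if len(selected) >= cfg.nsel:
            break
        j = col[rf.feature]
        ok = all(
            _cramers_v_codes(X[:, j], X[:, col[s]]) <= cfg.t + 1e-12
            for s in selected
        )
        if ok:
            selected.append(rf.feature)
    return selected


def select_features(
    table: AlleleFeatureTable, cfg: SelectionConfig
) -> tuple[list[str], list[RankedFeature]]:
    """Full filter: mode filter -> ranking -> greedy selection."""
    filtered = mode_filter(table, cfg.mode_threshold)
    ranked = rank_by_cramers_v(filtered)
    return greedy_forward_select(ranked, filtered, cfg), ranked


def selection_report(
    ranked: list[RankedFeature], selected: list[str]
) -> pd.DataFrame:
    """Tab-separated-friendly report: feature, V, rank, selected flag."""
    chosen = set(selected)
    return pd.DataFrame(
        {
            "feature": [r.feature for r in ranked],
            "cramers_v": [r.cramers_v for r in ranked],
            "rank": [r.rank for r in ranked],
            "selected": [r.feature in chosen for r in ranked],
        }
    )
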