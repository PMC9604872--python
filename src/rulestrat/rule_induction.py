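"""Conjunctive if-then rule induction with covering/error semantics.

A *rule* is a boolean AND of equality conditions on categorical features
("17:44038536_1 = CA AND Sex = F -> case").  Its quality on a labeled table is

* covering — percentage of samples of the rule's own class satisfying every
  condition;
* error — percentage of samples of the other class satisfying every condition.

The learner is a weighted sequential-covering scheme with beam search: for
each class it repeatedly grows the conjunction that maximizes (weighted)
covering subject to error <= 100*errmax, accepts it if its unweighted covering
clears a small floor, then multiplies the weights of the covered same-class
samples by 0.1 and repeats.  Down-weighting (rather than removing) covered
samples allows overlapping rules.  The procedure is fully deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .genotype_io import MISSING, AlleleFeatureTable

log = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"


@dataclass(frozen=True, order=True)
class Condition:
    feature: str
    value: str

    def __post_init__(self) -> None:
        if self.value == MISSING:
            raise ConfigError("a condition cannot require the missing code")

    @property
    def key(self) -> str:
        return f"{self.feature}={self.value}"


@dataclass
class Rule:
    id: int
    conditions: tuple[Condition, ...]
    klass: str  # "case" | "control"
    covering: float  # percent
    error: float  # percent

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("a rule needs at least one condition")
        if self.klass not in (CASE, CONTROL):
            raise ConfigError(f"unknown class {self.klass!r}")

    def features(self) -> set[str]:
        return {c.feature for c in self.conditions}

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "class": self.klass,
            "covering": self.covering,
            "error": self.error,
            "conditions": [{"feature": c.feature, "value": c.value} for c in self.conditions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            d["id"],
            tuple(Condition(c["feature"], c["value"]) for c in d["conditions"]),
            d["class"],
            d["covering"],
            d["error"],
        )


@dataclass
class RuleSet:
    rules: list[Rule]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rules)

    def by_class(self, klass: str) -> list[Rule]:
        return [r for r in self.rules if r.klass == klass]

    def features(self) -> set[str]:
        out: set[str] = set()
        for r in self.rules:
            out |= r.features()
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"rules": [r.to_dict() for r in self.rules], "metadata": self.metadata},
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "RuleSet":
        d = json.loads(source)
        return cls([Rule.from_dict(r) for r in d["rules"]], d.get("metadata", {}))

    def format_table(self) -> str:
        """Human-readable listing (Id, #conditions, output value, covering %,
        error %, conditions)."""
        lines = ["Id\tConditions\tOutput\tCovering %\tError %\tRule"]
        for r in self.rules:
            expr = " AND ".join(f"{c.feature} = \"{c.value}\"" for c in r.conditions)
            lines.append(
                f"{r.id}\t{len(r.conditions)}\t{r.klass}\t{r.covering:.2f}\t{r.error:.2f}\t{expr}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class InductionConfig:
    errmax: float = 0.05  # max rule error, as a fraction
    min_covering: float = 0.4  # percent floor for accepting a rule
    max_conditions: int = 13
    beam_width: int = 5
    seed: int = 0  # recorded in metadata; the search itself is deterministic
    max_rules_per_class: int = 40
    cover_weight: float = 0.1  # weight multiplier for covered class samples

    def __post_init__(self) -> None:
        if not 0 <= self.errmax < 1:
            raise ConfigError("errmax must be a fraction in [0, 1)")
        if self.max_conditions < 1 or self.beam_width < 1:
            raise ConfigError("max_conditions and beam_width must be >= 1")
        if not 0 <= self.cover_weight < 1:
            raise ConfigError("cover_weight must be in [0, 1)")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rule_match_mask(rule: Rule, table: AlleleFeatureTable) -> np.ndarray:
    """Boolean per-sample mask of rule satisfaction.  A missing value fails
    its condition (conditions never require the missing code)."""
    m = np.ones(table.n_samples, dtype=bool)
    for c in rule.conditions:
        m &= table.column(c.feature) == c.value
    return m


def rule_metrics(rule: Rule, table: AlleleFeatureTable) -> tuple[float, float]:
    """(covering %, error %) of a rule on a labeled table."""
    status = table.status_bool
    cls = status if rule.klass == CASE else ~status
    n_cls = int(cls.sum())
    n_other = int((~cls).sum())
    if n_cls == 0 or n_other == 0:
        raise DataError("rule_metrics needs samples of both classes")
    m = rule_match_mask(rule, table)
    covering = 100.0 * int((m & cls).sum()) / n_cls
    error = 100.0 * int((m & ~cls).sum()) / n_other
    return covering, error


# ---------------------------------------------------------------------------
# induction
# ---------------------------------------------------------------------------

def _beam_search(
    cond_masks: np.ndarray,
    cond_feat: np.ndarray,
    cond_keys: list[str],
    cls: np.ndarray,
    w: np.ndarray,
    cfg: InductionConfig,
):
    """Grow one conjunction for class ``cls`` under the current weights.

    Returns (condition index tuple, match mask) for the best *feasible*
    conjunction (error <= 100*errmax, weighted covering > 0), or None.

    Search policy: the beam retains the ``beam_width`` partial conjunctions
    with the largest covering-minus-error margin (high-covering branches whose
    error is still falling are worth extending); every feasible child competes
    for best-so-far by (higher weighted covering, lower error, lexicographic
    condition keys).  Because adding a condition can only shrink the matched
    set, any branch whose weighted covering no longer exceeds the best
    feasible covering is pruned exactly, and the search stops when no branch
    survives.
    """
    n = len(cls)
    other = ~cls
    n_other = int(other.sum())
    w_cls = w * cls
    total_w = w_cls.sum()
    errmax_pct = 100.0 * cfg.errmax + 1e-9

    beam = [((), frozenset(), np.ones(n, dtype=bool))]
    best = None  # (wcov, -err, keys, cond_ids, mask)

    for _depth in range(cfg.max_conditions):
        children: dict[tuple[int, ...], tuple] = {}
        for cond_ids, used, mask in beam:
            sub = cond_masks[mask]
            wcov_num = sub.T @ w_cls[mask]
            err_num = sub.T @ other[mask].astype(float)
            for j in range(cond_masks.shape[1]):
                if cond_feat[j] in used:
                    continue
                new_ids = tuple(sorted(cond_ids + (j,)))
                if new_ids in children:
                    continue
                wcov = 100.0 * wcov_num[j] / total_w if total_w > 0 else 0.0
                err = 100.0 * err_num[j] / n_other if n_other > 0 else 0.0
                children[new_ids] = (wcov, err, used | {cond_feat[j]}, j, mask)

        # feasible children compete for the final rule
        for ids, (wcov, err, _used, j, mask) in sorted(children.items()):
            if err <= errmax_pct and wcov > 0:
                keys = tuple(cond_keys[i] for i in ids)
                cand = (wcov, -err, keys)
                if best is None or cand > (best[0], best[1], best[2]):
                    best = (wcov, -err, keys, ids, mask & cond_masks[:, j])

        # exact bound: covering only shrinks, so branches at or below the
        # best feasible covering can never yield a better rule
        floor = best[0] if best is not None else 0.0
        survivors = [
            (ids, vals) for ids, vals in children.items() if vals[0] > floor
        ]
        if not survivors:
            break
        survivors.sort(
            key=lambda item: (
                -(item[1][0] - item[1][1]),
                item[1][1],
                tuple(cond_keys[i] for i in item[0]),
            )
        )
        beam = [
            (ids, used, mask & cond_masks[:, j])
            for ids, (_wc, _er, used, j, mask) in survivors[: cfg.beam_width]
        ]
    if best is None:
        return None
    return best[3], best[4]


def fit_ruleset(table: AlleleFeatureTable, cfg: InductionConfig) -> RuleSet:
    """Learn rules for both classes by weighted sequential covering.

    All accepted rules report their covering/error on the full *unweighted*
    training table, and every accepted rule satisfies
    ``error <= 100 * cfg.errmax`` there.
    """
    X, cats = table.codes()
    n, p = X.shape
    feats = table.feature_ids
    status = table.status_bool
    if status.sum() < 2 or (~status).sum() < 2:
        raise DataError("rule induction needs >= 2 samples per class")

    conds: list[Condition] = []
    cond_feat: list[int] = []
    masks: list[np.ndarray] = []
    for fi in range(p):
        for vi, v in enumerate(cats[fi]):
            conds.append(Condition(feats[fi], str(v)))
            cond_feat.append(fi)
            masks.append(X[:, fi] == vi)
    if not masks:
        raise DataError("no candidate conditions (empty feature table)")
    cond_masks = np.column_stack(masks)
    cond_feat_arr = np.array(cond_feat)
    cond_keys = [c.key for c in conds]

    rules: list[Rule] = []
    next_id = 1
    for klass in (CASE, CONTROL):
        cls = status if klass == CASE else ~status
        w = np.ones(n)
        emitted: set[frozenset[int]] = set()
        for _ in range(cfg.max_rules_per_class):
            found = _beam_search(cond_masks, cond_feat_arr, cond_keys, cls, w, cfg)
            if found is None:
                break
            ids, mask = found
            sig = frozenset(ids)
            if sig in emitted:
                break  # weights can no longer steer the search elsewhere
            conditions = tuple(sorted((conds[i] for i in ids), key=lambda c: c.key))
            rule = Rule(next_id, conditions, klass, 0.0, 0.0)
            rule.covering, rule.error = rule_metrics(rule, table)
            if rule.covering < cfg.min_covering:
                break
            assert rule.error <= 100.0 * cfg.errmax + 1e-9
            emitted.add(sig)
            rules.append(rule)
            next_id += 1
            w[cls & mask] *= cfg.cover_weight
        if not any(r.klass == klass for r in rules):
            log.warning("no rule reached min_covering=%.2f%% for class %s", cfg.min_covering, klass)

    return RuleSet(
        rules,
        metadata={
            "errmax": cfg.errmax,
            "min_covering": cfg.min_covering,
            "max_conditions": cfg.max_conditions,
            "beam_width": cfg.beam_width,
            "seed": cfg.seed,
            "features": feats,
        },
    )


# ---------------------------------------------------------------------------
# relevance
# ---------------------------------------------------------------------------

def feature_relevance(ruleset: RuleSet):
    """Aggregate per-feature relevance from rule quality.

    relevance_raw(f) = sum over rules containing f of
    max(0, covering - error) / 100; the normalized column rescales so the top
    feature equals 1.  This is a package-defined surrogate for per-feature
    importance in a ruleset (the covering/error gap a feature participates in),
    not any proprietary ranking.
    """
    import pandas as pd

    raw: dict[str, float] = {}
    for r in ruleset.rules:
        contrib = max(0.0, r.covering - r.error) / 100.0
        for f in r.features():
            raw[f] = raw.get(f, 0.0) + contrib
    if not raw:
        return pd.DataFrame(columns=["raw", "relevance"])
    mx = max(raw.values())
    df = pd.DataFrame(
        {
            "raw": pd.Series(raw),
            "relevance": pd.Series({f: (v / mx if mx > 0 else 0.0) for f, v in raw.items()}),
        }
    )
    df.index.name = "feature"
    return df.sort_values("relevance", ascending=False, kind="stable").sort_index(
        kind="stable"
    ).sort_values("relevance", ascending=False, kind="stable")
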