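"""Cross-cohort rule adaptation by all-confidence condition mining.

A ruleset learned on one cohort may reference variants absent from another
(different genotyping or imputation panels).  Because nearby variants are
often in strong linkage disequilibrium, a missing condition can be replaced by
a highly correlated condition on a retained variant.  Candidates are
restricted to the same chromosome within 500 kb; correlation is measured on
the *training* cohort (where both conditions are observed) by the
all-confidence score

    all_conf(c1, c2) = supp(c1 AND c2) / max(supp(c1), supp(c2))

and a replacement is accepted only when all-confidence >= 0.9.  Rules still
containing an unreplaced missing condition are dropped (a boolean AND cannot
be evaluated).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, AlleleFeatureTable
from .rule_induction import Condition, Rule, RuleSet

log = logging.getLogger(__name__)

MAX_DISTANCE = 500_000
MIN_CONFIDENCE = 0.9


def condition_support(condition: Condition, table: AlleleFeatureTable) -> float:
    """Fraction of all samples satisfying the condition (missing fails)."""
    col = table.column(condition.feature)
    return float(np.mean(col == condition.value))


def all_confidence(c1: Condition, c2: Condition, table: AlleleFeatureTable) -> float:
    """supp(c1 AND c2) / max(supp(c1), supp(c2)); 0 when both supports are 0."""
    m1 = table.column(c1.feature) == c1.value
    m2 = table.column(c2.feature) == c2.value
    s1 = float(m1.mean())
    s2 = float(m2.mean())
    denom = max(s1, s2)
    if denom == 0:
        return 0.0
    return float((m1 & m2).mean()) / denom


@dataclass(frozen=True)
class ReplacementCandidate:
    condition: Condition
    all_confidence: float
    distance: int  # bp from the replaced condition's variant


@dataclass
class AdaptationReport:
    """Condition-level replacement log plus ruleset-level counts."""

    replacements: dict[str, ReplacementCandidate | None] = field(default_factory=dict)
    n_missing: int = 0
    n_replaced: int = 0
    n_rules_total: int = 0
    n_rules_applicable: int = 0
    n_rules_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "replacements": {
                key: (
                    None
                    if cand is None
                    else {
                        "feature": cand.condition.feature,
                        "value": cand.condition.value,
                        "all_confidence": cand.all_confidence,
                        "distance": cand.distance,
                    }
                )
                for key, cand in self.replacements.items()
            },
            "n_missing": self.n_missing,
            "n_replaced": self.n_replaced,
            "n_rules_total": self.n_rules_total,
            "n_rules_applicable": self.n_rules_applicable,
            "n_rules_dropped": self.n_rules_dropped,
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def mine_replacement(
    c: Condition,
    training_table: AlleleFeatureTable,
    validation_features,
    max_dist: int = MAX_DISTANCE,
    min_conf: float = MIN_CONFIDENCE,
) -> ReplacementCandidate | None:
    """Best same-chromosome nearby substitute for a missing condition.

    Every observed value of every candidate feature (present in the
    validation cohort, on the same chromosome, within ``max_dist``) is tried;
    the maximal all-confidence wins, with ties broken by smaller distance,
    then lexicographic feature id, then value.  Returns None when the best
    candidate falls below ``min_conf`` or the condition has no coordinates.
    """
    coords = training_table.coords
    if c.feature not in coords:
        log.info("condition %s has no genomic coordinates; not replaced", c.key)
        return None
    chrom, pos = coords[c.feature]
    validation_features = set(validation_features)
    best_key = None
    best: ReplacementCandidate | None = None
    for f in sorted(validation_features):
        if f not in coords or f not in training_table.values.columns:
            continue
        fchrom, fpos = coords[f]
        dist = abs(fpos - pos)
        if fchrom != chrom or dist > max_dist:
            continue
        col = training_table.column(f)
        for v in sorted(set(col) - {MISSING}):
            cand_cond = Condition(f, str(v))
            conf = all_confidence(c, cand_cond, training_table)
            key = (-conf, dist, f, str(v))
            if best_key is None or key < best_key:
                best_key = key
                best = ReplacementCandidate(cand_cond, conf, dist)
    if best is None or best.all_confidence < min_conf:
        return None
    return best


def adapt_ruleset(
    ruleset: RuleSet,
    training_table: AlleleFeatureTable,
    validation_table: AlleleFeatureTable,
    max_dist: int = MAX_DISTANCE,
    min_conf: float = MIN_CONFIDENCE,
) -> tuple[RuleSet, AdaptationReport]:
    """Adapt a training ruleset to a validation cohort's feature set.

    Each condition whose feature is absent from the validation cohort is
    replaced globally (one substitute per condition) when a qualifying
    candidate exists; rules left with an unreplaced missing condition are
    dropped.  Adapted rules retain their training covering/error metadata.
    """
    val_feats = set(validation_table.values.columns)
    report = AdaptationReport(n_rules_total=len(ruleset.rules))

    # one replacement decision per unique missing condition
    missing: dict[str, Condition] = {}
    for rule in ruleset.rules:
        for cond in rule.conditions:
            if cond.feature not in val_feats:
                missing[cond.key] = cond
    for key in sorted(missing):
        cond = missing[key]
        cand = mine_replacement(cond, training_table, val_feats, max_dist, min_conf)
        if cand is not None:
            chrom, pos = training_table.coords[cond.feature]
            cchrom, _cpos = training_table.coords[cand.condition.feature]
            assert cchrom == chrom and cand.distance <= max_dist
            assert cand.all_confidence >= min_conf
        report.replacements[key] = cand
    report.n_missing = len(missing)
    report.n_replaced = sum(1 for v in report.replacements.values() if v is not None)

    adapted: list[Rule] = []
    for rule in ruleset.rules:
        new_conditions: list[Condition] = []
        applicable = True
        for cond in rule.conditions:
            if cond.feature in val_feats:
                new_conditions.append(cond)
                continue
            cand = report.replacements[cond.key]
            if cand is None:
                applicable = False
                break
            new_conditions.append(cand.condition)
        if not applicable:
            continue
        adapted.append(
            Rule(rule.id, tuple(new_conditions), rule.klass, rule.covering, rule.error)
        )
    report.n_rules_applicable = len(adapted)
    report.n_rules_dropped = report.n_rules_total - report.n_rules_applicable
    if not adapted:
        log.warning("no rule survived adaptation; forecast will be degenerate")
    return RuleSet(adapted, dict(ruleset.metadata)), report
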