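import numpy as np
import pytest

from rulestrat import (
    Condition,
    InductionConfig,
    Rule,
    RuleSet,
    SelectionConfig,
    adapt_ruleset,
    all_confidence,
    condition_support,
    fit_ruleset,
    mine_replacement,
    select_features,
)
from rulestrat.errors import DataError
from tests.conftest import make_table


def _geno_table(cols, coords, status=None):
    n = len(next(iter(cols.values())))
    status = status or ["case", "control"] * (n // 2)
    return make_table(cols, status, coords=coords)


class TestSupportAndAllConfidence:
    def test_constant_column_support_one(self):
        t = _geno_table({"1:100_1": ["A"] * 10}, {"1:100_1": ("1", 100)})
        assert condition_support(Condition("1:100_1", "A"), t) == 1.0

    def test_absent_value_support_zero(self):
        t = _geno_table({"1:100_1": ["A"] * 10}, {"1:100_1": ("1", 100)})
        assert condition_support(Condition("1:100_1", "T"), t) == 0.0

    def test_fractional_support(self):
        t = _geno_table({"f": ["T"] * 30 + ["A"] * 70}, {"f": ("1", 1)})
        assert condition_support(Condition("f", "T"), t) == pytest.approx(0.30)

    def test_unknown_feature_raises(self):
        t = _geno_table({"f": ["A", "B"]}, {})
        with pytest.raises(DataError):
            condition_support(Condition("g", "A"), t)

    def test_identity_is_one(self):
        t = _geno_table({"f": ["A", "B"] * 5}, {})
        c = Condition("f", "A")
        assert all_confidence(c, c, t) == 1.0

    def test_disjoint_is_zero(self):
        t = _geno_table({"f": ["A", "B"] * 5}, {})
        assert all_confidence(Condition("f", "A"), Condition("f", "B"), t) == 0.0

    def test_formula_example(self):
        # supp(c1)=0.5, supp(c2)=0.4, supp(both)=0.4 -> 0.8
        f = ["A"] * 5 + ["B"] * 5
        g = ["C"] * 4 + ["D"] * 6
        t = _geno_table({"f": f, "g": g}, {})
        assert all_confidence(Condition("f", "A"), Condition("g", "C"), t) == pytest.approx(0.8)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        t = _geno_table(
            {"f": list(rng.choice(["A", "B"], 40)), "g": list(rng.choice(["C", "D"], 40))},
            {},
        )
        c1, c2 = Condition("f", "A"), Condition("g", "C")
        assert all_confidence(c1, c2, t) == pytest.approx(all_confidence(c2, c1, t))


class TestMineReplacement:
    def _training(self):
        col = ["A"] * 6 + ["G"] * 4
        cols = {
            "1:1000_1": col,
            "1:11000_1": list(col),            # perfect proxy, 10 kb away
            "1:700000_1": list(col),           # perfect proxy but 699 kb away
            "2:1000_1": list(col),             # wrong chromosome
            "1:20000_1": ["A"] * 5 + ["G"] * 5,  # weak proxy
            "Sex": ["F"] * 10,
        }
        coords = {
            "1:1000_1": ("1", 1000),
            "1:11000_1": ("1", 11000),
            "1:700000_1": ("1", 700000),
            "2:1000_1": ("2", 1000),
            "1:20000_1": ("1", 20000),
        }
        return _geno_table(cols, coords)

    def test_perfect_nearby_proxy_found(self):
        t = self._training()
        cand = mine_replacement(
            Condition("1:1000_1", "A"), t, ["1:11000_1", "1:20000_1"]
        )
        assert cand.condition == Condition("1:11000_1", "A")
        assert cand.all_confidence == 1.0
        assert cand.distance == 10000

    def test_distance_filter_excludes_far_proxy(self):
        t = self._training()
        assert mine_replacement(Condition("1:1000_1", "A"), t, ["1:700000_1"]) is None

    def test_other_chromosome_excluded(self):
        t = self._training()
        assert mine_replacement(Condition("1:1000_1", "A"), t, ["2:1000_1"]) is None

    def test_below_min_confidence_rejected(self):
        t = self._training()
        assert mine_replacement(Condition("1:1000_1", "A"), t, ["1:20000_1"]) is None

    def test_non_genomic_condition_not_replaced(self):
        t = self._training()
        assert mine_replacement(Condition("Sex", "F"), t, ["1:11000_1"]) is None

    def test_tie_broken_by_distance(self):
        col = ["A"] * 6 + ["G"] * 4
        cols = {"1:1000_1": col, "1:9000_1": list(col), "1:5000_1": list(col)}
        coords = {"1:1000_1": ("1", 1000), "1:9000_1": ("1", 9000), "1:5000_1": ("1", 5000)}
        t = _geno_table(cols, coords)
        cand = mine_replacement(Condition("1:1000_1", "A"), t, ["1:9000_1", "1:5000_1"])
        assert cand.condition.feature == "1:5000_1"


class TestAdaptRuleset:
    def _ruleset(self):
        return RuleSet(
            [
                Rule(1, (Condition("1:1000_1", "A"),), "case", 30.0, 4.0),
                Rule(2, (Condition("1:20000_1", "A"), Condition("Sex", "F")), "case", 10.0, 2.0),
            ]
        )

    def test_superset_validation_is_identity(self):
        t = TestMineReplacement()._training()
        adapted, rep = adapt_ruleset(self._ruleset(), t, t)
        assert adapted.to_json() == self._ruleset().to_json()
        assert rep.n_missing == rep.n_rules_dropped == 0
        assert rep.n_rules_applicable == 2

    def test_unreplaceable_condition_drops_only_that_rule(self):
        train = TestMineReplacement()._training()
        # validation lacks 1:1000_1 (proxy available) and 1:20000_1 (no proxy)
        val_cols = {"1:11000_1": ["A"] * 4, "Sex": ["F"] * 4}
        val = make_table(val_cols, ["case", "control"] * 2,
                         coords={"1:11000_1": ("1", 11000)})
        adapted, rep = adapt_ruleset(self._ruleset(), train, val)
        assert rep.n_missing == 2 and rep.n_replaced == 1
        assert rep.n_rules_applicable == 1 and rep.n_rules_dropped == 1
        [rule] = adapted.rules
        assert rule.conditions == (Condition("1:11000_1", "A"),)
        assert (rule.covering, rule.error) == (30.0, 4.0)  # training metadata kept
        # report arithmetic invariants
        assert rep.n_replaced + sum(
            1 for v in rep.replacements.values() if v is None
        ) == rep.n_missing
        assert rep.n_rules_applicable + rep.n_rules_dropped == rep.n_rules_total


class TestSyntheticTransfer:
    def test_zero_dropout_is_identity(self, small_cfg, small_sim):
        import dataclasses

        from rulestrat import build_feature_table, degrade_to_validation, simulate_cohort

        cfg = dataclasses.replace(small_cfg, validation_dropout=0.0, seed=21)
        train, truth = simulate_cohort(cfg)
        valid = degrade_to_validation(train, cfg)
        assert [v.vid for v in valid.variants] == [v.vid for v in train.variants]
        ftr = build_feature_table(train, truth.hla_window)
        rs = fit_ruleset(
            ftr.subset_features(select_features(ftr, SelectionConfig(npresel=40, nsel=10))[0]),
            InductionConfig(),
        )
        fva = build_feature_table(valid, truth.hla_window)
        adapted, rep = adapt_ruleset(rs, ftr, fva)
        assert rep.n_rules_dropped == 0 and rep.n_missing == 0
        assert adapted.to_json() == rs.to_json()

    def test_replacements_obey_constraints(self, paired_cohorts):
        ftrain, fvalid, truth = paired_cohorts
        feats, _ = select_features(ftrain, SelectionConfig(npresel=60, nsel=15))
        rs = fit_ruleset(ftrain.subset_features(feats), InductionConfig())
        adapted, rep = adapt_ruleset(rs, ftrain, fvalid)
        val_feats = set(fvalid.feature_ids)
        for key, cand in rep.replacements.items():
            feature = key.split("=")[0]
            if cand is None:
                continue
            chrom, pos = ftrain.coords[feature]
            cchrom, cpos = ftrain.coords[cand.condition.feature]
            assert cchrom == chrom
            assert abs(cpos - pos) <= 500_000
            assert cand.all_confidence >= 0.9
            assert cand.condition.feature in val_feats
        for rule in adapted.rules:
            assert rule.features() <= val_feats

    def test_perfect_proxy_support_matches_exactly(self):
        import dataclasses

        from rulestrat import SimConfig, simulate_cohort

        cfg = SimConfig(
            n_cases=40, n_controls=80, n_loci=3, variants_per_locus=8,
            block_size=4, proxy_ld=1.0, seed=13,
        )
        train, truth = simulate_cohort(cfg)
        assert truth.dropped_vids
        idx = {v.vid: i for i, v in enumerate(truth.variants)}
        for dropped, partner in truth.proxy_partner.items():
            for slot in ("_1", "_2"):
                cd = train.column(dropped + slot)
                cp = train.column(partner + slot)
                # the alt-allele indicator columns coincide, so each condition
                # on the dropped variant has exactly its proxy's support
                alt_d = truth.alt[idx[dropped]]
                alt_p = truth.alt[idx[partner]]
                assert ((cd == alt_d) == (cp == alt_p)).all()
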