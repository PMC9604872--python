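"""Synthetic paired case/control genotype cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without access-restricted study
data: biallelic/indel variants laid out in LD blocks inside well-separated
locus windows, a female-skewed case group, a dominant-effect HLA-like top SNP
recoded ordinally, planted multi-SNP risk conjunctions (one on a chr17-like
haplotype block by default), and partial variant non-overlap between the
training and validation cohorts with nearby high-LD proxies.

Disease status is sampled directly from a logistic model:

    P(case) = sigmoid(beta0 + beta_sex * female
              + ln(hla_effect) * (HLA ordinal - 1)
              + sum_r ln(odds_r) * 1[rule r's conjunction met])

with ``beta0`` tuned by bisection on a pilot sample so the population
prevalence matches the requested case fraction; exact cohort counts are then
achieved by rejection sampling.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genotype_io import (
    AlleleFeatureTable,
    LocusWindow,
    VariantRecord,
    write_plink,  # re-exported: inverse of the genotype_io readers
)

__all__ = [
    "PlantedRule",
    "SimConfig",
    "TruthBundle",
    "simulate_cohort",
    "degrade_to_validation",
    "write_plink",
]

_CHROM_CYCLE = ["1", "2", "3", "6", "7", "9", "12", "14", "17", "19"]
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class PlantedRule:
    """A risk conjunction: every condition (feature, allele) must hold for the
    odds multiplier to apply."""

    conditions: tuple[tuple[str, str], ...]
    odds: float

    def __post_init__(self) -> None:
        if self.odds <= 0:
            raise ConfigError("planted rule odds multiplier must be > 0")


@dataclass(frozen=True)
class SimConfig:
    # cohort sizes (training / validation)
    n_cases: int = 200
    n_controls: int = 400
    n_cases_val: int = 110
    n_controls_val: int = 250
    # variant layout
    n_loci: int = 10
    variants_per_locus: int = 40
    block_size: int = 10  # variants per LD block
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.85  # prob. a block member copies its anchor's allele
    indel_fraction: float = 0.1
    # effects
    planted_rules: tuple[PlantedRule, ...] | None = None  # None -> default conjunction
    planted_maf: float = 0.5  # maf forced on default planted variants
    female_case_fraction: float = 0.92
    female_control_fraction: float = 0.47
    hla_effect: float = 1.6  # odds multiplier per ordinal step
    # cross-cohort heterogeneity
    validation_dropout: float = 0.1
    proxy_ld: float = 0.95  # allele agreement of the retained proxy
    seed: int = 0
    max_batches: int = 400

    def __post_init__(self) -> None:
        for name in (
            "female_case_fraction",
            "female_control_fraction",
            "validation_dropout",
            "proxy_ld",
            "ld_rho",
            "indel_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0 < self.female_case_fraction < 1 and 0 < self.female_control_fraction < 1):
            raise ConfigError("female fractions must be strictly inside (0, 1)")
        if self.hla_effect <= 0:
            raise ConfigError("hla_effect must be > 0")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 1")
        if min(self.n_cases, self.n_controls, self.n_cases_val, self.n_controls_val) < 1:
            raise ConfigError("cohort sizes must be >= 1")
        if self.n_loci < 1 or self.variants_per_locus < 1 or self.block_size < 1:
            raise ConfigError("layout sizes must be >= 1")


@dataclass
class TruthBundle:
    """Everything needed to verify recovery claims against the generator."""

    config: SimConfig
    variants: list[VariantRecord]
    maf: np.ndarray
    ref: list[str]
    alt: list[str]
    block_of: np.ndarray
    locus_of: np.ndarray
    locus_windows: list[LocusWindow]
    hla_vid: str
    hla_window: LocusWindow
    planted_rules: list[PlantedRule]
    dropped_vids: list[str]
    proxy_partner: dict[str, str]  # dropped vid -> retained partner vid
    beta0: float
    beta_sex: float
    liability: np.ndarray | None = None  # training-sample linear predictors
    liability_val: np.ndarray | None = None

    def to_json(self, path=None) -> str:
        d = {
            "config": _config_dict(self.config),
            "hla_vid": self.hla_vid,
            "hla_window": dataclasses.asdict(self.hla_window),
            "planted_rules": [
                {"conditions": [list(c) for c in r.conditions], "odds": r.odds}
                for r in self.planted_rules
            ],
            "dropped_vids": self.dropped_vids,
            "proxy_partner": self.proxy_partner,
            "beta0": self.beta0,
            "beta_sex": self.beta_sex,
            "n_variants": len(self.variants),
        }
        payload = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _config_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.planted_rules is not None:
        d["planted_rules"] = [
            {"conditions": [list(c) for c in r.conditions], "odds": r.odds}
            for r in cfg.planted_rules
        ]
    return d


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    truth: TruthBundle
    anchor_of: np.ndarray  # variant index of each variant's block anchor
    planted: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]]
    # each planted rule as (variant indices, slots, required bits, ln odds)
    hla_idx: int
    proxied_idx: np.ndarray
    partner_idx: np.ndarray


def _build_layout(cfg: SimConfig, rng: np.random.Generator) -> _Layout:
    m = cfg.n_loci * cfg.variants_per_locus
    chroms = [_CHROM_CYCLE[i % len(_CHROM_CYCLE)] for i in range(cfg.n_loci)]
    variants: list[VariantRecord] = []
    locus_of = np.empty(m, dtype=int)
    block_of = np.empty(m, dtype=int)
    windows: list[LocusWindow] = []
    maf = rng.uniform(*cfg.maf_range, size=m)
    ref: list[str] = []
    alt: list[str] = []
    n_blocks_per_locus = -(-cfg.variants_per_locus // cfg.block_size)

    for li in range(cfg.n_loci):
        start = 1_000_000 + li * 2_000_000  # locus windows >= 1 Mb apart
        chrom = chroms[li]
        windows.append(LocusWindow(chrom, start, start + (cfg.variants_per_locus - 1) * 1000))
        for j in range(cfg.variants_per_locus):
            v = li * cfg.variants_per_locus + j
            pos = start + j * 1000
            variants.append(VariantRecord(chrom, f"{chrom}:{pos}", 0.0, pos))
            locus_of[v] = li
            block_of[v] = li * n_blocks_per_locus + j // cfg.block_size
            pair = _ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))]
            r, a = pair
            if rng.random() < cfg.indel_fraction:
                a = r + a  # simple insertion allele, e.g. "CA"
            ref.append(r)
            alt.append(a)

    # anchor (first variant) of each block
    anchor_of = np.empty(m, dtype=int)
    seen: dict[int, int] = {}
    for v in range(m):
        b = int(block_of[v])
        if b not in seen:
            seen[b] = v
        anchor_of[v] = seen[b]

    # HLA-like locus on chromosome 6: the top SNP is the first anchor there
    try:
        hla_locus = chroms.index("6")
    except ValueError:
        hla_locus = cfg.n_loci - 1
    hla_idx = hla_locus * cfg.variants_per_locus
    ref[hla_idx], alt[hla_idx] = "A", "G"  # risk allele G, dominant-ish effect
    hla_window = windows[hla_locus]

    # default planted conjunction on the chr17-like locus
    planted_rules = cfg.planted_rules
    if planted_rules is None:
        planted_locus = chroms.index("17") if "17" in chroms else (
            cfg.n_loci - 1 if cfg.n_loci - 1 != hla_locus else 0
        )
        picks = []
        for k in range(3):
            off = (k * cfg.block_size + 1) % cfg.variants_per_locus
            picks.append(planted_locus * cfg.variants_per_locus + off)
        picks = sorted(set(picks))
        for v in picks:
            maf[v] = cfg.planted_maf
            # planted variants are drawn independently of their LD block, so
            # the planted conjunction is identifiable by its own conditions
            # rather than through a correlated block mate
            anchor_of[v] = v
        planted_rules = (
            PlantedRule(
                tuple(
                    (f"{variants[v].feature_base}_1", alt[v]) for v in picks
                ),
                odds=8.0,
            ),
        )
    planted_rules = tuple(planted_rules)

    # resolve planted conditions to (variant, slot, bit)
    base_to_idx = {variants[v].feature_base: v for v in range(m)}
    resolved = []
    for r in planted_rules:
        vs, slots, bits = [], [], []
        for feature, allele in r.conditions:
            base, slot = feature.rsplit("_", 1)
            if base not in base_to_idx or slot not in ("1", "2"):
                raise ConfigError(f"planted condition on unknown feature {feature!r}")
            v = base_to_idx[base]
            if allele == alt[v]:
                bits.append(1)
            elif allele == ref[v]:
                bits.append(0)
            else:
                raise ConfigError(
                    f"planted allele {allele!r} not among alleles of {base}"
                )
            vs.append(v)
            slots.append(int(slot) - 1)
        resolved.append(
            (np.array(vs), np.array(slots), np.array(bits), math.log(r.odds))
        )

    # plan the validation dropout with guaranteed nearby proxies
    n_drop = int(round(cfg.validation_dropout * m))
    planted_vs = {int(v) for vs, _s, _b, _o in resolved for v in vs}
    # only odd within-block offsets are droppable, so the (even-offset)
    # predecessor is always retained and can serve as the proxy
    candidates = [
        v
        for v in range(m)
        if ((v % cfg.variants_per_locus) % cfg.block_size) % 2 == 1
        and locus_of[v] != hla_locus
        and v not in planted_vs
    ]
    if n_drop > len(candidates):
        raise DataError(
            "proxy placement impossible: not enough non-anchor variants to drop "
            f"({n_drop} requested, {len(candidates)} available)"
        )
    dropped = sorted(rng.choice(candidates, size=n_drop, replace=False).tolist())
    partner = {v: v - 1 for v in dropped}  # predecessor: 1 kb away, retained
    for v, p in partner.items():
        assert p not in partner and variants[p].chrom == variants[v].chrom
        maf[v] = maf[p]  # the proxy pair shares its allele frequency

    beta_sex = math.log(
        (cfg.female_case_fraction / (1 - cfg.female_case_fraction))
        / (cfg.female_control_fraction / (1 - cfg.female_control_fraction))
    )

    truth = TruthBundle(
        config=cfg,
        variants=variants,
        maf=maf,
        ref=ref,
        alt=alt,
        block_of=block_of,
        locus_of=locus_of,
        locus_windows=windows,
        hla_vid=variants[hla_idx].vid,
        hla_window=hla_window,
        planted_rules=list(planted_rules),
        dropped_vids=[variants[v].vid for v in dropped],
        proxy_partner={variants[v].vid: variants[p].vid for v, p in partner.items()},
        beta0=0.0,
        beta_sex=beta_sex,
    )
    return _Layout(
        truth=truth,
        anchor_of=anchor_of,
        planted=resolved,
        hla_idx=hla_idx,
        proxied_idx=np.array(dropped, dtype=int),
        partner_idx=np.array([partner[v] for v in dropped], dtype=int),
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gen_batch(layout: _Layout, cfg: SimConfig, nb: int, rng: np.random.Generator):
    """Draw genotype bits (alt-allele indicators), sex and linear predictors
    (without intercept) for ``nb`` individuals."""
    truth = layout.truth
    m = len(truth.variants)
    maf = truth.maf

    base = rng.random((nb, m, 2)) < maf[None, :, None]
    shared = base[:, layout.anchor_of, :]  # every member sees its anchor's draw
    redraw = rng.random((nb, m, 2)) < maf[None, :, None]
    copy = rng.random((nb, m, 2)) < cfg.ld_rho
    bits = np.where(copy, shared, redraw)
    is_anchor = layout.anchor_of == np.arange(m)
    bits[:, is_anchor, :] = base[:, is_anchor, :]
    if len(layout.proxied_idx):
        keep = rng.random((nb, len(layout.proxied_idx), 2)) < cfg.proxy_ld
        redraw_p = rng.random((nb, len(layout.proxied_idx), 2)) < maf[layout.partner_idx][None, :, None]
        bits[:, layout.proxied_idx, :] = np.where(
            keep, bits[:, layout.partner_idx, :], redraw_p
        )

    f_pool = (
        cfg.n_cases * cfg.female_case_fraction
        + cfg.n_controls * cfg.female_control_fraction
    ) / (cfg.n_cases + cfg.n_controls)
    female = rng.random(nb) < f_pool

    hla_ord = bits[:, layout.hla_idx, :].sum(axis=1)  # 0/1/2 risk-allele count
    lp = truth.beta_sex * female + math.log(cfg.hla_effect) * hla_ord
    for vs, slots, req, ln_odds in layout.planted:
        met = np.all(bits[:, vs, slots] == req[None, :], axis=1)
        lp = lp + ln_odds * met
    return bits.astype(np.uint8), female, lp


def _tune_beta0(layout: _Layout, cfg: SimConfig, rng: np.random.Generator) -> float:
    """Bisection so that the population case probability matches the requested
    case fraction."""
    target = cfg.n_cases / (cfg.n_cases + cfg.n_controls)
    _bits, _female, lp = _gen_batch(layout, cfg, 5000, rng)
    lo, hi = -20.0, 20.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if _sigmoid(mid + lp).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _bits_to_table(
    layout: _Layout,
    bits: np.ndarray,
    female: np.ndarray,
    is_case: np.ndarray,
    prefix: str,
) -> AlleleFeatureTable:
    truth = layout.truth
    n = len(female)
    samples = pd.DataFrame(
        {
            "fid": [f"{prefix}{i:05d}" for i in range(n)],
            "iid": [f"{prefix}{i:05d}" for i in range(n)],
            "sex": np.where(female, "F", "M"),
            "status": np.where(is_case, "case", "control"),
        }
    )
    cols: dict[str, np.ndarray] = {}
    coords: dict[str, tuple[str, int]] = {}
    for v, rec in enumerate(truth.variants):
        f1, f2 = rec.slot_features()
        alleles = np.array([truth.ref[v], truth.alt[v]], dtype=object)
        cols[f1] = alleles[bits[:, v, 0]]
        cols[f2] = alleles[bits[:, v, 1]]
        coords[f1] = (rec.chrom, rec.pos)
        coords[f2] = (rec.chrom, rec.pos)
    values = pd.DataFrame(cols)
    return AlleleFeatureTable(samples, values, coords, variants=truth.variants, truth=truth)


def _sample_cohort(
    layout: _Layout,
    cfg: SimConfig,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    prefix: str,
):
    """Rejection-sample genotype/sex/status until the exact quotas are met."""
    truth = layout.truth
    kept_bits, kept_female, kept_case, kept_lp = [], [], [], []
    got_cases = got_controls = 0
    for _ in range(cfg.max_batches):
        if got_cases >= n_cases and got_controls >= n_controls:
            break
        nb = 500
        bits, female, lp = _gen_batch(layout, cfg, nb, rng)
        p = _sigmoid(truth.beta0 + lp)
        case = rng.random(nb) < p
        take = np.zeros(nb, dtype=bool)
        case_idx = np.flatnonzero(case)[: max(0, n_cases - got_cases)]
        ctrl_idx = np.flatnonzero(~case)[: max(0, n_controls - got_controls)]
        take[case_idx] = True
        take[ctrl_idx] = True
        got_cases += len(case_idx)
        got_controls += len(ctrl_idx)
        kept_bits.append(bits[take])
        kept_female.append(female[take])
        kept_case.append(case[take])
        kept_lp.append(lp[take])
    if got_cases < n_cases or got_controls < n_controls:
        raise DataError(
            f"could not reach {n_cases} cases / {n_controls} controls within "
            f"{cfg.max_batches} batches (got {got_cases}/{got_controls}); "
            "the configured effects make a class near-impossible"
        )
    bits = np.concatenate(kept_bits)
    female = np.concatenate(kept_female)
    case = np.concatenate(kept_case)
    lp = np.concatenate(kept_lp)
    table = _bits_to_table(layout, bits, female, case, prefix)
    return table, lp


def simulate_cohort(cfg: SimConfig) -> tuple[AlleleFeatureTable, TruthBundle]:
    """Generate the training cohort (and the shared layout/truth)."""
    rng = np.random.default_rng([cfg.seed, 0])
    layout = _build_layout(cfg, rng)
    layout.truth.beta0 = _tune_beta0(layout, cfg, np.random.default_rng([cfg.seed, 1]))
    table, lp = _sample_cohort(
        layout, cfg, cfg.n_cases, cfg.n_controls, np.random.default_rng([cfg.seed, 2]), "T"
    )
    layout.truth.liability = lp
    table.meta["layout"] = layout  # reused by degrade_to_validation
    return table, layout.truth


def degrade_to_validation(
    table: AlleleFeatureTable, cfg: SimConfig
) -> AlleleFeatureTable:
    """Fresh validation-cohort samples from the same generative process, with
    the planned fraction of variants removed (each removed variant has a
    retained same-chromosome proxy within 500 kb at ``proxy_ld`` agreement)."""
    layout: _Layout | None = table.meta.get("layout")
    if layout is None:
        raise DataError("table was not produced by simulate_cohort")
    truth = layout.truth
    val, lp = _sample_cohort(
        layout, cfg, cfg.n_cases_val, cfg.n_controls_val, np.random.default_rng([cfg.seed, 3]), "V"
    )
    truth.liability_val = lp
    dropped = set(truth.dropped_vids)
    keep_variants = [v for v in truth.variants if v.vid not in dropped]
    keep_features = [f for v in keep_variants for f in v.slot_features()]
    out = AlleleFeatureTable(
        val.samples,
        val.values[keep_features],
        {f: val.coords[f] for f in keep_features},
        variants=keep_variants,
        truth=truth,
    )
    return out
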