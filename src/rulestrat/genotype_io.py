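"""PLINK text genotype I/O and categorical feature-table construction.

The pipeline treats genotypes as *categorical allele-slot features*: each
biallelic variant occupies two allele columns of a .ped file, and each column
becomes one feature named ``chrom:pos_1`` / ``chrom:pos_2`` whose values are
allele strings ("A", "T", "CA", ...).  ``"0"`` is the PLINK missing-allele
code and never satisfies an equality condition.  Sex and an ordinally recoded
top HLA SNP complete the feature vocabulary.

Coordinates are 1-based inclusive throughout (PLINK convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParseError

log = logging.getLogger(__name__)

MISSING = "0"
SEX_FEATURE = "Sex"
HLA_FEATURE = "HLA_ordinal"
#: features without genomic coordinates, exempt from filters/replacement
SPECIAL_FEATURES = (SEX_FEATURE, HLA_FEATURE)

_SEX_FROM_PED = {"1": "M", "2": "F"}
_SEX_TO_PED = {"M": "1", "F": "2"}
_STATUS_FROM_PED = {"1": "control", "2": "case"}
_STATUS_TO_PED = {"control": "1", "case": "2"}


@dataclass(frozen=True)
class VariantRecord:
    """One .map line: chromosome, variant id, genetic distance, bp position."""

    chrom: str
    vid: str
    cm: float
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise DataError("variant chromosome label must be non-empty")
        if self.pos < 1:
            raise DataError(f"variant {self.vid}: position must be >= 1")

    @property
    def feature_base(self) -> str:
        return f"{self.chrom}:{self.pos}"

    def slot_features(self) -> tuple[str, str]:
        base = self.feature_base
        return f"{base}_1", f"{base}_2"


@dataclass(frozen=True)
class SampleRecord:
    fid: str
    iid: str
    sex: str  # "F" | "M"
    status: str  # "case" | "control"


@dataclass(frozen=True)
class LocusWindow:
    """1-based inclusive genomic interval, e.g. a coding region +/- 250 kb."""

    chrom: str
    start: int
    end: int

    #: default padding applied around a coding region
    PAD = 250_000

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise DataError(f"window end {self.end} < start {self.start}")
        if self.start < 1:
            raise DataError("window start must be >= 1")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def around(cls, chrom: str, start: int, end: int, pad: int = PAD) -> "LocusWindow":
        return cls(chrom, max(1, start - pad), end + pad)


class AlleleFeatureTable:
    """Samples x categorical features, with per-feature genomic coordinates.

    Parameters
    ----------
    samples
        DataFrame with columns ``fid, iid, sex, status``.
    values
        DataFrame of categorical strings, one column per feature, aligned
        row-wise with ``samples``.
    coords
        feature id -> (chrom, pos) for genomic (allele-slot) features.
    variants
        Ordered variant records backing the allele-slot columns, when the
        table is still writable as .ped/.map.
    """

    def __init__(
        self,
        samples: pd.DataFrame,
        values: pd.DataFrame,
        coords: Mapping[str, tuple[str, int]],
        variants: Sequence[VariantRecord] | None = None,
        truth=None,
        meta: dict | None = None,
    ) -> None:
        if len(samples) != len(values):
            raise DataError("samples and values row counts differ")
        self.samples = samples.reset_index(drop=True)
        self.values = values.reset_index(drop=True)
        self.coords = dict(coords)
        self.variants = list(variants) if variants is not None else None
        self.truth = truth
        self.meta = dict(meta) if meta else {}
        self._codes: tuple[np.ndarray, list[list[str]]] | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def status_bool(self) -> np.ndarray:
        """Boolean vector, True for cases."""
        return (self.samples["status"].to_numpy() == "case")

    def column(self, feature: str) -> np.ndarray:
        if feature not in self.values.columns:
            raise DataError(f"unknown feature {feature!r}")
        return self.values[feature].to_numpy(dtype=object)

    # -- integer encoding (shared by selection and induction) --------------
    def codes(self) -> tuple[np.ndarray, list[list[str]]]:
        """Integer-encode every column; missing -> -1.

        Category order is sorted lexicographically for determinism.  The
        encoding is cached and shared with sample subsets.
        """
        if self._codes is None:
            n = self.n_samples
            cols, cats = [], []
            for f in self.values.columns:
                col = self.values[f].to_numpy(dtype=object).astype(str)
                levels = sorted(set(col) - {MISSING})
                mapping = {v: i for i, v in enumerate(levels)}
                code = np.fromiter((mapping.get(v, -1) for v in col), np.int32, n)
                cols.append(code)
                cats.append(levels)
            X = (
                np.column_stack(cols)
                if cols
                else np.empty((n, 0), dtype=np.int32)
            )
            self._codes = (X, cats)
        return self._codes

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, idx: np.ndarray) -> "AlleleFeatureTable":
        sub = AlleleFeatureTable(
            self.samples.iloc[idx],
            self.values.iloc[idx],
            self.coords,
            self.variants,
            truth=self.truth,
            meta=self.meta,
        )
        if self._codes is not None:  # category maps are reusable as-is
            X, cats = self._codes
            sub._codes = (X[np.asarray(idx)], cats)
        return sub

    def subset_features(self, features: Sequence[str]) -> "AlleleFeatureTable":
        features = list(features)
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise DataError(f"unknown features: {missing}")
        coords = {f: self.coords[f] for f in features if f in self.coords}
        return AlleleFeatureTable(
            self.samples,
            self.values[features],
            coords,
            self.variants,
            truth=self.truth,
            meta=self.meta,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_map(path) -> list[VariantRecord]:
    """Parse a PLINK .map file (chrom, vid, cM, bp; whitespace-delimited)."""
    records: list[VariantRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, vid, cm, pos = parts
            if vid in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate variant id {vid!r}")
            seen.add(vid)
            try:
                rec = VariantRecord(chrom, vid, float(cm), int(pos))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def read_ped(path, variants: Sequence[VariantRecord]) -> AlleleFeatureTable:
    """Parse a PLINK .ped file into an allele-slot feature table.

    Expects the standard 6 leading columns (fid iid pat mat sex phenotype),
    sex coded 1=M/2=F and phenotype 1=control/2=case; this pipeline requires
    labeled samples, so any other phenotype code is rejected.
    """
    expected = 6 + 2 * len(variants)
    rows: list[tuple[str, str, str, str]] = []
    geno: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != expected:
                raise ParseError(
                    f"{path}: line {lineno}: expected {expected} columns "
                    f"(6 + 2 x {len(variants)} variants), got {len(parts)}"
                )
            fid, iid, _pat, _mat, sex, phen = parts[:6]
            if sex not in _SEX_FROM_PED:
                raise DataError(f"{path}: line {lineno}: sex code {sex!r} not in 1/2")
            if phen not in _STATUS_FROM_PED:
                raise DataError(
                    f"{path}: line {lineno}: phenotype {phen!r} outside {{1,2}}; "
                    "this pipeline needs labeled case/control samples"
                )
            rows.append((fid, iid, _SEX_FROM_PED[sex], _STATUS_FROM_PED[phen]))
            geno.append(parts[6:])

    samples = pd.DataFrame(rows, columns=["fid", "iid", "sex", "status"])
    features: list[str] = []
    coords: dict[str, tuple[str, int]] = {}
    for v in variants:
        f1, f2 = v.slot_features()
        if f1 in coords:
            raise ParseError(f"duplicate feature position {v.feature_base}")
        features.extend([f1, f2])
        coords[f1] = (v.chrom, v.pos)
        coords[f2] = (v.chrom, v.pos)
    geno_arr = (
        np.array(geno, dtype=object)
        if geno
        else np.empty((0, 2 * len(variants)), dtype=object)
    )
    values = pd.DataFrame(geno_arr, columns=features)
    return AlleleFeatureTable(samples, values, coords, variants=variants)


def read_plink(prefix) -> AlleleFeatureTable:
    """Convenience: read ``prefix``.map + ``prefix``.ped."""
    variants = read_map(f"{prefix}.map")
    return read_ped(f"{prefix}.ped", variants)


def write_plink(table: AlleleFeatureTable, prefix) -> tuple[str, str]:
    """Emit .ped/.map in the same whitespace-delimited dialect the readers use.

    Only valid for tables that still carry their variant records and all
    allele-slot columns (i.e. raw tables, before HLA recoding).
    """
    if table.variants is None:
        raise DataError("table has no variant records; cannot write .ped/.map")
    slot_cols: list[str] = []
    for v in table.variants:
        f1, f2 = v.slot_features()
        if f1 not in table.values.columns or f2 not in table.values.columns:
            raise DataError(f"allele slots of variant {v.vid} missing from table")
        slot_cols.extend([f1, f2])

    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    with open(map_path, "w") as fh:
        for v in table.variants:
            fh.write(f"{v.chrom}\t{v.vid}\t{v.cm:g}\t{v.pos}\n")
    geno = table.values[slot_cols].to_numpy(dtype=object)
    with open(ped_path, "w") as fh:
        for i, s in enumerate(table.samples.itertuples(index=False)):
            lead = [s.fid, s.iid, "0", "0", _SEX_TO_PED[s.sex], _STATUS_TO_PED[s.status]]
            fh.write(" ".join(lead + [str(a) for a in geno[i]]) + "\n")
    return ped_path, map_path


def read_regions(path) -> list[LocusWindow]:
    """Read 3-column tab-separated region files (chrom, start, end)."""
    windows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 tab-separated columns")
            windows.append(LocusWindow(parts[0], int(parts[1]), int(parts[2])))
    return windows


def write_regions(windows: Iterable[LocusWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")


# ---------------------------------------------------------------------------
# association scan + ordinal recoding of the top HLA SNP
# ---------------------------------------------------------------------------

def _pearson_chi2(obs: np.ndarray) -> float:
    """Pearson chi-square without continuity correction; 0 for degenerate
    tables (a margin of zero)."""
    obs = np.asarray(obs, dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if n == 0 or (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        return 0.0
    exp = np.outer(rows, cols) / n
    mask = exp > 0
    return float(((obs - exp)[mask] ** 2 / exp[mask]).sum())


def allelic_association_scan(
    table: AlleleFeatureTable, window: LocusWindow
) -> list[tuple[str, float, float]]:
    """Per-variant allelic chi-square in a window (PLINK --assoc convention).

    Each sample contributes its two alleles to a 2x2 allele-by-status count
    table (missing alleles skipped); the statistic is the 1-df Pearson
    chi-square without continuity correction.  Monomorphic variants score
    chi2 = 0, p = 1.  Returns (vid, chi2, p) sorted by ascending p.
    """
    if table.variants is None:
        raise DataError("table has no variant records; cannot scan")
    status = table.status_bool
    if status.all() or not status.any():
        raise DataError("association scan needs both cases and controls")
    out: list[tuple[str, float, float]] = []
    for v in table.variants:
        if not window.contains(v.chrom, v.pos):
            continue
        f1, f2 = v.slot_features()
        if f1 not in table.values.columns or f2 not in table.values.columns:
            continue
        alleles = np.concatenate([table.column(f1), table.column(f2)])
        stat2 = np.concatenate([status, status])
        keep = alleles != MISSING
        alleles, stat2 = alleles[keep], stat2[keep]
        levels = sorted(set(alleles))
        if len(levels) > 2:
            raise DataError(f"variant {v.vid} is not biallelic ({levels})")
        if len(levels) < 2:
            out.append((v.vid, 0.0, 1.0))
            continue
        obs = np.array(
            [
                [np.sum((alleles == a) & stat2), np.sum((alleles == a) & ~stat2)]
                for a in levels
            ],
            dtype=float,
        )
        chi2 = _pearson_chi2(obs)
        p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
        out.append((v.vid, chi2, p))
    out.sort(key=lambda t: (t[2], t[0]))
    return out


def recode_ordinal(
    genotype: tuple[str, str], risk_order: tuple[str, str]
) -> int | None:
    """Recode a biallelic genotype to 1/2/3 (homozygous low / het / homozygous
    high), order-insensitive for heterozygotes.  Missing or third alleles
    return ``None`` so the caller can flag the sample."""
    low, high = risk_order
    a, b = genotype
    if a not in (low, high) or b not in (low, high):
        return None
    return 1 + int(a == high) + int(b == high)


def build_feature_table(
    table: AlleleFeatureTable,
    hla_window: LocusWindow | None = None,
    risk_order: tuple[str, str] | None = None,
) -> AlleleFeatureTable:
    """Assemble the model-facing feature table.

    Allele-slot features outside the HLA window are kept as-is; the HLA region
    is represented solely by the ordinal recode of its best-associated SNP
    (chosen per cohort by :func:`allelic_association_scan`), plus a ``Sex``
    feature.  When ``risk_order`` is not given, the minor allele of the top
    SNP is taken as the high-risk allele.
    """
    values = table.values.copy()
    coords = dict(table.coords)

    hla_col = None
    top_vid = None
    if hla_window is not None:
        ranked = allelic_association_scan(table, hla_window)
        if not ranked:
            log.warning("HLA window %s contains no variants; HLA_ordinal omitted", hla_window)
        else:
            top_vid = ranked[0][0]
            variant = next(v for v in table.variants if v.vid == top_vid)
            f1, f2 = variant.slot_features()
            a1, a2 = table.column(f1), table.column(f2)
            if risk_order is None:
                pooled = np.concatenate([a1, a2])
                pooled = pooled[pooled != MISSING]
                levels, counts = np.unique(pooled, return_counts=True)
                if len(levels) == 1:
                    risk_order = (str(levels[0]), str(levels[0]))
                else:
                    # minor allele (lexicographically first on a tie) is "high"
                    order = sorted(zip(counts, levels), key=lambda t: (-t[0], t[1]))
                    risk_order = (str(order[0][1]), str(order[1][1]))
            ords = [recode_ordinal((x, y), risk_order) for x, y in zip(a1, a2)]
            n_flagged = sum(o is None for o in ords)
            if n_flagged:
                log.warning("%d samples have unrecodable HLA genotypes", n_flagged)
            hla_col = np.array([MISSING if o is None else str(o) for o in ords], dtype=object)

        # drop every allele-slot feature inside the window
        in_window = [
            f
            for f, (c, p) in table.coords.items()
            if hla_window.contains(c, p) and f in values.columns
        ]
        values = values.drop(columns=in_window)
        for f in in_window:
            coords.pop(f, None)

    values[SEX_FEATURE] = table.samples["sex"].to_numpy(dtype=object)
    if hla_col is not None:
        values[HLA_FEATURE] = hla_col

    meta = dict(table.meta)
    if top_vid is not None:
        meta["hla_top_vid"] = top_vid
        meta["hla_risk_order"] = list(risk_order)
    return AlleleFeatureTable(
        table.samples, values, coords, variants=table.variants, truth=table.truth, meta=meta
    )
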