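"""Hard filtering, genotype-quality masking, variant classification and Ti/Tv QC.

The site filters are the GATK-convention hard-filter expressions for pooled
short-read calls: a site fails when any *present* metric violates its strict
inequality (QUAL < 30, QD < 2, MQ < 40, FS > 60, HaplotypeScore > 13,
MQRankSum < -12.5, ReadPosRankSum < -8). Metrics GATK did not emit for a site
never fail it: rank-sum annotations, for instance, only exist at sites with
heterozygous calls, and treating their absence as 0 would discard valid sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import PoolData, VariantRecord, mask_pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterCriteria:
    """Hard-filter thresholds (strict inequalities) plus the genotype-quality floor."""

    qual_min: float = 30.0
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0
    gq_min: int = 20

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if not math.isfinite(val):
                raise ValueError(f"criterion {name} must be finite, got {val}")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("verdict passed flag inconsistent with reasons")


#: (reason name, INFO key or None for QUAL, direction, criteria attribute)
_RULES = (
    ("QUAL", None, "lt", "qual_min"),
    ("QD", "QD", "lt", "qd_min"),
    ("MQ", "MQ", "lt", "mq_min"),
    ("FS", "FS", "gt", "fs_max"),
    ("HaplotypeScore", "HaplotypeScore", "gt", "haplotype_score_max"),
    ("MQRankSum", "MQRankSum", "lt", "mq_rank_sum_min"),
    ("ReadPosRankSum", "ReadPosRankSum", "lt", "read_pos_rank_sum_min"),
)


def apply_hard_filters(
    record: VariantRecord, criteria: FilterCriteria = FilterCriteria()
) -> FilterVerdict:
    """Test one record against the hard filters; all violated criteria are listed."""
    reasons = []
    for name, key, direction, attr in _RULES:
        value = record.qual if key is None else record.info.get(key)
        if value is None:
            continue
        threshold = getattr(criteria, attr)
        if (direction == "lt" and value < threshold) or (
            direction == "gt" and value > threshold
        ):
            reasons.append(name)
    reasons = tuple(sorted(set(reasons)))
    return FilterVerdict(passed=not reasons, reasons=reasons)


def hard_filter_frame(
    table: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> pd.Series:
    """Vectorised pass mask for a variant table with QUAL/QD/... columns.

    NaN means the metric is absent and, as in the per-record path, never fails.
    """
    n = len(table)
    fail = np.zeros(n, dtype=bool)
    for name, key, direction, attr in _RULES:
        col = "QUAL" if key is None else key
        if col not in table.columns:
            continue
        vals = table[col].to_numpy(dtype=float)
        threshold = getattr(criteria, attr)
        # NaN (absent metric) compares False in both directions → never fails
        with np.errstate(invalid="ignore"):
            fail |= vals < threshold if direction == "lt" else vals > threshold
    return pd.Series(~fail, index=table.index, name="pass")


def mask_low_gq(
    record: VariantRecord, criteria: FilterCriteria = FilterCriteria()
) -> VariantRecord | None:
    """Mask pools with GQ below the floor; return None when no pool survives.

    Masking clears the pool genotype and GQ but keeps the observed read depths:
    the reads exist regardless of genotype confidence, and the sweep scan works
    on reads. Pools with absent GQ are retained (absence is not evidence).
    """
    masked = record
    surviving = 0
    for i, p in enumerate(record.pools):
        if p.gq is not None and p.gq < criteria.gq_min:
            masked = mask_pool(masked, i)
        elif p.genotype is not None:
            surviving += 1
    return masked if surviving >= 1 else None


class VariantType(str, Enum):
    SNP = "SNP"
    INDEL = "indel"
    MIXED = "mixed"


def classify_variant_type(record: VariantRecord) -> VariantType:
    """SNP iff ref and every alt are single bases; any length change makes an
    indel; a site mixing substitution and length-change alts is ``mixed``."""
    has_len_change = any(len(a) != len(record.ref) for a in record.alts)
    has_sub = any(len(a) == len(record.ref) for a in record.alts)
    if has_len_change and has_sub:
        return VariantType.MIXED
    if has_len_change:
        return VariantType.INDEL
    if len(record.ref) == 1 and all(len(a) == 1 for a in record.alts):
        return VariantType.SNP
    return VariantType.MIXED  # equal-length multi-base substitution (MNP)


class Zygosity(str, Enum):
    FIXED = "fixed"
    SEGREGATING = "segregating"
    REFERENCE = "reference"


class MaskedPoolError(ValueError):
    """The pool genotype is missing (e.g. masked for low GQ)."""


def classify_zygosity(record: VariantRecord, pool_index: int) -> Zygosity:
    """Within-pool class: fixed (all alleles one non-reference allele),
    segregating (≥2 distinct alleles) or reference (all alleles reference).

    ``reference`` is not one of the two published classes; joint-called
    multi-pool VCFs contain pool-level non-variant sites, and the two
    published classes only partition variant-in-pool sites.
    """
    pool = record.pools[pool_index]
    if pool.genotype is None:
        raise MaskedPoolError(f"{record.chrom}:{record.pos}: pool {pool_index} genotype masked")
    alleles = set(pool.genotype)
    if len(alleles) >= 2:
        return Zygosity.SEGREGATING
    return Zygosity.REFERENCE if alleles == {0} else Zygosity.FIXED


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(ref: str, alt: str) -> bool:
    return {ref, alt} == _PURINES or {ref, alt} == _PYRIMIDINES


def count_titv(substitutions: Iterable[tuple[str, str]]) -> tuple[int, int]:
    """Count (transitions, transversions) over (ref, alt) single-base pairs."""
    ti = tv = 0
    for ref, alt in substitutions:
        if is_transition(ref, alt):
            ti += 1
        else:
            tv += 1
    return ti, tv


def titv_ratio(records: Iterable[VariantRecord]) -> float:
    """Transition/transversion ratio over SNP records.

    Multiallelic SNPs contribute one ref→alt substitution per alt. Zero
    transversions yields NaN with a warning (undefined ratio).
    """
    subs = (
        (rec.ref, alt)
        for rec in records
        if classify_variant_type(rec) is VariantType.SNP
        for alt in rec.alts
    )
    ti, tv = count_titv(subs)
    if tv == 0:
        logger.warning("Ti/Tv undefined: no transversions among %d transitions", ti)
        return float("nan")
    return ti / tv


def titv_from_alleles(refs: Sequence[str], alts: Sequence[str]) -> float:
    """Vectorised Ti/Tv for parallel single-base ref/alt arrays."""
    r = np.asarray(refs, dtype="U1")
    a = np.asarray(alts, dtype="U1")
    ti = (
        ((r == "A") & (a == "G"))
        | ((r == "G") & (a == "A"))
        | ((r == "C") & (a == "T"))
        | ((r == "T") & (a == "C"))
    ).sum()
    tv = len(r) - ti
    if tv == 0:
        logger.warning("Ti/Tv undefined: no transversions")
        return float("nan")
    return float(ti) / float(tv)


def filter_records(
    records: Iterable[VariantRecord], criteria: FilterCriteria = FilterCriteria()
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply hard filters then GQ masking to a record stream.

    Returns the passing (possibly pool-masked) records and a rejects table
    with columns chrom, pos, reasons (semicolon-joined).
    """
    passing: list[VariantRecord] = []
    rejects: list[tuple[str, int, str]] = []
    for rec in records:
        verdict = apply_hard_filters(rec, criteria)
        if not verdict.passed:
            rejects.append((rec.chrom, rec.pos, ";".join(verdict.reasons)))
            continue
        masked = mask_low_gq(rec, criteria)
        if masked is None:
            rejects.append((rec.chrom, rec.pos, "GQ"))
            continue
        passing.append(masked)
    reject_table = pd.DataFrame(rejects, columns=["chrom", "pos", "reasons"])
    return passing, reject_table
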