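"""Pooled-heterozygosity (Hp/ZHp) selective-sweep scan.

For each pool and SNP the read counts of the most and least abundant alleles
(n_MAJ, n_MIN) are taken from the per-allele depths. Over a sliding window,

    Hp = 2 * ΣnMAJ * ΣnMIN / (ΣnMAJ + ΣnMIN)^2

with the sums running over all SNPs in the window, so Hp lies in [0, 0.5]:
0 when the window is monomorphic in reads, 0.5 when major and minor reads
balance exactly. Window Hp values are Z-transformed genome-wide,
ZHp = (Hp - μHp)/σHp with the population standard deviation (divisor N), and
strongly negative ZHp marks windows of excess homozygosity — the signature of
a selective sweep. Windows at or below tier thresholds (-4 candidate,
-5 putative, -6 extreme) are merged into distinct loci per tier.

Windows are 150 kb with 50% overlap by default, full windows only: starts at
multiples of the 75 kb step while start + size ≤ chromosome length, so every
interior base is covered by exactly two windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import VariantType, classify_variant_type
from .genome_io import GenomeLayout, VariantRecord

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """All scored windows share one Hp value; the Z-transform is undefined."""


@dataclass(frozen=True)
class PoolAlleleCounts:
    """Read counts of the two most abundant alleles at one site in one pool."""

    chrom: str
    pos: int  # 1-based, as on the record
    pool: int
    n_maj: int
    n_min: int

    def __post_init__(self) -> None:
        if not (self.n_maj >= self.n_min >= 0):
            raise ValueError(f"require n_maj >= n_min >= 0, got ({self.n_maj}, {self.n_min})")


@dataclass(frozen=True)
class SweepThresholds:
    """ZHp tier thresholds; a window qualifies at a tier when zhp <= value."""

    candidate: float = -4.0
    putative: float = -5.0
    extreme: float = -6.0

    def __post_init__(self) -> None:
        if not (self.extreme <= self.putative <= self.candidate < 0):
            raise ValueError("require extreme <= putative <= candidate < 0")

    def tiers(self) -> dict[str, float]:
        return {"candidate": self.candidate, "putative": self.putative, "extreme": self.extreme}


@dataclass(frozen=True)
class SweepLocus:
    """A merged run of sweep windows; within a tier, loci never overlap."""

    chrom: str
    start: int
    end: int
    min_zhp: float
    n_windows: int
    tier: str


@dataclass
class HpScan:
    """Genome-wide window scan for one pool.

    ``windows`` columns: chrom, start, end, n_snps, sum_maj, sum_min, hp, zhp.
    Windows with fewer than ``min_snps`` SNPs are unscored (NaN hp/zhp) and
    excluded from μ/σ and sweep calling.
    """

    pool: str
    windows: pd.DataFrame
    mu_hp: float = float("nan")
    sigma_hp: float = float("nan")
    min_snps: int = 10
    size: int = 150_000
    step: int = 75_000

    @property
    def scored(self) -> pd.DataFrame:
        return self.windows[self.windows["hp"].notna()]


def pool_allele_counts(record: VariantRecord, pool: int) -> PoolAlleleCounts | None:
    """(n_MAJ, n_MIN) for one pool from its per-allele read depths.

    The two largest depths are used (for a biallelic site, max and min of the
    two); ties in "most abundant" are harmless because Hp is symmetric in the
    two counts. A pool with zero total depth has no read evidence and is
    skipped (None).
    """
    depths = sorted(record.pools[pool].allele_depths, reverse=True)
    if not depths or depths[0] == 0:
        return None
    n_maj = depths[0]
    n_min = depths[1] if len(depths) > 1 else 0
    return PoolAlleleCounts(record.chrom, record.pos, pool, n_maj, n_min)


def make_sliding_windows(
    layout: GenomeLayout, size: int = 150_000, overlap: float = 0.5
) -> pd.DataFrame:
    """Sliding windows (0-based half-open), full windows only.

    step = size * (1 - overlap); starts run 0, step, 2·step, ... while
    start + size <= chromosome length. Chromosomes shorter than one window
    contribute no windows (logged).
    """
    if not 0 < overlap < 1:
        raise ValueError(f"overlap must be in (0, 1), got {overlap}")
    step = int(round(size * (1 - overlap)))
    if step < 1:
        raise ValueError("window step must be >= 1")
    chroms, starts = [], []
    for name, length in layout.chromosomes:
        if length < size:
            logger.info("chromosome %s shorter than one %d bp window; no windows", name, size)
            continue
        s = np.arange(0, length - size + 1, step, dtype=np.int64)
        chroms.extend([name] * len(s))
        starts.append(s)
    start_arr = np.concatenate(starts) if starts else np.array([], dtype=np.int64)
    return pd.DataFrame({"chrom": chroms, "start": start_arr, "end": start_arr + size})


def pooled_heterozygosity(sum_maj, sum_min):
    """Hp = 2·ΣnMAJ·ΣnMIN / (ΣnMAJ + ΣnMIN)²; NaN where the window has no reads."""
    M = np.asarray(sum_maj, dtype=float)
    m = np.asarray(sum_min, dtype=float)
    tot = M + m
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(tot > 0, 2.0 * M * m / (tot * tot), np.nan)
    return hp if hp.ndim else float(hp)


def scan_counts(
    counts: pd.DataFrame,
    layout: GenomeLayout,
    pool: str = "pool",
    size: int = 150_000,
    overlap: float = 0.5,
    min_snps: int = 10,
) -> HpScan:
    """Window scan from a flat per-SNP count table.

    ``counts`` columns: chrom, pos (0-based), n_maj, n_min. Each SNP
    contributes to every window containing it (two, in the interior, at 50%
    overlap). The Z-transform is applied genome-wide over scored windows.
    """
    windows = make_sliding_windows(layout, size, overlap)
    step = int(round(size * (1 - overlap)))
    n_win = len(windows)
    sum_maj = np.zeros(n_win, dtype=np.int64)
    sum_min = np.zeros(n_win, dtype=np.int64)
    n_snps = np.zeros(n_win, dtype=np.int64)
    base = {}
    for name, sub in windows.groupby("chrom", sort=False):
        base[name] = (sub.index[0], len(sub))
    n_per_window = -(-size // step)  # max windows covering any base
    for name, sub in counts.groupby("chrom", sort=False):
        if name not in base:
            if name in layout:
                continue  # chromosome shorter than one window
            logger.warning("skipping %d SNP(s) on %s: not in genome layout", len(sub), name)
            continue
        first, n_chrom = base[name]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        maj = sub["n_maj"].to_numpy(dtype=np.int64)
        mn = sub["n_min"].to_numpy(dtype=np.int64)
        top = pos // step  # last window ordinal whose span could include pos
        for k in range(n_per_window):
            w = top - k
            ok = (w >= 0) & (w < n_chrom) & (pos < w * step + size)
            idx = first + w[ok]
            np.add.at(sum_maj, idx, maj[ok])
            np.add.at(sum_min, idx, mn[ok])
            np.add.at(n_snps, idx, 1)
    windows["n_snps"] = n_snps
    windows["sum_maj"] = sum_maj
    windows["sum_min"] = sum_min
    hp = pooled_heterozygosity(sum_maj, sum_min)
    hp[n_snps < min_snps] = np.nan
    windows["hp"] = hp
    scan = HpScan(pool=pool, windows=windows, min_snps=min_snps, size=size, step=step)
    return scan


def z_transform(scan: HpScan) -> HpScan:
    """Attach genome-wide ZHp = (Hp − μHp)/σHp over scored windows.

    μ and σ are computed over all scored windows genome-wide; σ is the
    population standard deviation (divisor N), so a two-window scan with
    distinct Hp gives ZHp = ∓1. Identical Hp everywhere raises
    :class:`ZeroVarianceError`.
    """
    hp = scan.windows["hp"].to_numpy(dtype=float)
    scored = ~np.isnan(hp)
    if scored.sum() < 2:
        raise ZeroVarianceError("need >= 2 scored windows to Z-transform")
    mu = float(np.mean(hp[scored]))
    sigma = float(np.std(hp[scored]))  # ddof=0: population SD
    if sigma == 0:
        raise ZeroVarianceError("zero variance in Hp across scored windows")
    zhp = (hp - mu) / sigma
    scan.windows["zhp"] = zhp
    scan.mu_hp = mu
    scan.sigma_hp = sigma
    return scan


def hp_scan(
    records: Iterable[VariantRecord],
    pool: int,
    layout: GenomeLayout,
    pool_name: str | None = None,
    size: int = 150_000,
    overlap: float = 0.5,
    min_snps: int = 10,
) -> HpScan:
    """Full scan from a record stream for one pool: SNPs only (indels and
    mixed sites are excluded), counts from read depths, Z-transform applied."""
    rows = []
    for rec in records:
        if classify_variant_type(rec) is not VariantType.SNP:
            continue
        pc = pool_allele_counts(rec, pool)
        if pc is None:
            continue
        rows.append((pc.chrom, pc.pos - 1, pc.n_maj, pc.n_min))
    counts = pd.DataFrame(rows, columns=["chrom", "pos", "n_maj", "n_min"])
    name = pool_name if pool_name is not None else f"pool{pool + 1}"
    return z_transform(
        scan_counts(counts, layout, pool=name, size=size, overlap=overlap, min_snps=min_snps)
    )


def _merge_windows(sub: pd.DataFrame, tier: str) -> list[SweepLocus]:
    loci = []
    cur_start = cur_end = None
    cur_min = np.inf
    cur_n = 0
    chrom = None
    for row in sub.itertuples(index=False):
        if cur_end is None or row.chrom != chrom or row.start > cur_end:
            if cur_end is not None:
                loci.append(SweepLocus(chrom, cur_start, cur_end, cur_min, cur_n, tier))
            chrom, cur_start, cur_end, cur_min, cur_n = (
                row.chrom,
                int(row.start),
                int(row.end),
                float(row.zhp),
                1,
            )
        else:
            cur_end = max(cur_end, int(row.end))
            cur_min = min(cur_min, float(row.zhp))
            cur_n += 1
    if cur_end is not None:
        loci.append(SweepLocus(chrom, cur_start, cur_end, cur_min, cur_n, tier))
    return loci


def call_sweeps(
    scan: HpScan,
    thresholds: SweepThresholds = SweepThresholds(),
    layout: GenomeLayout | None = None,
) -> list[SweepLocus]:
    """Tiered sweep loci: per tier, windows with zhp <= threshold are selected
    and overlapping or book-ended windows on one chromosome merge into a
    single locus (min zhp over its windows). Tiers are called independently,
    so an extreme locus also lies inside a putative and a candidate locus.
    """
    if "zhp" not in scan.windows.columns:
        raise ValueError("scan has no zhp; run z_transform first")
    loci: list[SweepLocus] = []
    df = scan.windows
    order = {c: i for i, c in enumerate(layout.names)} if layout is not None else None
    for tier, thr in thresholds.tiers().items():
        sel = df[df["zhp"].notna() & (df["zhp"] <= thr)]
        if order is not None:
            sel = sel.sort_values(
                by=["chrom", "start"], key=lambda s: s.map(order) if s.name == "chrom" else s
            )
        else:
            sel = sel.sort_values(by=["chrom", "start"], kind="mergesort")
        loci.extend(_merge_windows(sel, tier))
    return loci


def loci_table(loci: Sequence[SweepLocus], pool: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [(l.chrom, l.start, l.end, l.min_zhp, l.n_windows, l.tier) for l in loci],
        columns=["chrom", "start", "end", "min_zhp", "n_windows", "tier"],
    )
    if pool is not None:
        df.insert(0, "pool", pool)
    return df


def _overlaps(a: SweepLocus, b: SweepLocus) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def sweep_report(
    loci_by_pool: Mapping[str, Sequence[SweepLocus]]
) -> dict[str, pd.DataFrame]:
    """Per-pool tier counts, the full locus table, and cross-pool shared loci.

    Shared loci are pairwise overlaps of same-tier loci between pools,
    reported as the intersection interval.
    """
    tier_rows = []
    for pool, loci in loci_by_pool.items():
        counts = {"pool": pool, "candidate": 0, "putative": 0, "extreme": 0}
        for l in loci:
            counts[l.tier] += 1
        tier_rows.append(counts)
    locus_frames = [loci_table(loci, pool) for pool, loci in loci_by_pool.items() if loci]
    if locus_frames:
        loci_df = pd.concat(locus_frames, ignore_index=True)
    else:
        loci_df = loci_table([], pool="")
    shared_rows = []
    pools = list(loci_by_pool)
    for i, pa in enumerate(pools):
        for pb in pools[i + 1 :]:
            for a in loci_by_pool[pa]:
                for b in loci_by_pool[pb]:
                    if a.tier == b.tier and _overlaps(a, b):
                        shared_rows.append(
                            {
                                "pool_a": pa,
                                "pool_b": pb,
                                "tier": a.tier,
                                "chrom": a.chrom,
                                "start": max(a.start, b.start),
                                "end": min(a.end, b.end),
                            }
                        )
    shared = pd.DataFrame(
        shared_rows, columns=["pool_a", "pool_b", "tier", "chrom", "start", "end"]
    )
    return {
        "tier_counts": pd.DataFrame(tier_rows, columns=["pool", "candidate", "putative", "extreme"]),
        "loci": loci_df,
        "shared": shared,
    }
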