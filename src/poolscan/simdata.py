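"""Synthetic pool-seq data with the statistical structure the analyses assume.

The generator emulates a three-pool study design: pools of 30 diploids
(ploidy 60) sequenced to ~20× each, variants placed as a Poisson process
(~1 SNP / 250 bp), per-pool alternate-allele copy numbers drawn from a
neutral 1/f spectrum, read depths split binomially by allele frequency, and
GATK-style site metrics drawn from pass-region distributions. Sweeps are
planted by compressing the minor-allele frequency inside an interval (variant
density is left untouched, so the read-balance statistic — not SNP count — is
the detecting signal); density hotspots are planted by multiplying the local
variant rate. A catalogue standing in for a large known-variant resource
contains each simulated variant with probability ``known_fraction``.

Everything is drawn from a single numpy Generator stream seeded once, so a
fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    INFO_METRICS,
    GeneInterval,
    GenomeLayout,
    PoolData,
    VariantRecord,
    write_gene_bed,
    write_layout,
    write_tsv,
    write_vcf,
)
from .novelty import KnownCatalogue, write_catalogue_tsv

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ["C", "T"], "G": ["C", "T"], "C": ["A", "G"], "T": ["A", "G"]}

#: SO term frequencies loosely echoing a whole-genome cattle annotation
#: (intergenic-dominated; genic terms at realistic relative rates).
_TERM_PROBS: dict[str, float] = {
    "intergenic_variant": 0.6150,
    "intron_variant": 0.2706,
    "upstream_gene_variant": 0.0435,
    "downstream_gene_variant": 0.0437,
    "mature_miRNA_variant": 0.0033,
    "synonymous_variant": 0.0039,
    "missense_variant": 0.0031,
    "3_prime_UTR_variant": 0.0019,
    "5_prime_UTR_variant": 0.0004,
    "non_coding_transcript_variant": 0.0009,
    "splice_region_variant": 0.0008,
    "splice_donor_variant": 0.000025,
    "splice_acceptor_variant": 0.000025,
    "stop_lost": 0.00009,
    "stop_gained": 0.00001,
}
_TERMS = list(_TERM_PROBS)
_PROBS = np.array(list(_TERM_PROBS.values()))
_PROBS[0] += 1.0 - _PROBS.sum()  # absorb rounding into intergenic

_LOF_TERMS = {"stop_gained", "stop_lost"}


@dataclass(frozen=True)
class PlantedSweep:
    """Interval whose minor-allele frequency is multiplied by (1 − het_reduction).

    ``pools=None`` applies the sweep to every pool (a shared sweep); a tuple of
    pool indices restricts it.
    """

    chrom: str
    start: int
    end: int
    het_reduction: float
    pools: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.het_reduction <= 1.0:
            raise ValueError("het_reduction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedHotspot:
    """Interval whose variant rate is multiplied by ``multiplier`` (≥ 1)."""

    chrom: str
    start: int
    end: int
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 1.0:
            raise ValueError("hotspot multiplier must be >= 1")


def _coerce_sweep(s) -> PlantedSweep:
    return s if isinstance(s, PlantedSweep) else PlantedSweep(*s)


def _coerce_hotspot(h) -> PlantedHotspot:
    return h if isinstance(h, PlantedHotspot) else PlantedHotspot(*h)


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the emulated study conditions."""

    layout: GenomeLayout
    n_pools: int = 3
    pool_size: int = 30  # diploids per pool → ploidy 60
    mean_coverage: float = 20.0
    snp_rate: float = 1.0 / 250.0
    maf_spectrum: tuple[float, ...] | None = None  # P(k copies) over 1..ploidy-1
    planted_sweeps: tuple[PlantedSweep, ...] = ()
    planted_hotspots: tuple[PlantedHotspot, ...] = ()
    known_fraction: float = 0.93
    indel_fraction: float = 0.11
    filter_fail_fraction: float = 0.0
    titv: float = 2.2  # expected transition/transversion ratio of simulated SNPs
    pool_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "planted_sweeps", tuple(_coerce_sweep(s) for s in self.planted_sweeps)
        )
        object.__setattr__(
            self, "planted_hotspots", tuple(_coerce_hotspot(h) for h in self.planted_hotspots)
        )
        for frac, name in (
            (self.known_fraction, "known_fraction"),
            (self.indel_fraction, "indel_fraction"),
            (self.filter_fail_fraction, "filter_fail_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for iv in (*self.planted_sweeps, *self.planted_hotspots):
            if iv.chrom not in self.layout:
                raise ValueError(f"planted interval on unknown chromosome {iv.chrom!r}")
            if not 0 <= iv.start < iv.end <= self.layout.length(iv.chrom):
                raise ValueError(
                    f"planted interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome"
                )

    @property
    def ploidy(self) -> int:
        return 2 * self.pool_size

    def pool_labels(self) -> tuple[str, ...]:
        if self.pool_names is not None:
            if len(self.pool_names) != self.n_pools:
                raise ValueError("pool_names length must equal n_pools")
            return self.pool_names
        return tuple(f"pool{i + 1}" for i in range(self.n_pools))

    def spectrum(self) -> np.ndarray:
        if self.maf_spectrum is not None:
            p = np.asarray(self.maf_spectrum, dtype=float)
            if len(p) != self.ploidy - 1 or (p < 0).any() or p.sum() <= 0:
                raise ValueError("maf_spectrum must be non-negative over 1..ploidy-1")
        else:
            p = 1.0 / np.arange(1, self.ploidy)
        return p / p.sum()


@dataclass
class TruthSet:
    """Ground truth: one row per emitted variant plus the planted intervals."""

    variants: pd.DataFrame  # chrom, pos (1-based), ref, alt, is_snp, category, novel, freq_*
    sweeps: tuple[PlantedSweep, ...]
    hotspots: tuple[PlantedHotspot, ...]


@dataclass
class SimResult:
    """In-memory simulation output; use :meth:`write` for the file forms.

    ``variants`` holds one row per site with 0-based ``pos0`` (1-based
    coordinates appear only in files and record objects). Per-pool arrays are
    shaped (n_pools, n_variants).
    """

    params: SimParams
    variants: pd.DataFrame
    alt_count: np.ndarray
    depth: np.ndarray
    alt_reads: np.ndarray
    gq: np.ndarray
    genes: list[GeneInterval]
    consequences: pd.DataFrame
    catalogue: KnownCatalogue
    truth: TruthSet

    def __len__(self) -> int:
        return len(self.variants)

    def records(self) -> Iterator[VariantRecord]:
        """Materialise VariantRecord objects (1-based positions)."""
        ploidy = self.params.ploidy
        v = self.variants
        cols = {k: v[k].to_numpy() for k in ("chrom", "pos0", "ref", "alt", "qual", *INFO_METRICS)}
        for i in range(len(v)):
            pools = []
            for p in range(self.params.n_pools):
                k = int(self.alt_count[p, i])
                d = int(self.depth[p, i])
                a = int(self.alt_reads[p, i])
                genotype = (0,) * (ploidy - k) + (1,) * k
                pools.append(PoolData((d - a, a), genotype, int(self.gq[p, i])))
            info = {
                key: float(cols[key][i]) for key in INFO_METRICS if not np.isnan(cols[key][i])
            }
            yield VariantRecord(
                chrom=str(cols["chrom"][i]),
                pos=int(cols["pos0"][i]) + 1,
                ref=str(cols["ref"][i]),
                alts=(str(cols["alt"][i]),),
                qual=float(cols["qual"][i]),
                info=info,
                pools=tuple(pools),
            )

    def pool_counts(self, pool: int, snps_only: bool = True) -> pd.DataFrame:
        """Flat (chrom, pos [0-based], n_maj, n_min) table for the sweep scan."""
        mask = self.variants["is_snp"].to_numpy() if snps_only else np.ones(len(self), bool)
        d = self.depth[pool]
        a = self.alt_reads[pool]
        r = d - a
        covered = mask & (d > 0)
        return pd.DataFrame(
            {
                "chrom": self.variants["chrom"].to_numpy()[covered],
                "pos": self.variants["pos0"].to_numpy()[covered],
                "n_maj": np.maximum(r, a)[covered],
                "n_min": np.minimum(r, a)[covered],
            }
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write VCF, layout, catalogue, consequence table, genes and truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "pools.vcf",
            "layout": outdir / "genome.fai",
            "catalogue": outdir / "known_catalogue.tsv",
            "consequences": outdir / "consequences.tsv",
            "genes": outdir / "genes.bed",
            "truth": outdir / "truth.tsv",
        }
        write_vcf(
            self.records(), paths["vcf"], layout=self.params.layout,
            pool_names=self.params.pool_labels(),
        )
        write_layout(self.params.layout, paths["layout"])
        write_catalogue_tsv(self.catalogue.keys, paths["catalogue"])
        write_tsv(self.consequences, paths["consequences"])
        write_gene_bed(self.genes, paths["genes"])
        write_tsv(self.truth.variants, paths["truth"])
        return paths


def _simulate_positions(params: SimParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson variant positions with hotspot rate multipliers; returns
    (chrom_index, pos0) sorted by layout order then position."""
    chrom_idx_parts, pos_parts = [], []
    for ci, (name, length) in enumerate(params.layout.chromosomes):
        cuts = {0, length}
        spots = [h for h in params.planted_hotspots if h.chrom == name]
        for h in spots:
            cuts.update((h.start, h.end))
        bounds = sorted(cuts)
        positions = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mult = 1.0
            for h in spots:
                if h.start <= lo and hi <= h.end:
                    mult = max(mult, h.multiplier)
            n = rng.poisson(params.snp_rate * mult * (hi - lo))
            if n:
                positions.append(lo + rng.integers(0, hi - lo, size=n))
        if positions:
            pos = np.unique(np.concatenate(positions))
            pos_parts.append(pos)
            chrom_idx_parts.append(np.full(len(pos), ci, dtype=np.int32))
    if not pos_parts:
        return np.array([], np.int32), np.array([], np.int64)
    return np.concatenate(chrom_idx_parts), np.concatenate(pos_parts).astype(np.int64)


def _simulate_alleles(
    n: int, params: SimParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ref, alt, is_snp): transitions at odds titv:1, indels of 1–3 bp."""
    is_snp = rng.random(n) >= params.indel_fraction
    ref_idx = rng.integers(0, 4, size=n)
    ref = _BASES[ref_idx].astype(object)
    p_ti = params.titv / (1.0 + params.titv)
    ti = rng.random(n) < p_ti
    which_tv = rng.integers(0, 2, size=n)
    # ACGT indices: transition partner, and the two transversion partners
    ti_map = np.array([2, 3, 0, 1])
    tv_map = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])
    alt_idx = np.where(ti, ti_map[ref_idx], tv_map[ref_idx, which_tv])
    alt = _BASES[alt_idx].astype(object)
    ins = rng.random(n) < 0.5
    indel_len = rng.integers(1, 4, size=n)
    extra = _BASES[rng.integers(0, 4, size=(n, 3))]
    for i in np.flatnonzero(~is_snp):
        b = ref[i]
        tail = "".join(extra[i, : indel_len[i]])
        if ins[i]:
            alt[i] = b + tail
        else:
            ref[i] = b + tail
            alt[i] = b
    return ref, alt, is_snp


def _simulate_genes(layout: GenomeLayout) -> list[GeneInterval]:
    """Deterministic gene model: a 30 kb gene every 120 kb, alternating strand."""
    period, glen = 120_000, 30_000
    genes = []
    for name, length in layout.chromosomes:
        n = max(1, length // period)
        for i in range(n):
            start = i * period
            end = min(start + glen, length)
            if end - start < 1000:
                continue
            genes.append(
                GeneInterval(name, start, end, f"G{name}_{i}", "+" if i % 2 == 0 else "-")
            )
    return genes


def _fail_value(reason: str, rng: np.random.Generator) -> tuple[str, float]:
    """(field, value) violating one criterion (strict GATK inequalities)."""
    draws = {
        "QUAL": lambda: rng.uniform(0.0, 29.9),
        "QD": lambda: rng.uniform(0.0, 1.9),
        "MQ": lambda: rng.uniform(10.0, 39.9),
        "FS": lambda: rng.uniform(60.1, 200.0),
        "HaplotypeScore": lambda: rng.uniform(13.1, 40.0),
        "MQRankSum": lambda: rng.uniform(-20.0, -12.6),
        "ReadPosRankSum": lambda: rng.uniform(-15.0, -8.1),
    }
    return reason, float(draws[reason]())


_FAIL_FIELDS = ("QUAL", "QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")


def simulate(params: SimParams) -> SimResult:
    """Run the generator; deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    chrom_idx, pos0 = _simulate_positions(params, rng)
    n = len(pos0)
    names = np.array(params.layout.names)
    chrom = names[chrom_idx]
    ref, alt, is_snp = _simulate_alleles(n, params, rng)

    ploidy = params.ploidy
    spectrum = params.spectrum()
    alt_count = rng.choice(np.arange(1, ploidy), size=(params.n_pools, n), p=spectrum).astype(
        np.int16
    )

    # sweep compression: minor-allele frequency × (1 − het_reduction)
    for sw in params.planted_sweeps:
        in_sweep = (chrom == sw.chrom) & (pos0 >= sw.start) & (pos0 < sw.end)
        if not in_sweep.any():
            continue
        pools = range(params.n_pools) if sw.pools is None else sw.pools
        for p in pools:
            k = alt_count[p, in_sweep].astype(np.int64)
            m = np.minimum(k, ploidy - k)
            m2 = np.rint(m * (1.0 - sw.het_reduction)).astype(np.int64)
            k2 = np.where(k <= ploidy // 2, m2, ploidy - m2)
            alt_count[p, in_sweep] = k2.astype(np.int16)

    depth = rng.poisson(params.mean_coverage, size=(params.n_pools, n)).astype(np.int32)
    alt_reads = rng.binomial(depth, alt_count / float(ploidy)).astype(np.int32)
    gq = np.clip(rng.normal(70.0, 15.0, size=(params.n_pools, n)), 0, 99).astype(np.int16)

    info = pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": pos0,
            "ref": ref,
            "alt": alt,
            "is_snp": is_snp,
            "qual": 30.0 + rng.gamma(2.0, 150.0, size=n),
            "QD": rng.uniform(5.0, 35.0, size=n),
            "MQ": rng.uniform(45.0, 65.0, size=n),
            "FS": np.minimum(rng.exponential(3.0, size=n), 59.9),
            "HaplotypeScore": np.minimum(rng.exponential(2.0, size=n), 12.9),
            "MQRankSum": np.clip(rng.normal(0.0, 2.0, size=n), -12.4, None),
            "ReadPosRankSum": np.clip(rng.normal(0.0, 2.0, size=n), -7.9, None),
        }
    )

    fail_ids = np.array([], dtype=np.int64)
    if params.filter_fail_fraction > 0 and n > 0:
        n_fail = int(round(params.filter_fail_fraction * n))
        fail_ids = rng.choice(n, size=n_fail, replace=False)
        fields = rng.integers(0, len(_FAIL_FIELDS), size=n_fail)
        for idx, fi in zip(fail_ids, fields):
            name, value = _fail_value(_FAIL_FIELDS[fi], rng)
            info.loc[idx, "qual" if name == "QUAL" else name] = value
    info["filter_fail"] = False
    if len(fail_ids):
        info.loc[fail_ids, "filter_fail"] = True

    known = rng.random(n) < params.known_fraction
    info["known"] = known
    # simulated alleles are emitted parsimony-minimal (SNPs, and indels that
    # share only their anchor base), so the catalogue keys need no trimming
    cat_keys = frozenset(
        (str(c), int(p) + 1, r, a)
        for c, p, r, a in zip(chrom[known], pos0[known], ref[known], alt[known])
    )
    catalogue = KnownCatalogue(cat_keys, frozenset((c, p) for c, p, _, _ in cat_keys))

    genes = _simulate_genes(params.layout)
    term_idx = rng.choice(len(_TERMS), size=n, p=_PROBS)
    terms = np.array(_TERMS, dtype=object)[term_idx]
    keys = np.array(
        [f"{c}:{p + 1}:{r}:{a}" for c, p, r, a in zip(chrom, pos0, ref, alt)], dtype=object
    )
    gene_period, gene_len = 120_000, 30_000
    gidx = pos0 // gene_period
    gene_names = np.array(
        [f"G{c}_{i}" for c, i in zip(chrom, gidx)], dtype=object
    )
    cons = pd.DataFrame(
        {
            "variant_key": keys,
            "consequence": terms,
            "gene": np.where(
                np.char.equal(terms.astype(str), "intergenic_variant"), "-", gene_names
            ),
            "transcript": np.where(
                np.char.equal(terms.astype(str), "intergenic_variant"), "-",
                gene_names + np.array([".t1"], dtype=object),
            ),
        }
    )
    # a slice of genic variants gets a second, milder annotation (multi-transcript)
    genic = np.flatnonzero(terms != "intergenic_variant")
    if len(genic):
        second = rng.choice(genic, size=max(1, len(genic) // 20), replace=False)
        extra = cons.iloc[second].copy()
        extra["consequence"] = "intron_variant"
        extra["transcript"] = extra["gene"] + ".t2"
        cons = pd.concat([cons, extra], ignore_index=True)
        cons = cons.drop_duplicates(["variant_key", "transcript", "consequence"]).reset_index(
            drop=True
        )

    category = np.where(
        np.isin(terms.astype(str), sorted(_LOF_TERMS)),
        "lof",
        np.where(terms.astype(str) == "missense_variant", "missense", "other"),
    )
    truth_df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos0 + 1,
            "ref": ref,
            "alt": alt,
            "is_snp": is_snp,
            "category": category,
            "novel": ~known,
        }
    )
    for p, label in enumerate(params.pool_labels()):
        truth_df[f"freq_{label}"] = alt_count[p] / float(ploidy)
    truth = TruthSet(truth_df, params.planted_sweeps, params.planted_hotspots)

    return SimResult(
        params=params,
        variants=info,
        alt_count=alt_count,
        depth=depth,
        alt_reads=alt_reads,
        gq=gq,
        genes=genes,
        consequences=cons,
        catalogue=catalogue,
        truth=truth,
    )


def inject_filter_failures(
    records: Sequence[VariantRecord], fraction: float, seed: int
) -> tuple[list[VariantRecord], list[int]]:
    """Give exactly ``round(fraction·N)`` records at least one failing metric.

    Returns the modified record list and the (sorted) indices of modified
    records. Each chosen record gets one randomly selected criterion pushed
    past its threshold; already-failing records count toward the quota only if
    chosen.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_fail = int(round(fraction * n))
    out = list(records)
    if n_fail == 0:
        return out, []
    chosen = sorted(rng.choice(n, size=n_fail, replace=False).tolist())
    for idx in chosen:
        rec = out[idx]
        name, value = _fail_value(_FAIL_FIELDS[rng.integers(0, len(_FAIL_FIELDS))], rng)
        if name == "QUAL":
            out[idx] = dc_replace(rec, qual=value)
        else:
            new_info = dict(rec.info)
            new_info[name] = value
            out[idx] = dc_replace(rec, info=new_info)
    return out, chosen
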