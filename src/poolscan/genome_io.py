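"""Genome coordinate model and readers/writers for the formats the pipeline touches.

Internally every interval is 0-based half-open; VCF's 1-based convention is
converted at read/write time and nowhere else. Only the fields the downstream
analyses use are modelled (positions, alleles, QUAL, the six GATK site metrics,
per-pool AD/GT/GQ) — this is deliberately not a general VCF library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: INFO keys carried through parsing and filtering, in GATK's spelling.
INFO_METRICS = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")


class GenomeIOError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths; the order is the reporting order."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise GenomeIOError(f"duplicate chromosome name(s): {', '.join(dup)}")
        for name, length in self.chromosomes:
            if not isinstance(length, int) or length < 1:
                raise GenomeIOError(f"chromosome {name!r} has non-positive length {length!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    def __contains__(self, chrom: object) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class PoolData:
    """Per-pool payload of one variant site.

    ``genotype`` is the allele-index multiset at pool ploidy (e.g. 60 entries
    for a pool of 30 diploids), or ``None`` when masked/missing.
    """

    allele_depths: tuple[int, ...]
    genotype: tuple[int, ...] | None = None
    gq: int | None = None


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site restricted to the fields the pipeline consumes.

    ``pos`` is 1-based (VCF convention); use :attr:`start` for the internal
    0-based coordinate. Missing INFO metrics are simply absent from ``info``,
    never imputed as 0 — GATK omits e.g. rank-sum annotations at sites without
    heterozygous calls, and the hard filters must not fail those sites.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    info: Mapping[str, float] = field(default_factory=dict)
    pools: tuple[PoolData, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenomeIOError(f"{self.chrom}: position {self.pos} < 1")
        if not self.ref:
            raise GenomeIOError(f"{self.chrom}:{self.pos}: empty REF allele")
        n_alleles = 1 + len(self.alts)
        for i, p in enumerate(self.pools):
            if len(p.allele_depths) != n_alleles:
                raise GenomeIOError(
                    f"{self.chrom}:{self.pos}: pool {i} has {len(p.allele_depths)} "
                    f"allele depths for {n_alleles} alleles"
                )
            if any(d < 0 for d in p.allele_depths):
                raise GenomeIOError(f"{self.chrom}:{self.pos}: negative allele depth")

    @property
    def start(self) -> int:
        """0-based start coordinate."""
        return self.pos - 1


@dataclass(frozen=True)
class GeneInterval:
    """A gene span in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene_name: str
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"gene {self.gene_name}: invalid interval [{self.start}, {self.end})"
            )


# ---------------------------------------------------------------------------
# layout (.fai dialect)
# ---------------------------------------------------------------------------


def read_layout(path: str | Path) -> GenomeLayout:
    """Read a FASTA-index dialect file: ``name<TAB>length``, extra columns ignored."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GenomeIOError(f"{path}, line {lineno}: expected name<TAB>length")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise GenomeIOError(
                    f"{path}, line {lineno}: non-integer length {parts[1]!r}"
                ) from None
            if name in seen:
                raise GenomeIOError(f"{path}, line {lineno}: duplicate chromosome {name!r}")
            if length < 1:
                raise GenomeIOError(f"{path}, line {lineno}: non-positive length {length}")
            seen.add(name)
            chroms.append((name, length))
    if not chroms:
        raise GenomeIOError(f"{path}: empty layout file")
    return GenomeLayout(tuple(chroms))


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, layout: GenomeLayout | None = None) -> Iterator[VariantRecord]:
    """Yield :class:`VariantRecord` from a VCF 4.x file in file order.

    Contigs absent from ``layout`` (when given) are skipped with one warning
    each — unplaced scaffolds are outside the autosome-scan scope.
    Parse failures are re-raised naming the failing record index.
    """
    warned: set[str] = set()
    vf = pysam.VariantFile(str(path))
    i = 0
    try:
        while True:
            try:
                rec = next(vf)
            except StopIteration:
                break
            except Exception as exc:  # htslib parse error
                raise GenomeIOError(f"{path}: malformed VCF near data line {i + 1}: {exc}") from exc
            i += 1
            if layout is not None and rec.chrom not in layout:
                if rec.chrom not in warned:
                    logger.warning("skipping contig %s: not in genome layout", rec.chrom)
                    warned.add(rec.chrom)
                continue
            yield _from_pysam(rec, path, i)
    finally:
        vf.close()


def _from_pysam(rec: "pysam.VariantRecord", path: str | Path, i: int) -> VariantRecord:
    alts = tuple(rec.alts or ())
    info: dict[str, float] = {}
    for key in INFO_METRICS:
        if key in rec.info:
            val = rec.info[key]
            if isinstance(val, tuple):
                val = val[0]
            if val is not None:
                info[key] = float(val)
    pools = []
    n_alleles = 1 + len(alts)
    for sample in rec.samples.values():
        ad = sample.get("AD")
        if ad is None or all(v is None for v in ad):
            depths = (0,) * n_alleles
        else:
            depths = tuple(int(v) if v is not None else 0 for v in ad)
        gt = sample.get("GT")
        genotype = None
        if gt is not None and not all(a is None for a in gt):
            genotype = tuple(int(a) for a in gt if a is not None)
        gq = sample.get("GQ")
        pools.append(PoolData(depths, genotype, int(gq) if gq is not None else None))
    try:
        return VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=alts,
            qual=float(rec.qual) if rec.qual is not None else None,
            info=info,
            pools=tuple(pools),
        )
    except GenomeIOError as exc:
        raise GenomeIOError(f"{path}: data line {i}: {exc}") from exc


_VCF_HEADER_METRICS = "\n".join(
    f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">' for k in INFO_METRICS
)


def _fmt_float(x: float) -> str:
    s = f"{x:.6g}"
    return s


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    layout: GenomeLayout | None = None,
    pool_names: Sequence[str] | None = None,
) -> None:
    """Write records as VCF 4.2 with GT/AD/GQ FORMAT fields.

    Positions are written 1-based as stored on the records. When ``layout`` is
    given its contigs are declared in the header (required for pysam reads).
    """
    records = iter(records)
    first = next(records, None)
    if pool_names is None:
        n = len(first.pools) if first is not None else 0
        pool_names = [f"pool{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolscan\n")
        if layout is not None:
            for name, length in layout.chromosomes:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(_VCF_HEADER_METRICS + "\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pool_names)
            + "\n"
        )
        for rec in ([] if first is None else [first]):
            fh.write(_vcf_line(rec))
        for rec in records:
            fh.write(_vcf_line(rec))


def _vcf_line(rec: VariantRecord) -> str:
    alt = ",".join(rec.alts) if rec.alts else "."
    qual = _fmt_float(rec.qual) if rec.qual is not None else "."
    info = (
        ";".join(f"{k}={_fmt_float(rec.info[k])}" for k in INFO_METRICS if k in rec.info) or "."
    )
    cells = []
    for p in rec.pools:
        gt = "/".join(map(str, p.genotype)) if p.genotype is not None else "."
        ad = ",".join(map(str, p.allele_depths))
        gq = str(p.gq) if p.gq is not None else "."
        cells.append(f"{gt}:{ad}:{gq}")
    fmt = "GT:AD:GQ"
    return (
        f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{alt}\t{qual}\t.\t{info}\t{fmt}\t"
        + "\t".join(cells)
        + "\n"
    )


# ---------------------------------------------------------------------------
# BED / gene intervals / TSV
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[tuple],
    path: str | Path,
    layout: GenomeLayout | None = None,
) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED3+ (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if layout is not None and chrom in layout and end > layout.length(chrom):
                raise GenomeIOError(
                    f"interval {chrom}:{start}-{end} exceeds chromosome length "
                    f"{layout.length(chrom)}"
                )
            rest = "\t".join(str(x) for x in iv[3:])
            fh.write(f"{chrom}\t{start}\t{end}" + (f"\t{rest}" if rest else "") + "\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_intervals(path: str | Path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene spans from BED (0-based) or GFF3 (1-based inclusive, converted)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    if fmt == "bed":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise GenomeIOError(f"{path}, line {lineno}: expected ≥3 BED columns")
                name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(GeneInterval(parts[0], int(parts[1]), int(parts[2]), name, strand))
        return genes
    if fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
        genes = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
            genes.append(
                GeneInterval(feat.seqid, feat.start - 1, feat.end, name, feat.strand or ".")
            )
        return genes
    raise ValueError(f"unknown gene interval format {fmt!r}")


def write_gene_bed(genes: Iterable[GeneInterval], path: str | Path) -> None:
    write_bed(((g.chrom, g.start, g.end, g.gene_name, 0, g.strand) for g in genes), path)


def mask_pool(record: VariantRecord, pool_index: int) -> VariantRecord:
    """Return a copy of ``record`` with one pool's genotype/GQ set to missing."""
    pools = list(record.pools)
    p = pools[pool_index]
    pools[pool_index] = PoolData(p.allele_depths, None, None)
    return replace(record, pools=tuple(pools))
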