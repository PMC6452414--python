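"""End-to-end orchestration: simulate → filter → novelty → consequences →
density → sweeps → report, as one reproducible, seeded run.

Each stage writes its outputs before the next starts, so a run directory is
self-documenting; the report aggregates per-pool variant totals and SNP/indel
proportions, Ti/Tv, novelty, functional-class tables, top-density windows and
sweep tier counts. Headline percentages are unweighted means of per-pool
proportions (multi-pool totals are unions, which per-pool counts cannot
reconstruct).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consequences as cq
from . import density as dn
from . import novelty as nv
from . import sweeps as sw
from .filtering import (
    FilterCriteria,
    VariantType,
    classify_variant_type,
    filter_records,
    titv_ratio,
)
from .genome_io import GenomeLayout, read_gene_intervals, read_layout, read_vcf, write_bed, write_tsv
from .novelty import KnownCatalogue, round_half_up
from .simdata import PlantedHotspot, PlantedSweep, SimParams, simulate
from .sweeps import SweepThresholds

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _plain(x):
    """Recursively convert tuples and numpy scalars for YAML serialisation."""
    if isinstance(x, dict):
        return {k: _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, np.generic):
        return x.item()
    return x


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through YAML."""

    outdir: str
    seed: int = 0
    sim: SimParams | None = None  # when None, the four input paths must be set
    vcf: str | None = None
    layout: str | None = None
    catalogue: str | None = None
    consequence_table: str | None = None
    genes: str | None = None
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    thresholds: SweepThresholds = field(default_factory=SweepThresholds)
    density_window: int = 1_000_000
    sweep_window: int = 150_000
    sweep_overlap: float = 0.5
    min_snps: int = 10
    match_mode: str = "allele"
    severity_mode: str = "most_severe"
    top_fraction: float = 0.01
    density_denominator: str = "all"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            simd = d["sim"]
            simd["layout"] = [list(c) for c in self.sim.layout.chromosomes]
            simd["planted_sweeps"] = [list(dataclasses.astuple(s)) for s in self.sim.planted_sweeps]
            simd["planted_hotspots"] = [
                list(dataclasses.astuple(h)) for h in self.sim.planted_hotspots
            ]
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(d), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("sim") is not None:
            simd = d["sim"]
            simd["layout"] = GenomeLayout(tuple((c, int(l)) for c, l in simd["layout"]))
            simd["planted_sweeps"] = tuple(
                PlantedSweep(*(s[:4] + [tuple(s[4]) if s[4] is not None else None]))
                if len(s) > 4
                else PlantedSweep(*s)
                for s in simd.get("planted_sweeps", [])
            )
            simd["planted_hotspots"] = tuple(
                PlantedHotspot(*h) for h in simd.get("planted_hotspots", [])
            )
            if simd.get("maf_spectrum") is not None:
                simd["maf_spectrum"] = tuple(simd["maf_spectrum"])
            if simd.get("pool_names") is not None:
                simd["pool_names"] = tuple(simd["pool_names"])
            d["sim"] = SimParams(**simd)
        if d.get("criteria") is not None:
            d["criteria"] = FilterCriteria(**d["criteria"])
        if d.get("thresholds") is not None:
            d["thresholds"] = SweepThresholds(**d["thresholds"])
        return cls(**d)


@dataclass
class RunReport:
    """Aggregated outputs of one pipeline run."""

    pools: tuple[str, ...]
    variant_summary: pd.DataFrame
    titv: dict[str, float]
    novelty: pd.DataFrame | None
    novelty_skipped: bool
    class_table_snps: pd.DataFrame
    class_table_indels: pd.DataFrame
    density_top: pd.DataFrame
    sweep_tiers: pd.DataFrame
    sweep_loci: pd.DataFrame
    log: list[str]

    def summary_dict(self) -> dict:
        d: dict = {"pools": list(self.pools), "titv": {k: v for k, v in self.titv.items()}}
        d["variant_summary"] = self.variant_summary.to_dict(orient="records")
        d["novelty"] = (
            None if self.novelty is None else self.novelty.to_dict(orient="records")
        )
        d["novelty_skipped"] = self.novelty_skipped
        d["sweep_tiers"] = self.sweep_tiers.to_dict(orient="records")
        d["n_density_top_windows"] = int(len(self.density_top))
        d["log"] = self.log
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_variant_counts(
    counts: Mapping[str, tuple[int, int, int]]
) -> pd.DataFrame:
    """Per-pool (variants, SNPs, indels) with proportions and an Average row.

    Proportions are rounded half-up to 2 decimals; the Average row carries the
    unweighted mean of per-pool proportions and the summed counts.
    """
    rows = []
    props_snp, props_indel = [], []
    for pool, (n_var, n_snp, n_indel) in counts.items():
        p_snp = n_snp / n_var if n_var else float("nan")
        p_ind = n_indel / n_var if n_var else float("nan")
        if n_var:
            props_snp.append(p_snp)
            props_indel.append(p_ind)
        rows.append(
            {
                "pool": pool,
                "n_variants": n_var,
                "n_snps": n_snp,
                "proportion_snps": round_half_up(p_snp) if n_var else float("nan"),
                "n_indels": n_indel,
                "proportion_indels": round_half_up(p_ind) if n_var else float("nan"),
            }
        )
    rows.append(
        {
            "pool": "Average",
            "n_variants": sum(r["n_variants"] for r in rows),
            "n_snps": sum(r["n_snps"] for r in rows),
            "proportion_snps": round_half_up(float(np.mean(props_snp))) if props_snp else float("nan"),
            "n_indels": sum(r["n_indels"] for r in rows),
            "proportion_indels": round_half_up(float(np.mean(props_indel)))
            if props_indel
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def summarize_variants(records: Sequence, pool_names: Sequence[str]) -> pd.DataFrame:
    """Table-2-style block from records: a pool carries a variant when its
    genotype holds at least one non-reference allele."""
    counts = {}
    for p, name in enumerate(pool_names):
        n_var = n_snp = n_indel = 0
        for rec in records:
            pool = rec.pools[p]
            if pool.genotype is None or not any(a != 0 for a in pool.genotype):
                continue
            n_var += 1
            vt = classify_variant_type(rec)
            if vt is VariantType.SNP:
                n_snp += 1
            elif vt is VariantType.INDEL:
                n_indel += 1
        counts[name] = (n_var, n_snp, n_indel)
    return summarize_variant_counts(counts)


def _carried(rec, p: int) -> bool:
    pool = rec.pools[p]
    return pool.genotype is not None and any(a != 0 for a in pool.genotype)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order; identical config + seed ⇒ identical report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage_log(stage: str, **kv) -> None:
        line = f"stage={stage} " + " ".join(f"{k}={v}" for k, v in kv.items())
        log.append(line)
        logger.info(line)

    # ---- inputs -----------------------------------------------------------
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            result = simulate(sim)
            paths = result.write(outdir / "inputs")
            vcf_path, layout_path = paths["vcf"], paths["layout"]
            catalogue_path, cons_path = paths["catalogue"], paths["consequences"]
            genes_path = paths["genes"]
            stage_log("simulate", n_variants=len(result), seed=config.seed)
        else:
            if config.vcf is None or config.layout is None:
                raise ValueError("need either sim params or vcf+layout paths")
            vcf_path, layout_path = Path(config.vcf), Path(config.layout)
            catalogue_path = Path(config.catalogue) if config.catalogue else None
            cons_path = Path(config.consequence_table) if config.consequence_table else None
            genes_path = Path(config.genes) if config.genes else None
            stage_log("inputs", vcf=vcf_path)
    except Exception as exc:
        raise StageError(f"stage 'inputs' failed: {exc}") from exc

    layout = read_layout(layout_path)

    # ---- filtering --------------------------------------------------------
    try:
        records_in = list(read_vcf(vcf_path, layout))
        passing, rejects = filter_records(records_in, config.criteria)
        from .genome_io import write_vcf

        pool_names = _pool_names_from_vcf(vcf_path)
        write_vcf(passing, outdir / "pass.vcf", layout=layout, pool_names=pool_names)
        write_tsv(rejects, outdir / "rejects.tsv")
        stage_log("filter", n_in=len(records_in), n_pass=len(passing), n_reject=len(rejects))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage 'filter' failed: {exc}") from exc

    pools = tuple(pool_names)
    snp_records = [r for r in passing if classify_variant_type(r) is VariantType.SNP]

    # ---- summary + Ti/Tv --------------------------------------------------
    try:
        variant_summary = summarize_variants(passing, pools)
        write_tsv(variant_summary, outdir / "variant_summary.tsv")
        titv = {
            name: titv_ratio(r for r in snp_records if _carried(r, p))
            for p, name in enumerate(pools)
        }
        titv["all"] = titv_ratio(snp_records)
        stage_log("summary", n_snps=len(snp_records), **{f"titv_{k}": f"{v:.3f}" for k, v in titv.items()})
    except Exception as exc:
        raise StageError(f"stage 'summary' failed: {exc}") from exc

    # ---- novelty ----------------------------------------------------------
    novelty_df = None
    novel_flags: dict[str, dict[str, bool]] = {}
    novelty_skipped = catalogue_path is None
    if not novelty_skipped:
        try:
            catalogue = KnownCatalogue.from_tsv(catalogue_path)
            keys = [(r.chrom, r.pos, r.ref, r.alts[0]) for r in snp_records]
            known = nv.match_known(keys, catalogue, mode=config.match_mode)
            flags_by_pool = {}
            for p, name in enumerate(pools):
                flags, per_variant = [], {}
                for rec, key, kn in zip(snp_records, keys, known):
                    if _carried(rec, p):
                        flags.append(kn)
                        per_variant[_key_str(key)] = not kn
                flags_by_pool[name] = flags
                novel_flags[name] = per_variant
            novelty_df = nv.novelty_summary(flags_by_pool=flags_by_pool)
            write_tsv(novelty_df, outdir / "novelty.tsv")
            stage_log("novelty", catalogue_size=len(catalogue), pools=len(flags_by_pool))
        except Exception as exc:
            raise StageError(f"stage 'novelty' failed: {exc}") from exc
    else:
        stage_log("novelty", skipped=True)

    # ---- consequences -----------------------------------------------------
    try:
        if cons_path is not None:
            cons_rows = pd.read_csv(cons_path, sep="\t")
            reduced = cq.reduce_per_variant(cons_rows, mode=config.severity_mode)
            class_of = dict(zip(reduced["variant_key"], reduced["functional_class"]))
        else:
            class_of = {}
        by_pool_snv = {name: [] for name in pools}
        by_pool_indel = {name: [] for name in pools}
        for rec in passing:
            vt = classify_variant_type(rec)
            if vt is VariantType.MIXED:
                continue
            key = _key_str((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            cls = class_of.get(key, "Intergenic")
            target = by_pool_snv if vt is VariantType.SNP else by_pool_indel
            for p, name in enumerate(pools):
                if _carried(rec, p):
                    target[name].append(cls)
        class_table_snps = cq.tabulate(by_pool_snv, pools=pools)
        class_table_indels = cq.tabulate(by_pool_indel, pools=pools)
        write_tsv(class_table_snps, outdir / "class_table_snps.tsv")
        write_tsv(class_table_indels, outdir / "class_table_indels.tsv")
        stage_log(
            "consequences",
            n_classified=len(class_of),
            snp_rows=len(class_table_snps),
            indel_rows=len(class_table_indels),
        )
        class_by_variant = class_of
    except Exception as exc:
        raise StageError(f"stage 'consequences' failed: {exc}") from exc

    # ---- density ----------------------------------------------------------
    try:
        genes = read_gene_intervals(genes_path) if genes_path is not None else []
        windows = dn.make_fixed_windows(layout, config.density_window)
        windows_by_pool = {}
        for p, name in enumerate(pools):
            rows = []
            for rec in snp_records:
                if not _carried(rec, p):
                    continue
                key = _key_str((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
                cls = class_by_variant.get(key, "Intergenic")
                rows.append(
                    (
                        rec.chrom,
                        rec.pos - 1,
                        cls == "Nonsynonymous_coding",
                        cls in ("Stop_gain", "Stop_lost"),
                        novel_flags.get(name, {}).get(key, False),
                    )
                )
            snp_df = pd.DataFrame(rows, columns=["chrom", "pos", "missense", "lof", "novel"])
            windows_by_pool[name] = dn.assign_counts(
                windows, snp_df, layout, config.density_window
            )
        density_top = dn.enriched_window_report(
            windows_by_pool,
            genes,
            layout,
            fraction=config.top_fraction,
            denominator=config.density_denominator,
        )
        write_tsv(density_top, outdir / "density_top_windows.tsv")
        for cat in dn.CATEGORIES:
            sub = density_top[density_top["category"] == cat]
            write_bed(
                zip(sub["chrom"], sub["start"], sub["end"], sub["density"].round(6)),
                outdir / f"density_top_{cat}.bed",
            )
        stage_log("density", n_windows=len(windows), n_top=len(density_top))
    except Exception as exc:
        raise StageError(f"stage 'density' failed: {exc}") from exc

    # ---- sweeps -----------------------------------------------------------
    try:
        loci_by_pool = {}
        zhp_frames = []
        for p, name in enumerate(pools):
            scan = sw.hp_scan(
                (r for r in snp_records if _carried(r, p)),
                p,
                layout,
                pool_name=name,
                size=config.sweep_window,
                overlap=config.sweep_overlap,
                min_snps=config.min_snps,
            )
            win = scan.windows.copy()
            win.insert(0, "pool", name)
            zhp_frames.append(win)
            loci_by_pool[name] = sw.call_sweeps(scan, config.thresholds, layout=layout)
        zhp_long = pd.concat(zhp_frames, ignore_index=True)
        write_tsv(zhp_long, outdir / "zhp_windows.tsv")
        report_tabs = sw.sweep_report(loci_by_pool)
        write_tsv(report_tabs["tier_counts"], outdir / "sweep_tier_counts.tsv")
        write_tsv(report_tabs["loci"], outdir / "sweep_loci.tsv")
        write_tsv(report_tabs["shared"], outdir / "sweep_shared.tsv")
        for name, loci in loci_by_pool.items():
            for tier in ("candidate", "putative", "extreme"):
                rows = [(l.chrom, l.start, l.end, f"{l.min_zhp:.3f}") for l in loci if l.tier == tier]
                write_bed(rows, outdir / f"sweeps_{name}_{tier}.bed")
        stage_log(
            "sweeps",
            n_windows=len(zhp_long) // max(1, len(pools)),
            n_loci=len(report_tabs["loci"]),
        )
    except Exception as exc:
        raise StageError(f"stage 'sweeps' failed: {exc}") from exc

    report = RunReport(
        pools=pools,
        variant_summary=variant_summary,
        titv=titv,
        novelty=novelty_df,
        novelty_skipped=novelty_skipped,
        class_table_snps=class_table_snps,
        class_table_indels=class_table_indels,
        density_top=density_top,
        sweep_tiers=report_tabs["tier_counts"],
        sweep_loci=report_tabs["loci"],
        log=log,
    )
    report.to_json(outdir / "report.json")
    stage_log("report", path=outdir / "report.json")
    return report


def _key_str(key: tuple[str, int, str, str]) -> str:
    c, p, r, a = key
    return f"{c}:{p}:{r}:{a}"


def _pool_names_from_vcf(path) -> list[str]:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        return list(vf.header.samples)
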