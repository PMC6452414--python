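"""1 Mb fixed-window SNP-density scan, top-percentile extraction and gene
annotation of enriched windows.

Four SNP categories are scanned per pool: all, missense, LoF (stop-gain plus
stop-loss) and novel. Windows tile each chromosome without overlap; the final
window is truncated at the chromosome end and densities always use the true
window length in kb, so short telomeric windows are neither discarded nor
inflated.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneInterval, GenomeLayout

logger = logging.getLogger(__name__)

CATEGORIES = ("all", "missense", "lof", "novel")


def make_fixed_windows(layout: GenomeLayout, size: int = 1_000_000) -> pd.DataFrame:
    """Non-overlapping windows covering every base exactly once (0-based
    half-open); the trailing window is truncated at the chromosome end."""
    if size < 1:
        raise ValueError(f"window size must be ≥1, got {size}")
    chroms, starts, ends = [], [], []
    for name, length in layout.chromosomes:
        s = np.arange(0, length, size)
        chroms.extend([name] * len(s))
        starts.append(s)
        ends.append(np.minimum(s + size, length))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.concatenate(starts).astype(np.int64),
            "end": np.concatenate(ends).astype(np.int64),
        }
    )


def assign_counts(
    windows: pd.DataFrame,
    snps: pd.DataFrame,
    layout: GenomeLayout,
    size: int = 1_000_000,
) -> pd.DataFrame:
    """Count SNPs per window and category and derive densities per kb.

    ``snps`` needs columns ``chrom`` and ``pos`` (0-based) plus optional
    boolean flag columns ``missense``, ``lof``, ``novel``. Every SNP increments
    exactly one window per category it belongs to; categories are not
    exclusive, and "all" includes every SNP. SNPs on chromosomes missing from
    the layout are skipped with a warning.
    """
    out = windows.copy()
    flag_cols = [c for c in CATEGORIES[1:] if c in snps.columns]
    for cat in CATEGORIES:
        out[f"count_{cat}"] = 0
    # window row index lookup: per chromosome, window i covers [i*size, ...)
    offsets: dict[str, np.ndarray] = {}
    for name, sub in out.groupby("chrom", sort=False):
        offsets[name] = sub.index.to_numpy()
    for name, sub in snps.groupby("chrom", sort=False):
        if name not in layout:
            logger.warning("skipping %d SNP(s) on %s: not in genome layout", len(sub), name)
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= layout.length(name)).any():
            raise ValueError(f"SNP position outside chromosome {name}")
        widx = offsets[name][pos // size]
        counts = np.bincount(widx, minlength=len(out))
        out["count_all"] += counts
        for cat in flag_cols:
            mask = sub[cat].to_numpy(dtype=bool)
            out[f"count_{cat}"] += np.bincount(widx[mask], minlength=len(out))
    length_kb = (out["end"] - out["start"]) / 1_000.0
    for cat in CATEGORIES:
        out[f"density_{cat}"] = out[f"count_{cat}"] / length_kb
    return out


def top_percent(
    windows: pd.DataFrame,
    category: str = "all",
    fraction: float = 0.01,
    layout: GenomeLayout | None = None,
    denominator: str = "all",
) -> pd.DataFrame:
    """Top windows by category density: sorted descending, ties broken by
    genomic coordinate (chromosome order then start), first ``ceil(f·N)`` kept.

    ``denominator="all"`` counts every window toward N (the default fixed
    denominator); ``"nonzero"`` counts only windows with ≥1 SNP of any
    category.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if f"density_{category}" not in windows.columns:
        raise KeyError(f"unknown category {category!r}")
    if len(windows) == 0:
        raise ValueError("no windows to rank")
    if denominator == "all":
        n = len(windows)
    elif denominator == "nonzero":
        count_cols = [f"count_{c}" for c in CATEGORIES if f"count_{c}" in windows]
        n = int((windows[count_cols].sum(axis=1) > 0).sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    k = math.ceil(fraction * n)
    order = (
        {c: i for i, c in enumerate(layout.names)}
        if layout is not None
        else {c: i for i, c in enumerate(dict.fromkeys(windows["chrom"]))}
    )
    df = windows.copy()
    df["_chrom_order"] = df["chrom"].map(order)
    df = df.sort_values(
        by=[f"density_{category}", "_chrom_order", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_chrom_order")
    return df.head(k).reset_index(drop=True)


def annotate_windows(
    windows: pd.DataFrame, genes: Iterable[GeneInterval]
) -> pd.DataFrame:
    """Ascribe to each window the names of genes overlapping it by ≥1 bp
    (deduplicated, sorted); windows without genes keep an empty list."""
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_name)
    out = windows.copy()
    names = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        tree = trees.get(chrom)
        hits = sorted({iv.data for iv in tree.overlap(start, end)}) if tree else []
        names.append(hits)
    out["genes"] = names
    return out


def enriched_window_report(
    windows_by_pool: Mapping[str, pd.DataFrame],
    genes: Iterable[GeneInterval],
    layout: GenomeLayout,
    fraction: float = 0.01,
    categories: Sequence[str] = CATEGORIES,
    denominator: str = "all",
) -> pd.DataFrame:
    """Long-format report of top-percentile windows per pool and category,
    annotated with overlapping gene names."""
    genes = list(genes)
    frames = []
    for pool, win in windows_by_pool.items():
        for cat in categories:
            top = top_percent(win, cat, fraction, layout=layout, denominator=denominator)
            top = annotate_windows(top, genes)
            top = top[["chrom", "start", "end", f"count_{cat}", f"density_{cat}", "genes"]]
            top = top.rename(columns={f"count_{cat}": "count", f"density_{cat}": "density"})
            top.insert(0, "category", cat)
            top.insert(0, "pool", pool)
            frames.append(top)
    report = pd.concat(frames, ignore_index=True)
    report["genes"] = report["genes"].map(lambda g: ",".join(g))
    return report
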