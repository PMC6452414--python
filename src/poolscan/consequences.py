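"""Map Sequence-Ontology consequence terms to functional classes and tabulate.

The class vocabulary follows the legacy Ensembl annotation style
(Nonsynonymous_coding, Essential_splice_site, ...) used in per-breed summary
tables; modern VEP terms (missense_variant, splice_donor_variant, ...) are
mapped onto it. A variant may carry several annotations across transcripts;
the default reduction keeps the most severe class per variant so per-class
counts partition the variant set, while ``mode="all"`` counts every
annotation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Functional classes in reporting order.
FUNCTIONAL_CLASSES = (
    "Downstream_gene",
    "Stop_lost",
    "Stop_gain",
    "Splice_site",
    "Upstream_gene",
    "Intronic",
    "miRNA",
    "Synonymous_coding",
    "Nonsynonymous_coding",
    "3'_UTR",
    "5'_UTR",
    "Within_non_coding_gene",
    "Essential_splice_site",
    "Intergenic",
)

UNMAPPED = "unmapped"

#: Severity order for the most-severe reduction (first = most severe).
SEVERITY_ORDER = (
    "Stop_gain",
    "Stop_lost",
    "Essential_splice_site",
    "Nonsynonymous_coding",
    "Synonymous_coding",
    "Splice_site",
    "3'_UTR",
    "5'_UTR",
    "miRNA",
    "Intronic",
    "Within_non_coding_gene",
    "Upstream_gene",
    "Downstream_gene",
    "Intergenic",
    UNMAPPED,
)

_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

TERM_TO_CLASS: dict[str, str] = {
    "missense_variant": "Nonsynonymous_coding",
    "synonymous_variant": "Synonymous_coding",
    "stop_gained": "Stop_gain",
    "stop_lost": "Stop_lost",
    "splice_region_variant": "Splice_site",
    "splice_donor_variant": "Essential_splice_site",
    "splice_acceptor_variant": "Essential_splice_site",
    "intron_variant": "Intronic",
    "upstream_gene_variant": "Upstream_gene",
    "downstream_gene_variant": "Downstream_gene",
    "3_prime_UTR_variant": "3'_UTR",
    "5_prime_UTR_variant": "5'_UTR",
    "mature_miRNA_variant": "miRNA",
    "non_coding_transcript_variant": "Within_non_coding_gene",
    "non_coding_transcript_exon_variant": "Within_non_coding_gene",
    "intergenic_variant": "Intergenic",
}

_warned_terms: set[str] = set()


def classify_consequence(term: str) -> str:
    """Deterministic SO-term → functional-class mapping; unknown terms go to
    the ``unmapped`` bucket (logged once per term)."""
    if not term:
        raise ValueError("empty consequence term")
    cls = TERM_TO_CLASS.get(term)
    if cls is None:
        if term not in _warned_terms:
            logger.warning("unmapped consequence term %r", term)
            _warned_terms.add(term)
        return UNMAPPED
    return cls


def severity_rank(cls: str) -> int:
    return _SEVERITY_RANK.get(cls, len(SEVERITY_ORDER))


def reduce_per_variant(
    rows: pd.DataFrame, mode: str = "most_severe"
) -> pd.DataFrame:
    """Reduce multi-annotation rows to classes per variant.

    ``rows`` needs columns ``variant_key`` and either ``functional_class`` or
    ``consequence`` (terms are classified on the fly). ``most_severe`` keeps
    one row per variant by the fixed severity order (deterministic and
    independent of input row order); ``all`` keeps one row per distinct
    (variant, class).
    """
    if mode not in {"most_severe", "all"}:
        raise ValueError(f"unknown reduction mode {mode!r}")
    df = rows.copy()
    if "functional_class" not in df.columns:
        df["functional_class"] = df["consequence"].map(classify_consequence)
    df = df[["variant_key", "functional_class"]].drop_duplicates()
    if mode == "all":
        return df.reset_index(drop=True)
    df["_rank"] = df["functional_class"].map(severity_rank)
    df = df.sort_values(["variant_key", "_rank"], kind="mergesort")
    out = df.groupby("variant_key", sort=True).first().reset_index()
    return out[["variant_key", "functional_class"]]


def tabulate_counts(
    counts: Mapping[str, Mapping[str, int]],
    pool_totals: Mapping[str, int] | None = None,
    classes: Sequence[str] = FUNCTIONAL_CLASSES,
) -> pd.DataFrame:
    """Build a class × pool count table with per-pool percentages and a Total
    column equal to the row-wise sum over pools.

    ``counts`` maps pool → {class: count}. Percentages are count over the
    pool's total classified variants (``pool_totals`` overrides, e.g. to use
    all variants of a type as denominator).
    """
    pools = list(counts)
    rows = []
    totals = {
        pool: (pool_totals[pool] if pool_totals is not None else sum(counts[pool].values()))
        for pool in pools
    }
    class_list = list(classes)
    extra = sorted({c for pool in pools for c in counts[pool]} - set(class_list))
    for cls in class_list + extra:
        row: dict[str, object] = {"class": cls}
        total = 0
        for pool in pools:
            c = int(counts[pool].get(cls, 0))
            row[pool] = c
            row[f"{pool}_pct"] = round(100.0 * c / totals[pool], 4) if totals[pool] else 0.0
            total += c
        row["Total"] = total
        rows.append(row)
    return pd.DataFrame(rows)


def tabulate(
    classified: Mapping[str, Iterable[str]] | pd.DataFrame,
    pools: Sequence[str] | None = None,
    pool_totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate per-pool class labels into a :func:`tabulate_counts` table.

    ``classified`` maps pool → iterable of functional-class labels (one per
    variant after reduction), or is a DataFrame with ``pool`` and
    ``functional_class`` columns.
    """
    if isinstance(classified, pd.DataFrame):
        grouped = {
            pool: sub["functional_class"].tolist()
            for pool, sub in classified.groupby("pool", sort=False)
        }
        classified = grouped
    if pools is not None:
        unknown = set(classified) - set(pools)
        if unknown:
            raise KeyError(f"unknown pool name(s): {sorted(unknown)}")
        classified = {p: classified.get(p, []) for p in pools}
    counts = {
        pool: pd.Series(list(labels), dtype=object).value_counts().to_dict()
        for pool, labels in classified.items()
    }
    return tabulate_counts(counts, pool_totals=pool_totals)
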