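"""Known/novel flagging against a variant catalogue and Table-style summaries.

Variants are keyed as (chrom, pos, ref, alt) after parsimony trimming
(right-trim shared trailing bases, then left-trim shared leading bases with a
position shift — the bcftools/vt convention). Matching is allele-exact by
default, the dbSNP convention; a position-only mode is available. Trimming is
reference-free; full left-alignment of indels through homopolymer runs would
need the genome sequence and is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import VariantRecord

VariantKey = tuple[str, int, str, str]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the convention used for reported proportions."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalise_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-trim one allele pair; SNPs pass through unchanged.

    Shared trailing bases are trimmed first, then shared leading bases (each
    leading trim advances ``pos`` by one). At least one base of each allele is
    always retained. ``ref == alt`` is a non-variant and an error.
    """
    if not ref or not alt:
        raise ValueError(f"{chrom}:{pos}: empty allele")
    if ref == alt:
        raise ValueError(f"{chrom}:{pos}: ref == alt ({ref!r}) is not a variant")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


@dataclass(frozen=True)
class KnownCatalogue:
    """Set of normalised variant keys standing in for a population catalogue."""

    keys: frozenset[VariantKey]
    positions: frozenset[tuple[str, int]]

    @classmethod
    def from_keys(cls, keys: Iterable[VariantKey]) -> "KnownCatalogue":
        normed = frozenset(normalise_variant(*k) for k in keys)
        return cls(normed, frozenset((c, p) for c, p, _, _ in normed))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownCatalogue":
        """Read a 4-column TSV (chrom, pos, ref, alt; 1-based positions)."""
        df = pd.read_csv(path, sep="\t", header=0)
        df.columns = ["chrom", "pos", "ref", "alt"] + list(df.columns[4:])
        return cls.from_keys(
            zip(df["chrom"].astype(str), df["pos"].astype(int), df["ref"], df["alt"])
        )

    @classmethod
    def from_vcf(cls, path: str | Path) -> "KnownCatalogue":
        from .genome_io import read_vcf

        return cls.from_keys(
            (rec.chrom, rec.pos, rec.ref, alt) for rec in read_vcf(path) for alt in rec.alts
        )

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: VariantKey) -> bool:
        return normalise_variant(*key) in self.keys


def write_catalogue_tsv(keys: Iterable[VariantKey], path: str | Path) -> None:
    pd.DataFrame(sorted(keys), columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def match_known(
    records: Iterable[VariantRecord | VariantKey],
    catalogue: KnownCatalogue,
    mode: str = "allele",
) -> list[bool]:
    """Per-record known flag (True = present in the catalogue).

    ``mode="allele"`` (default) requires chrom+pos+ref+alt agreement after
    normalisation; ``mode="position"`` matches on chrom+pos only. Multiallelic
    records are known iff any alt allele matches.
    """
    if mode not in {"allele", "position"}:
        raise ValueError(f"unknown match mode {mode!r}")
    flags = []
    for rec in records:
        if isinstance(rec, VariantRecord):
            keys = [(rec.chrom, rec.pos, rec.ref, alt) for alt in rec.alts]
        else:
            keys = [rec]
        normed = [normalise_variant(*k) for k in keys]
        if mode == "allele":
            flags.append(any(k in catalogue.keys for k in normed))
        else:
            flags.append(any((c, p) in catalogue.positions for c, p, _, _ in normed))
    return flags


def novelty_summary(
    counts: Mapping[str, tuple[int, int]] | None = None,
    flags_by_pool: Mapping[str, Sequence[bool]] | None = None,
) -> pd.DataFrame:
    """Per-pool known/novel counts, proportions and the unweighted average.

    Accepts either ``counts`` mapping pool → (known, novel) or
    ``flags_by_pool`` mapping pool → known flags. Proportions are rounded
    half-up to 2 decimals for reporting; a zero total reports a missing
    proportion. The ``Average`` row holds the unweighted mean of the per-pool
    proportions (the convention behind "on average" headline figures), with
    summed counts for reference.
    """
    if (counts is None) == (flags_by_pool is None):
        raise ValueError("provide exactly one of counts or flags_by_pool")
    if flags_by_pool is not None:
        counts = {
            pool: (int(sum(f)), int(len(f) - sum(f))) for pool, f in flags_by_pool.items()
        }
    rows = []
    props = []
    for pool, (known, novel) in counts.items():
        total = known + novel
        prop = novel / total if total else float("nan")
        if total:
            props.append(prop)
        rows.append(
            {
                "pool": pool,
                "known": known,
                "novel": novel,
                "total": total,
                "proportion_novel": round_half_up(prop) if total else float("nan"),
            }
        )
    mean_prop = sum(props) / len(props) if props else float("nan")
    rows.append(
        {
            "pool": "Average",
            "known": sum(r["known"] for r in rows),
            "novel": sum(r["novel"] for r in rows),
            "total": sum(r["total"] for r in rows),
            "proportion_novel": round_half_up(mean_prop) if props else float("nan"),
        }
    )
    return pd.DataFrame(rows)
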