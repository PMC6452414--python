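"""Self-contained simulation studies used to validate the sweep scan.

The recovery study plants a handful of strong sweeps (minor-allele frequency
compressed by 95%) in an otherwise neutral three-chromosome genome at the
default pool design, scans every pool, and scores how many planted intervals
are hit by candidate loci (ZHp ≤ −4) and how many called loci hit nothing.
Sweeps are planted in all pools; a sweep counts as recovered when any pool's
candidate locus overlaps it, and every candidate locus in any pool that
overlaps no planted interval counts as a false call for that genome.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomeLayout
from .simdata import SimParams, simulate
from .sweeps import SweepThresholds, call_sweeps, scan_counts, z_transform


@dataclass
class RecoveryResult:
    n_seeds: int
    n_planted: int
    n_recovered: int
    false_loci_per_seed: list[int]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_planted

    @property
    def mean_false_loci(self) -> float:
        return sum(self.false_loci_per_seed) / len(self.false_loci_per_seed)


def default_recovery_layout(chrom_length: int = 30_000_000, n_chroms: int = 3) -> GenomeLayout:
    return GenomeLayout(tuple((f"chr{i + 1}", chrom_length) for i in range(n_chroms)))


def default_planted_sweeps(sweep_length: int = 300_000, het_reduction: float = 0.95):
    """Five sweeps spread over the three chromosomes, clear of the edges."""
    anchors = [("chr1", 5_000_000), ("chr1", 20_000_000), ("chr2", 10_000_000),
               ("chr3", 3_000_000), ("chr3", 25_000_000)]
    return tuple(
        (chrom, start, start + sweep_length, het_reduction) for chrom, start in anchors
    )


def sweep_recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    het_reduction: float = 0.95,
    sweep_length: int = 300_000,
    thresholds: SweepThresholds = SweepThresholds(),
) -> RecoveryResult:
    """Run the planted-sweep recovery experiment over ``n_seeds`` replicates."""
    layout = default_recovery_layout()
    sweeps = default_planted_sweeps(sweep_length, het_reduction)
    n_recovered = 0
    false_per_seed = []
    for s in range(n_seeds):
        params = SimParams(layout=layout, seed=base_seed + s, planted_sweeps=sweeps)
        sim = simulate(params)
        candidate_loci = []
        for p in range(params.n_pools):
            scan = z_transform(scan_counts(sim.pool_counts(p), layout, pool=f"pool{p + 1}"))
            candidate_loci.append(
                [l for l in call_sweeps(scan, thresholds, layout=layout) if l.tier == "candidate"]
            )

        def hits(locus, sweep):
            chrom, start, end, _ = sweep
            return locus.chrom == chrom and locus.start < end and start < locus.end

        for sweep in sweeps:
            if any(hits(l, sweep) for loci in candidate_loci for l in loci):
                n_recovered += 1
        n_false = sum(
            1
            for loci in candidate_loci
            for l in loci
            if not any(hits(l, sweep) for sweep in sweeps)
        )
        false_per_seed.append(n_false)
    return RecoveryResult(
        n_seeds=n_seeds,
        n_planted=n_seeds * len(sweeps),
        n_recovered=n_recovered,
        false_loci_per_seed=false_per_seed,
    )
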