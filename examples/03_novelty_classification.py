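"""Flag variants as known or novel against a catalogue and summarise per pool.

Matching is allele-exact on (chrom, pos, ref, alt) after parsimony trimming,
so the same indel in different VCF spellings still matches.
"""

from poolscan import GenomeLayout, KnownCatalogue, SimParams, match_known, novelty_summary, simulate

sim = simulate(SimParams(layout=GenomeLayout((("chr1", 1_000_000),)), seed=4,
                         pool_names=("AFR", "DRA", "NGI")))
snps = sim.variants[sim.variants["is_snp"]]
keys = list(zip(snps["chrom"], snps["pos0"] + 1, snps["ref"], snps["alt"]))
known = match_known(keys, sim.catalogue)

flags = {"all_SNPs": known}
print(novelty_summary(flags_by_pool=flags).to_string(index=False))

# different spellings of one insertion still match
cat = KnownCatalogue.from_keys([("chr1", 100, "CA", "CG")])
print("\nalternate spelling (chr1:101 A>G) known?",
      match_known([("chr1", 101, "A", "G")], cat)[0])
# ~7% of simulated SNPs are novel (1 - known_fraction), matching the share of
# variants a large known-variant catalogue would not contain.
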