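"""Hard-filter a record set with injected failures and compute Ti/Tv QC.

One in ten records gets a metric pushed past a GATK-convention threshold
(QUAL < 30, QD < 2, MQ < 40, FS > 60, HaplotypeScore > 13, MQRankSum < -12.5,
ReadPosRankSum < -8); filtering should remove exactly those.
"""

from poolscan import GenomeLayout, SimParams, filter_records, simulate, titv_ratio
from poolscan.simdata import inject_filter_failures

sim = simulate(SimParams(layout=GenomeLayout((("chr1", 500_000),)), seed=2))
records = list(sim.records())
records, injected = inject_filter_failures(records, fraction=0.1, seed=3)

passing, rejects = filter_records(records)
print(f"records in: {len(records)}  injected failures: {len(injected)}")
print(f"passing: {len(passing)}  rejected: {len(rejects)}")
print("rejection reasons seen:", sorted(set(";".join(rejects["reasons"]).split(";"))))
print(f"Ti/Tv of passing SNPs: {titv_ratio(passing):.2f}")
# The rejected count equals the injected count, and Ti/Tv sits near 2.2 -
# the genome-wide value expected for real cattle sequence data.
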