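"""Reduce multi-transcript consequence annotations and build class tables.

A variant annotated against several transcripts keeps its most severe class
(stop-gain > stop-loss > essential splice > missense > ...), so per-class
counts partition the variant set.
"""

import pandas as pd

from poolscan import reduce_per_variant, tabulate

rows = pd.DataFrame(
    {
        "variant_key": ["chr1:100:A:G", "chr1:100:A:G", "chr1:200:C:T", "chr1:300:G:A"],
        "consequence": ["intron_variant", "missense_variant",
                        "synonymous_variant", "stop_gained"],
    }
)
reduced = reduce_per_variant(rows, mode="most_severe")
print("per-variant class after most-severe reduction:")
print(reduced.to_string(index=False))

table = tabulate({"AFR": reduced["functional_class"].tolist(),
                  "DRA": ["Intronic", "Intronic", "Nonsynonymous_coding"]},
                 pools=["AFR", "DRA"])
nonzero = table[table["Total"] > 0]
print("\nclass count table (non-zero rows):")
print(nonzero.to_string(index=False))
# The variant with both intron and missense annotations counts once, as
# Nonsynonymous_coding; the Total column is the row-wise sum over pools.
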