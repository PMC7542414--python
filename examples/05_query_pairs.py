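"""Post-linkage analytics over the merged pairs table.

The standard query workload after a deduplication run: pair count, pair
score histogram, and pairs within a score range (scores near the potential
threshold are the clerical-review zone).
"""

import tempfile
from pathlib import Path

import binlink as bl

records, _ = bl.generate_dataset(n_entities=300, seed=5)
config = bl.default_config(secret_key=b"example-key")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    data = tmp / "data.csv"
    bl.write_dataset(records, data)
    bl.run_pipeline(config, data, tmp / "run")
    table = bl.dedupe_pairs([tmp / "run" / "merged" / "pairs.csv.gz"])

print(f"pair count: {table.unique_pairs}")
print("score histogram (width 5):")
for edge, count in bl.score_histogram(table, 5.0):
    print(f"  [{edge:6.2f}, {edge + 5:6.2f})  {count:6d}  {'#' * (count // 50)}")
sub = bl.pairs_in_range(table, 15.0, 16.0)
print(f"pairs in score range 15-16: {len(sub)}")

# Histogram counts sum to the pair count; the 15-16 band holds weak
# potential matches just above the emission threshold.
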