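"""Run the end-to-end deduplication pipeline and measure linkage quality.

encode -> stage -> plan -> split -> parallel match -> merge -> group.
The merged pairs table is identical whatever the worker count, because
bins partition the comparison space per blocking strategy.
"""

import tempfile
from pathlib import Path

import binlink as bl

records, truth = bl.generate_dataset(n_entities=300, seed=5)
config = bl.default_config(secret_key=b"example-key")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    data = tmp / "data.csv"
    bl.write_dataset(records, data)
    report = bl.run_pipeline(config, data, tmp / "run", workers=4)

    print(f"records:        {report['n_records']}")
    print(f"bins:           {report['bin_count']}")
    print(f"total pairs:    {report['total_pairs']}   "
          f"(unique: {report['unique_pairs']})")
    print(f"entity groups:  {report['n_groups']}")

    table = bl.dedupe_pairs([tmp / "run" / "merged" / "pairs.csv.gz"])
    q = bl.linkage_quality(table, truth, config.thresholds.match)
    print(f"pairwise precision {q['precision']:.3f}, "
          f"recall {q['recall']:.3f}, F1 {q['f1']:.3f}")

# total pairs > unique pairs: the two blocking passes overlap, so some pairs
# are scored twice and de-duplicated after classification.
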