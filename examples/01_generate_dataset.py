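"""Generate a synthetic person dataset with known ground truth.

Base records are drawn from skewed name-frequency tables; each entity gets
a heavy-tailed number of duplicates, each independently corrupted by the
high-error preset (typos, truncations, nicknames, missing values).
"""

import binlink as bl

records, truth = bl.generate_dataset(n_entities=200, seed=7)

sizes = {}
for eid in truth.values():
    sizes[eid] = sizes.get(eid, 0) + 1

print(f"records:          {len(records)}")
print(f"entities:         {len(sizes)}")
print(f"largest entity:   {max(sizes.values())} records")
print("sample rows:")
for r in records[:4]:
    print(f"  {r.record_id}  {r.first_name!r:12} {r.last_name!r:12} "
          f"{r.dob}  {r.sex}  {r.postcode}")

# The record count exceeds the entity count because of duplicates; the truth
# table (record_id -> entity_id) is what linkage quality is measured against.
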