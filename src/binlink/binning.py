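"""Comparison-space-balanced bin planning and dataset splitting.

The first batch task of the pipeline: block-key frequencies give each key a
comparison space c = f(f-1)/2; the bin count is the total remaining space
divided by the maximum desired per-bin space (ceiling, floor of 1); keys are
sorted by space descending and dealt round-robin across bins, largest first,
returning to the first bin when the end is reached.  Oversized keys are
discarded up front — very high-frequency blocking values are poor
discriminators and would overload a single matching node.

Because the split is on blocking values, the total comparison space of the
linkage is unchanged: per-bin spaces plus discarded space sum exactly to the
per-strategy totals, and no record pair is compared under the same strategy
in two different bins.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .blocking import BlockStats, comparison_space_self
from .encoding import EncodedRecord, write_encoded

__all__ = ["BinPlan", "plan_bins", "split_dataset", "write_plan", "read_plan"]


@dataclass(frozen=True)
class BinPlan:
    """Assignment of (strategy, key digest) to bins, with space accounting."""

    max_space: int
    bin_count: int
    assignment: Mapping[tuple[str, str], int]
    key_info: Mapping[tuple[str, str], tuple[int, int]]  # key -> (f, c)
    discarded: tuple[tuple[str, str, int, int], ...]  # (strategy, digest, f, c)
    bin_spaces: tuple[int, ...]

    def keys_of_bin(self, b: int) -> set[tuple[str, str]]:
        return {k for k, kb in self.assignment.items() if kb == b}

    @property
    def total_assigned_space(self) -> int:
        return sum(self.bin_spaces)

    @property
    def discarded_space(self) -> int:
        return sum(c for *_rest, c in self.discarded)


def plan_bins(
    stats: Sequence[BlockStats],
    max_space: int,
    discard_rule: str = "space",
    force_bins: int | None = None,
) -> BinPlan:
    """Plan bins of approximately equal comparison space.

    ``discard_rule`` selects what is compared against ``max_space`` when
    discarding oversized keys: the key's comparison space c (default) or its
    raw frequency f.  ``force_bins`` overrides the derived bin count (used
    for splitting-invariance experiments).
    """
    if max_space < 1:
        raise ValueError(f"max_space must be >= 1, got {max_space}")
    if discard_rule not in ("space", "frequency"):
        raise ValueError(f"unknown discard rule {discard_rule!r}")

    keys: list[tuple[str, str, int, int]] = []   # (strategy, digest, f, c)
    for st in stats:
        for digest, f in st.frequencies.items():
            keys.append((st.strategy, digest, f, comparison_space_self(f)))

    discarded = []
    kept = []
    for strategy, digest, f, c in keys:
        measure = c if discard_rule == "space" else f
        if measure > max_space:
            discarded.append((strategy, digest, f, c))
        else:
            kept.append((strategy, digest, f, c))

    remaining = sum(c for *_r, c in kept)
    if force_bins is not None:
        if force_bins < 1:
            raise ValueError("force_bins must be >= 1")
        n_bins = force_bins
    else:
        n_bins = max(1, math.ceil(remaining / max_space))

    # largest space first; ties by digest then strategy for determinism
    kept.sort(key=lambda k: (-k[3], k[1], k[0]))
    assignment: dict[tuple[str, str], int] = {}
    key_info: dict[tuple[str, str], tuple[int, int]] = {}
    spaces = [0] * n_bins
    for i, (strategy, digest, f, c) in enumerate(kept):
        b = i % n_bins
        assignment[(strategy, digest)] = b
        key_info[(strategy, digest)] = (f, c)
        spaces[b] += c

    discarded.sort(key=lambda k: (-k[3], k[1], k[0]))
    return BinPlan(max_space, n_bins, assignment, key_info,
                   tuple(discarded), tuple(spaces))


def split_dataset(
    encoded: Sequence[EncodedRecord],
    plan: BinPlan,
    out_dir,
) -> list[Path]:
    """Write one gzip CSV per bin; a record joins every bin its keys map to.

    A record appears at most once per bin even when several of its keys land
    there.  Keys present in the data but absent from the plan (neither
    assigned nor discarded) are a consistency error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    discarded = {(s, d) for s, d, _f, _c in plan.discarded}
    members: dict[int, list[EncodedRecord]] = {b: [] for b in range(plan.bin_count)}
    for rec in encoded:
        bins_seen: set[int] = set()
        for key in rec.block_keys:
            if key in discarded:
                continue
            b = plan.assignment.get(key)
            if b is None:
                raise ValueError(
                    f"block key {key!r} of record {rec.record_id} is neither "
                    "assigned nor discarded by the plan")
            bins_seen.add(b)
        for b in sorted(bins_seen):
            members[b].append(rec)

    paths: list[Path] = []
    for b in range(plan.bin_count):
        path = out_dir / f"bin-{b:04d}.csv.gz"
        write_encoded(members[b], path)
        paths.append(path)
    return paths


def write_plan(plan: BinPlan, path) -> None:
    """CSV strategy,key_digest,frequency,space,bin (bin = -1 for discarded).

    The first data row carries the plan's max_space in a comment-style
    pseudo-key so that a plan file round-trips completely.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strategy", "key_digest", "frequency", "space", "bin"])
        w.writerow(["#max_space", "", "", plan.max_space, plan.bin_count])
        rows = []
        for (strategy, digest), b in plan.assignment.items():
            f, c = plan.key_info[(strategy, digest)]
            rows.append([strategy, digest, f, c, b])
        for strategy, digest, f, c in plan.discarded:
            rows.append([strategy, digest, f, c, -1])
        rows.sort(key=lambda r: (-r[3], r[1], r[0]))
        w.writerows(rows)


def read_plan(path) -> BinPlan:
    assignment: dict[tuple[str, str], int] = {}
    key_info: dict[tuple[str, str], tuple[int, int]] = {}
    discarded: list[tuple[str, str, int, int]] = []
    max_space = bin_count = None
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if row[0] == "#max_space":
                max_space, bin_count = int(row[3]), int(row[4])
                continue
            strategy, digest, f, c, b = row[0], row[1], int(row[2]), int(row[3]), int(row[4])
            if b == -1:
                discarded.append((strategy, digest, f, c))
            else:
                assignment[(strategy, digest)] = b
                key_info[(strategy, digest)] = (f, c)
    if max_space is None or bin_count is None:
        raise ValueError("plan file lacks the #max_space metadata row")
    spaces = [0] * bin_count
    for key, b in assignment.items():
        spaces[b] += key_info[key][1]
    discarded.sort(key=lambda k: (-k[3], k[1], k[0]))
    return BinPlan(max_space, bin_count, assignment, key_info,
                   tuple(discarded), tuple(spaces))
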