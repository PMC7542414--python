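"""Blocking keys, block-value frequencies, and comparison-space accounting.

Two blocking passes are the default: (1) first-name initial concatenated
with last-name Soundex, and (2) date of birth concatenated with sex.  Key
values are assembled from the raw fields and immediately digested with the
project key, so staged files reveal neither initials nor phonetic codes.

The comparison space of a block of f records in a deduplication (self-join)
is f(f-1)/2; the per-strategy total is the sum over blocks.  The two-file
formula f_A * f_B is provided for completeness but is unused by the
deduplication pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

from .encoding import EncodedRecord, exact_digest

__all__ = [
    "BlockingStrategy",
    "BlockStats",
    "default_strategies",
    "soundex",
    "block_keys",
    "block_frequencies",
    "candidate_pairs",
    "comparison_space_self",
    "comparison_space_two_file",
    "write_frequencies",
]

TRANSFORMS = ("identity", "first_initial", "soundex")
_SEP = "\x1f"


@dataclass(frozen=True)
class BlockingStrategy:
    """A named blocking pass: ordered (field, transform) components."""

    name: str
    components: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("strategy needs at least one component")
        for _, t in self.components:
            if t not in TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}")


def default_strategies() -> tuple[BlockingStrategy, ...]:
    return (
        BlockingStrategy("name", (("first_name", "first_initial"),
                                  ("last_name", "soundex"))),
        BlockingStrategy("dobsex", (("dob", "identity"), ("sex", "identity"))),
    )


_SOUNDEX_CODES = {
    **dict.fromkeys("bfpv", "1"),
    **dict.fromkeys("cgjkqsxz", "2"),
    **dict.fromkeys("dt", "3"),
    "l": "4",
    **dict.fromkeys("mn", "5"),
    "r": "6",
}


def soundex(name: str) -> str:
    """American Soundex: leading letter plus three digits, zero-padded.

    h and w are transparent between consonants of equal code; vowels break
    runs.  Empty or non-alphabetic input yields the empty code.
    """
    letters = [ch for ch in name.lower() if ch.isalpha()]
    if not letters:
        return ""
    first = letters[0]
    code = first.upper()
    prev = _SOUNDEX_CODES.get(first, "")
    for ch in letters[1:]:
        if ch in "hw":
            continue
        digit = _SOUNDEX_CODES.get(ch, "")
        if digit and digit != prev:
            code += digit
            if len(code) == 4:
                break
        prev = digit
    return (code + "000")[:4]


def _first_initial(value: str) -> str:
    for ch in value.lower():
        if ch.isalnum():
            return ch
    return ""


def _transform(value: str, transform: str) -> str:
    if transform == "identity":
        return value.strip().lower()
    if transform == "first_initial":
        return _first_initial(value)
    if transform == "soundex":
        return soundex(value)
    raise ValueError(f"unknown transform {transform!r}")


def block_keys(
    rec,
    strategies: Sequence[BlockingStrategy],
    key: bytes,
) -> list[tuple[str, str]]:
    """Compute digested blocking keys for one raw record.

    A strategy yields no key when any of its component values is missing or
    transforms to the empty string (no sentinel missing-value blocks).
    """
    if not strategies:
        raise ValueError("at least one blocking strategy is required")
    out: list[tuple[str, str]] = []
    for strat in strategies:
        parts: list[str] = []
        for field_name, transform in strat.components:
            value = rec.get(field_name)
            part = _transform(value, transform) if value else ""
            if not part:
                parts = []
                break
            parts.append(part)
        if parts:
            digest = exact_digest(_SEP.join(parts), f"block:{strat.name}", key)
            out.append((strat.name, digest))
    return out


def comparison_space_self(f: int) -> int:
    """Within-block pair count for deduplication: f(f-1)/2."""
    return f * (f - 1) // 2


def comparison_space_two_file(f_a: int, f_b: int) -> int:
    """Cross-file block comparison space (Cartesian product); unused by dedup."""
    return f_a * f_b


@dataclass(frozen=True)
class BlockStats:
    """Key-digest frequencies and comparison-space totals for one strategy."""

    strategy: str
    frequencies: Mapping[str, int]

    def space(self, key_digest: str) -> int:
        return comparison_space_self(self.frequencies[key_digest])

    @property
    def total_space(self) -> int:
        return sum(comparison_space_self(f) for f in self.frequencies.values())


def block_frequencies(
    dataset: Iterable[EncodedRecord], strategy_name: str
) -> BlockStats:
    """Exact multiset counts of one strategy's key digests across the dataset."""
    freqs: dict[str, int] = {}
    for rec in dataset:
        for s, digest in rec.block_keys:
            if s == strategy_name:
                freqs[digest] = freqs.get(digest, 0) + 1
    return BlockStats(strategy_name, freqs)


def candidate_pairs(
    records: Sequence[EncodedRecord],
    strategy_names: Iterable[str],
    assigned_keys: set[tuple[str, str]] | None = None,
) -> Iterator[tuple[str, str, str]]:
    """Yield (id_a, id_b, strategy) for records sharing a block key.

    Each unordered pair appears at most once per strategy, never a record
    with itself; ids are ordered lexicographically within a pair.  When
    ``assigned_keys`` is given, only keys in that set generate candidates
    (this is how a bin restricts itself to its own share of the comparison
    space).
    """
    wanted = set(strategy_names)
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        for s, digest in rec.block_keys:
            if s not in wanted:
                continue
            if assigned_keys is not None and (s, digest) not in assigned_keys:
                continue
            groups.setdefault((s, digest), []).append(rec.record_id)
    for (s, _digest), ids in sorted(groups.items()):
        for a, b in combinations(sorted(set(ids)), 2):
            yield a, b, s


def write_frequencies(stats: Sequence[BlockStats], path) -> None:
    """CSV strategy,key_digest,frequency; descending frequency then digest."""
    rows = [
        (st.strategy, digest, f)
        for st in stats
        for digest, f in st.frequencies.items()
    ]
    rows.sort(key=lambda r: (r[0], -r[2], r[1]))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strategy", "key_digest", "frequency"])
        w.writerows(rows)
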