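"""Fellegi-Sunter probabilistic comparison and classification.

Each configured field contributes a log-likelihood-ratio weight: agreement
weight log2(m/u) when the field similarity clears t_high, disagreement
weight log2((1-m)/(1-u)) below t_low, with linear interpolation in between
so that graded Bloom-filter (Dice) similarities contribute partial evidence.
Here m is the probability of field agreement among true matches and u among
non-matches.  Missing comparisons contribute weight 0 — neither evidence
for nor against.

A pair's score is the sum of its field weights; pairs scoring at or above
the potential-match threshold are emitted, and the match threshold is
applied later at grouping time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .blocking import candidate_pairs
from .encoding import EncodedRecord, dice_similarity

__all__ = [
    "FieldComparisonSpec",
    "ClassificationThresholds",
    "Pair",
    "default_field_specs",
    "default_thresholds",
    "field_weight",
    "field_similarity",
    "compare_pair",
    "match_bin",
    "match_all",
    "estimate_u",
]

COMPARATORS = ("bloom_dice", "exact_digest", "date_parts")
_DATE_PARTS = ("dob_day", "dob_month", "dob_year")


@dataclass(frozen=True)
class FieldComparisonSpec:
    """m/u probabilities and partial-agreement thresholds for one field."""

    field: str
    comparator: str
    m: float
    u: float
    t_low: float = 0.6
    t_high: float = 1.0

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if not (0.0 < self.u < self.m < 1.0):
            raise ValueError(
                f"require 0 < u < m < 1 for field {self.field!r}: "
                f"m={self.m}, u={self.u}")
        if not (0.0 <= self.t_low <= self.t_high <= 1.0):
            raise ValueError("require 0 <= t_low <= t_high <= 1")

    @property
    def agreement_weight(self) -> float:
        return math.log2(self.m / self.u)

    @property
    def disagreement_weight(self) -> float:
        return math.log2((1.0 - self.m) / (1.0 - self.u))


@dataclass(frozen=True)
class ClassificationThresholds:
    """Match and potential-match score cut-offs (T_p <= T_m)."""

    match: float = 25.0
    potential: float = 15.0

    def __post_init__(self) -> None:
        if self.potential > self.match:
            raise ValueError("potential threshold must not exceed match threshold")


@dataclass(frozen=True)
class Pair:
    """One scored candidate pair; ids ordered so record_id_a < record_id_b."""

    record_id_a: str
    record_id_b: str
    score: float
    strategy: str
    field_weights: tuple[float, ...]


def default_field_specs() -> tuple[FieldComparisonSpec, ...]:
    """Shipped m/u preset; u values are refined from data by estimate_u."""
    return (
        FieldComparisonSpec("first_name", "bloom_dice", m=0.95, u=0.005),
        FieldComparisonSpec("middle_name", "bloom_dice", m=0.90, u=0.005),
        FieldComparisonSpec("last_name", "bloom_dice", m=0.95, u=0.002),
        FieldComparisonSpec("dob", "date_parts", m=0.98, u=0.001),
        FieldComparisonSpec("sex", "exact_digest", m=0.95, u=0.5),
        FieldComparisonSpec("address", "bloom_dice", m=0.90, u=0.001),
        FieldComparisonSpec("postcode", "exact_digest", m=0.90, u=0.01),
    )


def default_thresholds() -> ClassificationThresholds:
    return ClassificationThresholds()


def field_weight(spec: FieldComparisonSpec, similarity: float | None) -> float:
    """Interpolated Fellegi-Sunter weight for one field similarity."""
    if similarity is None:
        return 0.0
    w_a = spec.agreement_weight
    w_d = spec.disagreement_weight
    if similarity >= spec.t_high:
        return w_a
    if similarity <= spec.t_low:
        return w_d
    frac = (similarity - spec.t_low) / (spec.t_high - spec.t_low)
    return w_d + frac * (w_a - w_d)


def field_similarity(
    a: EncodedRecord, b: EncodedRecord, spec: FieldComparisonSpec
) -> float | None:
    """Similarity in [0,1] for one field, or None when either side is missing."""
    if spec.comparator == "bloom_dice":
        fa, fb = a.bloom(spec.field), b.bloom(spec.field)
        ia = int.from_bytes(fa, "big")
        ib = int.from_bytes(fb, "big")
        if ia == 0 or ib == 0:      # all-zero filter <=> field was missing
            return None
        return dice_similarity(fa, fb)
    if spec.comparator == "exact_digest":
        da, db = a.digest(spec.field), b.digest(spec.field)
        if da is None or db is None:
            return None
        return 1.0 if da == db else 0.0
    if spec.comparator == "date_parts":
        parts_a = [a.digest(p) for p in _DATE_PARTS]
        parts_b = [b.digest(p) for p in _DATE_PARTS]
        if all(p is None for p in parts_a) or all(p is None for p in parts_b):
            return None
        agree = sum(
            1 for pa, pb in zip(parts_a, parts_b)
            if pa is not None and pa == pb
        )
        return agree / len(_DATE_PARTS)
    raise ValueError(f"unknown comparator {spec.comparator!r}")


def compare_pair(
    a: EncodedRecord,
    b: EncodedRecord,
    specs: Sequence[FieldComparisonSpec],
) -> tuple[float, tuple[float, ...]]:
    """Score one record pair: per-field weights and their sum."""
    weights = tuple(field_weight(s, field_similarity(a, b, s)) for s in specs)
    return sum(weights), weights


def match_bin(
    records: Sequence[EncodedRecord],
    specs: Sequence[FieldComparisonSpec],
    thresholds: ClassificationThresholds,
    strategy_names: Iterable[str],
    assigned_keys: set[tuple[str, str]] | None = None,
) -> list[Pair]:
    """Deduplicate one bin: evaluate its candidate pairs, keep score >= T_p.

    Only keys in ``assigned_keys`` (the bin's share of the plan) generate
    candidates, so bins can be matched independently without duplicating
    comparisons.  Output order is (record_id_a, record_id_b, strategy).
    """
    by_id = {r.record_id: r for r in records}
    out: list[Pair] = []
    for id_a, id_b, strategy in candidate_pairs(records, strategy_names,
                                                assigned_keys):
        score, weights = compare_pair(by_id[id_a], by_id[id_b], specs)
        if score >= thresholds.potential:
            out.append(Pair(id_a, id_b, score, strategy, weights))
    out.sort(key=lambda p: (p.record_id_a, p.record_id_b, p.strategy))
    return out


def match_all(
    records: Sequence[EncodedRecord],
    specs: Sequence[FieldComparisonSpec],
    thresholds: ClassificationThresholds,
    strategy_names: Iterable[str],
) -> list[Pair]:
    """Single-process matcher over all blocks (no binning); the reference
    against which the distributed pipeline must be identical."""
    return match_bin(records, specs, thresholds, strategy_names, None)


def estimate_u(
    records: Sequence[EncodedRecord],
    specs: Sequence[FieldComparisonSpec],
    floor: float = 1e-6,
) -> dict[str, float]:
    """Frequency-based u estimate for exact-digest fields.

    u is the expected agreement probability of a random record pair:
    sum_v f_v(f_v - 1)/2 over value frequencies, divided by N(N-1)/2.
    Values are clamped to [floor, 1 - floor] so weights stay finite.  Bloom
    and date fields keep their configured u (returned unchanged).
    """
    n = len(records)
    out: dict[str, float] = {}
    for spec in specs:
        if spec.comparator != "exact_digest" or n < 2:
            out[spec.field] = spec.u
            continue
        freqs: dict[str, int] = {}
        for r in records:
            d = r.digest(spec.field)
            if d is not None:
                freqs[d] = freqs.get(d, 0) + 1
        agree = sum(f * (f - 1) // 2 for f in freqs.values())
        total = n * (n - 1) // 2
        u = agree / total if total else spec.u
        out[spec.field] = min(max(u, floor), 1.0 - floor)
    return out
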