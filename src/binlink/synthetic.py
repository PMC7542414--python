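"""Seeded synthetic person datasets with known ground truth.

Emulates a population-style administrative dataset: base records are drawn
from skewed name frequency tables and a street-address grammar, duplicates
are sampled per entity from a configurable count distribution, and each
duplicate is independently corrupted by a per-field error model (value
replacement, truncation, misspelling, character deletion/insertion,
alternate names, and missing values).

Every dataset carries a hidden ground-truth ``entity_id`` per record so that
pairwise linkage quality can be measured exactly.  All sampling is driven by
a single integer seed; a fixed seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import csv
import string
from dataclasses import dataclass, field, replace as dc_replace
from datetime import date, timedelta
from typing import Iterable, Mapping

import numpy as np

from . import _freqdata
from ._ioutil import open_text as _open_text

__all__ = [
    "PersonRecord",
    "FrequencyTable",
    "ErrorModel",
    "FieldErrors",
    "DuplicateDistribution",
    "default_frequency_tables",
    "default_error_model",
    "sample_base_record",
    "corrupt_record",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "write_truth",
    "read_truth",
]

MISSING = ""

STRING_FIELDS = ("first_name", "middle_name", "last_name", "address")
ALL_FIELDS = (
    "first_name", "middle_name", "last_name", "dob", "sex", "address", "postcode",
)

ERROR_KINDS = (
    "replace", "truncate", "misspell", "delete_char", "insert_char",
    "alternate_name", "set_missing",
)


@dataclass(frozen=True)
class PersonRecord:
    """One raw person row plus its hidden ground-truth entity id."""

    record_id: str
    entity_id: str
    first_name: str = MISSING
    middle_name: str = MISSING
    last_name: str = MISSING
    dob: str = MISSING          # ISO date string, or missing
    sex: str = MISSING          # "M", "F", or missing
    address: str = MISSING
    postcode: str = MISSING

    def get(self, name: str) -> str:
        return getattr(self, name)


@dataclass(frozen=True)
class FrequencyTable:
    """Value frequency table for one field: draws are proportional to counts."""

    field: str
    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        values = [v for v, _ in self.entries]
        if len(set(values)) != len(values):
            raise ValueError(f"duplicate values in frequency table for {self.field!r}")
        if any(c <= 0 for _, c in self.entries):
            raise ValueError(f"non-positive count in frequency table for {self.field!r}")

    @property
    def values(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.entries)

    def probabilities(self) -> np.ndarray:
        counts = np.array([c for _, c in self.entries], dtype=float)
        return counts / counts.sum()

    def sample(self, rng: np.random.Generator) -> str:
        idx = rng.choice(len(self.entries), p=self.probabilities())
        return self.entries[idx][0]


@dataclass(frozen=True)
class FieldErrors:
    """Error rate and error-kind mixture for one field."""

    rate: float
    kinds: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"error rate {self.rate} outside [0, 1]")
        unknown = set(self.kinds) - set(ERROR_KINDS)
        if unknown:
            raise ValueError(f"unknown error kinds: {sorted(unknown)}")
        total = sum(self.kinds.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"error-kind probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class ErrorModel:
    """Per-field error rates and kind mixtures."""

    fields: Mapping[str, FieldErrors]

    def scaled(self, multiplier: float) -> "ErrorModel":
        """Return a copy with every field's error rate scaled (capped at 1)."""
        return ErrorModel({
            name: FieldErrors(min(1.0, fe.rate * multiplier), dict(fe.kinds))
            for name, fe in self.fields.items()
        })


@dataclass(frozen=True)
class DuplicateDistribution:
    """Distribution of the number of duplicates sampled per entity.

    kinds:
      fixed     -- params["count"] duplicates for every entity
      geometric -- rng.geometric(params["p"]) - 1 (mean (1-p)/p)
      zipf      -- rng.zipf(params["a"]) - 1, a heavy tail
    All draws are capped at ``max_duplicates``.
    """

    kind: str = "zipf"
    params: Mapping[str, float] = field(default_factory=lambda: {"a": 2.0})
    max_duplicates: int = 50

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            n = int(self.params["count"])
        elif self.kind == "geometric":
            n = int(rng.geometric(self.params["p"])) - 1
        elif self.kind == "zipf":
            n = int(rng.zipf(self.params["a"])) - 1
        else:
            raise ValueError(f"unknown duplicate distribution kind {self.kind!r}")
        if n < 0:
            raise ValueError("sampled negative duplicate count")
        return min(n, self.max_duplicates)


def default_frequency_tables() -> dict[str, FrequencyTable]:
    """Bundled skewed name tables (middle names reuse the given-name pool)."""
    return {
        "first_name": FrequencyTable("first_name", tuple(_freqdata.FIRST_NAMES)),
        "middle_name": FrequencyTable("middle_name", tuple(_freqdata.FIRST_NAMES)),
        "last_name": FrequencyTable("last_name", tuple(_freqdata.LAST_NAMES)),
    }


def default_error_model() -> ErrorModel:
    """High-error preset: rates deliberately high to stress matching accuracy."""
    name_kinds = {
        "replace": 0.15, "truncate": 0.10, "misspell": 0.25, "delete_char": 0.15,
        "insert_char": 0.10, "alternate_name": 0.10, "set_missing": 0.15,
    }
    return ErrorModel({
        "first_name": FieldErrors(0.25, name_kinds),
        "middle_name": FieldErrors(0.35, {**name_kinds, "set_missing": 0.35,
                                          "misspell": 0.05}),
        "last_name": FieldErrors(0.20, name_kinds),
        "dob": FieldErrors(0.12, {"replace": 0.7, "set_missing": 0.3}),
        "sex": FieldErrors(0.08, {"replace": 0.5, "set_missing": 0.5}),
        "address": FieldErrors(0.40, {"replace": 0.45, "truncate": 0.10,
                                      "misspell": 0.20, "delete_char": 0.10,
                                      "insert_char": 0.05, "set_missing": 0.10}),
        "postcode": FieldErrors(0.12, {"replace": 0.5, "misspell": 0.3,
                                       "set_missing": 0.2}),
    })


# ---------------------------------------------------------------------------
# sampling

_DOB_START = date(1920, 1, 1)
_DOB_DAYS = (date(2006, 1, 1) - _DOB_START).days
_LETTERS = string.ascii_lowercase


def _sample_dob(rng: np.random.Generator) -> str:
    return (_DOB_START + timedelta(days=int(rng.integers(_DOB_DAYS)))).isoformat()


def _sample_address(rng: np.random.Generator) -> str:
    number = int(rng.integers(1, 300))
    name = _freqdata.STREET_NAMES[rng.integers(len(_freqdata.STREET_NAMES))]
    kind = _freqdata.STREET_TYPES[rng.integers(len(_freqdata.STREET_TYPES))]
    return f"{number} {name} {kind}"


def _sample_postcode(rng: np.random.Generator) -> str:
    return str(int(rng.integers(6000, 6800)))


def sample_base_record(
    freq_tables: Mapping[str, FrequencyTable],
    rng: np.random.Generator,
    record_id: str = "r0",
    entity_id: str = "e0",
) -> PersonRecord:
    """Draw one base record; name fields come from the frequency tables."""
    for f in ("first_name", "middle_name", "last_name"):
        table = freq_tables.get(f)
        if table is None or not table.entries:
            raise ValueError(f"missing or empty frequency table for field {f!r}")
    if not _freqdata.STREET_NAMES:
        raise ValueError("address street-name list is empty")
    return PersonRecord(
        record_id=record_id,
        entity_id=entity_id,
        first_name=freq_tables["first_name"].sample(rng),
        middle_name=freq_tables["middle_name"].sample(rng),
        last_name=freq_tables["last_name"].sample(rng),
        dob=_sample_dob(rng),
        sex="M" if rng.random() < 0.5 else "F",
        address=_sample_address(rng),
        postcode=_sample_postcode(rng),
    )


# ---------------------------------------------------------------------------
# corruption

def _misspell(value: str, rng: np.random.Generator) -> str:
    if not value:
        return value
    i = int(rng.integers(len(value)))
    new = _LETTERS[rng.integers(26)]
    while new == value[i]:
        new = _LETTERS[rng.integers(26)]
    return value[:i] + new + value[i + 1:]


def _delete_char(value: str, rng: np.random.Generator) -> str:
    if len(value) < 2:
        return value
    i = int(rng.integers(len(value)))
    return value[:i] + value[i + 1:]


def _insert_char(value: str, rng: np.random.Generator) -> str:
    i = int(rng.integers(len(value) + 1))
    return value[:i] + _LETTERS[rng.integers(26)] + value[i:]


def _truncate(value: str, rng: np.random.Generator) -> str:
    if len(value) < 2:
        return value
    cut = int(rng.integers(1, len(value)))
    return value[:cut]


def _alternate_name(value: str, rng: np.random.Generator) -> str:
    forward = _freqdata.NICKNAMES.get(value)
    if forward is not None:
        return forward
    for full, nick in _freqdata.NICKNAMES.items():
        if nick == value:
            return full
    return _misspell(value, rng)   # no lexicon entry: degrade to a typo


def _replace_value(
    field_name: str,
    freq_tables: Mapping[str, FrequencyTable],
    rng: np.random.Generator,
) -> str:
    if field_name in ("first_name", "middle_name", "last_name"):
        return freq_tables[field_name].sample(rng)
    if field_name == "dob":
        return _sample_dob(rng)
    if field_name == "sex":
        return "M" if rng.random() < 0.5 else "F"
    if field_name == "address":
        return _sample_address(rng)
    if field_name == "postcode":
        return _sample_postcode(rng)
    raise ValueError(f"unknown field {field_name!r}")


def _apply_error(
    field_name: str,
    value: str,
    kind: str,
    freq_tables: Mapping[str, FrequencyTable],
    rng: np.random.Generator,
) -> str:
    # dob must stay a parseable date and sex a category: character-level edits
    # degrade to replacement for those fields.
    if field_name in ("dob", "sex") and kind not in ("replace", "set_missing"):
        kind = "replace"
    if kind == "set_missing":
        return MISSING
    if kind == "replace":
        return _replace_value(field_name, freq_tables, rng)
    if kind == "truncate":
        return _truncate(value, rng)
    if kind == "misspell":
        return _misspell(value, rng)
    if kind == "delete_char":
        return _delete_char(value, rng)
    if kind == "insert_char":
        return _insert_char(value, rng)
    if kind == "alternate_name":
        return _alternate_name(value, rng)
    raise ValueError(f"unknown error kind {kind!r}")


def corrupt_record(
    rec: PersonRecord,
    model: ErrorModel,
    rng: np.random.Generator,
    freq_tables: Mapping[str, FrequencyTable] | None = None,
    record_id: str | None = None,
) -> PersonRecord:
    """Return a corrupted copy: same entity_id, new record_id.

    For each field, with that field's error rate, one error kind is drawn
    from the field's kind mixture and applied.  Missing source values pass
    through unchanged (except ``replace``, which may re-introduce a value's
    worth of noise only on present values).
    """
    freq_tables = freq_tables or default_frequency_tables()
    updates: dict[str, str] = {}
    for field_name, fe in model.fields.items():
        if rng.random() >= fe.rate:
            continue
        value = rec.get(field_name)
        if value == MISSING:
            continue
        kinds = sorted(fe.kinds)
        probs = np.array([fe.kinds[k] for k in kinds])
        kind = kinds[rng.choice(len(kinds), p=probs / probs.sum())]
        updates[field_name] = _apply_error(field_name, value, kind, freq_tables, rng)
    return dc_replace(
        rec,
        record_id=record_id if record_id is not None else rec.record_id + "x",
        **updates,
    )


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(
    n_entities: int,
    dup_dist: DuplicateDistribution | None = None,
    model: ErrorModel | None = None,
    freq_tables: Mapping[str, FrequencyTable] | None = None,
    seed: int = 0,
) -> tuple[list[PersonRecord], dict[str, str]]:
    """Generate ``n_entities`` base records plus per-entity duplicates.

    Returns the record list (base records then duplicates, in entity order)
    and the truth table mapping record_id -> entity_id.  Deterministic for a
    fixed seed.
    """
    if n_entities < 1:
        raise ValueError(f"n_entities must be >= 1, got {n_entities}")
    dup_dist = dup_dist or DuplicateDistribution()
    model = model or default_error_model()
    freq_tables = freq_tables or default_frequency_tables()
    rng = np.random.default_rng(seed)

    records: list[PersonRecord] = []
    truth: dict[str, str] = {}
    serial = 0
    for e in range(n_entities):
        entity_id = f"e{e:06d}"
        base = sample_base_record(
            freq_tables, rng, record_id=f"r{serial:07d}", entity_id=entity_id)
        serial += 1
        records.append(base)
        truth[base.record_id] = entity_id
        for _ in range(dup_dist.sample(rng)):
            dup = corrupt_record(
                base, model, rng, freq_tables, record_id=f"r{serial:07d}")
            serial += 1
            records.append(dup)
            truth[dup.record_id] = entity_id
    return records, truth


# ---------------------------------------------------------------------------
# I/O

DATASET_HEADER = ["record_id", "first_name", "middle_name", "last_name",
                  "dob", "sex", "address", "postcode"]


def write_dataset(records: Iterable[PersonRecord], path) -> None:
    """Write records as CSV (``.gz`` suffix gzips); entity ids are withheld."""
    with _open_text(path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(DATASET_HEADER)
        for r in records:
            w.writerow([r.record_id, r.first_name, r.middle_name, r.last_name,
                        r.dob, r.sex, r.address, r.postcode])


def read_dataset(path) -> list[PersonRecord]:
    """Read a raw dataset CSV; entity ids are unknown (set to empty)."""
    out: list[PersonRecord] = []
    seen: set[str] = set()
    with _open_text(path, "r") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            rid = row.get("record_id") or ""
            if not rid or rid in seen:
                raise ValueError(f"line {i}: missing or duplicate record_id {rid!r}")
            seen.add(rid)
            out.append(PersonRecord(
                record_id=rid, entity_id="",
                first_name=row.get("first_name", ""),
                middle_name=row.get("middle_name", ""),
                last_name=row.get("last_name", ""),
                dob=row.get("dob", ""), sex=row.get("sex", ""),
                address=row.get("address", ""), postcode=row.get("postcode", ""),
            ))
    return out


def write_truth(truth: Mapping[str, str], path) -> None:
    with _open_text(path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "entity_id"])
        for rid, eid in truth.items():
            w.writerow([rid, eid])


def read_truth(path) -> dict[str, str]:
    truth: dict[str, str] = {}
    with _open_text(path, "r") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["record_id", "entity_id"]:
            raise ValueError(f"line 1: bad truth header {header!r}")
        for i, row in enumerate(reader, start=2):
            if len(row) != 2 or not row[0] or not row[1]:
                raise ValueError(f"line {i}: malformed truth row {row!r}")
            if row[0] in truth:
                raise ValueError(f"line {i}: duplicate record_id {row[0]!r}")
            truth[row[0]] = row[1]
    return truth
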