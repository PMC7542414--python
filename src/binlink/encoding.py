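"""Privacy-preserving encoding: Bloom filters and keyed digests.

This is the "on-premises" step of the pipeline.  String identifiers (names,
address) are split into character bigrams and hashed into fixed-length Bloom
filters; structured fields (date-of-birth day/month/year, sex, postcode) are
replaced by keyed SHA-2 digests (HMAC).  Blocking keys are computed from the
raw values and digested before anything leaves this step, so downstream
stages only ever see privacy-preserved artifacts.

Bloom-filter hashing uses the double-hashing construction: two independent
keyed digests h1, h2 of each token give positions h1 + i*h2 (mod filter
length) for i = 0..k-1.  Set-membership semantics match k independent keyed
hashes at a fraction of the digest cost.
"""

from __future__ import annotations

import csv
import hashlib
import hmac
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._ioutil import open_text as _open_text

__all__ = [
    "BloomParams",
    "EncodedRecord",
    "bigrams",
    "bloom_encode",
    "exact_digest",
    "dice_similarity",
    "encode_dataset",
    "write_encoded",
    "read_encoded",
    "MISSING_MARKER",
]

MISSING_MARKER = "␀"

BLOOM_FIELDS = ("first_name", "middle_name", "last_name", "address")
DIGEST_FIELDS = ("dob_day", "dob_month", "dob_year", "sex", "postcode")


@dataclass(frozen=True)
class BloomParams:
    """Bloom-filter parameters: 512-bit filters, 30 hash positions by default."""

    secret_key: bytes
    filter_length_bits: int = 512
    num_hashes: int = 30

    def __post_init__(self) -> None:
        if not self.secret_key:
            raise ValueError("secret_key must be non-empty")
        if self.filter_length_bits <= 0 or self.filter_length_bits % 8:
            raise ValueError("filter_length_bits must be a positive multiple of 8")
        if self.num_hashes < 1:
            raise ValueError("num_hashes must be >= 1")

    @property
    def n_bytes(self) -> int:
        return self.filter_length_bits // 8


@dataclass(frozen=True)
class EncodedRecord:
    """Privacy-preserved record: Bloom filters, field digests, block keys."""

    record_id: str
    blooms: Mapping[str, bytes]            # field -> filter bytes
    digests: Mapping[str, str | None]      # field -> hex digest, None if missing
    block_keys: tuple[tuple[str, str], ...]  # (strategy name, key digest)

    def bloom(self, name: str) -> bytes:
        return self.blooms[name]

    def digest(self, name: str) -> str | None:
        return self.digests[name]


def _normalize(s: str) -> str:
    return "".join(ch for ch in s.lower() if ch.isalnum())


def bigrams(s: str) -> list[str]:
    """Overlapping character 2-grams of the normalized string, unpadded.

    Normalization lowercases and strips non-alphanumerics; inputs shorter
    than two characters yield no tokens.
    """
    t = _normalize(s)
    return [t[i:i + 2] for i in range(len(t) - 1)]


def _hash_pair(token: str, key: bytes) -> tuple[int, int]:
    h1 = hmac.new(key, b"bf1\x00" + token.encode("utf-8"), hashlib.sha256)
    h2 = hmac.new(key, b"bf2\x00" + token.encode("utf-8"), hashlib.sha256)
    return (int.from_bytes(h1.digest()[:8], "big"),
            int.from_bytes(h2.digest()[:8], "big"))


def bloom_encode(tokens: Sequence[str], p: BloomParams) -> bytes:
    """Hash each token ``num_hashes`` times into a filter of the configured length."""
    bits = 0
    L = p.filter_length_bits
    for token in tokens:
        h1, h2 = _hash_pair(token, p.secret_key)
        for i in range(p.num_hashes):
            bits |= 1 << ((h1 + i * h2) % L)
    return bits.to_bytes(p.n_bytes, "big")


def exact_digest(value: str, field_label: str, key: bytes) -> str:
    """Keyed SHA-2 digest of a field value, salted by the field label.

    Equal values under one key map to equal digests; the label salt prevents
    cross-field digest equality.  Missing values must be handled by the
    caller (they map to an explicit marker, never a digest).
    """
    if not key:
        raise ValueError("secret key must be non-empty")
    msg = field_label.encode("utf-8") + b"\x1f" + _normalize(value).encode("utf-8")
    return hmac.new(key, msg, hashlib.sha256).hexdigest()


def dice_similarity(a: bytes, b: bytes) -> float:
    """Dice coefficient 2|a∧b| / (|a|+|b|) of two equal-length bit vectors."""
    if len(a) != len(b):
        raise ValueError(f"filter length mismatch: {len(a)} vs {len(b)} bytes")
    ia = int.from_bytes(a, "big")
    ib = int.from_bytes(b, "big")
    denom = ia.bit_count() + ib.bit_count()
    if denom == 0:
        return 0.0
    return 2.0 * (ia & ib).bit_count() / denom


def _split_dob(dob: str) -> tuple[str, str, str]:
    y, m, d = dob.split("-")
    return d, m, y


def encode_record(rec, params: BloomParams, strategies=None) -> EncodedRecord:
    """Encode one raw record (see :func:`encode_dataset`)."""
    from . import blocking  # late import: blocking uses exact_digest

    blooms = {
        f: bloom_encode(bigrams(rec.get(f)), params) for f in BLOOM_FIELDS
    }
    digests: dict[str, str | None] = {}
    if rec.dob:
        day, month, year = _split_dob(rec.dob)
        digests["dob_day"] = exact_digest(day, "dob_day", params.secret_key)
        digests["dob_month"] = exact_digest(month, "dob_month", params.secret_key)
        digests["dob_year"] = exact_digest(year, "dob_year", params.secret_key)
    else:
        digests["dob_day"] = digests["dob_month"] = digests["dob_year"] = None
    for f in ("sex", "postcode"):
        v = rec.get(f)
        digests[f] = exact_digest(v, f, params.secret_key) if v else None

    keys: tuple[tuple[str, str], ...] = ()
    if strategies:
        keys = tuple(blocking.block_keys(rec, strategies, params.secret_key))
    return EncodedRecord(rec.record_id, blooms, digests, keys)


def encode_dataset(records, params: BloomParams, strategies=None) -> list[EncodedRecord]:
    """Encode a raw dataset into its privacy-preserved form.

    One output row per input record; the ground-truth entity id (if any) is
    never carried through.  Duplicate record ids are rejected.
    """
    seen: set[str] = set()
    out: list[EncodedRecord] = []
    for rec in records:
        if rec.record_id in seen:
            raise ValueError(f"duplicate record_id {rec.record_id!r}")
        seen.add(rec.record_id)
        out.append(encode_record(rec, params, strategies))
    return out


# ---------------------------------------------------------------------------
# serialization

ENCODED_HEADER = (
    ["record_id"]
    + [f"bf_{f}" for f in BLOOM_FIELDS]
    + [f"dg_{f}" for f in DIGEST_FIELDS]
    + ["block_keys"]
)


def write_encoded(records: Iterable[EncodedRecord], path) -> None:
    """Serialize encoded records: hex Bloom filters, hex digests, key list."""
    with _open_text(path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(ENCODED_HEADER)
        for r in records:
            row = [r.record_id]
            row += [r.blooms[f].hex() for f in BLOOM_FIELDS]
            row += [r.digests[f] if r.digests[f] is not None else MISSING_MARKER
                    for f in DIGEST_FIELDS]
            row.append(";".join(f"{s}:{d}" for s, d in r.block_keys))
            w.writerow(row)


def read_encoded(path) -> list[EncodedRecord]:
    out: list[EncodedRecord] = []
    with _open_text(path, "r") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            blooms = {f: bytes.fromhex(row[f"bf_{f}"]) for f in BLOOM_FIELDS}
            digests = {
                f: (None if row[f"dg_{f}"] == MISSING_MARKER else row[f"dg_{f}"])
                for f in DIGEST_FIELDS
            }
            raw = row["block_keys"]
            keys = tuple(
                tuple(part.split(":", 1)) for part in raw.split(";") if part
            )
            out.append(EncodedRecord(row["record_id"], blooms, digests, keys))
    return out
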