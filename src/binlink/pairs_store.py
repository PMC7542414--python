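"""Merged pairs table: de-duplication, entity grouping, and analytics.

Overlapping blocking passes produce the same record pair from more than one
strategy; duplicates are removed after classification, keeping the row with
the maximal score (ties broken by strategy name).  Matches at or above the
match threshold are grouped by transitive closure into entity groups, and
the de-duplicated table answers the standard post-linkage queries: pair
count, score histogram, and pairs within a score range.
"""

from __future__ import annotations

import csv
import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._ioutil import open_text
from .matching import Pair

__all__ = [
    "PairsTable",
    "EntityGroup",
    "write_pairs",
    "read_pairs",
    "dedupe_pairs",
    "merge_pairs",
    "group_entities",
    "write_groups",
    "score_histogram",
    "pairs_in_range",
    "linkage_quality",
]

PAIR_COLUMNS = ["record_id_a", "record_id_b", "score", "strategy"]


def _weight_columns(field_names: Sequence[str]) -> list[str]:
    return [f"w_{f}" for f in field_names]


@dataclass(frozen=True)
class PairsTable:
    """De-duplicated pairs spanning all bins, with pair accounting."""

    frame: pd.DataFrame        # one row per unique unordered id pair
    total_pairs: int           # rows before de-duplication
    unique_pairs: int          # rows after

    def __post_init__(self) -> None:
        if self.unique_pairs > self.total_pairs:
            raise ValueError("unique_pairs cannot exceed total_pairs")


@dataclass(frozen=True)
class EntityGroup:
    """Transitive-closure group of record ids linked by match pairs."""

    group_id: str
    members: frozenset[str]


def write_pairs(pairs: Iterable[Pair], path, field_names: Sequence[str]) -> None:
    """Per-bin pairs file: gzip CSV with per-field weight columns."""
    with open_text(path, "w") as fh:
        w = csv.writer(fh)
        w.writerow(PAIR_COLUMNS + _weight_columns(field_names))
        # repr gives the shortest digit string that round-trips the float,
        # so scores survive serialization exactly
        for p in pairs:
            w.writerow([p.record_id_a, p.record_id_b,
                        repr(float(p.score)), p.strategy]
                       + [repr(float(x)) for x in p.field_weights])


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"record_id_a": str, "record_id_b": str,
                                  "strategy": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pairs file {path} lacks columns {missing}")
    return df


def dedupe_pairs(
    sources: Sequence,
    keep: str = "max_score",
) -> PairsTable:
    """Merge pair files/frames and drop duplicate unordered id pairs.

    ``keep='max_score'`` retains the row with the highest score (ties broken
    by strategy name order); ``keep='first'`` retains the first occurrence in
    input order, for bit-exact replay of a previous run.
    """
    if keep not in ("max_score", "first"):
        raise ValueError(f"unknown keep policy {keep!r}")
    frames = []
    schema: list[str] | None = None
    for src in sources:
        df = src if isinstance(src, pd.DataFrame) else read_pairs(src)
        if schema is None:
            schema = list(df.columns)
        elif list(df.columns) != schema:
            raise ValueError(
                f"pairs schema mismatch: {list(df.columns)} vs {schema}")
        frames.append(df)
    if not frames:
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        return PairsTable(empty, 0, 0)
    merged = pd.concat(frames, ignore_index=True)
    total = len(merged)
    if keep == "max_score":
        merged = merged.sort_values(
            ["record_id_a", "record_id_b", "score", "strategy"],
            ascending=[True, True, False, True], kind="mergesort")
    else:
        merged = merged.sort_values(
            ["record_id_a", "record_id_b"], kind="mergesort")  # stable
    deduped = merged.drop_duplicates(
        ["record_id_a", "record_id_b"], keep="first").reset_index(drop=True)
    return PairsTable(deduped, total, len(deduped))


def merge_pairs(pair_paths: Sequence, out_dir, keep: str = "max_score") -> PairsTable:
    """Catalogue per-bin pair files into one logical table.

    Writes the de-duplicated table as ``pairs.csv.gz`` plus ``manifest.json``
    listing the member files and their row counts — a single queryable table
    backed by a series of individual text files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = dedupe_pairs(pair_paths, keep=keep)
    out_path = out_dir / "pairs.csv.gz"
    csv_text = table.frame.to_csv(index=False)
    out_path.write_bytes(gzip.compress(csv_text.encode("utf-8"), mtime=0))
    manifest = {
        "members": [
            {"path": str(Path(p).name), "rows": int(len(read_pairs(p)))}
            for p in pair_paths
        ],
        "total_pairs": table.total_pairs,
        "unique_pairs": table.unique_pairs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def group_entities(table: PairsTable, match_threshold: float) -> list[EntityGroup]:
    """Connected components of the match graph (score >= threshold).

    Group ids are the lexicographically smallest member record id, and the
    group list is sorted by group id.
    """
    matched = table.frame[table.frame["score"] >= match_threshold]
    g = nx.Graph()
    g.add_edges_from(zip(matched["record_id_a"], matched["record_id_b"]))
    groups = [
        EntityGroup(min(comp), frozenset(comp))
        for comp in nx.connected_components(g)
    ]
    groups.sort(key=lambda grp: grp.group_id)
    return groups


def write_groups(groups: Sequence[EntityGroup], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["group_id", "record_id"])
        for grp in groups:
            for rid in sorted(grp.members):
                w.writerow([grp.group_id, rid])


def score_histogram(
    table: PairsTable, bin_width: float
) -> list[tuple[float, int]]:
    """Histogram of pair scores in half-open bins [x, x+w) from the minimum.

    Returns (bin left edge, count) for every bin from min to max score; the
    counts sum to the pair count.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    scores = table.frame["score"].to_numpy()
    if len(scores) == 0:
        return []
    lo = float(scores.min())
    idx = np.floor((scores - lo) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    return [(lo + k * bin_width, int(counts[k])) for k in range(n_bins)]


def pairs_in_range(table: PairsTable, lo: float, hi: float) -> pd.DataFrame:
    """Pairs with lo <= score < hi (e.g. the score range 15-16 query)."""
    f = table.frame
    return f[(f["score"] >= lo) & (f["score"] < hi)].reset_index(drop=True)


def linkage_quality(
    table: PairsTable,
    truth: Mapping[str, str],
    match_threshold: float,
    record_ids: Iterable[str] | None = None,
) -> dict[str, float]:
    """Pairwise precision/recall/F1 of match pairs against ground truth.

    True pairs are all unordered pairs of records sharing an entity id among
    ``record_ids`` (defaults to every id in the truth table).  Empty
    predicted sets have precision 1.0 by convention, empty truth sets recall
    1.0, so the metrics are total.
    """
    ids = set(record_ids) if record_ids is not None else set(truth)
    predicted = set()
    matched = table.frame[table.frame["score"] >= match_threshold]
    for a, b in zip(matched["record_id_a"], matched["record_id_b"]):
        if a not in truth or b not in truth:
            raise KeyError(f"record id {a if a not in truth else b!r} not in truth")
        predicted.add((a, b) if a < b else (b, a))

    by_entity: dict[str, list[str]] = {}
    for rid in sorted(ids):
        by_entity.setdefault(truth[rid], []).append(rid)
    n_true = sum(len(m) * (len(m) - 1) // 2 for m in by_entity.values())
    tp = sum(1 for a, b in predicted if truth[a] == truth[b])

    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / n_true if n_true else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "true_pairs": float(n_true), "predicted_pairs": float(len(predicted)),
            "true_positives": float(tp)}
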