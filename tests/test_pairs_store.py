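"""Pairs table: de-duplication, grouping, analytics, linkage quality."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import binlink as bl
from binlink.matching import Pair
from binlink.pairs_store import (PairsTable, pairs_in_range, score_histogram)

FIELDS = ("first_name", "last_name")


def mk_pair(a, b, score, strategy="name"):
    return Pair(a, b, score, strategy, (score / 2, score / 2))


def frame_of(pairs):
    return pd.DataFrame({
        "record_id_a": [p.record_id_a for p in pairs],
        "record_id_b": [p.record_id_b for p in pairs],
        "score": [p.score for p in pairs],
        "strategy": [p.strategy for p in pairs],
    })


class TestDedupe:
    def test_same_pair_from_two_strategies(self):
        table = bl.dedupe_pairs([frame_of([
            mk_pair("r1", "r2", 18.2, "name"),
            mk_pair("r1", "r2", 18.2, "dobsex"),
        ])])
        assert (table.total_pairs, table.unique_pairs) == (2, 1)
        assert table.frame.iloc[0]["strategy"] == "dobsex"   # tie: name order

    def test_keeps_max_score(self):
        table = bl.dedupe_pairs([frame_of([
            mk_pair("r1", "r2", 12.0, "name"),
            mk_pair("r1", "r2", 20.0, "dobsex"),
        ])])
        assert table.frame.iloc[0]["score"] == 20.0

    def test_keep_first_policy(self):
        table = bl.dedupe_pairs([frame_of([
            mk_pair("r1", "r2", 12.0, "name"),
            mk_pair("r1", "r2", 20.0, "dobsex"),
        ])], keep="first")
        assert table.frame.iloc[0]["score"] == 12.0

    def test_disjoint_files_concatenate(self):
        a = frame_of([mk_pair(f"a{i}", f"b{i}", 10.0) for i in range(10)])
        b = frame_of([mk_pair(f"c{i}", f"d{i}", 10.0) for i in range(15)])
        table = bl.dedupe_pairs([a, b])
        assert (table.total_pairs, table.unique_pairs) == (25, 25)

    def test_unique_set_equals_hash_set_oracle(self):
        rng = np.random.default_rng(17)
        pairs = [
            mk_pair(f"r{rng.integers(30):02d}", f"s{rng.integers(30):02d}",
                    float(rng.integers(10, 30)),
                    ("name", "dobsex")[rng.integers(2)])
            for _ in range(400)
        ]
        table = bl.dedupe_pairs([frame_of(pairs)])
        oracle = {(p.record_id_a, p.record_id_b) for p in pairs}
        got = set(zip(table.frame["record_id_a"], table.frame["record_id_b"]))
        assert got == oracle

    def test_schema_mismatch_rejected(self):
        a = frame_of([mk_pair("r1", "r2", 10.0)])
        b = a.rename(columns={"score": "weight"})
        with pytest.raises(ValueError, match="schema"):
            bl.dedupe_pairs([a, b])


class TestGrouping:
    def test_transitive_chain_forms_one_group(self):
        table = bl.dedupe_pairs([frame_of([
            mk_pair("r1", "r2", 30.0), mk_pair("r2", "r3", 30.0),
        ])])
        groups = bl.group_entities(table, match_threshold=25.0)
        assert len(groups) == 1
        assert groups[0].members == frozenset({"r1", "r2", "r3"})
        assert groups[0].group_id == "r1"

    def test_no_pairs_above_threshold_no_groups(self):
        table = bl.dedupe_pairs([frame_of([mk_pair("r1", "r2", 10.0)])])
        assert bl.group_entities(table, match_threshold=25.0) == []

    def test_components_equal_union_find_oracle(self):
        # independent second implementation: plain union-find
        rng = np.random.default_rng(23)
        edges = [(f"n{rng.integers(300):03d}", f"n{rng.integers(300):03d}")
                 for _ in range(1000)]
        edges = [(a, b) for a, b in edges if a != b]
        table = bl.dedupe_pairs([frame_of(
            [mk_pair(*sorted(e), 30.0) for e in edges])])

        parent: dict[str, str] = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for a, b in edges:
            union(a, b)
        oracle: dict[str, set[str]] = {}
        for n in parent:
            oracle.setdefault(find(n), set()).add(n)
        expected = sorted(frozenset(s) for s in oracle.values())

        got = sorted(g.members for g in bl.group_entities(table, 25.0))
        assert got == expected


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(31)
    n = 5000
    scores = rng.uniform(10.0, 40.0, n)
    frame = pd.DataFrame({
        "record_id_a": [f"a{i:05d}" for i in range(n)],
        "record_id_b": [f"b{i:05d}" for i in range(n)],
        "score": scores,
        "strategy": ["name"] * n,
    })
    return PairsTable(frame, n, n)


class TestAnalytics:
    def test_histogram_conserves_count(self, table):
        hist = score_histogram(table, 1.0)
        assert sum(c for _e, c in hist) == table.unique_pairs

    def test_histogram_equals_linear_scan(self, table):
        hist = score_histogram(table, 2.5)
        scores = table.frame["score"].to_numpy()
        lo = scores.min()
        for edge, count in hist:
            assert count == int(((scores >= edge) & (scores < edge + 2.5)).sum())

    def test_range_query_equals_filter_oracle(self, table):
        sub = pairs_in_range(table, 15.0, 16.0)
        scores = table.frame["score"]
        assert len(sub) == int(((scores >= 15.0) & (scores < 16.0)).sum())

    def test_full_range_returns_all(self, table):
        sub = pairs_in_range(table, -np.inf, np.inf)
        assert len(sub) == table.unique_pairs

    def test_non_positive_bin_width_rejected(self, table):
        with pytest.raises(ValueError):
            score_histogram(table, 0.0)


class TestLinkageQuality:
    def test_perfect_output(self):
        truth = {"r1": "e1", "r2": "e1", "r3": "e2"}
        table = bl.dedupe_pairs([frame_of([mk_pair("r1", "r2", 30.0)])])
        q = bl.linkage_quality(table, truth, 25.0)
        assert q["precision"] == 1.0 and q["recall"] == 1.0 and q["f1"] == 1.0

    def test_empty_output_convention(self):
        truth = {"r1": "e1", "r2": "e1"}
        table = bl.dedupe_pairs([])
        q = bl.linkage_quality(table, truth, 25.0)
        assert q["precision"] == 1.0     # documented convention
        assert q["recall"] == 0.0

    def test_unknown_record_id_rejected(self):
        table = bl.dedupe_pairs([frame_of([mk_pair("r1", "zz", 30.0)])])
        with pytest.raises(KeyError):
            bl.linkage_quality(table, {"r1": "e1"}, 25.0)

    def test_confusion_counts_match_brute_force(self, small_dataset, config,
                                                small_encoded):
        from itertools import combinations
        _records, truth = small_dataset
        pairs = bl.match_all(small_encoded, config.field_specs,
                             config.thresholds, config.strategy_names)
        table = bl.dedupe_pairs([frame_of(pairs)])
        q = bl.linkage_quality(table, truth, config.thresholds.match)

        predicted = {
            (a, b) for a, b, s in zip(table.frame["record_id_a"],
                                      table.frame["record_id_b"],
                                      table.frame["score"]) if s >= config.thresholds.match
        }
        tp = fp = 0
        for a, b in predicted:
            if truth[a] == truth[b]:
                tp += 1
            else:
                fp += 1
        fn = sum(
            1 for x, y in combinations(sorted(truth), 2)
            if truth[x] == truth[y] and (x, y) not in predicted
        )
        assert q["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 1.0)
        assert q["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 1.0)


def test_pairs_file_round_trip(tmp_path):
    pairs = [mk_pair("r1", "r2", 18.25), mk_pair("r1", "r3", 31.5, "dobsex")]
    path = tmp_path / "pairs.csv.gz"
    bl.write_pairs(pairs, path, FIELDS)
    df = bl.read_pairs(path)
    assert list(df["record_id_b"]) == ["r2", "r3"]
    assert list(df["score"]) == [18.25, 31.5]
    assert list(df.columns) == ["record_id_a", "record_id_b", "score",
                                "strategy", "w_first_name", "w_last_name"]


def test_merge_writes_manifest(tmp_path):
    a = tmp_path / "pairs-0000.csv.gz"
    b = tmp_path / "pairs-0001.csv.gz"
    bl.write_pairs([mk_pair("r1", "r2", 20.0)], a, FIELDS)
    bl.write_pairs([mk_pair("r1", "r2", 22.0, "dobsex")], b, FIELDS)
    table = bl.merge_pairs([a, b], tmp_path / "merged")
    assert (table.total_pairs, table.unique_pairs) == (2, 1)
    import json
    manifest = json.loads((tmp_path / "merged" / "manifest.json").read_text())
    assert manifest["unique_pairs"] == 1
    assert len(manifest["members"]) == 2
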