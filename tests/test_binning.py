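"""Bin planning: round-robin balance, discard rule, conservation, splitting."""

from __future__ import annotations

import numpy as np
import pytest

import binlink as bl
from binlink.blocking import BlockStats, comparison_space_self


def stats_from_spaces(spaces, strategy="s"):
    """Build BlockStats whose keys have the given comparison spaces.

    Comparison space c = f(f-1)/2, so f is recovered by inverting; only
    triangular numbers are representable, so tests use frequencies instead
    where that matters.
    """
    freqs = {}
    for i, c in enumerate(spaces):
        # find f with f(f-1)/2 == c (caller passes triangular numbers)
        f = int((1 + np.sqrt(1 + 8 * c)) / 2)
        assert comparison_space_self(f) == c, f"{c} is not triangular"
        freqs[f"k{i:03d}"] = f
    return BlockStats(strategy, freqs)


class TestPlanBins:
    def test_single_bin_when_total_below_max(self):
        st = stats_from_spaces([10, 6, 3, 1])
        plan = bl.plan_bins([st], max_space=100)
        assert plan.bin_count == 1
        assert plan.bin_spaces == (20,)

    def test_forced_two_bins_round_robin(self):
        # largest->bin0, next->bin1, next->bin0, ... per the dealing rule
        st = stats_from_spaces([10, 6, 3, 1])
        plan = bl.plan_bins([st], max_space=100, force_bins=2)
        assert plan.bin_spaces == (13, 7)   # {10,3} and {6,1}

    def test_round_robin_matches_independent_oracle(self):
        # independent re-implementation: sort by (-c, digest, strategy),
        # deal i -> i mod B
        rng = np.random.default_rng(21)
        freqs = {f"k{i:04d}": int(rng.integers(1, 40)) for i in range(500)}
        st = BlockStats("s", freqs)
        total = st.total_space
        m = max(1, total // 8)
        plan = bl.plan_bins([st], max_space=m)

        items = sorted(
            ((digest, comparison_space_self(f)) for digest, f in freqs.items()
             if comparison_space_self(f) <= m),
            key=lambda kv: (-kv[1], kv[0]))
        expected = [0] * plan.bin_count
        for i, (_d, c) in enumerate(items):
            expected[i % plan.bin_count] += c
        assert list(plan.bin_spaces) == expected

    def test_conservation_with_discards(self):
        rng = np.random.default_rng(3)
        freqs = {f"k{i}": int(rng.integers(1, 60)) for i in range(200)}
        st = BlockStats("s", freqs)
        plan = bl.plan_bins([st], max_space=300)
        assert plan.total_assigned_space + plan.discarded_space == st.total_space

    def test_space_discard_rule(self):
        st = BlockStats("s", {"big": 10, "small": 3})   # c = 45 and 3
        plan = bl.plan_bins([st], max_space=20)
        assert [d[0:2] for d in plan.discarded] == [("s", "big")]
        assert ("s", "small") in plan.assignment

    def test_frequency_discard_rule(self):
        st = BlockStats("s", {"big": 10, "small": 3})
        plan = bl.plan_bins([st], max_space=20, discard_rule="frequency")
        assert plan.discarded == ()        # both f below 20
        plan2 = bl.plan_bins([st], max_space=5, discard_rule="frequency")
        assert [d[1] for d in plan2.discarded] == ["big"]

    def test_decreasing_max_space_never_decreases_bins(self):
        # holds whenever the discarded set is unchanged, so keep every key's
        # space below the smallest M probed (a smaller M can otherwise
        # discard more keys and shrink the remaining space)
        rng = np.random.default_rng(8)
        freqs = {f"k{i}": int(rng.integers(1, 20)) for i in range(150)}
        st = BlockStats("s", freqs)
        assert max(comparison_space_self(f) for f in freqs.values()) <= 200
        counts = [bl.plan_bins([st], m).bin_count
                  for m in (5000, 2000, 1000, 500, 200)]
        assert counts == sorted(counts)

    def test_balance_on_well_conditioned_fixture(self):
        # >= 100 keys, no key above M/4 -> max bin space <= 1.5x mean
        rng = np.random.default_rng(13)
        freqs = {f"k{i:04d}": int(rng.integers(2, 30)) for i in range(300)}
        st = BlockStats("s", freqs)
        total = st.total_space
        m = total // 10
        assert max(comparison_space_self(f) for f in freqs.values()) <= m / 4
        plan = bl.plan_bins([st], max_space=m)
        mean = np.mean(plan.bin_spaces)
        assert max(plan.bin_spaces) <= 1.5 * mean

    def test_invalid_max_space_rejected(self):
        with pytest.raises(ValueError):
            bl.plan_bins([BlockStats("s", {"a": 2})], max_space=0)


class TestSplitDataset:
    def test_shared_key_single_bin(self, config, tmp_path):
        recs = [
            bl.PersonRecord(f"r{i}", f"e{i}", first_name="ann",
                            last_name="smith", dob=f"19{i}0-01-01", sex="F")
            for i in range(4)
        ]
        encoded = bl.encode_dataset(recs, config.bloom_params,
                                    config.strategies)
        stats = [bl.block_frequencies(encoded, s)
                 for s in config.strategy_names]
        plan = bl.plan_bins(stats, max_space=100)
        paths = bl.split_dataset(encoded, plan, tmp_path)
        non_empty = [p for p in paths if len(bl.read_encoded(p)) > 0]
        assert len(non_empty) == 1
        assert len(bl.read_encoded(non_empty[0])) == 4

    def test_record_copied_to_every_key_bin_once(self, small_encoded, config,
                                                 tmp_path):
        # multiset oracle: recompute each record's bins from the plan
        stats = [bl.block_frequencies(small_encoded, s)
                 for s in config.strategy_names]
        plan = bl.plan_bins(stats, max_space=50)
        assert plan.bin_count >= 2
        paths = bl.split_dataset(small_encoded, plan, tmp_path)
        discarded = {(s, d) for s, d, _f, _c in plan.discarded}
        expected: dict[int, set[str]] = {b: set()
                                         for b in range(plan.bin_count)}
        for rec in small_encoded:
            for key in rec.block_keys:
                if key in discarded:
                    continue
                expected[plan.assignment[key]].add(rec.record_id)
        for b, path in enumerate(paths):
            members = [r.record_id for r in bl.read_encoded(path)]
            assert len(members) == len(set(members))   # at most once per bin
            assert set(members) == expected[b]

    def test_unknown_key_is_consistency_error(self, config, tmp_path):
        recs = [bl.PersonRecord("r1", "e1", first_name="ann",
                                last_name="smith", dob="1970-01-01", sex="F")]
        encoded = bl.encode_dataset(recs, config.bloom_params,
                                    config.strategies)
        plan = bl.plan_bins([BlockStats("name", {})], max_space=10)
        with pytest.raises(ValueError, match="neither"):
            bl.split_dataset(encoded, plan, tmp_path)

    def test_per_bin_space_recomputed_from_files_conserves_total(
            self, small_encoded, config, tmp_path):
        # conservation from the bin files' own frequencies, restricted to
        # the keys assigned to each bin
        stats = [bl.block_frequencies(small_encoded, s)
                 for s in config.strategy_names]
        total = sum(st.total_space for st in stats)
        plan = bl.plan_bins(stats, max_space=60)
        paths = bl.split_dataset(small_encoded, plan, tmp_path)
        recomputed = 0
        for b, path in enumerate(paths):
            records = bl.read_encoded(path)
            assigned = plan.keys_of_bin(b)
            for s in config.strategy_names:
                stb = bl.block_frequencies(records, s)
                recomputed += sum(
                    comparison_space_self(f)
                    for digest, f in stb.frequencies.items()
                    if (s, digest) in assigned)
        assert recomputed == total - plan.discarded_space

    def test_no_pair_compared_twice_under_one_strategy(self, small_encoded,
                                                       config, tmp_path):
        stats = [bl.block_frequencies(small_encoded, s)
                 for s in config.strategy_names]
        plan = bl.plan_bins(stats, max_space=60)
        paths = bl.split_dataset(small_encoded, plan, tmp_path)
        seen: set[tuple[str, str, str]] = set()
        for b, path in enumerate(paths):
            records = bl.read_encoded(path)
            for cand in bl.candidate_pairs(records, config.strategy_names,
                                           plan.keys_of_bin(b)):
                assert cand not in seen
                seen.add(cand)


def test_plan_round_trip(tmp_path):
    rng = np.random.default_rng(2)
    freqs = {f"k{i}": int(rng.integers(1, 50)) for i in range(80)}
    plan = bl.plan_bins([BlockStats("s", freqs)], max_space=200)
    bl.write_plan(plan, tmp_path / "plan.csv")
    back = bl.read_plan(tmp_path / "plan.csv")
    assert back == plan
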