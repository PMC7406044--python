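from collections import Counter

import numpy as np
import pytest
from scipy import stats as sps

import blockrand as br
from blockrand.fixtures import enumerate_all_block_sets
from blockrand.generator import UniqueSampler


class TestCanonicalKey:
    def test_within_block_order_irrelevant(self):
        a = br.BlockSet(blocks=(frozenset("ab"), frozenset("cd")))
        b = br.BlockSet(blocks=(frozenset("ba"), frozenset("dc")))
        assert br.canonical_key(a) == br.canonical_key(b)

    def test_equal_size_blocks_unlabeled(self):
        a = br.BlockSet(blocks=(frozenset("ab"), frozenset("cd")))
        b = br.BlockSet(blocks=(frozenset("cd"), frozenset("ab")))
        assert br.canonical_key(a) == br.canonical_key(b)

    def test_different_partition_different_key(self):
        a = br.BlockSet(blocks=(frozenset("ab"), frozenset("cde")))
        b = br.BlockSet(blocks=(frozenset("cd"), frozenset("abe")))
        assert br.canonical_key(a) != br.canonical_key(b)

    def test_leftover_distinguished_from_block(self):
        # same groups of ids, but one as a block vs as the leftover pool
        a = br.BlockSet(blocks=(frozenset("ab"), frozenset("cd")))
        b = br.BlockSet(blocks=(frozenset("ab"),), leftover=frozenset("cd"))
        assert br.canonical_key(a) != br.canonical_key(b)

    def test_key_distinct_across_all_unique_sets(self):
        cohort = br.generate_cohort(n_units=10, marker_labels=(), rng=0)
        keys = {
            br.canonical_key(bs)
            for bs in enumerate_all_block_sets(cohort, (3, 3))
        }
        assert len(keys) == br.count_unique_block_sets(10, (3, 3)).total_unique


class TestSampleBlockSet:
    def test_single_block_holds_everything(self, tiny_cohort):
        bs = br.sample_block_set(tiny_cohort, br.BlockDesign(block_sizes=(4,)), rng=0)
        assert bs.blocks[0] == frozenset("abcd")
        assert not bs.leftover

    def test_uniform_over_the_three_pairings(self, tiny_cohort):
        design = br.BlockDesign(block_sizes=(2, 2))
        rng = np.random.default_rng(42)
        counts = Counter(
            br.canonical_key(br.sample_block_set(tiny_cohort, design, rng=rng))
            for _ in range(30_000)
        )
        assert len(counts) == 3
        _, p = sps.chisquare(list(counts.values()))
        assert p > 1e-4  # uniform at 3 sigma-ish

    def test_fixed_unit_lands_in_each_block_with_equal_probability(self):
        cohort = br.generate_cohort(n_units=24, marker_labels=(), rng=0)
        design = br.BlockDesign(block_sizes=(6, 6, 6, 6))
        rng = np.random.default_rng(7)
        hits = np.zeros(4)
        uid = cohort.ids[0]
        draws = 8000
        for _ in range(draws):
            bs = br.sample_block_set(cohort, design, rng=rng)
            for j, block in enumerate(bs.blocks):
                if uid in block:
                    hits[j] += 1
        assert hits.sum() == draws
        _, p = sps.chisquare(hits)
        assert p > 1e-4


class TestUniqueSampler:
    def test_registry_yields_distinct_canonical_rows(self):
        sampler = UniqueSampler(8, (3, 3), rng=0, batch_size=64)
        rows = [
            tuple(row)
            for canon, _ in sampler.take(target=10**9, max_attempts=3000)
            for row in canon
        ]
        assert len(rows) == len(set(rows))
        assert sampler.attempts == sampler.unique + sampler.duplicates
        # full exhaustion of the 280 unique sets
        assert sampler.unique == br.count_unique_block_sets(8, (3, 3)).total_unique

    def test_canonical_rows_sorted_within_and_between_blocks(self):
        sampler = UniqueSampler(9, (2, 2, 4), rng=1)
        for canon, _ in sampler.take(target=50, max_attempts=10_000):
            for row in canon:
                b1, b2, b4 = row[:2], row[2:4], row[4:]
                assert list(b1) == sorted(b1) and list(b2) == sorted(b2)
                assert list(b4) == sorted(b4)
                assert b1[0] < b2[0]  # equal-size blocks ordered by minimum


class TestRunEngine:
    def test_target_one(self, s1_cohort):
        board, stats = br.run_engine(
            s1_cohort,
            br.BlockDesign(block_sizes=(8, 8)),
            br.StopCriteria(target_unique=1),
            rng=0,
        )
        assert len(board) == 1
        assert stats.unique_created == 1
        assert stats.attempts == 1

    def test_deterministic_given_seed(self, s1_cohort, s1_design):
        runs = [
            br.run_engine(
                s1_cohort, s1_design, br.StopCriteria(target_unique=400), rng=99
            )
            for _ in range(2)
        ]
        (b1, s1), (b2, s2) = runs
        assert s1 == s2
        assert b1.scores == b2.scores
        assert [e.block_set.to_dict() for e in b1] == [
            e.block_set.to_dict() for e in b2
        ]

    def test_attempts_account_for_duplicates(self, s1_cohort):
        _, stats = br.run_engine(
            s1_cohort,
            br.BlockDesign(block_sizes=(8, 8)),
            br.StopCriteria(target_fraction=0.5),
            rng=5,
        )
        assert stats.attempts == stats.unique_created + stats.duplicates_rejected
        assert stats.unique_created == 3218

    def test_attempt_cap_reported_not_fatal(self, s1_cohort):
        _, stats = br.run_engine(
            s1_cohort,
            br.BlockDesign(block_sizes=(8, 8)),
            br.StopCriteria(target_fraction=1.0, max_attempts=500),
            rng=5,
        )
        assert stats.capped
        assert stats.attempts == 500
        assert stats.unique_created < stats.target

    def test_leaderboard_matches_exhaustive_best(self, s1_cohort, s1_all_scores):
        board, stats = br.run_engine(
            s1_cohort,
            br.BlockDesign(block_sizes=(8, 8), leaderboard_capacity=10),
            br.StopCriteria(target_fraction=1.0),
            rng=11,
        )
        assert stats.unique_created == s1_all_scores.total_unique
        expected = np.sort(s1_all_scores.scores)[:10]
        assert np.allclose(np.array(board.scores), expected, atol=1e-12)

    def test_marker_modifications_attached_iff_subgroups(self, s1_cohort, s1_design):
        board, _ = br.run_engine(
            s1_cohort, s1_design, br.StopCriteria(target_unique=50), rng=2
        )
        assert all(e.marker_modifications is not None for e in board)
        board2, _ = br.run_engine(
            s1_cohort,
            br.BlockDesign(block_sizes=(8, 8)),
            br.StopCriteria(target_unique=50),
            rng=2,
        )
        assert all(e.marker_modifications is None for e in board2)


class TestLeaderboard:
    def test_bounded_sorted_eviction(self):
        lb = br.Leaderboard(capacity=3)
        for seq, score in enumerate([5.0, 1.0, 3.0, 2.0, 4.0]):
            lb.add(score, seq, f"p{seq}")
        assert lb.scores == [1.0, 2.0, 3.0]
        assert lb.entries == ["p1", "p3", "p2"]

    def test_first_discovered_wins_ties(self):
        lb = br.Leaderboard(capacity=2)
        lb.add(1.0, 0, "first")
        lb.add(1.0, 1, "second")
        lb.add(1.0, 2, "third")
        assert lb.entries == ["first", "second"]
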