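import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import blockrand as br
from blockrand.model import ExperimentalUnit
from blockrand.ranking import batch_ranking_values

from conftest import pure_python_score


def one_cov_cohort(values, markers=False):
    units = tuple(
        ExperimentalUnit(id=f"u{k}", covariates=(float(v),))
        for k, v in enumerate(values)
    )
    return br.CohortTable(covariate_names=("x",), units=units)


class TestSummarizeCovariate:
    def test_hand_computed_toy(self, tiny_cohort):
        bs = br.BlockSet(blocks=(frozenset("ac"), frozenset("bd")))
        s = br.summarize_covariate(bs, tiny_cohort, 0)
        assert s.block_means == (2.0, 3.0)
        assert s.block_sds == pytest.approx((math.sqrt(2), math.sqrt(2)))
        assert s.block_cvs == pytest.approx((math.sqrt(2) / 2, math.sqrt(2) / 3))
        assert s.blockset_sd == pytest.approx(math.sqrt(5 / 3))
        assert s.delta_mean_max == pytest.approx(1.0)
        assert s.delta_cv_max == pytest.approx(math.sqrt(2) / 2 - math.sqrt(2) / 3)

    def test_identical_multisets_have_zero_deltas(self):
        cohort = one_cov_cohort([1, 2, 1, 2])
        bs = br.BlockSet(blocks=(frozenset({"u0", "u1"}), frozenset({"u2", "u3"})))
        s = br.summarize_covariate(bs, cohort, 0)
        assert s.delta_mean_max == 0.0
        assert s.delta_cv_max == 0.0

    def test_constant_covariate(self):
        cohort = one_cov_cohort([3, 3, 3, 3])
        bs = br.BlockSet(blocks=(frozenset({"u0", "u1"}), frozenset({"u2", "u3"})))
        s = br.summarize_covariate(bs, cohort, 0)
        assert s.blockset_sd == 0.0
        assert s.block_cvs == (0.0, 0.0)
        assert s.mean_term() == 0.0

    def test_zero_block_mean_is_hard_error(self):
        cohort = one_cov_cohort([-1, 1, 2, 4])
        bs = br.BlockSet(blocks=(frozenset({"u0", "u1"}), frozenset({"u2", "u3"})))
        with pytest.raises(br.UndefinedCVError):
            br.summarize_covariate(bs, cohort, 0)

    def test_singleton_block_cv_is_zero(self):
        cohort = one_cov_cohort([5, 1, 2])
        bs = br.BlockSet(blocks=(frozenset({"u0"}), frozenset({"u1", "u2"})))
        s = br.summarize_covariate(bs, cohort, 0)
        assert s.block_cvs[0] == 0.0

    def test_population_sd_switch(self, tiny_cohort):
        bs = br.BlockSet(blocks=(frozenset("ac"), frozenset("bd")))
        s = br.summarize_covariate(bs, tiny_cohort, 0, sample_sd=False)
        assert s.block_sds == pytest.approx((1.0, 1.0))
        assert s.blockset_sd == pytest.approx(math.sqrt(5 / 4))

    def test_cv_percent_switch(self, tiny_cohort):
        bs = br.BlockSet(blocks=(frozenset("ac"), frozenset("bd")))
        s = br.summarize_covariate(bs, tiny_cohort, 0, cv_percent=True)
        assert s.block_cvs == pytest.approx((100 * math.sqrt(2) / 2, 100 * math.sqrt(2) / 3))


class TestRankBlockSet:
    def test_hand_oracle_value(self, tiny_cohort):
        bs = br.BlockSet(blocks=(frozenset("ac"), frozenset("bd")))
        ranked = br.rank_block_set(bs, tiny_cohort, br.BlockDesign(block_sizes=(2, 2)))
        expected = 1 / math.sqrt(5 / 3) + math.sqrt(2) / 2 - math.sqrt(2) / 3
        assert ranked.ranking_value == pytest.approx(expected)
        assert ranked.ranking_value == pytest.approx(pure_python_score(bs, tiny_cohort))

    def test_zero_iff_identical_block_statistics(self):
        cohort = one_cov_cohort([1, 2, 1, 2])
        perfect = br.BlockSet(blocks=(frozenset({"u0", "u1"}), frozenset({"u2", "u3"})))
        design = br.BlockDesign(block_sizes=(2, 2))
        assert br.rank_block_set(perfect, cohort, design).ranking_value == 0.0
        lopsided = br.BlockSet(blocks=(frozenset({"u0", "u2"}), frozenset({"u1", "u3"})))
        assert br.rank_block_set(lopsided, cohort, design).ranking_value > 0.0

    def test_weight_linearity(self, s1_cohort):
        bs = br.sample_block_set(s1_cohort, br.BlockDesign(block_sizes=(8, 8)), rng=3)
        base = br.BlockDesign(block_sizes=(8, 8), weights=(1.0, 0.0, 0.0))
        doubled = br.BlockDesign(block_sizes=(8, 8), weights=(2.0, 0.0, 0.0))
        v1 = br.rank_block_set(bs, s1_cohort, base).ranking_value
        v2 = br.rank_block_set(bs, s1_cohort, doubled).ranking_value
        assert v2 == pytest.approx(2 * v1)

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 50))
    def test_scale_invariance_under_positive_rescaling(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(1.0, 10.0, size=8)
        design = br.BlockDesign(block_sizes=(4, 4))
        c1 = one_cov_cohort(values)
        c2 = one_cov_cohort(values * scale)
        bs = br.sample_block_set(c1, design, rng=seed)
        v1 = br.rank_block_set(bs, c1, design).ranking_value
        v2 = br.rank_block_set(bs, c2, design).ranking_value
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_score_is_nonnegative_on_random_sets(self, s1_cohort, rng):
        design = br.BlockDesign(block_sizes=(5, 8))
        for _ in range(50):
            bs = br.sample_block_set(s1_cohort, design, rng=rng)
            assert br.rank_block_set(bs, s1_cohort, design).ranking_value >= 0.0


class TestBatchScorer:
    def test_matches_per_set_scorer_and_pure_python(self, s1_cohort, rng):
        design = br.BlockDesign(block_sizes=(8, 8))
        X = s1_cohort.covariate_matrix()
        ids = s1_cohort.ids
        rows = np.stack([rng.permutation(16) for _ in range(40)])
        scores = batch_ranking_values(rows, (8, 8), X, [1.0, 1.0, 1.0])
        for row, score in zip(rows, scores):
            bs = br.BlockSet(
                blocks=(
                    frozenset(ids[j] for j in row[:8]),
                    frozenset(ids[j] for j in row[8:]),
                )
            )
            assert score == pytest.approx(
                br.rank_block_set(bs, s1_cohort, design).ranking_value, abs=1e-12
            )
            assert score == pytest.approx(pure_python_score(bs, s1_cohort), abs=1e-9)

    def test_leftover_excluded_from_blockset_sd(self, s1_cohort):
        # 10 of 16 units blocked: the batch and per-set paths must agree on
        # which units enter the whole-set SD.
        design = br.BlockDesign(block_sizes=(5, 5))
        bs = br.sample_block_set(s1_cohort, design, rng=0)
        ranked = br.rank_block_set(bs, s1_cohort, design)
        assert ranked.ranking_value == pytest.approx(
            pure_python_score(bs, s1_cohort), abs=1e-9
        )
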