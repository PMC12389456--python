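"""Quintile-rank scoring: cutpoints, subscores, totals, quartiles, reliability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hpds.experiments import brute_force_hpds, reliability_at_noise
from hpds.scoring import (
    HeartProtectiveDietScorer,
    assign_score_quartiles,
    compute_hpds,
    quintile_cutpoints,
    reliability,
    score_group,
)

from conftest import random_intake_matrix


class TestCutpoints:
    def test_linear_interpolation_definition(self):
        cuts, degen = quintile_cutpoints(np.arange(1, 101, dtype=float))
        assert cuts == pytest.approx([20.8, 40.6, 60.4, 80.2])
        assert not degen.any()

    def test_constant_distribution_fully_degenerate(self):
        cuts, degen = quintile_cutpoints(np.full(50, 3.0))
        assert (cuts == 3.0).all()
        assert degen.all()

    def test_zero_inflation_collapses_lower_boundaries(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([np.zeros(60), rng.uniform(1, 10, 40)])
        cuts, degen = quintile_cutpoints(v)
        assert cuts[0] == 0 and cuts[1] == 0
        assert degen[0] and degen[1]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            quintile_cutpoints(np.array([1.0, 2.0, np.nan, 4.0, np.nan]))


class TestScoreGroup:
    def test_top_quintile_sign_antisymmetry(self):
        cuts = np.array([1.0, 2.0, 3.0, 4.0])
        assert score_group(10.0, cuts, +1) == 2
        assert score_group(10.0, cuts, -1) == -2

    def test_zero_consumer_in_zero_inflated_group_gets_lowest(self):
        cuts = np.array([0.0, 0.0, 1.5, 4.0])   # 60% zeros collapse p20/p40
        assert score_group(0.0, cuts, +1) == -2

    def test_tie_with_threshold_goes_to_lower_quintile(self):
        cuts = np.array([1.0, 2.0, 3.0, 4.0])
        assert score_group(2.0, cuts, +1) == -1   # rank 1, not 2

    def test_ten_value_cohort_matches_exhaustive_ranking(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 100, 10)
        cuts, _ = quintile_cutpoints(v)
        for x in v:
            rank = sum(1 for c in cuts if c < x)
            assert score_group(x, cuts, +1) == rank - 2


class TestComputeHPDS:
    def test_identical_intakes_degenerate_cohort(self, taxonomy):
        m = pd.DataFrame(
            np.ones((6, 22)) * 50.0, columns=taxonomy.group_ids
        )
        res = compute_hpds(m, taxonomy)
        assert res.total.nunique() == 1
        assert (res.quartile == "Q1").all()

    def test_monotone_dominance(self, taxonomy):
        rng = np.random.default_rng(1)
        m = random_intake_matrix(rng, 10, taxonomy)
        # participant 0 dominates participant 1 in the health-aligned sense
        for g in taxonomy.group_ids:
            lo, hi = sorted(rng.uniform(0, 100, 2))
            if taxonomy[g].direction == 1:
                m.iloc[0, m.columns.get_loc(g)] = hi + 1
                m.iloc[1, m.columns.get_loc(g)] = lo
            else:
                m.iloc[0, m.columns.get_loc(g)] = lo
                m.iloc[1, m.columns.get_loc(g)] = hi + 1
        res = compute_hpds(m, taxonomy)
        assert res.total.iloc[0] >= res.total.iloc[1]

    def test_matches_brute_force_oracle(self, taxonomy):
        rng = np.random.default_rng(7)
        m = random_intake_matrix(rng, 50, taxonomy)
        res = compute_hpds(m, taxonomy)
        oracle = brute_force_hpds(m, taxonomy)
        pd.testing.assert_frame_equal(
            res.subscores, oracle, check_dtype=False
        )

    def test_direction_flip_negates_exactly_that_group(self, taxonomy):
        import dataclasses

        rng = np.random.default_rng(11)
        m = random_intake_matrix(rng, 30, taxonomy)
        # flip one + group and one - group to keep the 11/11 balance
        flip = {"fruits", "potatoes"}
        groups = tuple(
            dataclasses.replace(g, direction=-g.direction)
            if g.group_id in flip else g
            for g in taxonomy.groups
        )
        flipped = dataclasses.replace(taxonomy, groups=groups)
        a = compute_hpds(m, taxonomy).subscores
        b = compute_hpds(m, flipped).subscores
        for g in taxonomy.group_ids:
            if g in flip:
                assert (b[g] == -a[g]).all()
            else:
                assert (b[g] == a[g]).all()

    def test_fixed_cutpoints_monotone_in_protective_intake(self, taxonomy):
        rng = np.random.default_rng(13)
        m = random_intake_matrix(rng, 40, taxonomy)
        scorer = HeartProtectiveDietScorer(taxonomy).fit(m)
        bumped = m.copy()
        bumped["fruits"] = bumped["fruits"] + 25.0
        t0 = scorer.transform(m).sum(axis=1)
        t1 = scorer.transform(bumped).sum(axis=1)
        assert (t1 >= t0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_decomposition_and_bounds(self, taxonomy, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        m = random_intake_matrix(rng, n, taxonomy,
                                 zero_frac=float(rng.uniform(0, 0.8)))
        res = compute_hpds(m, taxonomy)
        assert res.subscores.to_numpy().min() >= -2
        assert res.subscores.to_numpy().max() <= 2
        assert (res.total == res.subscores.sum(axis=1)).all()
        assert res.total.between(-44, 44).all()


class TestQuartiles:
    def test_four_distinct_values(self):
        q = assign_score_quartiles(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(q) == ["Q1", "Q2", "Q3", "Q4"]

    def test_all_equal_all_q1(self):
        q = assign_score_quartiles(pd.Series([5.0] * 8))
        assert (q == "Q1").all()

    def test_balanced_sizes_without_ties(self):
        rng = np.random.default_rng(5)
        q = assign_score_quartiles(pd.Series(rng.standard_normal(1000)))
        counts = q.value_counts()
        assert all(abs(counts[lab] - 250) <= 1 for lab in
                   ["Q1", "Q2", "Q3", "Q4"])

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            assign_score_quartiles(pd.Series([1.0, 2.0, 3.0]))


class TestReliability:
    def test_identical_vectors(self):
        r, p = reliability(np.arange(10.0), np.arange(10.0))
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_negation(self):
        r, _ = reliability(np.arange(10.0), -np.arange(10.0))
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            reliability(np.ones(5), np.arange(5.0))

    def test_monotone_decrease_with_recall_noise(self):
        rs = [reliability_at_noise(sd, n=600, n_recalls=3, seed=21)
              for sd in (0.2, 0.6, 1.2)]
        assert rs[0] > rs[1] > rs[2]
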