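"""Tests of ranking, quantile/window variance estimation and weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from pmrwls.sampling import simulate_pmr_batch
from pmrwls.scenarios import sample_dna_quantity
from pmrwls.weighting import (
    PmrObservation,
    quantile_group_sizes,
    quantile_variances,
    quantile_variances_ranked,
    rank_by_surrogate,
    threshold_weights,
    uniform_weights,
    window_variances,
    window_variances_ranked,
)


class TestRanking:
    def test_quantity_orientation(self):
        assert rank_by_surrogate([3, 1, 2], "quantity").tolist() == [1, 2, 0]

    def test_ct_orientation_inverts(self):
        # high C(t) = little DNA, so effective quantity order flips
        assert rank_by_surrogate([3, 1, 2], "ct").tolist() == [0, 2, 1]

    def test_stable_ties(self):
        assert rank_by_surrogate([1, 1, 2], "quantity").tolist() == [0, 1, 2]
        assert rank_by_surrogate([2, 1, 1], "ct").tolist() == [0, 1, 2]

    def test_unknown_orientation(self):
        with pytest.raises(ValueError):
            rank_by_surrogate([1, 2], "absorbance")


class TestQuantileVariances:
    def test_group_sizes_even_split(self):
        assert quantile_group_sizes(200, 5).tolist() == [40] * 5

    def test_remainder_goes_to_lowest_quantity_groups(self):
        assert quantile_group_sizes(11, 3).tolist() == [4, 4, 3]

    def test_hand_computed_variances(self):
        # ranked PMRs [0,0,1,1,2 | 10,10,20,20,40]: sample variances
        # 2.8/4 = 0.7 and 600/4 = 150
        ranked = np.array([0.0, 0, 1, 1, 2, 10, 10, 20, 20, 40])
        variances = quantile_variances_ranked(ranked, 2)
        assert variances[:5] == pytest.approx(np.full(5, 0.7))
        assert variances[5:] == pytest.approx(np.full(5, 150.0))
        # independent oracle: numpy's own variance on each block
        assert variances[0] == pytest.approx(np.var(ranked[:5], ddof=1))
        assert variances[-1] == pytest.approx(np.var(ranked[5:], ddof=1))

    def test_scheme_weights_inverse_variance(self):
        table = make_table(
            pmr=[0, 0, 1, 1, 2, 10, 10, 20, 20, 40],
            surrogate=np.arange(10),
            group=[1, 2] * 5,
        )
        scheme = quantile_variances(table, k=2)
        ratio = scheme.weights[0] / scheme.weights[-1]
        assert ratio == pytest.approx(150.0 / 0.7)

    def test_identical_pmrs_reduce_to_equal_weights(self):
        table = make_table(
            pmr=np.full(20, 7.0), surrogate=np.arange(20), group=[1, 2] * 10
        )
        scheme = quantile_variances(table, k=5)
        assert np.allclose(scheme.weights, scheme.weights[0])
        assert np.isfinite(scheme.weights).all()

    def test_insufficient_data(self):
        table = make_table(pmr=[1, 2, 3], surrogate=[1, 2, 3], group=[1, 2, 1])
        with pytest.raises(ValueError):
            quantile_variances(table, k=2)


class TestWindowVariances:
    def test_whole_sample_window(self):
        ranked = np.arange(41, dtype=float)
        variances = window_variances_ranked(ranked, 41)
        assert np.allclose(variances, variances[0])
        assert variances[0] == pytest.approx(np.var(ranked, ddof=1))

    def test_consecutive_integers_all_unit_variance(self):
        # any 3 consecutive integers have sample variance exactly 1
        variances = window_variances_ranked(np.arange(1.0, 10.0), 3)
        assert variances == pytest.approx(np.ones(9))

    def test_edge_rule_shares_extreme_windows(self):
        rng = np.random.default_rng(3)
        ranked = np.sort(rng.gamma(2, 10, size=200))
        variances = window_variances_ranked(ranked, 41)
        # the 20 lowest-ranked observations all use ranks 0..40
        assert np.allclose(variances[:20], np.var(ranked[:41], ddof=1))
        assert np.allclose(variances[-20:], np.var(ranked[-41:], ddof=1))
        # interior brute force at a few ranks
        for r in (20, 57, 100, 179):
            assert variances[r] == pytest.approx(
                np.var(ranked[r - 20 : r + 21], ddof=1)
            )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            window_variances_ranked(np.arange(50.0), 40)

    def test_window_larger_than_sample_rejected(self):
        with pytest.raises(ValueError):
            window_variances_ranked(np.arange(10.0), 11)

    def test_matches_quantile_at_group_centers_on_aligned_data(self):
        # w equal to the group size, window centered in each group block
        rng = np.random.default_rng(9)
        ranked = np.sort(rng.normal(50, 10, size=50))
        k, w = 10, 5
        qvar = quantile_variances_ranked(ranked, k)
        wvar = window_variances_ranked(ranked, w)
        centers = np.arange(w // 2, 50, w)
        assert wvar[centers] == pytest.approx(qvar[centers])


class TestThresholdWeights:
    def test_quantity_thresholds(self):
        table = make_table(pmr=[1, 2, 3], surrogate=[0.5, 5, 50], group=[1, 2, 1])
        assert threshold_weights(table, 1.0).weights.tolist() == [0, 1, 1]
        assert threshold_weights(table, 10.0).weights.tolist() == [0, 0, 1]
        assert threshold_weights(table, 0.0).weights.tolist() == [1, 1, 1]

    def test_ct_threshold_keeps_low_ct(self):
        table = make_table(pmr=[1, 2, 3], surrogate=[18.0, 26.0, 22.0], group=[1, 2, 1])
        scheme = threshold_weights(table, 24.0, orientation="ct")
        assert scheme.weights.tolist() == [1, 0, 1]

    def test_empty_analysis_rejected(self):
        table = make_table(pmr=[1, 2], surrogate=[0.1, 0.2], group=[1, 2])
        with pytest.raises(ValueError):
            threshold_weights(table, 10.0)


class TestSchemeInvariants:
    def test_permutation_invariance(self, rng):
        n = 120
        table = make_table(
            pmr=rng.gamma(2, 10, size=n),
            surrogate=rng.uniform(0.5, 500, size=n),
            group=rng.choice([1, 2], size=n),
        )
        perm = rng.permutation(n)
        shuffled = table.iloc[perm].reset_index(drop=True)
        for fn, kw in (
            (quantile_variances, {"k": 5}),
            (window_variances, {"w": 41}),
        ):
            base = fn(table, **kw)
            moved = fn(shuffled, **kw)
            assert moved.variances == pytest.approx(base.variances[perm])
            assert moved.weights == pytest.approx(base.weights[perm])

    def test_orientation_flip_equivalence(self, rng):
        # analysing genome counts or a monotone-decreasing C(t) proxy of them
        # gives identical weights once the orientation is declared
        n = 80
        pmr = rng.gamma(2, 10, size=n)
        q = rng.uniform(0.5, 500, size=n)
        group = rng.choice([1, 2], size=n)
        as_quantity = make_table(pmr=pmr, surrogate=q, group=group)
        as_ct = make_table(pmr=pmr, surrogate=30 - np.log10(q), group=group)
        a = window_variances(as_quantity, 41, orientation="quantity")
        b = window_variances(as_ct, 41, orientation="ct")
        assert b.weights == pytest.approx(a.weights)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0, 500, allow_nan=False),
                st.floats(0.01, 600, allow_nan=False),
            ),
            min_size=12,
            max_size=60,
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_weight_totality(self, data):
        # every scheme yields one finite weight per observation, strictly
        # positive for the inverse-variance schemes
        pmr = np.array([d[0] for d in data])
        surrogate = np.array([d[1] for d in data])
        table = make_table(pmr=pmr, surrogate=surrogate, group=[1, 2] * (len(data) // 2) + [1] * (len(data) % 2))
        for scheme in (
            quantile_variances(table, k=3),
            window_variances(table, w=5),
            uniform_weights(table),
        ):
            assert len(scheme.weights) == len(table)
            assert np.isfinite(scheme.weights).all()
            assert (scheme.weights > 0).all()

    def test_variance_recovery_decreasing_in_quantity(self, consts, qmodel, rng):
        # simulated PMR heteroscedasticity is recovered: quintile variances
        # fall as DNA quantity rises (fixed p, so all variance is sampling)
        n = 2000
        genomes = sample_dna_quantity(qmodel, n, rng)
        pmr = simulate_pmr_batch(genomes, np.full(n, 0.2), consts, rng)
        table = make_table(pmr=pmr, surrogate=genomes, group=[1, 2] * (n // 2))
        scheme = quantile_variances(table, k=5)
        order = np.argsort(genomes, kind="stable")
        per_quintile = scheme.variances[order][:: n // 5]
        assert all(a > b for a, b in zip(per_quintile, per_quintile[1:]))


def test_observation_record_validation():
    with pytest.raises(ValueError):
        PmrObservation(pmr=-1.0, surrogate=10.0, group=1)
    with pytest.raises(ValueError):
        PmrObservation(pmr=1.0, surrogate=float("nan"), group=1)
    obs = [
        PmrObservation(pmr=5.0, surrogate=10.0, group=1, id="s1"),
        PmrObservation(pmr=7.0, surrogate=2.0, group=2, id="s2"),
    ]
    scheme = uniform_weights(obs)
    assert scheme.weights.tolist() == [1.0, 1.0]
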