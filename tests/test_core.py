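"""Unit tests for the embedding machinery and the three estimators."""

import itertools
import math

import numpy as np
import pytest

from mfreen import (
    EmbeddingConfig,
    MultibandSeries,
    chebyshev_distance,
    compute_entropy,
    distance_rank_pattern,
    embed_uniform,
    m_fre_en,
    mv_perm_entropy,
    mv_samp_entropy,
    ordinal_pattern,
    pairwise_band_distances,
)
from mfreen.core import samp_en_counts

from .oracles import (
    m_fre_en_bf,
    mv_perm_entropy_bf,
    mv_samp_entropy_bf,
    ordinal_pattern_bf,
    univariate_samp_entropy_bf,
)


class TestEmbedding:
    def test_univariate_windows_unrolled(self):
        traj = embed_uniform([1.0, 2.0, 3.0, 4.0], EmbeddingConfig(m=2, tau=1))
        assert traj.vectors.shape == (1, 3, 2)
        np.testing.assert_array_equal(
            traj.vectors[0], [[1, 2], [2, 3], [3, 4]]
        )

    def test_vector_count_formula(self, rng):
        series = MultibandSeries(rng.standard_normal((1500, 1)))
        traj = embed_uniform(series, EmbeddingConfig(m=7, tau=1))
        assert traj.n_vectors == 1494

    def test_boundary_single_window(self):
        traj = embed_uniform([5.0, 5.0, 5.0], EmbeddingConfig(m=3, tau=1))
        assert traj.vectors.shape == (1, 1, 3)

    def test_too_short_raises_with_minimum(self):
        with pytest.raises(ValueError, match="N = 7"):
            embed_uniform([1.0, 2.0, 3.0], EmbeddingConfig(m=4, tau=2))

    def test_layouts_agree_on_content(self, trivariate_integers):
        cfg = EmbeddingConfig(m=3, tau=2)
        per_var = embed_uniform(trivariate_integers, cfg, "per-variate")
        tf = embed_uniform(trivariate_integers, cfg, "time-frequency")
        cat = embed_uniform(trivariate_integers, cfg, "concatenated")
        # per-variate (g, P, m) vs time-frequency (P, m, g)
        np.testing.assert_array_equal(
            per_var.vectors, np.transpose(tf.vectors, (2, 0, 1))
        )
        g, P, m = per_var.vectors.shape
        assert cat.vectors.shape == (P, g * m)
        np.testing.assert_array_equal(
            cat.vectors[:, :m], per_var.vectors[0]
        )


class TestOrdinalPattern:
    @pytest.mark.parametrize(
        "vector,expected",
        [
            ((0.3, 0.1, 0.7), (2, 1, 3)),
            ((5, 5, 5), (1, 2, 3)),  # ties keep original position order
            ((2, 1), (2, 1)),
        ],
    )
    def test_examples(self, vector, expected):
        assert ordinal_pattern(vector) == expected

    def test_bijective_over_distinct_values(self):
        patterns = {
            ordinal_pattern(perm) for perm in itertools.permutations((1, 2, 3))
        }
        assert len(patterns) == 6
        assert patterns == set(itertools.permutations((1, 2, 3)))


class TestMvPermEntropy:
    def test_monotone_series_is_zero(self):
        res = mv_perm_entropy(np.arange(1.0, 21.0), EmbeddingConfig(m=3))
        assert res.value == pytest.approx(0.0, abs=1e-15)

    def test_alternating_series_is_one(self):
        res = mv_perm_entropy(
            np.array([0.0, 1.0, 0.0, 1.0, 0.0]), EmbeddingConfig(m=2)
        )
        assert res.value == pytest.approx(1.0, abs=1e-15)

    def test_pooled_bivariate_matches_oracle(self):
        X = np.column_stack(
            [[1.0, 4, 2, 5, 3, 6], [6.0, 3, 5, 2, 4, 1]]
        )
        res = mv_perm_entropy(MultibandSeries(X), EmbeddingConfig(m=2))
        assert res.value == pytest.approx(mv_perm_entropy_bf(X, m=2), abs=1e-12)

    def test_pattern_total_pools_across_variates(self, trivariate_integers):
        # distribution totals g*(N-(m-1)tau) patterns; value within [0,1]
        res = mv_perm_entropy(trivariate_integers, EmbeddingConfig(m=3))
        assert 0.0 <= res.value <= 1.0
        assert res.normalized


class TestChebyshev:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 2, 3), (1, 2, 3), 0.0), ((0, 0), (1, -2), 2.0)],
    )
    def test_examples(self, a, b, expected):
        assert chebyshev_distance(a, b) == expected

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.standard_normal((2, 5))
            assert chebyshev_distance(a, b) == chebyshev_distance(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            chebyshev_distance([1, 2], [1, 2, 3])


class TestMvSampEntropy:
    def test_constant_series_is_zero(self):
        series = MultibandSeries(np.full((20, 2), 3.0))
        res = mv_samp_entropy(series, EmbeddingConfig(m=2, r=0.5))
        assert res.value == pytest.approx(0.0, abs=1e-15)

    def test_univariate_reduces_to_classic_sampen(self, rng):
        x = rng.standard_normal(200)
        r = 0.15 * x.std(ddof=0)
        res = mv_samp_entropy(x, EmbeddingConfig(m=2, r=r))
        expected = univariate_samp_entropy_bf(x, m=2, tau=1, r=r)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_bivariate_matches_naive_double_loop(self):
        X = np.column_stack(
            [[3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3], [2.0, 7, 1, 8, 2, 8, 1, 8, 2, 8]]
        )
        res = mv_samp_entropy(MultibandSeries(X), EmbeddingConfig(m=2, r=1.5))
        expected = mv_samp_entropy_bf(X, m=2, tau=1, r=1.5)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_default_tolerance_scales_each_variate(self, rng):
        # r unset: each variate scaled to unit SD, r = r_factor; rescaling
        # one variate must then not change the result
        X = rng.standard_normal((150, 2))
        scaled = X * np.array([1.0, 40.0])
        a = mv_samp_entropy(MultibandSeries(X), EmbeddingConfig(m=2, r_factor=0.5))
        b = mv_samp_entropy(MultibandSeries(scaled), EmbeddingConfig(m=2, r_factor=0.5))
        assert a.defined and b.defined
        assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_no_matches_flagged_undefined_not_infinite(self):
        x = np.array([0.0, 100.0, 1.0, 205.0, 3.0, 310.0, 7.0, 444.0, 15.0, 590.0])
        res = mv_samp_entropy(x, EmbeddingConfig(m=2, r=0.5))
        assert not res.defined
        assert math.isnan(res.value)
        assert "no template matches" in res.diagnostic

    def test_counts_are_probabilities(self, rng):
        counts = samp_en_counts(
            rng.standard_normal((80, 2)), EmbeddingConfig(m=2)
        )
        assert 0.0 <= counts.phi_m <= 1.0
        assert 0.0 <= counts.phi_m_plus_1 <= 1.0


class TestPairwiseBandDistances:
    def test_identical_blocks_give_zero_tuple(self):
        X = np.tile(np.arange(4.0)[:, None], (1, 3))
        X[:, 1] *= -1  # keep columns distinct, rows repeated via embedding
        series = MultibandSeries(np.vstack([X, X]))
        traj = embed_uniform(series, EmbeddingConfig(m=4, tau=1), "time-frequency")
        dists = pairwise_band_distances(traj)
        i, j = 0, 4  # blocks 0 and 4 are identical by construction
        pair_index = {
            (a, b): k
            for k, (a, b) in enumerate(
                itertools.combinations(range(traj.n_vectors), 2)
            )
        }
        np.testing.assert_allclose(dists[pair_index[(i, j)]], np.zeros(3))

    def test_componentwise_maximum(self):
        # two blocks, g=3, m=2: columns differ by (2, 1, 0)
        values = np.array(
            [[1.0, 0.0, 5.0], [2.0, 0.0, 5.0], [2.0, 0.0, 5.0], [4.0, 1.0, 5.0]]
        )
        traj = embed_uniform(
            MultibandSeries(values), EmbeddingConfig(m=2, tau=2), "time-frequency"
        )
        assert traj.n_vectors == 2
        np.testing.assert_allclose(pairwise_band_distances(traj)[0], [2.0, 1.0, 0.0])

    def test_pair_count(self, rng):
        series = MultibandSeries(rng.standard_normal((5, 3)))
        traj = embed_uniform(series, EmbeddingConfig(m=2, tau=1), "time-frequency")
        assert pairwise_band_distances(traj).shape == (6, 3)  # C(4,2)


class TestDistanceRankPattern:
    def test_examples(self):
        assert distance_rank_pattern((0.2, 0.9, 0.5)) == (1, 3, 2)
        assert distance_rank_pattern((0.4, 0.4, 0.4)) == (1, 2, 3)

    def test_all_patterns_reachable(self):
        seen = {
            distance_rank_pattern(perm)
            for perm in itertools.permutations((0.1, 0.5, 0.9))
        }
        assert len(seen) == 6


class TestMFreEn:
    def test_identical_bands_give_zero(self):
        col = np.sin(np.arange(30.0))
        series = MultibandSeries(np.column_stack([col, col, col]))
        res = m_fre_en(series, EmbeddingConfig(m=2))
        assert res.value == pytest.approx(0.0, abs=1e-15)

    def test_balanced_bivariate_is_one(self):
        # both orderings of the per-band distances occur 3 times each
        X = np.array([[3.0, 1], [1, 3], [3, 3], [1, 2], [3, 2]])
        res = m_fre_en(MultibandSeries(X), EmbeddingConfig(m=2))
        assert res.value == pytest.approx(1.0, abs=1e-12)
        value_bf, counts = m_fre_en_bf(X, m=2)
        assert value_bf == pytest.approx(1.0, abs=1e-12)
        assert sorted(counts.values()) == [3, 3]

    def test_three_band_matches_naive_oracle(self):
        X = np.array(
            [
                [2.0, 7, 1],
                [8.0, 2, 8],
                [1.0, 8, 2],
                [8.0, 1, 8],
                [2.0, 8, 1],
                [7.0, 2, 8],
            ]
        )
        res = m_fre_en(MultibandSeries(X), EmbeddingConfig(m=2))
        expected, _ = m_fre_en_bf(X, m=2)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_needs_two_bands(self):
        with pytest.raises(ValueError, match="g >= 2"):
            m_fre_en(np.arange(10.0), EmbeddingConfig(m=2))


def test_dispatch_by_name(trivariate_integers):
    cfg = EmbeddingConfig(m=2, r=1.5)
    for name, direct in [
        ("mvPerEn", mv_perm_entropy),
        ("mvSampEn", mv_samp_entropy),
        ("mFreEn", m_fre_en),
    ]:
        np.testing.assert_equal(
            compute_entropy(trivariate_integers, name, cfg).value,
            direct(trivariate_integers, cfg).value,
        )
    with pytest.raises(ValueError, match="unknown algorithm"):
        compute_entropy(trivariate_integers, "spectral", cfg)
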