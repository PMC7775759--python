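"""Geospatial estimator: haversine k-NN isogloss density and bootstrap."""

import math

import numpy as np
import pytest
from sklearn.metrics.pairwise import haversine_distances

from linguatemp import geo
from linguatemp.geo import (
    EstimatorConfig, FeatureSample, InsufficientSampleError, LanguagePoint,
    bootstrap_temperature, empirical_frequency, empirical_isogloss_density,
    haversine_distance, hemisphere_split_test, knn_neighbors, point_estimate,
)


def make_sample(lats, lons, values, feature_id="F", ids=None):
    n = len(values)
    ids = ids if ids is not None else [f"l{i:03d}" for i in range(n)]
    return FeatureSample(
        feature_id=feature_id,
        ids=np.array(ids, dtype=object),
        names=np.array(ids, dtype=object),
        latitudes=np.array(lats, dtype=float),
        longitudes=np.array(lons, dtype=float),
        values=np.array(values, dtype=np.int8),
    )


class TestHaversine:
    def test_identical_points(self):
        assert haversine_distance(10.0, 20.0, 10.0, 20.0) == 0.0

    def test_antipodal_and_quarter(self):
        assert haversine_distance(0, 0, 0, 180) == pytest.approx(math.pi)
        assert haversine_distance(0, 0, 0, 90) == pytest.approx(math.pi / 2)
        assert haversine_distance(0, 0, 90, 0) == pytest.approx(math.pi / 2)

    def test_against_sklearn(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-85, 85, 40)
        lon = rng.uniform(-180, 180, 40)
        ours = geo._pairwise_haversine(lat, lon)
        ref = haversine_distances(np.radians(np.column_stack([lat, lon])))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_symmetry_and_triangle(self):
        a, b, c = (10.0, 30.0), (-20.0, 100.0), (55.0, -60.0)
        dab = haversine_distance(*a, *b)
        dba = haversine_distance(*b, *a)
        dac = haversine_distance(*a, *c)
        dcb = haversine_distance(*c, *b)
        assert dab == pytest.approx(dba)
        assert dab <= dac + dcb + 1e-12


class TestLanguagePoint:
    def test_validation(self):
        LanguagePoint("x", "X", 10, 20, 1)
        with pytest.raises(ValueError):
            LanguagePoint("x", "X", 95, 20, 1)
        with pytest.raises(ValueError):
            LanguagePoint("x", "X", 10, 20, 2)


class TestKnnNeighbors:
    def test_three_equatorial_points(self):
        s = make_sample([0, 0, 0], [0, 120, -120], [0, 1, 0])
        nb = knn_neighbors(s, 2)
        for i in range(3):
            assert set(nb[i]) == {0, 1, 2} - {i}

    def test_meridian_chain_brute_force(self):
        lats = [0.0, 1.0, 2.0, 3.0, 10.0]
        s = make_sample(lats, [0.0] * 5, [0, 1, 0, 1, 0])
        nb = knn_neighbors(s, 1)
        # brute-force oracle via sklearn pairwise distances
        D = haversine_distances(np.radians(np.column_stack(
            [lats, [0.0] * 5])))
        np.fill_diagonal(D, np.inf)
        expected = D.argmin(axis=1)
        np.testing.assert_array_equal(nb[:, 0], expected)
        assert nb[4, 0] == 3

    def test_duplicate_coordinates_are_nearest(self):
        s = make_sample([0, 0, 40], [10, 10, 60], [1, 0, 1])
        nb = knn_neighbors(s, 1)
        assert nb[0, 0] == 1 and nb[1, 0] == 0

    def test_insufficient_sample(self):
        s = make_sample([0, 1], [0, 1], [0, 1])
        with pytest.raises(InsufficientSampleError):
            knn_neighbors(s, 2)


class TestEmpiricalStatistics:
    def test_frequency(self):
        assert empirical_frequency(
            make_sample([0, 0, 0], [0, 1, 2], [1, 1, 1])) == 1.0
        s = make_sample(range(8), range(8), [1, 1, 1, 0, 0, 0, 0, 0])
        assert empirical_frequency(s) == pytest.approx(0.375)
        assert empirical_frequency(s.complemented()) == pytest.approx(0.625)

    def test_uniform_values_zero_density(self):
        s = make_sample([0, 1, 2, 3], [0, 0, 0, 0], [1, 1, 1, 1])
        assert empirical_isogloss_density(s, 2) == 0.0

    def test_square_checkerboard(self):
        # four corners of a small square, diagonal values equal: each
        # corner's two nearest neighbors are the edge-adjacent corners,
        # which both disagree -> all 8 directed pairs disagree
        s = make_sample([0, 0, 1, 1], [0, 1, 0, 1], [0, 1, 1, 0])
        assert empirical_isogloss_density(s, 2) == 1.0

    def test_two_clusters_enumeration(self):
        # east cluster present, west cluster absent; k=2 neighborhoods
        # stay within each cluster except at the facing edge
        lats = [0, 0, 0, 0, 0, 0]
        lons = [-10.0, -9.0, -8.0, 8.0, 9.0, 10.0]
        vals = [0, 0, 0, 1, 1, 1]
        s = make_sample(lats, lons, vals)
        # brute-force enumeration of all directed pairs
        D = haversine_distances(np.radians(np.column_stack([lats, lons])))
        np.fill_diagonal(D, np.inf)
        disagree = 0
        for i in range(6):
            for j in np.argsort(D[i], kind="stable")[:2]:
                disagree += vals[i] != vals[j]
        expected = disagree / 12.0
        assert empirical_isogloss_density(s, 2) == pytest.approx(expected)
        assert expected == 0.0  # clusters are wider than k=2 reach

    def test_complement_and_permutation_invariance(self):
        rng = np.random.default_rng(3)
        s = make_sample(rng.uniform(-40, 40, 30), rng.uniform(-40, 40, 30),
                        rng.integers(0, 2, 30))
        sigma = empirical_isogloss_density(s, 5)
        assert empirical_isogloss_density(s.complemented(), 5) == \
            pytest.approx(sigma)
        perm = rng.permutation(30)
        assert empirical_isogloss_density(s.take(perm), 5) == \
            pytest.approx(sigma)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            empirical_frequency(make_sample([], [], []))


class TestBootstrap:
    def test_single_replicate_reproducible(self):
        rng = np.random.default_rng(5)
        s = make_sample(rng.uniform(-30, 30, 40), rng.uniform(-30, 30, 40),
                        rng.integers(0, 2, 40))
        cfg = EstimatorConfig(k_neighbors=5, n_bootstrap=1, seed=8)
        a = bootstrap_temperature(s, cfg)
        b = bootstrap_temperature(s, cfg)
        assert a.rho_b[0] == b.rho_b[0]
        assert a.sigma_b[0] == b.sigma_b[0]
        assert a.tau_b[0] == b.tau_b[0]

    def test_constant_sample_is_frozen(self):
        s = make_sample(range(20), range(20), [1] * 20)
        bs = bootstrap_temperature(
            s, EstimatorConfig(k_neighbors=3, n_bootstrap=25, seed=1))
        assert np.all(bs.sigma_b == 0.0)
        assert np.all(bs.tau_b == 0.0)
        assert bs.tau_median == 0.0

    def test_medians_inside_intervals(self):
        rng = np.random.default_rng(9)
        s = make_sample(rng.uniform(-30, 30, 60), rng.uniform(-30, 30, 60),
                        rng.integers(0, 2, 60))
        bs = bootstrap_temperature(
            s, EstimatorConfig(k_neighbors=5, n_bootstrap=100, seed=2))
        assert bs.rho_interval[0] <= bs.rho_median <= bs.rho_interval[1]
        assert bs.sigma_interval[0] <= bs.sigma_median <= bs.sigma_interval[1]
        assert bs.ellipse_cov.shape == (2, 2)
        assert bs.ellipse_radius2() > 0

    def test_relabeling_mirrors_rho_only(self):
        rng = np.random.default_rng(12)
        s = make_sample(rng.uniform(-30, 30, 50), rng.uniform(-30, 30, 50),
                        rng.integers(0, 2, 50))
        cfg = EstimatorConfig(k_neighbors=5, n_bootstrap=50, seed=3)
        a = bootstrap_temperature(s, cfg)
        b = bootstrap_temperature(s.complemented(), cfg)
        np.testing.assert_allclose(a.rho_b, 1 - b.rho_b)
        np.testing.assert_allclose(a.sigma_b, b.sigma_b)
        np.testing.assert_allclose(a.tau_b, b.tau_b)


class TestHemisphereSplit:
    def _sample_spanning(self, rng, n_per_side, value_rule):
        lat = rng.uniform(-30, 30, 2 * n_per_side)
        lon = np.concatenate([rng.uniform(-170, -40, n_per_side),
                              rng.uniform(-20, 170, n_per_side)])
        vals = value_rule(lat, lon, rng)
        return make_sample(lat, lon, vals)

    def test_one_hemisphere_empty_drops_feature(self):
        rng = np.random.default_rng(1)
        west_only = make_sample(rng.uniform(-30, 30, 30),
                                rng.uniform(-170, -40, 30),
                                rng.integers(0, 2, 30))
        with pytest.raises(InsufficientSampleError):
            hemisphere_split_test([west_only],
                                  EstimatorConfig(k_neighbors=5))

    def test_single_feature_correlation_undefined(self):
        rng = np.random.default_rng(2)
        s = self._sample_spanning(
            rng, 30, lambda la, lo, r: r.integers(0, 2, len(la)))
        with pytest.raises(ValueError):
            hemisphere_split_test([s], EstimatorConfig(k_neighbors=5))

    def test_smoke_two_features(self):
        rng = np.random.default_rng(7)
        samples = [
            self._sample_spanning(
                rng, 40, lambda la, lo, r: r.integers(0, 2, len(la))),
            self._sample_spanning(
                rng, 40, lambda la, lo, r: (lo > 0).astype(int)),
        ]
        samples[0].feature_id, samples[1].feature_id = "A", "B"
        result, dropped = hemisphere_split_test(
            samples, EstimatorConfig(k_neighbors=5))
        assert dropped == []
        assert set(result["feature_ids"]) == {"A", "B"}
        assert -1.0 <= result["spearman_r"] <= 1.0
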