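"""Bray–Curtis, Mantel tests, composition-size regressions, dispersion."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from islesar.beta import (
    beta_dispersion,
    bray_curtis,
    composition_size_regression,
    dispersion_vs_size,
    mantel_spearman,
    size_distance,
)
from islesar.core import CountTable, DistanceMatrix


class TestBrayCurtis:
    def test_self_distance_zero(self):
        t = CountTable([[3, 1, 0], [3, 1, 0]], ["a", "b"], ["x", "y", "z"])
        d = bray_curtis(t)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_is_one(self):
        t = CountTable([[1, 1, 0], [0, 0, 1]], ["a", "b"], ["x", "y", "z"])
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_direct_formula_example(self):
        # sum|diff| = 2, sum(total) = 6 -> 1/3
        t = CountTable([[2, 0, 1], [1, 1, 1]], ["a", "b"], ["x", "y", "z"])
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_zero_read_sample_rejected(self):
        t = CountTable([[1, 0], [0, 0]], ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="zero-read"):
            bray_curtis(t)


class TestSizeDistance:
    def test_equal_sizes_zero(self, tiny_islands):
        isl = tiny_islands.assign(water_volume_ml=50.0)
        d = size_distance(isl, "water_volume_ml")
        assert np.allclose(d.values, 0.0)

    def test_log_scale_collinearity(self):
        isl = pd.DataFrame({"island_id": ["a", "b", "c"],
                            "water_volume_ml": [10.0, 100.0, 1000.0]})
        d = size_distance(isl, "water_volume_ml")
        assert d.values[0, 2] == pytest.approx(d.values[0, 1] + d.values[1, 2])


def _random_distance(rng, n):
    pts = rng.random((n, 3))
    return DistanceMatrix([f"o{i}" for i in range(n)],
                          squareform(pdist(pts)))


class TestMantel:
    def test_monotone_transform_gives_r_one(self, rng):
        d1 = _random_distance(rng, 8)
        d2 = DistanceMatrix(d1.ids, np.sqrt(d1.values))
        res = mantel_spearman(d1, d2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0 / 100.0)

    def test_joint_relabeling_leaves_r_unchanged(self, rng):
        d1 = _random_distance(rng, 9)
        d2 = _random_distance(rng, 9)
        r0 = mantel_spearman(d1, d2, n_perm=49, seed=1).r
        perm = rng.permutation(9)
        d1p = DistanceMatrix([d1.ids[i] for i in perm], d1.values[np.ix_(perm, perm)])
        d2p = DistanceMatrix([d2.ids[i] for i in perm], d2.values[np.ix_(perm, perm)])
        r1 = mantel_spearman(d1p, d2p, n_perm=49, seed=1).r
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_seeded_reproducibility(self, rng):
        d1, d2 = _random_distance(rng, 8), _random_distance(rng, 8)
        a = mantel_spearman(d1, d2, n_perm=199, seed=5)
        b = mantel_spearman(d1, d2, n_perm=199, seed=5)
        assert a.p_value == b.p_value

    def test_constant_matrix_rejected(self, rng):
        d1 = _random_distance(rng, 6)
        flat = DistanceMatrix(d1.ids, np.ones((6, 6)) - np.eye(6))
        with pytest.raises(ValueError, match="constant"):
            mantel_spearman(d1, flat, n_perm=9, seed=0)


class TestCompositionSizeRegression:
    def test_exact_proportionality(self, rng):
        isl = pd.DataFrame({"island_id": [f"i{k}" for k in range(6)],
                            "water_volume_ml": np.exp(rng.uniform(1, 5, 6))})
        d_size = size_distance(isl, "water_volume_ml")
        d_comm = DistanceMatrix(d_size.ids, 0.1 * d_size.values)
        res = composition_size_regression(d_comm, d_size, b=50, seed=0)
        assert res.fit.slope == pytest.approx(0.1, abs=1e-12)
        assert res.fit.r_squared == pytest.approx(1.0)
        np.testing.assert_allclose(res.slopes.slopes, 0.1, atol=1e-10)

    def test_constant_dissimilarity_zero_slope(self, rng):
        isl = pd.DataFrame({"island_id": [f"i{k}" for k in range(6)],
                            "water_volume_ml": np.exp(rng.uniform(1, 5, 6))})
        d_size = size_distance(isl, "water_volume_ml")
        d_comm = DistanceMatrix(d_size.ids, 0.5 * (1 - np.eye(6)))
        res = composition_size_regression(d_comm, d_size, b=20, seed=0)
        assert res.fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_island_bootstrap_inflates_sd_under_island_effects(self, rng):
        # strong island-level effects on all pairs sharing an island make
        # naive pair resampling overconfident
        n = 15
        effect = rng.normal(0, 1.0, n)
        base = np.abs(effect[:, None] + effect[None, :]) + rng.normal(0, 0.05, (n, n))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
        ids = [f"i{k}" for k in range(n)]
        isl = pd.DataFrame({"island_id": ids,
                            "water_volume_ml": np.exp(rng.uniform(1, 5, n))})
        d_size = size_distance(isl, "water_volume_ml")
        d_comm = DistanceMatrix(ids, base)
        island_boot = composition_size_regression(d_comm, d_size, b=400, seed=2)
        iu = np.triu_indices(n, 1)
        x, y = d_size.values[iu], base[iu]
        pair_slopes = []
        prng = np.random.default_rng(3)
        for _ in range(400):
            take = prng.integers(0, x.size, x.size)
            xs, ys = x[take], y[take]
            pair_slopes.append(((xs - xs.mean()) * (ys - ys.mean())).sum()
                               / ((xs - xs.mean()) ** 2).sum())
        assert island_boot.slopes.slopes.std(ddof=1) > np.std(pair_slopes, ddof=1)


class TestBetaDispersion:
    def test_square_corners_distance_half_diagonal(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        d = DistanceMatrix(list("abcd"), squareform(pdist(pts)))
        res = beta_dispersion(d, ["g"] * 4)
        np.testing.assert_allclose(res.distances, np.sqrt(2) / 2, atol=1e-10)

    def test_singleton_group_distance_zero(self, rng):
        d = _random_distance(rng, 5)
        res = beta_dispersion(d, ["a", "a", "a", "a", "solo"])
        assert res.distances[4] == pytest.approx(0.0)

    def test_euclidean_input_reproduces_coordinate_centroids(self, rng):
        pts = rng.normal(0, 1, (12, 4))
        groups = ["g1"] * 6 + ["g2"] * 6
        d = DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(pts)))
        res = beta_dispersion(d, groups)
        expected = np.empty(12)
        for g, sl in (("g1", slice(0, 6)), ("g2", slice(6, 12))):
            centroid = pts[sl].mean(axis=0)
            expected[sl] = np.linalg.norm(pts[sl] - centroid, axis=1)
        np.testing.assert_allclose(res.distances, expected, atol=1e-10)

    def test_bray_curtis_negative_eigenvalues_clamped(self, rng):
        counts = rng.integers(0, 4, size=(12, 8))
        counts[:, 0] += 1
        t = CountTable(counts, [f"s{i}" for i in range(12)], [f"a{j}" for j in range(8)])
        d = bray_curtis(t)
        res = beta_dispersion(d, ["g1"] * 6 + ["g2"] * 6)
        assert (res.distances >= 0).all()
        assert res.n_negative_eigenvalues > 0  # Bray-Curtis is non-Euclidean


class TestDispersionVsSize:
    def test_matches_hand_ols(self, rng):
        isl = pd.DataFrame({"island_id": ["i1", "i2", "i3"],
                            "water_volume_ml": [10.0, 100.0, 1000.0]})
        from islesar.beta import DispersionResult

        disp = DispersionResult(
            sample_ids=[f"s{i}" for i in range(6)],
            groups=["i1", "i1", "i2", "i2", "i3", "i3"],
            distances=np.array([0.1, 0.2, 0.3, 0.35, 0.5, 0.55]),
            n_negative_eigenvalues=0,
            min_eigenvalue=0.0,
        )
        fit = dispersion_vs_size(disp, isl, "water_volume_ml")
        x = np.log([10, 10, 100, 100, 1000, 1000])
        y = np.array([0.1, 0.2, 0.3, 0.35, 0.5, 0.55])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
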