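"""PCA rotation, minimum-volume enclosing ellipsoids, nestedness."""

import numpy as np
import pytest

from vespaspread.niche import (
    Ellipsoid,
    background_rows,
    compare_niches,
    contains,
    fit_pca,
    mvee,
    nestedness,
)
from vespaspread.occurrences import OccurrenceSet


def _ball(center, radius, d=3):
    c = np.asarray(center, dtype=float)
    A = np.eye(d) / radius**2
    vol = 4 / 3 * np.pi * radius**3
    return Ellipsoid(center=c, shape=A, volume=vol, tolerance=1e-7)


class TestPCA:
    def test_three_dim_data_fully_explained(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(500, 3))
        W = rng.normal(size=(3, 8))
        rot = fit_pca(Z @ W + rng.normal(size=8), n_components=3)
        assert rot.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_equal_ratios(self):
        rng = np.random.default_rng(1)
        rot = fit_pca(rng.normal(size=(10_000, 8)), n_components=3)
        assert np.allclose(rot.explained_variance_ratio, 1 / 8, atol=0.02)

    def test_loadings_orthonormal_and_sign_fixed(self):
        rng = np.random.default_rng(2)
        rot = fit_pca(rng.normal(size=(300, 5)) * [1, 2, 3, 4, 5])
        assert np.allclose(rot.loadings.T @ rot.loadings, np.eye(3), atol=1e-9)
        for k in range(3):
            j = np.argmax(np.abs(rot.loadings[:, k]))
            assert rot.loadings[j, k] > 0

    def test_reconstruction_error_is_discarded_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 6)) * [5, 4, 3, 2, 1, 0.5]
        rot = fit_pca(X, n_components=3)
        Z = (X - rot.means) / rot.scales
        proj = Z @ rot.loadings
        # Pythagoras: squared norm splits into retained + discarded parts
        residual_sq = (Z**2).sum() - (proj**2).sum()
        discarded = (1 - rot.explained_variance_ratio.sum()) * (Z**2).sum()
        assert residual_sq == pytest.approx(discarded, rel=1e-6)

    def test_collinear_layers_rejected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=200)
        with pytest.raises(ValueError, match="collinear|constant"):
            fit_pca(np.column_stack([a, a, rng.normal(size=200)]))


class TestMVEE:
    def test_unit_axis_points_give_unit_ball(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        e = mvee(pts)
        assert e.volume == pytest.approx(4 / 3 * np.pi, abs=1e-6)
        assert np.allclose(e.center, 0, atol=1e-6)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 3))
        e = mvee(pts)
        s = 2.5
        assert mvee(pts * s).volume == pytest.approx(e.volume * s**3, rel=1e-5)
        # rotation leaves volume unchanged
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert mvee(pts @ Q).volume == pytest.approx(e.volume, rel=1e-5)

    def test_all_points_contained_on_every_fit(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            pts = rng.normal(size=(rng.integers(5, 60), 3))
            e = mvee(pts)
            assert np.all(e.mahalanobis_sq(pts) <= 1 + 10 * e.tolerance)

    def test_shape_matrix_symmetric_positive_definite(self):
        rng = np.random.default_rng(7)
        e = mvee(rng.normal(size=(40, 3)))
        assert np.allclose(e.shape, e.shape.T, atol=1e-9)
        assert np.all(np.linalg.eigvalsh(e.shape) > 0)
        assert e.volume == pytest.approx(
            4 / 3 * np.pi / np.sqrt(np.linalg.det(e.shape))
        )

    def test_degenerate_coplanar_rejected(self):
        pts = np.column_stack([np.random.default_rng(8).normal(size=(10, 2)),
                               np.zeros(10)])
        with pytest.raises(ValueError, match="jitter"):
            mvee(pts)

    def test_no_smaller_containing_ellipsoid_found_by_search(self):
        # randomized minimality probe on a small point set
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 3))
        e = mvee(pts, tolerance=1e-9)
        for _ in range(2000):
            dc = rng.normal(scale=0.05, size=3)
            B = rng.normal(scale=0.05, size=(3, 3))
            A_new = e.shape @ (np.eye(3) + B + B.T) * (1 + rng.normal(scale=0.05))
            A_new = (A_new + A_new.T) / 2
            if np.any(np.linalg.eigvalsh(A_new) <= 0):
                continue
            cand = Ellipsoid(
                e.center + dc, A_new,
                4 / 3 * np.pi / np.sqrt(np.linalg.det(A_new)), 1e-9,
            )
            if np.all(cand.mahalanobis_sq(pts) <= 1):
                assert cand.volume >= e.volume * (1 - 1e-6)


class TestNestedness:
    def test_self_nestedness_is_exactly_one(self):
        rng = np.random.default_rng(10)
        e = mvee(rng.normal(size=(25, 3)))
        assert nestedness(e, e, n_mc=20_000, seed=0) == 1.0

    def test_disjoint_is_zero(self):
        assert nestedness(_ball([10, 0, 0], 1), _ball([0, 0, 0], 1), 20_000, 0) == 0.0

    def test_ball_in_larger_ball(self):
        assert nestedness(_ball([0, 0, 0], 1), _ball([0, 0, 0], 2), 20_000, 0) == 1.0

    def test_volume_ratio_recovered(self):
        est = nestedness(_ball([0, 0, 0], 2), _ball([0, 0, 0], 1), 100_000, 1)
        assert est == pytest.approx(1 / 8, abs=4 * np.sqrt(0.125 * 0.875 / 100_000))

    def test_mc_error_scales_with_sample_size(self):
        # empirical spread over seeds tracks sqrt(p(1-p)/n)
        inner, outer = _ball([0, 0, 0], 2), _ball([0, 0, 0], 1)
        ests = [nestedness(inner, outer, 2000, seed=s) for s in range(30)]
        theory = np.sqrt(0.125 * 0.875 / 2000)
        assert 0.4 * theory < np.std(ests) < 2.5 * theory

    def test_deterministic_per_seed(self):
        inner, outer = _ball([0.5, 0, 0], 1.2), _ball([0, 0, 0], 1.0)
        assert nestedness(inner, outer, 5000, 3) == nestedness(inner, outer, 5000, 3)


class TestCompareNiches:
    def test_interior_introduced_points_fully_nested(self, small_stack):
        rot = fit_pca(background_rows(small_stack, n=2000, seed=0))
        tmpl = small_stack.template
        rng = np.random.default_rng(11)
        # native: a broad cloud of cells; introduced: a few of those same cells
        rows = rng.integers(5, 55, 200)
        cols = rng.integers(5, 55, 200)
        lon, lat = tmpl.cell_center(rows, cols)
        native = OccurrenceSet(np.column_stack([lon, lat]))
        # introduced = the 8 records deepest inside the native ellipsoid
        e_native = mvee(rot.project(
            np.column_stack([small_stack[n].values[rows, cols]
                             for n in small_stack.names])
        ))
        depth = e_native.mahalanobis_sq(rot.project(
            np.column_stack([small_stack[n].values[rows, cols]
                             for n in small_stack.names])
        ))
        interior = np.argsort(depth)[:8]
        introduced = OccurrenceSet(
            np.column_stack([lon[interior], lat[interior]]),
            population="introduced",
        )
        cmp = compare_niches(native, introduced, small_stack, rot,
                             n_mc=20_000, seed=0)
        assert cmp.volume_introduced < cmp.volume_native
        assert cmp.nested_fraction >= 0.99

    def test_identical_populations_ratio_one(self, small_stack):
        rot = fit_pca(background_rows(small_stack, n=2000, seed=0))
        tmpl = small_stack.template
        rng = np.random.default_rng(12)
        rows = rng.integers(0, 60, 50)
        cols = rng.integers(0, 60, 50)
        lon, lat = tmpl.cell_center(rows, cols)
        occ = OccurrenceSet(np.column_stack([lon, lat]))
        occ2 = OccurrenceSet(np.column_stack([lon, lat]), population="introduced")
        cmp = compare_niches(occ, occ2, small_stack, rot, n_mc=10_000, seed=0)
        assert cmp.volume_introduced == pytest.approx(cmp.volume_native, rel=1e-4)
        assert cmp.nested_fraction >= 0.999

    def test_tiny_introduced_sample_falls_back_to_containment(self, small_stack):
        rot = fit_pca(background_rows(small_stack, n=2000, seed=0))
        tmpl = small_stack.template
        rng = np.random.default_rng(13)
        rows = rng.integers(0, 60, 100)
        cols = rng.integers(0, 60, 100)
        lon, lat = tmpl.cell_center(rows, cols)
        native = OccurrenceSet(np.column_stack([lon, lat]))
        introduced = OccurrenceSet(
            np.column_stack([lon[:3], lat[:3]]), population="introduced"
        )
        cmp = compare_niches(native, introduced, small_stack, rot,
                             n_mc=10_000, seed=0)
        assert cmp.fallback_containment
        assert cmp.nested_fraction == 1.0  # native subset: always contained

    def test_order_invariance(self, small_stack):
        rot = fit_pca(background_rows(small_stack, n=2000, seed=0))
        tmpl = small_stack.template
        rng = np.random.default_rng(14)
        rows = rng.integers(0, 60, 40)
        cols = rng.integers(0, 60, 40)
        lon, lat = tmpl.cell_center(rows, cols)
        pts = np.column_stack([lon, lat])
        intro = OccurrenceSet(pts[:10], population="introduced")
        a = compare_niches(OccurrenceSet(pts), intro, small_stack, rot, 10_000, 0)
        perm = np.random.default_rng(15).permutation(len(pts))
        b = compare_niches(OccurrenceSet(pts[perm]), intro, small_stack, rot,
                           10_000, 0)
        assert a.volume_native == pytest.approx(b.volume_native, rel=1e-5)
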