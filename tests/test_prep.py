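"""Thinning, accessible area, pseudoabsences and the train/test split."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vespaspread.occurrences import OccurrenceSet
from vespaspread.prep import (
    AccessibleArea,
    accessible_area,
    haversine_km,
    sample_pseudoabsences,
    split_records,
    thin_occurrences,
)
from vespaspread.raster import RasterGrid
from vespaspread.synthetic import gen_elevation


def _oracle_greedy_thin(points, min_km):
    """Independent O(n^2) greedy oracle with its own spherical distance."""
    R = 6371.0088
    kept = []
    for lon, lat in points:
        ok = True
        for klon, klat in kept:
            p1 = math.radians(lat), math.radians(lon)
            p2 = math.radians(klat), math.radians(klon)
            d = R * math.acos(
                min(1.0, math.sin(p1[0]) * math.sin(p2[0])
                    + math.cos(p1[0]) * math.cos(p2[0]) * math.cos(p1[1] - p2[1]))
            )
            if d < min_km:
                ok = False
                break
        if ok:
            kept.append((lon, lat))
    return np.array(kept)


class TestThinning:
    def test_close_pair_collapses(self):
        # ~3 km apart at the equator
        occ = OccurrenceSet(np.array([[100.0, 0.0], [100.027, 0.0]]))
        assert len(thin_occurrences(occ, 5.0)) == 1

    def test_sparse_grid_untouched(self):
        lon, lat = np.meshgrid(np.arange(5) * 0.1, np.arange(5) * 0.09)
        occ = OccurrenceSet(np.column_stack([lon.ravel(), lat.ravel()]))
        assert len(thin_occurrences(occ, 5.0)) == 25

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        pts = np.column_stack(
            [rng.uniform(100, 101, 100), rng.uniform(35, 36, 100)]
        )
        ours = thin_occurrences(OccurrenceSet(pts), 5.0).points
        oracle = _oracle_greedy_thin(pts, 5.0)
        assert np.allclose(ours, oracle)

    def test_empty_input_ok(self):
        occ = OccurrenceSet(np.empty((0, 2)))
        assert len(thin_occurrences(occ, 5.0)) == 0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(100, 102, allow_nan=False),
                st.floats(30, 32, allow_nan=False),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_all_pairs_bound_and_idempotence(self, coords):
        occ = OccurrenceSet(np.array(coords))
        out = thin_occurrences(occ, 5.0)
        pts = out.points
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert (
                    haversine_km(pts[i, 0], pts[i, 1], pts[j, 0], pts[j, 1]) >= 5.0
                )
        again = thin_occurrences(out, 5.0)
        assert np.array_equal(again.points, out.points)


class TestAccessibleArea:
    @pytest.fixture
    def template(self):
        return RasterGrid(
            values=np.zeros((280, 280)),
            origin_lon=-7.0,
            origin_lat=51.0,
            pixel_size=0.05,
        )

    def test_zero_buffer_is_hull(self, template):
        occ = OccurrenceSet(
            np.array([[0.0, 44.0], [1.0, 44.0], [1.0, 45.0], [0.0, 45.0]])
        )
        area = accessible_area(occ, 0.0, template)
        # all interior cell centers of the unit square are masked
        inside = area.mask.values == 1
        rows, cols = np.nonzero(inside)
        lon, lat = template.cell_center(rows, cols)
        assert np.all((lon >= -0.05) & (lon <= 1.05))
        assert np.all((lat >= 43.95) & (lat <= 45.05))
        assert inside.sum() > 0

    def test_mask_monotone_in_buffer(self, template):
        occ = OccurrenceSet(np.array([[0.0, 44.0], [1.0, 44.5], [0.5, 45.0]]))
        a1 = accessible_area(occ, 100.0, template)
        a2 = accessible_area(occ, 200.0, template)
        assert np.all(a2.mask.values >= a1.mask.values)

    def test_buffered_triangle_area_matches_closed_form(self, template):
        # equilateral triangle, side 100 km, centered near 44.5 N
        side = 100.0
        lat0 = 44.5
        dlat = side / 111.195
        dlon = side / (111.195 * math.cos(math.radians(lat0)))
        pts = np.array(
            [
                [0.5 - dlon / 2, lat0],
                [0.5 + dlon / 2, lat0],
                [0.5, lat0 + dlat * math.sqrt(3) / 2],
            ]
        )
        area = accessible_area(OccurrenceSet(pts), 400.0, template)
        rows, cols = np.nonzero(area.mask.values == 1)
        _, lat = template.cell_center(rows, cols)
        cell_km2 = (0.05 * 111.195) ** 2 * np.cos(np.radians(lat))
        measured = cell_km2.sum()
        hull = math.sqrt(3) / 4 * side**2
        expected = hull + 3 * side * 400.0 + math.pi * 400.0**2
        assert measured == pytest.approx(expected, rel=0.05)
        # every input point's own cell is masked
        r, c = template.index_of(pts[:, 0], pts[:, 1])
        assert np.all(area.mask.values[r, c] == 1)

    def test_collinear_points_rejected(self, template):
        occ = OccurrenceSet(np.array([[0.0, 44.0], [0.5, 44.0], [1.0, 44.0]]))
        with pytest.raises(ValueError, match="mask"):
            accessible_area(occ, 100.0, template)


class TestPseudoAbsences:
    @pytest.fixture
    def full_area(self):
        mask = RasterGrid(
            values=np.ones((10, 10), dtype=np.int64),
            origin_lon=0.0,
            origin_lat=10.0,
            pixel_size=0.1,
        )
        return AccessibleArea(mask=mask, source_polygon=np.empty((0, 2)))

    def _elev(self, const):
        return RasterGrid(
            values=np.full((10, 10), float(const)),
            origin_lon=0.0,
            origin_lat=10.0,
            pixel_size=0.1,
            name="elevation",
        )

    def test_forbidden_band_everywhere_errors(self, full_area):
        with pytest.raises(ValueError, match="0 eligible"):
            sample_pseudoabsences(full_area, self._elev(700.0), n=10, seed=0)

    def test_exhaustive_sample_selects_every_cell_once(self, full_area):
        pa = sample_pseudoabsences(full_area, self._elev(0.0), n=100, seed=0)
        assert len(pa) == 100
        assert len({tuple(p) for p in pa.points}) == 100

    def test_sampled_points_respect_elevation_constraint(self):
        elev = gen_elevation(3, shape=(60, 60))
        mask = elev.with_values(np.ones_like(elev.values, dtype=np.int64))
        area = AccessibleArea(mask=mask, source_polygon=np.empty((0, 2)))
        pa = sample_pseudoabsences(area, elev, n=500, seed=9)
        r, c = elev.index_of(pa.lon, pa.lat)
        at = elev.values[r, c]
        assert np.all((at < 400.0) | (at > 1400.0))

    def test_deterministic_per_seed(self, full_area):
        a = sample_pseudoabsences(full_area, self._elev(0.0), n=30, seed=5)
        b = sample_pseudoabsences(full_area, self._elev(0.0), n=30, seed=5)
        assert np.array_equal(a.points, b.points)


class TestSplit:
    def test_half_split_sizes(self):
        s = split_records(np.arange(10), np.arange(20), fraction=0.5, seed=0)
        assert len(s.train_presence) == 5 and len(s.test_presence) == 5
        assert len(s.train_absence) == 10 and len(s.test_absence) == 10

    def test_thinned_record_count_splits_evenly(self):
        # 224 thinned records -> 112 training / 112 validation
        s = split_records(np.arange(224), np.arange(1000), fraction=0.5, seed=1)
        assert len(s.train_presence) == 112 and len(s.test_presence) == 112

    def test_partition_is_disjoint_and_complete(self):
        pres = np.arange(37)
        s = split_records(pres, np.arange(11), fraction=0.3, seed=2)
        union = np.sort(np.concatenate([s.train_presence, s.test_presence]))
        assert np.array_equal(union, pres)

    def test_same_seed_identical(self):
        a = split_records(np.arange(50), np.arange(50), seed=3)
        b = split_records(np.arange(50), np.arange(50), seed=3)
        assert np.array_equal(a.train_presence, b.train_presence)
        assert np.array_equal(a.train_absence, b.train_absence)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_records(np.arange(1), np.arange(10))
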