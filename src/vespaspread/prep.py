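"""Occurrence filtering and background design.

Implements the four preparatory stages of the suitability analysis:

1. spatial thinning at a minimum great-circle distance (default 5 km),
2. the accessible area as a minimum convex polygon of the records buffered
   by 400 km, rasterized onto the environmental lattice,
3. random pseudoabsences drawn from cells of the accessible area lying
   below 400 m or above 1,400 m elevation,
4. a seeded 50/50 train/validation split, stratified by class.

Thinning is deterministic greedy in input order: a record is kept iff it is
at least the minimum distance from every previously kept record — the
common `spThin`-style convention, made reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint

from .occurrences import OccurrenceSet
from .raster import RasterGrid

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEGREE",
    "haversine_km",
    "thin_occurrences",
    "AccessibleArea",
    "accessible_area",
    "PseudoAbsenceSet",
    "sample_pseudoabsences",
    "TrainTestSplit",
    "split_records",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius
KM_PER_DEGREE = 111.195  # one degree of latitude on that sphere


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def thin_occurrences(occ: OccurrenceSet, min_dist_km: float) -> OccurrenceSet:
    """Greedily thin records so all pairwise distances are >= *min_dist_km*.

    Scans in input order; keeps a point iff it is at least *min_dist_km*
    (great-circle) from every previously kept point.  Idempotent, and the
    output is always a subset of the input.
    """
    if not min_dist_km > 0:
        raise ValueError("min_dist_km must be positive")
    pts = occ.points
    if len(pts) == 0:
        return occ.subset(np.array([], dtype=int))
    kept: list[int] = []
    for i in range(len(pts)):
        if not kept:
            kept.append(i)
            continue
        kp = pts[kept]
        d = haversine_km(pts[i, 0], pts[i, 1], kp[:, 0], kp[:, 1])
        if np.all(d >= min_dist_km):
            kept.append(i)
    return occ.subset(np.array(kept, dtype=int))


@dataclass
class AccessibleArea:
    """Buffered convex-hull mask on the analysis lattice.

    ``mask`` is a {0, 1} integer grid; a cell is 1 iff its center falls
    inside the buffered hull.  ``source_polygon`` is the buffered hull's
    exterior ring as (lon, lat) vertices.
    """

    mask: RasterGrid
    source_polygon: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.mask.values.sum())


def accessible_area(
    occ: OccurrenceSet, buffer_km: float, template: RasterGrid
) -> AccessibleArea:
    """Rasterize the *buffer_km*-buffered minimum convex polygon of *occ*.

    Buffering is planar in a local metric: coordinates are scaled to km
    using the hull centroid's latitude (1 deg lat = 111.195 km, 1 deg lon =
    111.195 cos(lat) km), buffered by a Minkowski sum with a 64-vertex
    circle, and mapped back to degrees.  Approximate away from the poles;
    adequate at the 400-km scale used here.
    """
    if buffer_km < 0:
        raise ValueError("buffer_km must be >= 0")
    pts = occ.points
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError(
            "need >= 3 non-collinear points to build a convex hull; "
            "supply an explicit accessible-area mask instead"
        )
    lat0 = hull.centroid.y
    kx = KM_PER_DEGREE * np.cos(np.radians(lat0))
    ky = KM_PER_DEGREE

    hull_km = shapely.transform(hull, lambda xy: xy * np.array([kx, ky]))
    buffered_km = hull_km.buffer(buffer_km, quad_segs=16)  # 64-vertex circle
    buffered = shapely.transform(buffered_km, lambda xy: xy / np.array([kx, ky]))

    rows, cols = np.indices(template.shape)
    lon, lat = template.cell_center(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(buffered, lon, lat).reshape(template.shape)
    mask = template.with_values(inside.astype(np.int64), name="accessible_area")
    mask.nodata = -9999
    return AccessibleArea(
        mask=mask, source_polygon=np.asarray(buffered.exterior.coords)
    )


@dataclass
class PseudoAbsenceSet:
    """Random background points with an elevation constraint."""

    points: np.ndarray  # (n, 2) lon, lat at cell centers
    n_requested: int
    seed: int

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lon(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.points[:, 1]


def sample_pseudoabsences(
    area: AccessibleArea,
    elevation: RasterGrid,
    low_m: float = 400.0,
    high_m: float = 1400.0,
    n: int = 10_000,
    seed: int = 0,
) -> PseudoAbsenceSet:
    """Uniform sample of *n* cells with mask=1 and elevation < *low_m* or
    > *high_m* (strict inequalities), without replacement, placed at cell
    centers.  Deterministic per seed; errors if fewer than *n* cells are
    eligible, reporting the eligible count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = area.mask
    if not mask.same_lattice(elevation):
        raise ValueError("accessible-area mask and elevation not co-registered")
    elev = elevation.values
    eligible = (
        (mask.values == 1)
        & (elevation.data_mask)
        & ((elev < low_m) | (elev > high_m))
    )
    idx = np.flatnonzero(eligible.ravel())
    if idx.size < n:
        raise ValueError(
            f"only {idx.size} eligible cells for {n} pseudoabsences "
            f"(mask=1 and elevation <{low_m} m or >{high_m} m)"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, mask.shape)
    lon, lat = mask.cell_center(rows, cols)
    return PseudoAbsenceSet(np.column_stack([lon, lat]), n_requested=n, seed=seed)


@dataclass
class TrainTestSplit:
    """Seeded random partition, stratified for presences and absences."""

    train_presence: np.ndarray
    test_presence: np.ndarray
    train_absence: np.ndarray
    test_absence: np.ndarray
    fraction: float
    seed: int


def _partition(rows: np.ndarray, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n = len(rows)
    n_train = round(fraction * n)  # ties round to nearest even
    perm = rng.permutation(n)
    return rows[perm[:n_train]], rows[perm[n_train:]]


def split_records(
    presences: np.ndarray,
    absences: np.ndarray,
    fraction: float = 0.5,
    seed: int = 0,
) -> TrainTestSplit:
    """Split presence and absence rows into train/test at *fraction*.

    Rows may be coordinate pairs or extracted feature rows; the split only
    permutes along the first axis.  Stratification is separate per class;
    the train size is ``round(fraction * n)`` with banker's rounding.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    presences = np.asarray(presences)
    absences = np.asarray(absences)
    if len(presences) < 2 or len(absences) < 2:
        raise ValueError("need at least 2 presences and 2 absences to split")
    rng = np.random.default_rng(seed)
    tr_p, te_p = _partition(presences, fraction, rng)
    tr_a, te_a = _partition(absences, fraction, rng)
    return TrainTestSplit(tr_p, te_p, tr_a, te_a, fraction, seed)
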