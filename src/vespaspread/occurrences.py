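"""Occurrence records: labeled lon/lat point sets and CSV ingestion."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OccurrenceSet", "read_occurrences", "write_occurrences"]

POPULATIONS = ("native", "introduced")


@dataclass
class OccurrenceSet:
    """Geographic point records for one population (native or introduced)."""

    points: np.ndarray  # (n, 2) lon, lat
    population: str = "native"
    source: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.population not in POPULATIONS:
            raise ValueError(f"population must be one of {POPULATIONS}")
        if len(pts):
            lon, lat = pts[:, 0], pts[:, 1]
            bad = np.flatnonzero(
                (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
            )
            if bad.size:
                raise ValueError(
                    f"coordinate out of WGS84 range at record {bad[0]}: "
                    f"lon={lon[bad[0]]}, lat={lat[bad[0]]}"
                )
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lon(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def lat(self) -> np.ndarray:
        return self.points[:, 1]

    def subset(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.points[np.asarray(idx)], self.population, self.source)


def read_occurrences(
    path: str | Path,
    population: str = "native",
    lon_col: str = "lon",
    lat_col: str = "lat",
) -> OccurrenceSet:
    """Read a lon/lat CSV into a de-duplicated :class:`OccurrenceSet`.

    The header must contain *lon_col* and *lat_col*.  Exact duplicate
    coordinate pairs are dropped, keeping the first occurrence and preserving
    input order.  An out-of-range coordinate raises with the offending row
    index (0-based, data rows).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in (lon_col, lat_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    lon = df[lon_col].to_numpy(dtype=float)
    lat = df[lat_col].to_numpy(dtype=float)
    bad = np.flatnonzero(
        ~np.isfinite(lon) | ~np.isfinite(lat)
        | (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    )
    if bad.size:
        raise ValueError(
            f"{path}: invalid coordinate in row {bad[0]}: "
            f"lon={lon[bad[0]]}, lat={lat[bad[0]]}"
        )
    seen: set[tuple[float, float]] = set()
    keep = []
    for i, pair in enumerate(zip(lon, lat)):
        if pair not in seen:
            seen.add(pair)
            keep.append(i)
    pts = np.column_stack([lon[keep], lat[keep]])
    return OccurrenceSet(pts, population=population, source=str(path))


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    pd.DataFrame(
        {"lon": occ.lon, "lat": occ.lat, "population": occ.population}
    ).to_csv(path, index=False)
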