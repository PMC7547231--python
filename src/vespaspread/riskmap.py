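"""Bivariate suitability x human-footprint risk classification.

Climate suitability and the human-footprint index are each cut into k
quantile bins (terciles by default, the usual bivariate-choropleth
convention) and combined into a single class code per cell:

    class = (suitability_bin - 1) * k + footprint_bin,   bins in 1..k

so codes run 1..k**2, monotone in each axis with the other held fixed.
Cells with nodata in either input are nodata in the output.  Explicit bin
edges may be supplied where quantiles are inappropriate (e.g. a
near-constant layer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["BivariateClassMap", "bivariate_classify"]


@dataclass
class BivariateClassMap:
    classes: RasterGrid  # integer codes 1..k**2, nodata elsewhere
    bin_edges_suitability: np.ndarray  # interior edges, length k-1
    bin_edges_footprint: np.ndarray
    k: int

    def legend(self) -> pd.DataFrame:
        """Class code -> bin-range table for map legends."""
        def ranges(edges):
            full = np.concatenate([[-np.inf], edges, [np.inf]])
            return [(full[i], full[i + 1]) for i in range(len(full) - 1)]

        rows = []
        for si, (s_lo, s_hi) in enumerate(ranges(self.bin_edges_suitability), 1):
            for fi, (f_lo, f_hi) in enumerate(ranges(self.bin_edges_footprint), 1):
                rows.append(
                    {
                        "class": (si - 1) * self.k + fi,
                        "suitability_bin": si,
                        "footprint_bin": fi,
                        "suitability_low": s_lo,
                        "suitability_high": s_hi,
                        "footprint_low": f_lo,
                        "footprint_high": f_hi,
                    }
                )
        return pd.DataFrame(rows)


def _quantile_edges(vals: np.ndarray, k: int, label: str) -> np.ndarray:
    edges = np.quantile(vals, np.arange(1, k) / k)
    if np.any(np.diff(edges) <= 0) or edges[0] <= vals.min() == vals.max():
        raise ValueError(
            f"degenerate quantile bins for {label} (layer nearly constant); "
            "supply explicit bin edges"
        )
    return edges


def bivariate_classify(
    suitability: RasterGrid,
    footprint: RasterGrid,
    k: int = 3,
    suitability_edges=None,
    footprint_edges=None,
) -> BivariateClassMap:
    """Classify each cell into one of k*k suitability-by-footprint classes.

    Bin edges default to the per-layer quantiles of the non-nodata cells;
    a value equal to an edge falls in the upper bin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not suitability.same_lattice(footprint):
        raise ValueError("suitability and footprint rasters not co-registered")
    valid = suitability.data_mask & footprint.data_mask
    sv = suitability.values
    fv = footprint.values
    if suitability_edges is None:
        if not valid.any():
            raise ValueError("no valid cells to compute quantile edges")
        suitability_edges = _quantile_edges(sv[valid], k, "suitability")
    if footprint_edges is None:
        if not valid.any():
            raise ValueError("no valid cells to compute quantile edges")
        footprint_edges = _quantile_edges(fv[valid], k, "footprint")
    s_edges = np.asarray(suitability_edges, dtype=float)
    f_edges = np.asarray(footprint_edges, dtype=float)
    if len(s_edges) != k - 1 or len(f_edges) != k - 1:
        raise ValueError(f"need exactly {k - 1} interior edges per axis")
    if np.any(np.diff(s_edges) <= 0) or np.any(np.diff(f_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    s_bin = np.searchsorted(s_edges, sv, side="right") + 1  # 1..k
    f_bin = np.searchsorted(f_edges, fv, side="right") + 1
    codes = (s_bin - 1) * k + f_bin
    codes = codes.astype(np.int64)
    codes[~valid] = -9999
    grid = suitability.with_values(codes, name="bivariate_risk")
    grid.nodata = -9999
    return BivariateClassMap(
        classes=grid,
        bin_edges_suitability=s_edges,
        bin_edges_footprint=f_edges,
        k=k,
    )
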