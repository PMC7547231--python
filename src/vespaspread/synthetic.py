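"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline — thinning, background design,
ensemble fitting, niche ellipsoids, risk mapping, dispersal — can be driven
entirely from fields generated here, so nothing needs downloading.  The
generators are pure functions of ``(seed, parameters)``:

* :func:`gen_env_stack` — spatially autocorrelated standardized climate-like
  layers (white noise smoothed by a Gaussian of a chosen correlation length);
* :func:`gen_virtual_species` — a species whose habitat suitability is a
  known logistic function of the layers, with presences sampled
  probability-proportional-to-suitability so the niche edge is soft;
* :func:`gen_elevation` / :func:`gen_footprint` — elevation in [0, 3000] m
  and a human-footprint-index-like field in [0, 50].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .occurrences import OccurrenceSet
from .raster import EnvStack, RasterGrid

__all__ = [
    "VirtualSpeciesTruth",
    "gen_env_stack",
    "gen_virtual_species",
    "gen_elevation",
    "gen_footprint",
    "DEFAULT_LAYER_NAMES",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_QUADRATIC",
    "DEFAULT_INTERCEPT",
]

# Eight layers mirroring the climate variable set used for the hornet:
# four temperature summaries, three precipitation summaries, mean radiation.
DEFAULT_LAYER_NAMES = (
    "temp_mean",
    "temp_range",
    "temp_max_warmest",
    "temp_min_coldest",
    "precip_annual",
    "precip_wettest",
    "precip_driest",
    "radiation_mean",
)

# Virtual-species response: a climatically restricted species with sharp
# unimodal responses to annual temperature, warm-month maximum and annual
# precipitation, plus weaker linear effects of the remaining layers.  The
# resulting suitable fraction (~5% of the domain) and crisp niche edges
# emulate a species confined to a narrow climate band, like the hornet in
# its native range.  Fixed once; see docs/methods.md.
DEFAULT_COEFFICIENTS = (9.0, -1.5, 0.75, 0.75, 6.75, -0.75, 0.375, -0.375)
DEFAULT_QUADRATIC = (-6.0, 0.0, -2.25, 0.0, -4.5, 0.0, 0.0, 0.0)
DEFAULT_INTERCEPT = -4.5

_GRID_DEFAULTS = dict(origin_lon=-130.0, origin_lat=55.0)


@dataclass
class VirtualSpeciesTruth:
    """A generated species with fully known suitability surface."""

    true_suitability: RasterGrid
    response_coefficients: tuple
    occurrence_sample: OccurrenceSet
    seed: int


def _smooth_field(rng: np.random.Generator, shape, correlation_length: float):
    noise = rng.standard_normal(shape)
    if correlation_length > 0:
        noise = gaussian_filter(noise, sigma=correlation_length, mode="reflect")
    return noise


def _standardize(field: np.ndarray) -> np.ndarray:
    return (field - field.mean()) / field.std()


def _check_shape(shape) -> tuple[int, int]:
    nrows, ncols = int(shape[0]), int(shape[1])
    if nrows < 1 or ncols < 1:
        raise ValueError(f"degenerate grid shape {shape}")
    return nrows, ncols


def gen_env_stack(
    seed: int,
    shape: tuple[int, int] = (200, 200),
    pixel_size: float = 5 / 60,
    n_layers: int = 8,
    correlation_length: float = 10.0,
    origin_lon: float = _GRID_DEFAULTS["origin_lon"],
    origin_lat: float = _GRID_DEFAULTS["origin_lat"],
) -> EnvStack:
    """Generate *n_layers* standardized autocorrelated environmental fields.

    Each layer is white noise convolved with a Gaussian of ``sigma =
    correlation_length`` pixels, then standardized to zero mean and unit
    variance.  ``correlation_length=0`` gives i.i.d. per-cell noise.
    Deterministic per seed.
    """
    nrows, ncols = _check_shape(shape)
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    rng = np.random.default_rng(seed)
    names = (
        list(DEFAULT_LAYER_NAMES[:n_layers])
        if n_layers <= len(DEFAULT_LAYER_NAMES)
        else [f"env{i + 1:02d}" for i in range(n_layers)]
    )
    layers = []
    for name in names:
        vals = _standardize(_smooth_field(rng, (nrows, ncols), correlation_length))
        layers.append(
            RasterGrid(
                values=vals,
                origin_lon=origin_lon,
                origin_lat=origin_lat,
                pixel_size=pixel_size,
                name=name,
            )
        )
    return EnvStack(layers)


def gen_virtual_species(
    stack: EnvStack,
    coefficients=None,
    intercept: float = DEFAULT_INTERCEPT,
    n_presences: int = 300,
    seed: int = 0,
    quadratic=None,
) -> VirtualSpeciesTruth:
    """Define a virtual species on *stack* and sample presences from it.

    Suitability is ``logistic(intercept + sum c_i * layer_i + sum q_i *
    layer_i^2)``.  Presences are drawn without replacement from cells with
    positive suitability, with inclusion probability proportional to
    suitability, and placed at cell centers.  Deterministic per seed.
    """
    n_layers = len(stack)
    if coefficients is None:
        coefficients = DEFAULT_COEFFICIENTS[:n_layers]
    if quadratic is None:
        quadratic = DEFAULT_QUADRATIC[:n_layers]
    coefficients = tuple(float(c) for c in coefficients)
    quadratic = tuple(float(q) for q in quadratic)
    if len(coefficients) != n_layers or len(quadratic) != n_layers:
        raise ValueError("coefficient list length must equal layer count")

    arr = stack.array()  # (L, r, c)
    eta = np.full(arr.shape[1:], float(intercept))
    for c, q, layer in zip(coefficients, quadratic, arr):
        eta += c * layer + q * layer**2
    suit = expit(eta)
    tmpl = stack.template
    truth = tmpl.with_values(suit, name="true_suitability")

    rng = np.random.default_rng(seed)
    flat = suit.ravel()
    eligible = np.flatnonzero(flat > 0)
    if n_presences > eligible.size:
        raise ValueError(
            f"n_presences={n_presences} exceeds {eligible.size} cells with "
            "positive suitability"
        )
    w = flat[eligible] / flat[eligible].sum()
    chosen = rng.choice(eligible, size=n_presences, replace=False, p=w)
    rows, cols = np.unravel_index(chosen, suit.shape)
    lon, lat = tmpl.cell_center(rows, cols)
    occ = OccurrenceSet(
        np.column_stack([lon, lat]), population="native", source="virtual-species"
    )
    return VirtualSpeciesTruth(
        true_suitability=truth,
        response_coefficients=coefficients + quadratic,
        occurrence_sample=occ,
        seed=seed,
    )


def _scaled_field(
    seed: int,
    shape,
    pixel_size: float,
    lo: float,
    hi: float,
    correlation_length: float,
    name: str,
    origin_lon: float,
    origin_lat: float,
) -> RasterGrid:
    nrows, ncols = _check_shape(shape)
    rng = np.random.default_rng(seed)
    f = _smooth_field(rng, (nrows, ncols), correlation_length)
    f = (f - f.min()) / (f.max() - f.min())  # min-max to [0, 1]
    return RasterGrid(
        values=lo + f * (hi - lo),
        origin_lon=origin_lon,
        origin_lat=origin_lat,
        pixel_size=pixel_size,
        name=name,
    )


def gen_elevation(
    seed: int,
    shape: tuple[int, int] = (200, 200),
    pixel_size: float = 5 / 60,
    correlation_length: float = 8.0,
    origin_lon: float = _GRID_DEFAULTS["origin_lon"],
    origin_lat: float = _GRID_DEFAULTS["origin_lat"],
) -> RasterGrid:
    """Non-negative smoothed elevation field scaled to [0, 3000] m."""
    return _scaled_field(
        seed, shape, pixel_size, 0.0, 3000.0, correlation_length, "elevation",
        origin_lon, origin_lat,
    )


def gen_footprint(
    seed: int,
    shape: tuple[int, int] = (200, 200),
    pixel_size: float = 5 / 60,
    correlation_length: float = 5.0,
    origin_lon: float = _GRID_DEFAULTS["origin_lon"],
    origin_lat: float = _GRID_DEFAULTS["origin_lat"],
) -> RasterGrid:
    """Human-footprint-index-like field scaled to [0, 50]."""
    return _scaled_field(
        seed, shape, pixel_size, 0.0, 50.0, correlation_length, "footprint",
        origin_lon, origin_lat,
    )
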