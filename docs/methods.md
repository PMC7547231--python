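# Methods

This note documents the models, the synthetic world, the numerical choices
and the known limitations of the pipeline. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and raster conventions

All grids are WGS84 geographic lattices with square pixels, indexed
row-major from the top-left corner. Point-to-cell mapping uses half-open
intervals `[edge, edge + pixel)` on both axes, so extraction is
deterministic on cell boundaries. Nodata propagates: a cell missing in any
required layer is unusable downstream. Reprojection and resampling are out
of scope; the analysis resolution is 5 arcmin (~5.5 km), and distances in
occurrence processing use the haversine formula on a sphere of radius
6371.0088 km (sub-0.5% error at the scales involved).

GeoTIFF I/O is implemented over `tifffile` with the standard geo tags
(ModelPixelScale, ModelTiepoint, a minimal WGS84 GeoKeyDirectory, and
GDAL_NODATA); the ESRI ASCII grid reader/writer is ours. Integer rasters
round-trip bit-exactly; floats to better than 1e−6.

## Occurrence preparation

**Thinning** enforces a minimum pairwise great-circle distance (default
5 km) by a deterministic greedy scan in input order: a record is kept iff
it is far enough from every previously kept record. The rule is idempotent
and first-come-kept; which member of a close pair survives is otherwise
arbitrary, and no algorithm choice here is canonical — this one is
reproducible and matches common `spThin`-style practice.

**Accessible area.** The minimum convex polygon of the thinned records is
buffered (default 400 km) by a planar Minkowski sum with a 64-vertex
circle, after scaling coordinates to km with the hull centroid's latitude
(1° lat = 111.195 km, 1° lon = 111.195·cos φ km). This avoids projection
machinery at the cost of a small distortion far from the centroid latitude;
it is not geodesic-exact and degrades toward the poles.

**Pseudoabsences** (default 10,000) are drawn uniformly without replacement
from accessible cells whose elevation is strictly below 400 m or strictly
above 1,400 m, and placed at cell centers (sub-pixel position carries no
information for the models). The strictness of the inequalities is a
convention; the complementary band is excluded entirely.

**Split.** Presences and pseudoabsences are partitioned 50/50 into
training and validation independently per class, with banker's rounding of
the train count. A single seeded split is used (repeatable via config);
repeated cross-validation is not implemented.

## Consensus ensemble

The five member families are realized as:

| member | realization |
|---|---|
| GLM | logistic regression, linear + quadratic term per variable |
| GAM stand-in | logistic regression on a per-variable cubic spline basis (5 quantile knots) |
| boosted trees | gradient boosting, 500 trees, depth ≤ 3, learning rate 0.05 |
| random forest | 500 trees, min leaf 2 |
| MaxEnt equivalent | L1-penalized logistic regression on linear + quadratic + pairwise products, background as contrast class |

The MaxEnt member relies on the established equivalence between MaxEnt
with background points and penalized logistic regression on the same
features. Because pseudoabsences outnumber presences by orders of
magnitude, absence rows are down-weighted so total class weights are equal;
without this the intercept swamps the signal. Stochastic members are
seeded; linear members drop constant columns with a warning.

The consensus is the unweighted mean of member suitabilities (a
TSS-weighted mean is available but not the default — the reference
procedure simply averages). Evaluation on the hold-out uses a rank-based
AUC (ties counted one half) and TSS maximized over the observed predicted
values as thresholds, with the classification rule "predicted ≥ t ⇒
presence" and the largest maximizing threshold reported. Binary maps
default to the TSS-maximizing threshold, which also serves as the hard
suitability floor of the dispersal automaton.

## Realized-niche ellipsoids

The 3-D environmental space is a PCA of the standardized background
environment (10,000 random valid cells), not of the species records —
niche volumes are meant to be compared inside one fixed environmental
space. Components are fixed at three; the share of variance they retain is
reported and a warning is raised below 90% (on the synthetic world, whose
eight layers are independent by construction, three components necessarily
retain well under 90% — the warning is expected there and harmless).
Component signs are fixed by making each component's largest-magnitude
loading positive.

The minimum-volume enclosing ellipsoid is computed by Khachiyan iterative
reweighting with Wolfe–Atwood away steps (plain Khachiyan converges only
sublinearly and cannot reach tight tolerances in reasonable time). The
stopping rule is a duality-gap criterion of 1e−7 per dimension by default;
after convergence the shape matrix is rescaled, if necessary, so every
generating point is contained exactly (inflation at most of tolerance
order). Affinely degenerate inputs raise an error suggesting jitter or
dimension reduction rather than returning a flat ellipsoid.

Nestedness of ellipsoid A within B is the Monte-Carlo fraction of points
uniform in A (unit-ball draws mapped through A's affine transform) falling
in B; the standard error is at most `0.5/√n_mc` (~0.0016 at the default
1e5 samples). When the introduced sample is too small for an ellipsoid
(fewer than 4 usable, affinely independent points — the real introduced
record set is a handful of detections), the comparison degrades gracefully
to the fraction of introduced points contained in the native ellipsoid and
is flagged as such.

## Bivariate risk map

Suitability and human footprint are each cut into k = 3 quantile bins of
their valid cells (the standard bivariate-choropleth convention; the
reference figure does not state its binning) and combined as
`(s_bin − 1)·k + f_bin`, codes 1..9, monotone in each axis. Values equal
to an edge fall in the upper bin. Explicit edges can be supplied when
quantiles degenerate (near-constant layers).

## Dispersal automaton

One step is one year (colonies are founded annually). Every previously
colonized cell is a source; sources produce propagules with probability 1
per year (the literal reading of the reference procedure — no stochastic
extinction, no maturity delay). Short-range colonization: each uncolonized
cell within Euclidean pixel distance ≤ 9 of a producing source receives an
independent attempt succeeding with probability `P(d)·suitability`, with
`P(d) = exp(−λ(d−1))` and the integer-rounded pixel distance indexing the
kernel. Long-range: with probability `ldd_prob` per source per year, one
propagule lands on a uniformly random cell at distance in (9, 20] pixels
and establishes with probability equal to the target's suitability. Cells
below the suitability floor never colonize; colonization is permanent; the
lattice edge absorbs.

Offsets are admitted to each ring by *true* Euclidean distance, so the
reachability bounds (≤ 9 px/step short-only, ≤ 20 px/step with jumps) hold
exactly for every seed; rounding is used only for the kernel lookup.
Internally the per-cell colonization probability is aggregated as
`1 − Π(1 − P(d)·s)` over contributing sources, which is exactly the
independent-attempts model and allows a vectorized update.

Free parameters the reference procedure does not pin down, with defaults:

- **λ (decay rate per pixel) = 0.3**, giving P(9 px) ≈ 0.09; the kernel
  family and range are fixed by observation (the congener *V. velutina*
  spread 18–78 km/y in Europe, mean ~49.5 km, max ~110 km) but not the
  rate. Properties asserted in tests are λ-robust.
- **ldd_prob = 0.05** per source per year. The reference "dispersal
  probability of 1" describes propagule *production*, not jump frequency;
  the jump frequency is genuinely unstated and 0.05 is a typical value for
  this simulator family. This is the largest interpretive choice in the
  package and is exposed prominently in the config.

Spread summaries report distances as Euclidean pixel offsets scaled by the
pixel size in km (planar approximation; exactly linear in `pixel_km`), and
the mean front speed as the final maximum distance over the number of
steps.

## The synthetic world

`gen_env_stack` builds each layer as white noise convolved with a Gaussian
of σ = `correlation_length` pixels (default 10), standardized; Gaussian
convolution was preferred over spectral synthesis for simplicity. Default
eight layers mirror the climate variable set (four temperature, three
precipitation, one radiation summary). Elevation and footprint are min-max
scaled smoothed fields on [0, 3000] m and [0, 50].

The virtual species has suitability `logistic(β₀ + Σβᵢxᵢ + Σqᵢxᵢ²)` with
sharp unimodal responses to three layers and weak linear effects of the
rest (defaults in `synthetic.py`), making ~5% of the domain suitable with
crisp niche edges — a climatically restricted species, which is the regime
the hornet analysis operates in. This matters: with presences sampled
probability-proportional-to-suitability, the Bayes-optimal AUC against
uniform background is bounded near `1 − prevalence/2`, so a widespread,
soft-niched species cannot support high-AUC recovery no matter how good
the model. Presences are drawn without replacement, PPS, so the niche edge
stays soft like real data. The generators are pure functions of
`(seed, parameters)`.

What a green end-to-end test does **not** establish: robustness to the
sampling bias, spatial clustering and positional error of real GBIF-style
records; to correlated predictors (the synthetic layers are independent);
to non-equilibrium occupancy; or to the realism of any particular λ or
`ldd_prob`.

## Reproducibility

Every stochastic stage derives its seed as
`sha256(master_seed:stage_name) mod 2³¹`, so adding a stage never perturbs
the others. The run manifest records the config echo, all stage seeds and
input hashes; an identical config reproduces bit-identical outputs (verified
at reduced scale in the test suite to respect its time budget).

## Known limitations

- Buffering and simulation distances are planar approximations; fine near
  the study extent's latitude band, wrong near the poles.
- The GAM stand-in is a fixed spline basis, not a penalized smoother; no
  claim of numerical agreement with biomod2/MaxEnt outputs is made, and the
  reference analysis' exact AUC/TSS (0.95/0.34) are not reproduction
  targets — its TSS in particular depends on an unstated threshold rule.
- Dispersal omits barriers, habitat change, per-cell propagule pressure
  and re-colonization dynamics, matching the reference configuration that
  assumed none of them.
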