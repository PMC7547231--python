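# vespaspread

Invasion-risk modelling for the Asian giant hornet (*Vespa mandarinia*) —
and, more generally, a reusable pipeline for presence-background species
distribution modelling coupled to a cellular-automaton spread simulation.

The hornet, native to East Asia, was detected in British Columbia and
Washington State in 2019–2020. Assessing where it could establish and how
fast it could spread requires four linked analyses, all implemented here:

1. **Occurrence preparation** — spatial thinning of records at a 5-km
   minimum great-circle distance; an *accessible area* built as the
   400-km-buffered minimum convex polygon of the records; 10,000 random
   pseudoabsences drawn from accessible cells below 400 m or above 1,400 m
   elevation; a seeded 50/50 train/validation split.
2. **Consensus habitat suitability** — five member models (GLM with
   quadratic terms, spline-basis GAM stand-in, gradient-boosted trees,
   random forest, and an L1-penalized logistic MaxEnt equivalent) averaged
   into a consensus surface, evaluated by AUC (rank statistic, ties half)
   and TSS, `TSS = max_t [sens(t) + spec(t) − 1]`.
3. **Realized-niche comparison** — native and introduced records projected
   into a 3-D principal-component space built from a 10,000-cell background
   environmental sample; each population's niche summarized as its
   minimum-volume enclosing ellipsoid (Khachiyan/Wolfe–Atwood algorithm);
   niche conservatism quantified as the Monte-Carlo fraction of the
   introduced ellipsoid's volume nested inside the native one.
4. **Dispersal simulation** — an annual-step, suitability-gated cellular
   automaton: every colonized cell emits propagules each year; short-range
   colonization follows `P(d) = exp(−λ(d−1))` over pixel distances
   d ≤ 9 (~49.5 km at 5-arcmin pixels); rare human-mediated jumps land
   uniformly at distances in (9, 20] pixels (~110 km); an attempt succeeds
   with probability `P(d) × suitability(target)`.

A **synthetic-data module** generates every input with known ground truth
(autocorrelated climate fields, a virtual species with a known suitability
function, elevation and human-footprint layers), so the whole pipeline is
testable offline; a **bivariate risk map** combines suitability and human
footprint into 3×3 quantile classes.

## Worked example

Run the full synthetic pipeline from one master seed:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints (numbers are exactly reproducible for this seed):

```
run directory: scratch/acceptance_run_seed1
ensemble hold-out AUC 0.944, TSS 0.784
niche volumes (native/introduced): 103.91 / 0.202, nested fraction 1.000
dispersal [short]: 282 cells, front 80.1 km (4.0 km/y)
dispersal [short_ldd]: 1173 cells, front 372.3 km (18.6 km/y)
```

Reading: the consensus model discriminates the virtual species' habitat
from background almost perfectly on held-out data (AUC 0.944); the small
introduced population occupies a tiny environmental volume entirely nested
inside the native niche (fraction 1.000), i.e. nothing about the introduced
records suggests a niche shift; and enabling long-distance jumps quadruples
the colonized area and raises the 20-year front speed from 4 to ~19 km/y.
Every product (suitability, binary map, risk classes, colonization-step
rasters, spread trajectories, manifest with all stage seeds) is written to
the run directory.

The same stages are available as a CLI (`vespaspread synth | thin |
background | fit | predict | evaluate | niche | riskmap | simulate | run`)
and as plain library functions (`vespaspread.prep`, `.ensemble`, `.niche`,
`.riskmap`, `.dispersal`, `.pipeline`).

## What `scripts/acceptance.py` does

It executes the complete synthetic pipeline — input generation, thinning,
background design, ensemble fit/evaluation/prediction, niche-ellipsoid
comparison, risk classification, and both dispersal scenarios — from the
given `--seed`, prints the headline quantities of the run, and writes the
results JSON to `--out`. The quantitative correctness of each stage is
asserted by `tests/test_acceptance.py` (oracle equivalence of thinning,
ellipsoid geometry and nestedness calibration, hand-enumerated AUC/TSS,
virtual-species recovery, automaton reachability and colonization
frequencies, and bit-level reproducibility).
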