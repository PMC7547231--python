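"""End-to-end pipeline orchestration with seeded reproducibility.

``run_all`` executes the full analysis — thin -> accessible area ->
pseudoabsences -> split -> fit ensemble -> evaluate -> predict -> niche
comparison -> bivariate risk map -> dispersal simulation (two scenarios) —
from a single :class:`RunConfig`, writing every product plus a
machine-readable manifest under a run directory.  In synthetic mode the
inputs are generated by :mod:`vespaspread.synthetic` first, so a complete
run needs no external data.

Each stochastic stage draws its seed deterministically from the master
seed and the stage name (a hashed substream), so adding or reordering
stages never perturbs the randomness of the others and an identical config
reproduces bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dispersal, ensemble, niche, prep, riskmap, synthetic
from .occurrences import OccurrenceSet, write_occurrences
from .raster import RasterGrid, extract_values, write_raster

__all__ = ["RunConfig", "stage_seed", "run_all"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """All stage parameters, at the analysis defaults.

    Defaults: 5-km thinning, 400-km buffered convex hull, 10,000
    pseudoabsences from <400 m or >1,400 m elevation, a 50/50
    train/validation split, the five-member ensemble with mean consensus,
    and a 20-year simulation with a 9-px short / 20-px long kernel at a
    5-arcmin (~5.5 km) pixel.
    """

    master_seed: int = 0
    # occurrence prep
    thin_km: float = 5.0
    buffer_km: float = 400.0
    n_pseudoabsences: int = 10_000
    elev_low_m: float = 400.0
    elev_high_m: float = 1400.0
    split_fraction: float = 0.5
    # ensemble
    member_kinds: tuple = ensemble.MEMBER_KINDS
    consensus_rule: str = "mean"
    # niche
    n_background: int = 10_000
    n_mc_nestedness: int = 100_000
    # risk map
    risk_bins: int = 3
    # dispersal
    n_steps: int = 20
    short_max_px: int = 9
    ldd_min_px: int = 9
    ldd_max_px: int = 20
    decay_rate: float = 0.3
    ldd_prob: float = 0.05
    propagule_prob: float = 1.0
    pixel_km: float = dispersal.DEFAULT_PIXEL_KM
    # synthetic world
    grid_shape: tuple = (200, 200)
    pixel_size: float = 5 / 60
    n_layers: int = 8
    correlation_length: float = 10.0
    n_presences: int = 300
    n_introduced: int = 10
    raster_format: str = "ascii"

    def kernel_spec(self, ldd: bool, floor: float) -> dispersal.KernelSpec:
        return dispersal.KernelSpec(
            short_max_px=self.short_max_px,
            ldd_min_px=self.ldd_min_px,
            ldd_max_px=self.ldd_max_px,
            decay_rate=self.decay_rate,
            ldd_prob=self.ldd_prob if ldd else 0.0,
            propagule_prob=self.propagule_prob,
            suitability_floor=floor,
        )


def _sha256_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _gen_introduced(
    truth: synthetic.VirtualSpeciesTruth, n: int, seed: int, window_px: int = 12
) -> OccurrenceSet:
    """A small introduced population clustered near the suitability optimum.

    Emulates the handful of detection records at an invasion front: cells
    are drawn proportional to suitability within a window around the most
    suitable cell.
    """
    suit = truth.true_suitability
    vals = suit.values
    i0, j0 = np.unravel_index(np.argmax(vals), vals.shape)
    r0, r1 = max(0, i0 - window_px), min(vals.shape[0], i0 + window_px + 1)
    c0, c1 = max(0, j0 - window_px), min(vals.shape[1], j0 + window_px + 1)
    sub = vals[r0:r1, c0:c1]
    rng = np.random.default_rng(seed)
    flat = sub.ravel()
    chosen = rng.choice(flat.size, size=min(n, flat.size), replace=False,
                        p=flat / flat.sum())
    rr, cc = np.unravel_index(chosen, sub.shape)
    lon, lat = suit.cell_center(rr + r0, cc + c0)
    return OccurrenceSet(
        np.column_stack([lon, lat]), population="introduced", source="synthetic"
    )


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = config.raster_format
    ext = ".asc" if fmt == "ascii" else ".tif"

    def save(grid: RasterGrid, stem: str) -> None:
        write_raster(grid, out / f"{stem}{ext}", format=fmt)

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "input_hashes": {},
        "stages": {},
    }

    def seed_for(stage: str) -> int:
        s = stage_seed(config.master_seed, stage)
        manifest["stage_seeds"][stage] = s
        return s

    # ---- synthetic inputs ------------------------------------------------
    stack = synthetic.gen_env_stack(
        seed_for("env"),
        shape=config.grid_shape,
        pixel_size=config.pixel_size,
        n_layers=config.n_layers,
        correlation_length=config.correlation_length,
    )
    truth = synthetic.gen_virtual_species(
        stack, n_presences=config.n_presences, seed=seed_for("species")
    )
    elevation = synthetic.gen_elevation(
        seed_for("elevation"), shape=config.grid_shape, pixel_size=config.pixel_size
    )
    footprint = synthetic.gen_footprint(
        seed_for("footprint"), shape=config.grid_shape, pixel_size=config.pixel_size
    )
    native_occ = truth.occurrence_sample
    introduced_occ = _gen_introduced(
        truth, config.n_introduced, seed_for("introduced")
    )
    manifest["input_hashes"] = {
        "env_stack": _sha256_array(stack.array()),
        "elevation": _sha256_array(elevation.values),
        "footprint": _sha256_array(footprint.values),
        "true_suitability": _sha256_array(truth.true_suitability.values),
        "native_occurrences": _sha256_array(native_occ.points),
        "introduced_occurrences": _sha256_array(introduced_occ.points),
    }
    save(truth.true_suitability, "true_suitability")
    save(elevation, "elevation")
    save(footprint, "footprint")
    write_occurrences(native_occ, out / "occurrences_native.csv")
    write_occurrences(introduced_occ, out / "occurrences_introduced.csv")

    # ---- occurrence prep -------------------------------------------------
    thinned = prep.thin_occurrences(native_occ, config.thin_km)
    write_occurrences(thinned, out / "occurrences_thinned.csv")
    area = prep.accessible_area(thinned, config.buffer_km, stack.template)
    save(area.mask, "accessible_area")
    pa = prep.sample_pseudoabsences(
        area,
        elevation,
        low_m=config.elev_low_m,
        high_m=config.elev_high_m,
        n=config.n_pseudoabsences,
        seed=seed_for("pseudoabsence"),
    )
    np.savetxt(
        out / "pseudoabsences.csv",
        pa.points,
        delimiter=",",
        header="lon,lat",
        comments="",
        fmt="%.8f",
    )
    manifest["stages"]["prep"] = {
        "n_raw": len(native_occ),
        "n_thinned": len(thinned),
        "n_accessible_cells": area.n_cells,
        "n_pseudoabsences": len(pa),
    }

    # ---- extraction and split -------------------------------------------
    def usable_rows(points: np.ndarray) -> np.ndarray:
        occ = OccurrenceSet(points)
        df = extract_values(stack, occ)
        ok = ~(df["outside"] | df["nodata"])
        return df.loc[ok, stack.names].to_numpy(dtype=float)

    pres_rows = usable_rows(thinned.points)
    abs_rows = usable_rows(pa.points)
    split = prep.split_records(
        pres_rows, abs_rows, fraction=config.split_fraction, seed=seed_for("split")
    )

    # ---- ensemble --------------------------------------------------------
    ens = ensemble.fit_ensemble(
        split.train_presence,
        split.train_absence,
        seed=seed_for("fit"),
        kinds=config.member_kinds,
        consensus_rule=config.consensus_rule,
        feature_names=stack.names,
    )
    for m in ens.members:
        ens.evaluations[m.kind] = ensemble.evaluate(
            m, split.test_presence, split.test_absence
        )
    ens_eval = ensemble.evaluate(ens, split.test_presence, split.test_absence)
    ens.evaluations["ensemble"] = ens_eval
    suitability = ensemble.predict_ensemble(ens, stack)
    save(suitability, "suitability")
    binary = ensemble.binarize(suitability, ens_eval.tss_threshold)
    save(binary, "suitability_binary")
    manifest["stages"]["ensemble"] = {
        kind: dataclasses.asdict(res) for kind, res in ens.evaluations.items()
    }

    # ---- niche comparison ------------------------------------------------
    bg = niche.background_rows(stack, n=config.n_background,
                               seed=seed_for("niche_background"))
    rotation = niche.fit_pca(bg, n_components=3)
    cmp = niche.compare_niches(
        thinned,
        introduced_occ,
        stack,
        rotation,
        n_mc=config.n_mc_nestedness,
        seed=seed_for("nestedness"),
    )
    np.savetxt(out / "pca_loadings.csv", rotation.loadings, delimiter=",")
    manifest["stages"]["niche"] = {
        "explained_variance_ratio": rotation.explained_variance_ratio.tolist(),
        "volume_native": cmp.volume_native,
        "volume_introduced": cmp.volume_introduced,
        "nested_fraction": cmp.nested_fraction,
        "fallback_containment": cmp.fallback_containment,
    }

    # ---- bivariate risk map ---------------------------------------------
    risk = riskmap.bivariate_classify(suitability, footprint, k=config.risk_bins)
    save(risk.classes, "risk_classes")
    risk.legend().to_csv(out / "risk_legend.csv", index=False)
    manifest["stages"]["riskmap"] = {
        "bin_edges_suitability": risk.bin_edges_suitability.tolist(),
        "bin_edges_footprint": risk.bin_edges_footprint.tolist(),
    }

    # ---- dispersal simulation (two scenarios) ----------------------------
    floor = ens_eval.tss_threshold
    for label, ldd in (("short", False), ("short_ldd", True)):
        spec = config.kernel_spec(ldd=ldd, floor=floor)
        state, summary = dispersal.run(
            introduced_occ,
            suitability,
            spec,
            n_steps=config.n_steps,
            seed=seed_for(f"simulate_{label}"),
        )
        save(state.colonization_step, f"colonization_{label}")
        summary.to_frame().to_csv(out / f"spread_{label}.csv", index=False)
        manifest["stages"][f"dispersal_{label}"] = {
            "n_occupied_final": state.n_occupied,
            "max_distance_km": float(summary.max_distance_km[-1]),
            "mean_front_speed_km_y": summary.mean_front_speed_km_y,
        }

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
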