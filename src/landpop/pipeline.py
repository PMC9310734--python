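"""End-to-end orchestration: simulate -> popgen -> enm -> resistance -> stats.

A single config drives the whole analysis. The synthetic stage couples
population differentiation to terrain least-cost distance (gene flow
decays with accumulated terrain resistance), so the downstream inference
— Mantel tests, MMRR and GDM on the five predictor matrices (IBD,
IBR_Terrain, IBR_Habitat, IBI, IBE) against FST — has a known ground
truth: the terrain/geography predictors are causal, the environmental
distance is not.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import enm as enm_mod
from . import popgen, resistance, stats, synthetic
from .gl import read_beagle, write_beagle
from .matrices import DistanceMatrix
from .raster import read_ascii_grid, write_ascii_grid

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "landscape": {"shape": [48, 48], "extent": [-79.0, -1.0, -78.0, 0.0], "roughness": 1.2},
    "occurrences": {"n": 300},
    "localities": {"k": 5, "min_sep_km": 20.0, "near_pair_km": 12.0,
                   "n_ind_per_locality": 10, "ind_scatter_km": 1.0},
    "genetics": {"n_sites": 5000, "depth_mean": 8.0, "error_rate": 0.01,
                 "sigma": 1.2, "range_relative": 0.5},
    "enm": {"n_background": 10000, "train_frac": 0.8, "reps": 10, "max_iter": 500,
            "exclude_models": []},
    "resistance": {"hull_buffer_deg": 0.4, "elev_margin_m": 100.0,
                   "snap_radius_cells": 2.0, "epsilon": 1e-6},
    "stats": {"n_perm_mantel": 10000, "n_perm_mmrr": 10000, "n_perm_gdm": 500,
              "alpha": 0.05},
}


def merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    for section in DEFAULT_CONFIG:
        if section == "seed":
            continue
        if not isinstance(cfg.get(section), dict):
            raise ValueError(f"config section '{section}' missing or not a mapping")
        unknown = set(cfg[section]) - set(DEFAULT_CONFIG[section])
        if unknown:
            raise ValueError(f"unknown config keys in '{section}': {sorted(unknown)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None,
                 seed: int | None = None) -> dict:
    """Run the full analysis; returns the report dict (also written to out_dir)."""
    cfg = merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    rng = np.random.default_rng(cfg["seed"])
    seeds = {k: int(rng.integers(2**31 - 1)) for k in
             ("landscape", "occurrences", "localities", "genetics", "enm", "stats")}
    report: dict = {"config_hash": config_hash(cfg), "seed": cfg["seed"],
                    "stages": {}, "tables": {}}
    t_start = time.time()

    def stage_done(name):
        report["stages"][name] = {"wall_s": round(time.time() - t_start, 2)}

    # -- simulate landscape, occurrences, localities ------------------------
    lc = cfg["landscape"]
    bundle = synthetic.generate_landscape(
        tuple(lc["shape"]), tuple(lc["extent"]), lc["roughness"], seeds["landscape"]
    )
    suit_true = bundle.true_suitability("current")
    occ = synthetic.generate_occurrences(suit_true, cfg["occurrences"]["n"],
                                         seeds["occurrences"])
    stage_done("landscape")

    # -- terrain resistance -------------------------------------------------
    rc = cfg["resistance"]
    tri = resistance.terrain_ruggedness(bundle.elevation)
    occ_rc = [bundle.elevation.index_of(lon, lat) for lon, lat in occ]
    occ_elev = np.array([bundle.elevation.values[r, c] for r, c in occ_rc])
    tri_masked = resistance.elevation_mask(
        tri, occ, occ_elev, elevation=bundle.elevation,
        hull_buffer_deg=rc["hull_buffer_deg"], elev_margin_m=rc["elev_margin_m"],
    )
    occ_tri = np.array([tri.values[r, c] for r, c in occ_rc])
    terrain_cost = resistance.tri_cost_surface(tri_masked, occ_tri)
    terrain_graph = resistance.build_transition_graph(terrain_cost, rc["epsilon"])
    loc_cfg = cfg["localities"]
    localities = synthetic.place_localities(
        terrain_cost.raster, loc_cfg["k"], loc_cfg["min_sep_km"],
        loc_cfg["near_pair_km"], loc_cfg["n_ind_per_locality"],
        loc_cfg["ind_scatter_km"], seeds["localities"],
    )
    ibr_terrain = resistance.least_cost_distances(
        terrain_graph, localities, rc["snap_radius_cells"], kind="IBR_Terrain"
    )
    stage_done("terrain")

    # -- genetics coupled to terrain least-cost distance ---------------------
    gc = cfg["genetics"]
    truth = synthetic.MetapopulationTruth.default(
        n_pops=loc_cfg["k"], n_ind_per_pop=loc_cfg["n_ind_per_locality"],
        n_sites=gc["n_sites"], fst_target=0.0, depth_mean=gc["depth_mean"],
        error_rate=gc["error_rate"], seed=seeds["genetics"],
    )
    d = ibr_terrain.values
    off = d[np.triu_indices_from(d, k=1)]
    range_km = gc["range_relative"] * float(np.median(off))
    pop_freqs = synthetic.spatial_population_frequencies(
        d, truth.ancestral_freqs, gc["sigma"], range_km, seeds["genetics"]
    )
    sim = synthetic.simulate_genotype_likelihoods(truth, pop_freqs)
    # align individual names with the locality table
    sim.gl.individuals = list(localities.individuals["individual"])
    stage_done("genetics")

    # -- popgen: FST matrix ---------------------------------------------------
    fst, fst_raw = popgen.fst_matrix(sim.gl, localities)
    stage_done("popgen")

    # -- niche model, stability ----------------------------------------------
    ec = cfg["enm"]
    model, fit_report = enm_mod.fit_suitability(
        occ, bundle.bioclim, ec["n_background"], ec["train_frac"], ec["reps"],
        seeds["enm"], max_iter=ec["max_iter"],
    )
    suit_by_epoch = {}
    for epoch, layers in bundle.epochs.items():
        if epoch in ec["exclude_models"]:
            continue
        suit_by_epoch[epoch] = enm_mod.predict_suitability(model, layers)
    stability = enm_mod.habitat_stability(list(suit_by_epoch.values()))
    mess_ref = {
        name: enm_mod._extract_layer_values({name: bundle.bioclim[name]},
                                            occ[:, 0], occ[:, 1]).ravel()
        for name in bundle.bioclim
    }
    mess_lgm = enm_mod.mess(mess_ref, bundle.epochs["lgm"])
    stage_done("enm")

    # -- habitat / stability resistance --------------------------------------
    def _masked_like(r, lower_zero):
        return resistance.elevation_mask(
            r, occ, occ_elev, elevation=bundle.elevation,
            hull_buffer_deg=rc["hull_buffer_deg"], elev_margin_m=rc["elev_margin_m"],
            lower_bound_zero=lower_zero,
        )

    habitat_cost = resistance.suitability_cost_surface(
        _masked_like(suit_by_epoch["current"], False)
    )
    stability_cost = resistance.suitability_cost_surface(
        _masked_like(stability, True), provenance="one-minus-stability"
    )
    ibr_habitat = resistance.least_cost_distances(
        resistance.build_transition_graph(habitat_cost, rc["epsilon"]),
        localities, rc["snap_radius_cells"], kind="IBR_Habitat",
    )
    ibi = resistance.least_cost_distances(
        resistance.build_transition_graph(stability_cost, rc["epsilon"]),
        localities, rc["snap_radius_cells"], kind="IBI",
    )
    stage_done("resistance")

    # -- matrix statistics ----------------------------------------------------
    sc = cfg["stats"]
    ibd = stats.geographic_distance_matrix(localities)
    cent = localities.centroids()
    env_vals = enm_mod._extract_layer_values(bundle.bioclim, cent[:, 0], cent[:, 1])
    ibe = stats.environmental_distance_matrix(env_vals, labels=localities.names)
    fst_norm = stats.normalize_fst(fst)

    predictors = {"IBD": ibd, "IBR_Terrain": ibr_terrain,
                  "IBR_Habitat": ibr_habitat, "IBI": ibi, "IBE": ibe}
    srng = np.random.default_rng(seeds["stats"])
    mantel_table = {}
    for name, mat in predictors.items():
        res = stats.mantel_test(
            mat, fst_norm, sc["n_perm_mantel"], standardize_by_mean=True,
            seed=int(srng.integers(2**31 - 1)),
        )
        mantel_table[name] = {"r": res.r, "r_squared": res.r_squared, "p": res.p}
    # MMRR: best non-environmental predictor (highest Mantel r^2) plus IBE
    geo_like = {k: v for k, v in mantel_table.items() if k != "IBE"}
    best = max(geo_like, key=lambda k: geo_like[k]["r_squared"])
    mmrr_res = stats.mmrr(
        fst_norm, [predictors[best], predictors["IBE"]], sc["n_perm_mmrr"],
        seed=int(srng.integers(2**31 - 1)),
    )
    gdm_model = stats.gdm_backward_elimination(
        fst, list(predictors.values()), sc["n_perm_gdm"], sc["alpha"],
        seed=int(srng.integers(2**31 - 1)),
    )
    stage_done("stats")

    report["tables"]["mantel"] = mantel_table
    report["tables"]["mmrr"] = {
        "predictors": mmrr_res.predictor_names,
        "coefficients": mmrr_res.coefficients.tolist(),
        "r_squared": mmrr_res.r_squared,
        "coef_p": mmrr_res.coef_p.tolist(),
        "overall_p": mmrr_res.overall_p,
    }
    report["tables"]["gdm"] = {
        "final_predictors": gdm_model.predictor_names,
        "deviance_explained": gdm_model.deviance_explained,
        "importance": gdm_model.importance,
        "p_values": gdm_model.p_values,
        "elimination_history": gdm_model.elimination_history,
    }
    report["tables"]["enm_fit"] = {"auc": fit_report.auc, "tss": fit_report.tss}
    report["tables"]["mess_lgm_min"] = float(np.nanmin(mess_lgm.values))
    report["best_mantel_predictor"] = best
    report["fst"] = {"matrix": fst.values.tolist(), "labels": fst.labels,
                     "raw": fst_raw.tolist()}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fst.to_csv(out / "fst.csv")
        fst_norm.to_csv(out / "fst_normalized.csv")
        for name, mat in predictors.items():
            mat.to_csv(out / f"{name}.csv")
        write_beagle(sim.gl, out / "genolike.beagle")
        localities.write_sample_sheet(out / "samples.csv")
        truth.to_json(out / "truth.json")
        synthetic.write_landscape(bundle, out / "landscape")
        write_ascii_grid(suit_by_epoch["current"], out / "suitability_current.asc")
        write_ascii_grid(stability, out / "stability.asc")
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "config.yaml").write_text(yaml.safe_dump(cfg))
    return report


# ---------------------------------------------------------------------------


def validate_io_roundtrip(path: str | Path) -> dict:
    """read -> write -> read a supported file; report whether the roundtrip
    preserves values (to 1e-12) and metadata."""
    import tempfile

    path = Path(path)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        if path.suffix in {".beagle", ".gz"} or "beagle" in path.name:
            a = read_beagle(path)
            write_beagle(a, tmp / "copy.beagle")
            b = read_beagle(tmp / "copy.beagle")
            ok = (
                a.individuals == b.individuals
                and a.site_ids == b.site_ids
                and np.allclose(a.likelihoods, b.likelihoods, atol=1e-6)
            )
        elif path.suffix == ".asc":
            a = read_ascii_grid(path)
            write_ascii_grid(a, tmp / "copy.asc")
            b = read_ascii_grid(tmp / "copy.asc")
            ok = (
                a.shape == b.shape
                and np.array_equal(a.nodata_mask, b.nodata_mask)
                and np.allclose(a.masked_values(), b.masked_values(),
                                atol=1e-12, equal_nan=True)
                and abs(a.west - b.west) < 1e-12
            )
        elif path.suffix == ".csv":
            a = DistanceMatrix.from_csv(path)
            a.to_csv(tmp / "copy.csv")
            b = DistanceMatrix.from_csv(tmp / "copy.csv")
            ok = a.labels == b.labels and np.allclose(a.values, b.values, atol=1e-12)
        else:
            raise ValueError(f"unsupported format: {path.suffix}")
    return {"path": str(path), "roundtrip_ok": bool(ok)}
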