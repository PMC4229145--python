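"""End-to-end pipeline: simulate → volume → variogram → krige → ppa → territory.

One global seed is split deterministically into per-stage streams
(``SeedSequence(seed, spawn_key=(stage_index,))``), so toggling one stage
never perturbs another's randomness.  Each stage writes its outputs plus
provenance metadata; the run finishes with a manifest JSON listing every
file, its stage parameters and the seed.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .geostat import (
    GridSpec,
    empirical_variogram,
    fit_spherical,
    ordinary_krige,
    variogram_permutation_envelope,
)
from .point_pattern import PPConfig, csr_envelope
from .region import HabitatRegion
from .synthetic_data import SimulationConfig, simulate_dataset
from .territory_geometry import (
    dispersal_distances,
    dispersal_summary,
    territories_from_census,
    territory_summary,
)
from .volume_model import add_volume_columns

log = logging.getLogger("mistlemap")

STAGE_ORDER = ["simulate", "volume", "variogram", "krige", "ppa", "territory", "dispersal"]


@dataclass
class RunConfig:
    """Pipeline configuration: stage toggles, per-stage parameters, paths."""

    out_dir: str = "mistlemap_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    trees_path: str | None = None  # required when 'simulate' is off
    region_path: str | None = None
    territories_path: str | None = None
    dispersal_path: str | None = None
    elongate_k: float = 2.0
    lag_width: float = 25.0
    max_dist: float = 1000.0
    n_permutations: int = 1000
    alpha: float = 0.05
    krige_cell: float = 50.0
    neighborhood_k: int = 64
    n_sim: int = 199
    rank: int = 5
    r_max: float = 724.0
    n_r: int = 40
    ring_width: float = 18.6
    oring_cell: float = 6.2
    dispersal_thresholds: tuple = (250.0, 900.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STAGE_ORDER.index(stage),))
    )


def _need(path: str | None, stage: str, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"stage '{stage}' needs a {what} file but none was configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"stage '{stage}': missing {what} file {p}")
    return p


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[dict] = []
    trees = region = None

    def record(path, stage, params):
        outputs.append({"path": str(path), "stage": stage, "params": params})

    for stage in config.stages:
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")
    try:
        if "simulate" in config.stages:
            sim_seed = int(
                _stage_rng(config.seed, "simulate").integers(0, 2**31 - 1)
            )
            sim_cfg = SimulationConfig(**{"seed": sim_seed, **config.simulate})
            data = simulate_dataset(sim_cfg)
            region, trees = data["region"], data["trees"]
            params = {"n_trees": sim_cfg.n_trees, "pattern": sim_cfg.pattern}
            record(io.write_trees_csv(trees, out / "trees.csv", "simulate", params, sim_seed),
                   "simulate", params)
            record(io.write_region_geojson(region, out / "region.geojson", "simulate", params, sim_seed),
                   "simulate", params)
            record(io.write_table_csv(data["territories"], out / "territories.csv", "simulate", params, sim_seed),
                   "simulate", params)
            record(io.write_table_csv(data["dispersal"], out / "dispersal.csv", "simulate", params, sim_seed),
                   "simulate", params)
            config.territories_path = str(out / "territories.csv")
            config.dispersal_path = str(out / "dispersal.csv")
        elif any(s in config.stages for s in ("volume", "variogram", "krige", "ppa")):
            trees = io.read_trees_csv(_need(config.trees_path, "volume", "trees CSV"))
            if config.region_path:
                region = io.read_region_geojson(_need(config.region_path, "ppa", "region GeoJSON"))

        if "volume" in config.stages:
            from .volume_model import ClumpSizeScheme

            scheme = ClumpSizeScheme(elongate_multiplier=config.elongate_k)
            trees = add_volume_columns(trees, scheme)
            params = {"elongate_k": config.elongate_k}
            record(io.write_trees_csv(trees, out / "trees_volume.csv", "volume", params, config.seed),
                   "volume", params)

        pts = trees[["x_m", "y_m"]].to_numpy(float) if trees is not None else None
        marks = None
        if trees is not None and "log_volume" in trees:
            # trees with no recordable clumps carry no mark; geostatistics
            # uses the marked subset, point-pattern stages use all trees
            marked = trees["log_volume"].notna().to_numpy()
            marks = trees.loc[marked, "log_volume"].to_numpy(float)
            marked_pts = pts[marked]
        else:
            marked_pts = pts

        model = None
        if "variogram" in config.stages:
            if marks is None:
                raise RuntimeError("stage 'variogram': trees table has no log_volume column")
            evgm = empirical_variogram(marked_pts, marks, config.lag_width, config.max_dist)
            model = fit_spherical(evgm)
            rng = _stage_rng(config.seed, "variogram")
            env = variogram_permutation_envelope(
                marked_pts, marks, config.n_permutations, config.lag_width,
                config.max_dist, config.alpha, rng,
            )
            params = {"lag_width": config.lag_width, "max_dist": config.max_dist,
                      "n_permutations": config.n_permutations, "alpha": config.alpha,
                      "log_base": "e"}
            record(io.write_variogram_csv(evgm, out / "variogram.csv", env, "variogram", params, config.seed),
                   "variogram", params)
            record(io.write_model_json(model, out / "variogram_model.json", "variogram", params, config.seed),
                   "variogram", params)

        if "krige" in config.stages:
            if model is None:
                model = io.read_model_json(_need(str(out / "variogram_model.json"), "krige", "model JSON"))
            bounds = region.bounds if region is not None else (
                pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max()
            )
            grid = GridSpec.covering(bounds, config.krige_cell)
            surface = ordinary_krige(marked_pts, marks, model, grid, config.neighborhood_k)
            params = {"cell": config.krige_cell, "neighborhood_k": config.neighborhood_k}
            record(io.write_ascii_grid(surface, out / "kriged_logvolume.asc", stage="krige",
                                       params=params, seed=config.seed),
                   "krige", params)

        if "ppa" in config.stages:
            if region is None:
                from .region import HabitatRegion as HR

                log.warning("no habitat region supplied; using convex hull of trees")
                region = HR.convex_hull_of(pts)
            rng = _stage_rng(config.seed, "ppa")
            r_grid = np.linspace(config.r_max / config.n_r, config.r_max, config.n_r)
            departures = {}
            for statname, fname in (("K", "ripleys_k"), ("oring", "o_ring")):
                ppc = PPConfig(r_grid=r_grid, n_sim=config.n_sim, rank=config.rank,
                               ring_width=config.ring_width, cell_size=config.oring_cell)
                env = csr_envelope(pts, region, statname, ppc, rng)
                params = {"n_sim": config.n_sim, "rank": config.rank, "r_max": config.r_max,
                          "ring_width": config.ring_width, "cell_size": config.oring_cell}
                record(io.write_envelope_csv(env, out / f"{fname}_envelope.csv", "ppa", params, config.seed),
                       "ppa", params)
                departures[statname] = [
                    {"r_start_m": a, "r_end_m": b, "direction": d} for a, b, d in env.departures
                ]
            dep_path = out / "ppa_departures.json"
            dep_path.write_text(json.dumps(departures, indent=2))
            record(dep_path, "ppa", params)

        if "territory" in config.stages:
            census = io.read_territories_csv(
                _need(config.territories_path, "territory", "territory census CSV"))
            terr = territories_from_census(census)
            summary = territory_summary(terr)
            per = [
                {"territory_id": t.territory_id, "area_m2": t.area_m2,
                 "radius_m": t.equivalent_radius_m}
                for t in terr
            ]
            import pandas as pd

            record(io.write_table_csv(pd.DataFrame(per), out / "territory_areas.csv",
                                      "territory", {}, config.seed), "territory", {})
            tsum = out / "territory_summary.json"
            tsum.write_text(json.dumps(dataclasses.asdict(summary), indent=2))
            record(tsum, "territory", {})

        if "dispersal" in config.stages:
            rec = io.read_dispersal_csv(
                _need(config.dispersal_path, "dispersal", "dispersal CSV"))
            summ = dispersal_summary(dispersal_distances(rec),
                                     thresholds=config.dispersal_thresholds)
            params = {"thresholds": list(config.dispersal_thresholds)}
            dsum = out / "dispersal_summary.json"
            dsum.write_text(json.dumps(summ, indent=2))
            record(dsum, "dispersal", params)
    except (ValueError, FileNotFoundError, RuntimeError):
        raise
    except Exception as exc:  # pragma: no cover - unexpected stage failure
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "software": f"mistlemap {__version__}",
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


__all__ = ["RunConfig", "run_pipeline", "STAGE_ORDER"]
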