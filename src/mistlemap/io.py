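"""File I/O: trees/territory/dispersal CSVs, region GeoJSON, grids, metadata.

All readers validate that coordinates look like projected meters — input
whose coordinates all fit in |x| ≤ 180, |y| ≤ 90 is refused as probable
lon/lat.  Every writer can attach a provenance sidecar
(``<file>.meta.json``) recording the producing stage, its parameters and
the seed, so a finished run is self-describing.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import __version__
from .geostat import EmpiricalVariogram, GridSpec, KrigedSurface, SphericalModel
from .point_pattern import EnvelopeResult
from .region import HabitatRegion

TREE_REQUIRED = ["tree_id", "x_m", "y_m"]


def write_metadata(path, stage: str, params: dict | None = None, seed=None) -> Path:
    """Write the provenance sidecar ``<path>.meta.json``."""
    meta = {
        "stage": stage,
        "params": params or {},
        "seed": seed,
        "software": f"mistlemap {__version__}",
    }
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, default=str))
    return side


def _refuse_lonlat(x: np.ndarray, y: np.ndarray, what: str) -> None:
    if len(x) and np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0):
        raise ValueError(
            f"{what} coordinates all fall within |x|<=180, |y|<=90 and look "
            "like longitude/latitude; mistlemap requires projected meters "
            "(reproject first, e.g. to UTM)"
        )


def _numeric_or_report(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            lines = ", ".join(str(i + 2) for i in bad[:5])
            raise ValueError(
                f"{path}: column {col!r} is non-numeric at line(s) {lines}"
            )
        df[col] = coerced
    return df


def read_trees_csv(path) -> pd.DataFrame:
    """Read a trees table; requires tree_id, x_m, y_m; extras pass through."""
    df = pd.read_csv(path)
    missing = [c for c in TREE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trees CSV lacks required columns {missing}")
    df = _numeric_or_report(df, ["x_m", "y_m"], path)  # extras pass through untouched
    _refuse_lonlat(df["x_m"].to_numpy(), df["y_m"].to_numpy(), "tree")
    return df


def write_trees_csv(df: pd.DataFrame, path, stage="volume", params=None, seed=None):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    write_metadata(path, stage, params, seed)
    return Path(path)


def read_table_csv(path, required_columns, coord_columns=()) -> pd.DataFrame:
    """Generic CSV reader used for territory and dispersal tables."""
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: CSV lacks required columns {missing}")
    if coord_columns:
        df = _numeric_or_report(df, list(coord_columns), path)
        xs = df[list(coord_columns)[0]].to_numpy()
        ys = df[list(coord_columns)[1]].to_numpy()
        _refuse_lonlat(xs, ys, Path(str(path)).stem)
    return df


def read_territories_csv(path) -> pd.DataFrame:
    return read_table_csv(path, ["territory_id", "x_m", "y_m"], ("x_m", "y_m"))


def read_dispersal_csv(path) -> pd.DataFrame:
    return read_table_csv(
        path,
        ["male_id", "natal_x_m", "natal_y_m", "breeding_x_m", "breeding_y_m"],
        ("natal_x_m", "natal_y_m"),
    )


def write_table_csv(df: pd.DataFrame, path, stage, params=None, seed=None):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    write_metadata(path, stage, params, seed)
    return Path(path)


# ---- region GeoJSON -------------------------------------------------------


def read_region_geojson(path) -> HabitatRegion:
    """Read a habitat polygon (Polygon or MultiPolygon, holes honored)."""
    with open(path) as fh:
        obj = json.load(fh)
    region = HabitatRegion.from_geojson_dict(obj)
    xs, ys = np.asarray(region.geometry.envelope.exterior.coords).T
    _refuse_lonlat(xs, ys, "region")
    return region


def write_region_geojson(region: HabitatRegion, path, stage="simulate", params=None, seed=None):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    feature = {
        "type": "Feature",
        "geometry": mapping(region.geometry),
        "properties": {"area_m2": region.area, "stage": stage, "seed": seed,
                       "software": f"mistlemap {__version__}"},
    }
    Path(path).write_text(json.dumps(feature))
    write_metadata(path, stage, params, seed)
    return Path(path)


# ---- variogram / model / envelope ----------------------------------------


def write_variogram_csv(evgm: EmpiricalVariogram, path, envelope=None, stage="variogram", params=None, seed=None):
    df = pd.DataFrame(
        {"h_m": evgm.bin_centers, "gamma": evgm.gamma, "n_pairs": evgm.n_pairs}
    )
    if envelope is not None:
        df["lower"] = envelope.lower
        df["upper"] = envelope.upper
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    write_metadata(path, stage, params, seed)
    return Path(path)


def write_model_json(model: SphericalModel, path, stage="variogram", params=None, seed=None):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = model.to_dict()
    payload["metadata"] = {"stage": stage, "params": params or {}, "seed": seed,
                           "software": f"mistlemap {__version__}"}
    Path(path).write_text(json.dumps(payload, indent=2))
    return Path(path)


def read_model_json(path) -> SphericalModel:
    with open(path) as fh:
        return SphericalModel.from_dict(json.load(fh))


def write_envelope_csv(env: EnvelopeResult, path, stage="ppa", params=None, seed=None):
    df = pd.DataFrame(
        {
            "r_m": env.r,
            "observed": env.observed,
            "lower": env.lower,
            "upper": env.upper,
            "verdict": env.verdicts,
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    write_metadata(path, stage, params, seed)
    return Path(path)


# ---- ESRI ASCII grid ------------------------------------------------------


def write_ascii_grid(surface: KrigedSurface, path, nodata: float = -9999.0,
                     stage="krige", params=None, seed=None):
    """Write a kriged surface as an ESRI ASCII grid (.asc), north row first."""
    g = surface.grid
    vals = np.where(np.isfinite(surface.values), surface.values, nodata)
    header = (
        f"ncols {g.n_cols}\nnrows {g.n_rows}\nxllcorner {g.x0}\n"
        f"yllcorner {g.y0}\ncellsize {g.cell_size}\nNODATA_value {nodata}\n"
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals[::-1], fmt="%.6g")
    write_metadata(path, stage, params, seed)
    return Path(path)


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1]
    vals = np.where(vals == head["nodata_value"], np.nan, vals)
    grid = GridSpec(
        head["xllcorner"],
        head["yllcorner"],
        head["cellsize"],
        int(head["ncols"]),
        int(head["nrows"]),
    )
    return grid, vals


__all__ = [
    "read_trees_csv",
    "write_trees_csv",
    "read_territories_csv",
    "read_dispersal_csv",
    "read_table_csv",
    "write_table_csv",
    "read_region_geojson",
    "write_region_geojson",
    "write_variogram_csv",
    "write_model_json",
    "read_model_json",
    "write_envelope_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_metadata",
]
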