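"""Winter-territory geometry and natal-dispersal summaries.

A territory is the minimum convex polygon (MCP) around its census points;
its radial extent is the radius of the circle of equal area,
r = sqrt(A/π).  Dispersal records give straight-line natal-to-breeding
distances; the empirical CDF at reference thresholds (e.g. 250 m — one
territory diameter — and 900 m) links bird movement scales to the
variogram range of mistletoe volume.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint


def mcp(points) -> tuple[np.ndarray, float]:
    """Minimum convex polygon of census points: (vertices, area in m²).

    Interior points do not affect the hull.  Collinear point sets yield a
    degenerate hull of zero area with a warning.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least three census points for an MCP")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon":
        warnings.warn("all census points are collinear; MCP area is 0", stacklevel=2)
        verts = np.asarray(hull.coords) if hull.geom_type == "LineString" else pts[:1]
        return verts, 0.0
    return np.asarray(hull.exterior.coords)[:-1], float(hull.area)


def equivalent_radius(area_m2: float) -> float:
    """Radius (m) of the circle with the given area: sqrt(A/π)."""
    if area_m2 < 0:
        raise ValueError("area must be >= 0")
    return math.sqrt(area_m2 / math.pi)


@dataclass(frozen=True)
class Territory:
    """One winter territory: census points, MCP, area and equivalent radius."""

    territory_id: object
    census_points: np.ndarray
    mcp_vertices: np.ndarray
    area_m2: float

    @property
    def equivalent_radius_m(self) -> float:
        return equivalent_radius(self.area_m2)


def territories_from_census(census: pd.DataFrame) -> list[Territory]:
    """Build Territory objects from a census table (territory_id, x_m, y_m)."""
    required = {"territory_id", "x_m", "y_m"}
    if not required.issubset(census.columns):
        raise ValueError(f"census table needs columns {sorted(required)}")
    out = []
    for tid, grp in census.groupby("territory_id", sort=True):
        pts = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        verts, area = mcp(pts)
        out.append(Territory(tid, pts, verts, area))
    return out


@dataclass(frozen=True)
class TerritorySummary:
    """Mean ± SE of territory area and the radius of the mean-area circle."""

    n: int
    mean_area_m2: float
    se_area_m2: float | None
    mean_equivalent_radius_m: float


def territory_summary(territories: list[Territory]) -> TerritorySummary:
    """Summarise territory areas; the radius is computed FROM the mean area.

    (Radius of the mean-area circle, not the mean of per-territory radii —
    by concavity of sqrt the latter is never larger.)  SE = sd/√n is
    undefined for a single territory and reported as None.
    """
    if not territories:
        raise ValueError("need at least one territory")
    areas = np.array([t.area_m2 for t in territories], dtype=float)
    n = len(areas)
    mean = float(np.mean(areas))
    se = float(np.std(areas, ddof=1) / np.sqrt(n)) if n > 1 else None
    return TerritorySummary(n, mean, se, equivalent_radius(mean))


def dispersal_distances(records: pd.DataFrame) -> np.ndarray:
    """Euclidean natal-to-breeding distances from a dispersal table."""
    need = {"natal_x_m", "natal_y_m", "breeding_x_m", "breeding_y_m"}
    if not need.issubset(records.columns):
        raise ValueError(f"dispersal table needs columns {sorted(need)}")
    return np.hypot(
        records["breeding_x_m"].to_numpy(float) - records["natal_x_m"].to_numpy(float),
        records["breeding_y_m"].to_numpy(float) - records["natal_y_m"].to_numpy(float),
    )


def dispersal_summary(
    distances,
    thresholds=(250.0, 900.0),
    bin_width: float = 100.0,
    exclude: np.ndarray | None = None,
) -> dict:
    """Empirical CDF of dispersal distances at thresholds, plus a histogram.

    Threshold comparisons are strict (``d < t``, "settled < 900 m"); ties on
    a threshold count as not-below.  ``exclude`` is a boolean mask flagging
    records (e.g. a known long-distance outlier) dropped from every summary.
    """
    d = np.asarray(distances, dtype=float)
    if exclude is not None:
        d = d[~np.asarray(exclude, dtype=bool)]
    if len(d) == 0:
        raise ValueError("no dispersal distances to summarise")
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds <= 0):
        raise ValueError("thresholds must be > 0")
    fractions = {float(t): float(np.mean(d < t)) for t in thresholds}
    n_bins = int(np.ceil(d.max() / bin_width)) if d.max() > 0 else 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return {
        "n": int(len(d)),
        "fraction_below": fractions,
        "histogram": {"bin_edges_m": edges.tolist(), "counts": counts.tolist()},
        "mean_m": float(np.mean(d)),
        "median_m": float(np.median(d)),
    }


def correlated_area_ratio(range_m: float, mean_territory_area_m2: float) -> float:
    """Ratio of the autocorrelated disc area π·range² to mean territory area.

    A coarse count of how many territories fit inside the neighborhood over
    which mistletoe volume is spatially dependent.
    """
    if range_m <= 0 or mean_territory_area_m2 <= 0:
        raise ValueError("range and mean area must be > 0")
    return math.pi * range_m**2 / mean_territory_area_m2


__all__ = [
    "mcp",
    "equivalent_radius",
    "Territory",
    "territories_from_census",
    "TerritorySummary",
    "territory_summary",
    "dispersal_distances",
    "dispersal_summary",
    "correlated_area_ratio",
]
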