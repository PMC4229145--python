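"""Habitat regions: the polygonal windows that bound tree patterns and null models.

All coordinates are planar meters in an arbitrary projected system.  A region
is a simple polygon (or multipolygon, holes allowed) with positive area; it
serves both as the observation window for point-pattern statistics and as the
support on which null patterns are simulated.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass(frozen=True)
class HabitatRegion:
    """A polygonal habitat window carrying its area in m²."""

    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not isinstance(self.geometry, (Polygon, MultiPolygon)):
            raise TypeError(
                f"region geometry must be Polygon or MultiPolygon, got "
                f"{self.geometry.geom_type}"
            )
        if not self.geometry.is_valid:
            raise ValueError(
                "region polygon is invalid (self-intersecting or degenerate)"
            )
        if self.geometry.area <= 0:
            raise ValueError("region has zero area")

    @property
    def area(self) -> float:
        """Region area |A| in m² (holes subtracted)."""
        return float(self.geometry.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) bounding box."""
        return tuple(self.geometry.bounds)

    @property
    def diameter(self) -> float:
        """Diagonal of the bounding box — an upper bound on point separation."""
        minx, miny, maxx, maxy = self.bounds
        return float(np.hypot(maxx - minx, maxy - miny))

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorised strict containment test (boundary excluded)."""
        return shapely.contains_xy(self.geometry, np.asarray(x), np.asarray(y))

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the region.

        Bounding-box rejection sampling; deterministic given the generator
        state.  Returns an (n, 2) float array.
        """
        if n < 0:
            raise ValueError("n must be non-negative")
        minx, miny, maxx, maxy = self.bounds
        out = np.empty((n, 2), dtype=float)
        filled = 0
        # acceptance ratio = area / bbox area; batch accordingly
        frac = max(self.area / ((maxx - minx) * (maxy - miny)), 1e-6)
        while filled < n:
            m = int((n - filled) / frac * 1.2) + 16
            x = rng.uniform(minx, maxx, m)
            y = rng.uniform(miny, maxy, m)
            keep = self.contains_xy(x, y)
            pts = np.column_stack([x[keep], y[keep]])
            take = min(len(pts), n - filled)
            out[filled : filled + take] = pts[:take]
            filled += take
        return out

    # ---- constructors -------------------------------------------------

    @classmethod
    def from_rectangle(
        cls, width: float, height: float, origin: tuple[float, float] = (0.0, 0.0)
    ) -> "HabitatRegion":
        if width <= 0 or height <= 0:
            raise ValueError("rectangle dimensions must be positive")
        x0, y0 = origin
        return cls(
            Polygon(
                [(x0, y0), (x0 + width, y0), (x0 + width, y0 + height), (x0, y0 + height)]
            )
        )

    @classmethod
    def from_vertices(cls, vertices) -> "HabitatRegion":
        poly = Polygon(vertices)
        if not poly.is_valid:
            raise ValueError(
                "vertex list defines a self-intersecting polygon; supply a "
                "simple (non-self-intersecting) ring"
            )
        return cls(poly)

    @classmethod
    def from_geojson_dict(cls, obj: dict) -> "HabitatRegion":
        if obj.get("type") == "FeatureCollection":
            feats = obj.get("features", [])
            if not feats:
                raise ValueError("GeoJSON FeatureCollection contains no features")
            obj = feats[0]
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        return cls(shape(obj))

    @classmethod
    def convex_hull_of(cls, points) -> "HabitatRegion":
        """Convex hull of observed points — the fallback null region."""
        hull = shapely.MultiPoint(np.asarray(points, dtype=float)).convex_hull
        return cls(hull)

    @property
    def __geo_interface__(self):  # pragma: no cover - convenience
        return mapping(self.geometry)
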