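"""Synthetic study-system generator.

Emulates the spatial structure of the Carmel Valley oak-mistletoe survey so
the whole analysis pipeline is testable without the field data: an irregular
oak-habitat window of ~700 ha, ~2,658 mistletoe-bearing trees (aggregated,
via a Thomas cluster process, or complete spatial randomness), log-volume
marks drawn from a Gaussian random field with a spherical variogram
(nugget 2.4, partial sill 0.79, range 250.3 m), female volume linearly tied
to total volume, ~25 winter territories of ~41,663 m² mean area, and
short-tailed natal dispersal distances (~58.5% under 250 m).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import cdist

from .geostat import SphericalModel
from .region import HabitatRegion
from .volume_model import DEFAULT_SCHEME, ClumpSizeScheme, clump_volume


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ThomasParams:
    """Thomas cluster process: Poisson parents, Gaussian-displaced offspring."""

    parent_intensity: float = 2e-5  # parents per m²
    mean_offspring: float = 19.0
    offspring_sd: float = 50.0  # m

    def __post_init__(self) -> None:
        if min(self.parent_intensity, self.mean_offspring, self.offspring_sd) <= 0:
            raise ValueError("all Thomas parameters must be > 0")


@dataclass(frozen=True)
class DispersalMixture:
    """Two-component half-normal mixture of natal dispersal distances.

    Calibrated so that in expectation ~58.5% of distances fall below 250 m
    (one territory diameter) and ~97% below 900 m.
    """

    short_fraction: float = 0.3
    short_scale_m: float = 130.0
    long_scale_m: float = 439.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.short_fraction <= 1.0:
            raise ValueError("short_fraction must lie in [0, 1]")
        if self.short_scale_m <= 0 or self.long_scale_m <= 0:
            raise ValueError("dispersal scales must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one synthetic dataset.

    Defaults reproduce the study descriptors: a 2,646 × 2,646 m (700 ha)
    window, 2,658 trees, the published variogram parameters, 25 territories,
    and 82 dispersal records.
    """

    region_spec: dict = field(
        default_factory=lambda: {"rectangle": (2646.0, 2646.0)}
    )
    n_trees: int = 2658
    pattern: str = "thomas"  # {"csr", "thomas"}
    thomas_params: ThomasParams = field(default_factory=ThomasParams)
    grf_model: SphericalModel = field(
        default_factory=lambda: SphericalModel(2.4, 0.79, 250.3)
    )
    mean_log_volume: float = 10.0
    female_slope: float = 0.5
    female_noise_sd: float = 120000.0  # cm³
    n_territories: int = 25
    points_per_territory: int = 15
    territory_spacing: float = 250.0  # m between territory centers
    territory_radius: float = 158.0  # m, census-point scatter radius
    dispersal_mixture: DispersalMixture = field(default_factory=DispersalMixture)
    n_dispersal: int = 82
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 2:
            raise ValueError("n_trees must be >= 2")
        if self.pattern not in ("csr", "thomas"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.n_territories < 1 or self.points_per_territory < 1:
            raise ValueError("territory counts must be >= 1")
        if min(self.territory_spacing, self.territory_radius) <= 0:
            raise ValueError("territory scales must be > 0")
        if self.n_dispersal < 1:
            raise ValueError("n_dispersal must be >= 1")
        if not 0.0 < self.female_slope <= 1.0:
            raise ValueError("female_slope must lie in (0, 1]")
        if self.female_noise_sd < 0:
            raise ValueError("female_noise_sd must be >= 0")


# --------------------------------------------------------------------------
# region & tree pattern
# --------------------------------------------------------------------------


def gen_region(region_spec) -> HabitatRegion:
    """Build the habitat window from a spec dict (or pass a region through).

    Accepted forms: ``{"rectangle": (width, height)}`` (optionally with
    ``"origin"``) or ``{"vertices": [(x, y), ...]}``.  Self-intersecting
    vertex lists are rejected.
    """
    if isinstance(region_spec, HabitatRegion):
        return region_spec
    if not isinstance(region_spec, dict):
        raise TypeError("region_spec must be a dict or HabitatRegion")
    if "rectangle" in region_spec:
        w, h = region_spec["rectangle"]
        return HabitatRegion.from_rectangle(
            float(w), float(h), tuple(region_spec.get("origin", (0.0, 0.0)))
        )
    if "vertices" in region_spec:
        return HabitatRegion.from_vertices(region_spec["vertices"])
    raise ValueError("region_spec needs a 'rectangle' or 'vertices' entry")


def gen_trees(
    region: HabitatRegion,
    pattern: str,
    params: ThomasParams | None,
    n_trees: int,
    rng,
) -> np.ndarray:
    """Generate exactly ``n_trees`` tree locations inside the region.

    ``"csr"`` draws a binomial (conditionally uniform) pattern; ``"thomas"``
    draws a Thomas cluster process — Poisson parents on the (expanded)
    bounding box, Poisson-many Gaussian-displaced offspring per parent,
    offspring outside the region rejected — truncated/topped-up to the exact
    count after a shuffle.
    """
    rng = _as_rng(rng)
    if region.area <= 0:
        raise ValueError("region has zero area")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if pattern == "csr":
        return region.sample_uniform(n_trees, rng)
    if pattern != "thomas":
        raise ValueError(f"unknown pattern {pattern!r}")
    params = params or ThomasParams()
    minx, miny, maxx, maxy = region.bounds
    pad = 4.0 * params.offspring_sd  # parents outside may still place offspring in
    ext_area = (maxx - minx + 2 * pad) * (maxy - miny + 2 * pad)
    collected: list[np.ndarray] = []
    total = 0
    while total < n_trees:
        n_parents = max(rng.poisson(params.parent_intensity * ext_area), 1)
        px = rng.uniform(minx - pad, maxx + pad, n_parents)
        py = rng.uniform(miny - pad, maxy + pad, n_parents)
        n_off = rng.poisson(params.mean_offspring, n_parents)
        centers = np.repeat(np.column_stack([px, py]), n_off, axis=0)
        pts = centers + rng.normal(0.0, params.offspring_sd, centers.shape)
        keep = region.contains_xy(pts[:, 0], pts[:, 1])
        pts = pts[keep]
        collected.append(pts)
        total += len(pts)
    pts = np.concatenate(collected)
    rng.shuffle(pts, axis=0)
    return pts[:n_trees]


# --------------------------------------------------------------------------
# Gaussian random field marks
# --------------------------------------------------------------------------


def gen_logvolume_marks(
    points,
    grf_model: SphericalModel,
    mean: float = 0.0,
    rng=None,
    jitter_factor: float = 1e-8,
) -> np.ndarray:
    """Draw log-volume marks from a Gaussian random field.

    The covariance between distinct trees at separation h is the structured
    part c·ρ(h) of the spherical model (zero for h ≥ range); each tree
    additionally carries independent nugget variance c0, so Var(z_i) =
    c0 + c.  Dense Cholesky factorisation with additive jitter
    ``jitter_factor·(c0+c)`` on the diagonal guards near-singularity (e.g.
    duplicate coordinates).
    """
    rng = _as_rng(rng)
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least two points")
    C = grf_model.structured_covariance(cdist(points, points))
    C[np.diag_indices_from(C)] += grf_model.nugget + jitter_factor * grf_model.sill
    try:
        L = cholesky(C, lower=True, check_finite=False)
    except Exception as exc:
        raise ValueError(
            "covariance matrix not positive definite even after jitter"
        ) from exc
    return mean + L @ rng.standard_normal(n)


# --------------------------------------------------------------------------
# clump decomposition & female volume
# --------------------------------------------------------------------------


def decompose_volume_to_clumps(
    volume_cm3: float, scheme: ClumpSizeScheme = DEFAULT_SCHEME
) -> dict[int, int]:
    """Greedy largest-category-first decomposition of a volume into clumps.

    Returns counts per category 1..6 whose recomposed volume is ≤ the input
    and within one smallest-clump (category-1 sphere) volume of it, so
    synthetic trees carry field-like clump records.
    """
    if volume_cm3 < 0:
        raise ValueError("volume must be >= 0")
    counts = {cat: 0 for cat in range(1, 7)}
    remaining = float(volume_cm3)
    for cat in (6, 5, 4, 3, 2, 1):
        v = clump_volume(cat, scheme)
        # tiny relative slack so an exact multiple is not lost to rounding
        k = int(math.floor(remaining / v + 1e-9))
        counts[cat] = k
        remaining -= k * v
    return counts


def gen_female_volume(total_volumes, slope: float, noise_sd: float, rng) -> np.ndarray:
    """Female (fruit-bearing) volume as a noisy linear share of total volume.

    female_i = clamp(slope·total_i + ε_i, 0, total_i) with ε ~ N(0, noise_sd²);
    with noise_sd = 0 the correlation with total volume is exactly 1.
    """
    rng = _as_rng(rng)
    if not 0.0 < slope <= 1.0:
        raise ValueError("slope must lie in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    total = np.asarray(total_volumes, dtype=float)
    eps = rng.normal(0.0, noise_sd, total.shape) if noise_sd > 0 else 0.0
    return np.clip(slope * total + eps, 0.0, total)


# --------------------------------------------------------------------------
# territories & dispersal
# --------------------------------------------------------------------------


def gen_territories(
    region: HabitatRegion,
    n: int,
    pts_per_territory: int,
    spacing: float,
    rng,
    radius: float = 158.0,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Census-point table for ``n`` winter territories.

    Territory centers are dart-thrown inside the region at pairwise distance
    ≥ ``spacing`` (bounded retries, then an error); census points are uniform
    in the disc of ``radius`` around each center, rejected outside the
    region.  The default radius is calibrated so the mean minimum-convex-
    polygon area of 15 census points approximates the study's 41,663 m².
    """
    rng = _as_rng(rng)
    if n < 1:
        raise ValueError("n must be >= 1")
    if spacing <= 0 or radius <= 0:
        raise ValueError("spacing and radius must be > 0")
    inner = region.geometry.buffer(-radius)
    sample_region = region if inner.is_empty or inner.area <= 0 else HabitatRegion(inner)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries * n:
            raise RuntimeError(
                f"could not place {n} territory centers at spacing {spacing} m "
                f"within the region after {tries} tries"
            )
        cand = sample_region.sample_uniform(1, rng)[0]
        tries += 1
        if all(np.hypot(*(cand - c)) >= spacing for c in centers):
            centers.append(cand)
    rows = []
    for tid, center in enumerate(centers, start=1):
        got = 0
        while got < pts_per_territory:
            m = 4 * (pts_per_territory - got) + 8
            r = radius * np.sqrt(rng.random(m))
            th = rng.uniform(0, 2 * np.pi, m)
            pts = center + np.column_stack([r * np.cos(th), r * np.sin(th)])
            keep = region.contains_xy(pts[:, 0], pts[:, 1])
            for p in pts[keep][: pts_per_territory - got]:
                rows.append((tid, p[0], p[1]))
                got += 1
    return pd.DataFrame(rows, columns=["territory_id", "x_m", "y_m"])


def gen_dispersal(
    n: int,
    mixture: DispersalMixture,
    rng,
    natal_extent: float = 2646.0,
) -> pd.DataFrame:
    """Natal-to-breeding dispersal records with mixture-drawn distances.

    Distances come from the half-normal mixture; natal coordinates are
    uniform on a square of side ``natal_extent`` and breeding coordinates
    are placed at the drawn distance in a uniform direction, so the stored
    distance always equals the Euclidean distance of the two points.
    """
    rng = _as_rng(rng)
    if n < 1:
        raise ValueError("n must be >= 1")
    short = rng.random(n) < mixture.short_fraction
    scales = np.where(short, mixture.short_scale_m, mixture.long_scale_m)
    d = np.abs(rng.normal(0.0, 1.0, n)) * scales
    theta = rng.uniform(0, 2 * np.pi, n)
    natal = rng.uniform(0.0, natal_extent, (n, 2))
    breeding = natal + np.column_stack([d * np.cos(theta), d * np.sin(theta)])
    return pd.DataFrame(
        {
            "male_id": np.arange(1, n + 1),
            "natal_x_m": natal[:, 0],
            "natal_y_m": natal[:, 1],
            "breeding_x_m": breeding[:, 0],
            "breeding_y_m": breeding[:, 1],
            "distance_m": d,
        }
    )


# --------------------------------------------------------------------------
# one-shot dataset
# --------------------------------------------------------------------------


def simulate_dataset(
    config: SimulationConfig, scheme: ClumpSizeScheme = DEFAULT_SCHEME
) -> dict:
    """Generate the full synthetic dataset a field season would produce.

    Returns a dict with the habitat region, the trees table (locations,
    clump counts per category, total/female/log volumes), the territory
    census table and the dispersal table.  All randomness flows through one
    generator seeded from ``config.seed``; identical configs give identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    region = gen_region(config.region_spec)
    pts = gen_trees(region, config.pattern, config.thomas_params, config.n_trees, rng)
    logv = gen_logvolume_marks(pts, config.grf_model, config.mean_log_volume, rng)
    volume = np.exp(logv)
    counts = np.array(
        [list(decompose_volume_to_clumps(v, scheme).values()) for v in volume]
    )
    female = gen_female_volume(
        volume, config.female_slope, config.female_noise_sd, rng
    )
    trees = pd.DataFrame(
        {
            "tree_id": np.arange(1, config.n_trees + 1),
            "x_m": pts[:, 0],
            "y_m": pts[:, 1],
            **{f"n_cat{c}": counts[:, c - 1] for c in range(1, 6)},
            "n_elongate": counts[:, 5],
            "total_volume_cm3": volume,
            "female_volume_cm3": female,
            "log_volume": logv,
        }
    )
    territories = gen_territories(
        region,
        config.n_territories,
        config.points_per_territory,
        config.territory_spacing,
        rng,
        radius=config.territory_radius,
    )
    dispersal = gen_dispersal(
        config.n_dispersal,
        config.dispersal_mixture,
        rng,
        natal_extent=float(np.sqrt(region.area)),
    )
    return {
        "region": region,
        "trees": trees,
        "territories": territories,
        "dispersal": dispersal,
        "config": config,
    }


__all__ = [
    "ThomasParams",
    "DispersalMixture",
    "SimulationConfig",
    "gen_region",
    "gen_trees",
    "gen_logvolume_marks",
    "decompose_volume_to_clumps",
    "gen_female_volume",
    "gen_territories",
    "gen_dispersal",
    "simulate_dataset",
]
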