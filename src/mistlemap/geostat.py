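"""Variogram estimation, spherical-model fitting, permutation envelopes, kriging.

The semivariogram γ(h) is half the expected squared difference between
log-volume marks at separation h.  A spherical model

    γ(h; c0, c, a) = c0 + c * (1.5 h/a - 0.5 (h/a)^3)   for 0 < h <= a
    γ(h; c0, c, a) = c0 + c                              for h > a
    γ(0) = 0

is fitted to the empirical (binned) variogram by weighted least squares.
Spatial autocorrelation is judged against a permutation null: marks are
shuffled over the fixed tree locations and the envelope of the permuted
variograms brackets the no-autocorrelation hypothesis.  Ordinary kriging
interpolates the marks onto a grid using the fitted model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, solve
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SphericalModel:
    """Spherical variogram model: nugget ``c0``, partial sill ``c``, range ``a``.

    ``c0`` is micro-scale plus measurement variance (a discontinuity at the
    origin), ``c`` the spatially structured variance, and ``a`` the distance
    in meters beyond which marks are uncorrelated.  The sill is ``c0 + c``.
    """

    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.partial_sill < 0:
            raise ValueError("partial sill must be >= 0")
        if self.range_m <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def semivariance(self, h) -> np.ndarray:
        """γ(h); γ(0) = 0 by convention, the nugget applies for any h > 0."""
        h = np.asarray(h, dtype=float)
        t = np.minimum(h / self.range_m, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * t - 0.5 * t**3)
        return np.where(h > 0, g, 0.0)

    def structured_covariance(self, h) -> np.ndarray:
        """Covariance of the spatially structured component, c * ρ(h).

        ρ(h) = 1 - 1.5 h/a + 0.5 (h/a)^3 for h < a, 0 beyond; the nugget is
        not part of ρ and must be added on the diagonal of a covariance
        matrix (it is never shared between two trees, even co-located ones).
        """
        h = np.asarray(h, dtype=float)
        t = np.minimum(h / self.range_m, 1.0)
        return self.partial_sill * (1.0 - 1.5 * t + 0.5 * t**3)

    def to_dict(self) -> dict:
        return {
            "model": "spherical",
            "nugget": self.nugget,
            "partial_sill": self.partial_sill,
            "range_m": self.range_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SphericalModel":
        return cls(d["nugget"], d["partial_sill"], d["range_m"])


# --------------------------------------------------------------------------
# empirical variogram
# --------------------------------------------------------------------------


@dataclass
class EmpiricalVariogram:
    """Binned method-of-moments semivariance estimates.

    ``gamma`` is NaN in empty bins; ``n_pairs`` counts the point pairs per
    lag bin.  Bin k spans [k*lag_width, (k+1)*lag_width) with center
    (k + 0.5)*lag_width.
    """

    bin_centers: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    lag_width: float
    max_dist: float

    @property
    def nonempty(self) -> np.ndarray:
        return self.n_pairs > 0


def _pair_bins(points: np.ndarray, lag_width: float, max_dist: float):
    """Pair distances binned once; reused by the permutation envelope."""
    d = pdist(points)
    keep = (d > 0) & (d <= max_dist)
    n = len(points)
    iu, ju = np.triu_indices(n, k=1)
    bins = np.floor(d[keep] / lag_width).astype(np.intp)
    n_bins = int(np.ceil(max_dist / lag_width))
    bins = np.minimum(bins, n_bins - 1)  # d == max_dist lands in last bin
    return iu[keep], ju[keep], bins, n_bins


def empirical_variogram(
    points, marks, lag_width: float = 25.0, max_dist: float = 1000.0
) -> EmpiricalVariogram:
    """Method-of-moments semivariogram.

    γ̂(h_k) = 1/(2 N_k) Σ_{pairs in bin k} (z_i - z_j)², pairs beyond
    ``max_dist`` excluded.  Invariant to point/mark reordering.
    """
    points = np.asarray(points, dtype=float)
    marks = np.asarray(marks, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least two points")
    if len(points) != len(marks):
        raise ValueError("points and marks length mismatch")
    if lag_width <= 0:
        raise ValueError("lag_width must be > 0")
    i_idx, j_idx, bins, n_bins = _pair_bins(points, lag_width, max_dist)
    if len(bins) == 0:
        raise ValueError(f"no point pairs within max_dist = {max_dist} m")
    sq = (marks[i_idx] - marks[j_idx]) ** 2
    n_pairs = np.bincount(bins, minlength=n_bins)
    ssum = np.bincount(bins, weights=sq, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(n_pairs > 0, ssum / (2.0 * np.maximum(n_pairs, 1)), np.nan)
    centers = (np.arange(n_bins) + 0.5) * lag_width
    return EmpiricalVariogram(centers, gamma, n_pairs, lag_width, max_dist)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


def fit_spherical(
    evgm: EmpiricalVariogram, weights_mode: str = "cressie"
) -> SphericalModel:
    """Weighted least-squares fit of a spherical model to a sample variogram.

    weights_mode:
      * ``"cressie"`` (default) — minimise Σ N_k (γ̂_k / γ(h_k;θ) - 1)²,
        Cressie's relative criterion, robust to the steep rise in variance
        of γ̂ with its own magnitude;
      * ``"npairs"`` — minimise Σ N_k (γ̂_k - γ(h_k;θ))²;
      * ``"equal"`` — ordinary least squares.

    Deterministic multi-start over range initialisations; parameters bounded
    non-negative.  A flat-zero (or exactly constant) variogram returns a
    pure-nugget fit (c = 0, range tie-broken to ``max_dist``) with a warning.
    """
    ok = evgm.nonempty & np.isfinite(evgm.gamma)
    h = evgm.bin_centers[ok]
    g = evgm.gamma[ok]
    npairs = evgm.n_pairs[ok].astype(float)
    if len(h) < 3:
        raise ValueError("need at least three nonempty lag bins to fit")
    if weights_mode not in ("cressie", "npairs", "equal"):
        raise ValueError(f"unknown weights_mode {weights_mode!r}")

    if np.ptp(g) <= 1e-12 * max(1.0, abs(float(np.mean(g)))):
        warnings.warn(
            "flat sample variogram: returning pure-nugget model "
            "(partial sill 0, range set to max_dist)",
            stacklevel=2,
        )
        return SphericalModel(float(np.mean(g)), 0.0, float(evgm.max_dist))

    def model_gamma(theta: np.ndarray) -> np.ndarray:
        c0, c, a = theta
        t = np.minimum(h / a, 1.0)
        return c0 + c * (1.5 * t - 0.5 * t**3)

    def residuals(theta: np.ndarray) -> np.ndarray:
        gm = model_gamma(theta)
        if weights_mode == "cressie":
            return np.sqrt(npairs) * (g / np.maximum(gm, 1e-12) - 1.0)
        if weights_mode == "npairs":
            return np.sqrt(npairs) * (g - gm)
        return g - gm

    gmin, gmax = float(np.min(g)), float(np.max(g))
    hmax = float(np.max(h))
    c0_starts = [max(gmin, 1e-6 * gmax), 1e-6 * gmax]
    best = None
    for frac in (0.1, 0.25, 0.5, 0.75, 1.0):
        for c0_0 in c0_starts:
            x0 = np.array([c0_0, max(gmax - c0_0, 1e-6 * gmax), frac * hmax])
            try:
                res = least_squares(
                    residuals,
                    x0,
                    bounds=([0.0, 0.0, 1e-6 * hmax], [np.inf, np.inf, np.inf]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            if best is None or res.cost < best.cost - 1e-15 * (1 + best.cost):
                best = res
    if best is None:  # pragma: no cover
        raise RuntimeError("spherical fit failed from every start")
    c0, c, a = best.x
    return SphericalModel(float(c0), float(c), float(a))


# --------------------------------------------------------------------------
# permutation envelope
# --------------------------------------------------------------------------


@dataclass
class PermutationEnvelope:
    """Pointwise permutation envelope of the sample variogram.

    Marks are randomly re-assigned to the fixed point locations ``B`` times;
    the (alpha/2, 1 - alpha/2) percentiles of the permuted γ̂ per bin form
    the envelope.  The observed variogram lying inside the envelope at every
    bin is consistent with absence of spatial autocorrelation.
    """

    bin_centers: np.ndarray
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_pairs: np.ndarray
    n_permutations: int
    alpha: float
    seed: int | None = None

    @property
    def inside(self) -> np.ndarray:
        ok = self.n_pairs > 0
        res = np.ones_like(self.observed, dtype=bool)
        res[ok] = (self.observed[ok] >= self.lower[ok]) & (
            self.observed[ok] <= self.upper[ok]
        )
        return res

    @property
    def autocorrelation_evidence(self) -> bool:
        """True if the observed variogram escapes the envelope in any bin."""
        return bool(~np.all(self.inside))


def variogram_permutation_envelope(
    points,
    marks,
    n_permutations: int = 1000,
    lag_width: float = 25.0,
    max_dist: float = 1000.0,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> PermutationEnvelope:
    """Permutation test for spatial autocorrelation of marks.

    Locations stay fixed; marks are shuffled.  Pair binning is computed once,
    so each permutation costs one pass over the pair list.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations for a 95% envelope")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    points = np.asarray(points, dtype=float)
    marks = np.asarray(marks, dtype=float)
    i_idx, j_idx, bins, n_bins = _pair_bins(points, lag_width, max_dist)
    if len(bins) == 0:
        raise ValueError(f"no point pairs within max_dist = {max_dist} m")
    n_pairs = np.bincount(bins, minlength=n_bins)
    denom = 2.0 * np.maximum(n_pairs, 1)

    def gamma_of(z: np.ndarray) -> np.ndarray:
        sq = (z[i_idx] - z[j_idx]) ** 2
        s = np.bincount(bins, weights=sq, minlength=n_bins)
        return np.where(n_pairs > 0, s / denom, np.nan)

    observed = gamma_of(marks)
    sims = np.empty((n_permutations, n_bins))
    for b in range(n_permutations):
        sims[b] = gamma_of(rng.permutation(marks))
    lower = np.nanpercentile(sims, 100 * alpha / 2, axis=0)
    upper = np.nanpercentile(sims, 100 * (1 - alpha / 2), axis=0)
    centers = (np.arange(n_bins) + 0.5) * lag_width
    return PermutationEnvelope(
        centers, observed, lower, upper, n_pairs, n_permutations, alpha, seed
    )


# --------------------------------------------------------------------------
# ordinary kriging
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Regular prediction grid: lower-left origin, square cells, row-major."""

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    def cell_centers(self) -> np.ndarray:
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @classmethod
    def covering(cls, bounds, cell_size: float) -> "GridSpec":
        minx, miny, maxx, maxy = bounds
        return cls(
            minx,
            miny,
            cell_size,
            int(np.ceil((maxx - minx) / cell_size)),
            int(np.ceil((maxy - miny) / cell_size)),
        )


@dataclass
class KrigedSurface:
    """Ordinary-kriging predictions on a regular grid (row 0 = south row)."""

    grid: GridSpec
    values: np.ndarray  # (n_rows, n_cols)
    model: SphericalModel


def ordinary_krige(
    points,
    marks,
    model: SphericalModel,
    grid: GridSpec,
    neighborhood_k: int = 64,
) -> KrigedSurface:
    """Ordinary kriging of marks onto a grid with a k-nearest neighborhood.

    Per cell the system  [[Γ, 1], [1ᵀ, 0]] [λ; μ] = [γ0; 1]  is solved, with
    Γ the semivariance matrix among the ``k`` nearest data and γ0 the
    semivariances to the prediction point; the prediction is λᵀz with
    Σλ = 1 (unbiasedness).  With γ(0) = 0 the predictor honors the data
    exactly at data locations.  A singular system is retried with a small
    diagonal jitter, then reported as an error.
    """
    points = np.asarray(points, dtype=float)
    marks = np.asarray(marks, dtype=float)
    n = len(points)
    if n < 1:
        raise ValueError("need at least one datum")
    k = min(neighborhood_k, n)
    tree = cKDTree(points)
    targets = grid.cell_centers()
    _, nbrs = tree.query(targets, k=k)
    nbrs = np.atleast_2d(nbrs)
    if k == 1:
        nbrs = nbrs.reshape(-1, 1)

    preds = np.empty(len(targets))
    ones = np.ones(k)
    for c, t in enumerate(targets):
        idx = nbrs[c]
        sub = points[idx]
        dx = sub[:, 0][:, None] - sub[:, 0][None, :]
        dy = sub[:, 1][:, None] - sub[:, 1][None, :]
        gam = model.semivariance(np.hypot(dx, dy))
        g0 = model.semivariance(np.hypot(sub[:, 0] - t[0], sub[:, 1] - t[1]))
        A = np.empty((k + 1, k + 1))
        A[:k, :k] = gam
        A[k, :k] = ones
        A[:k, k] = ones
        A[k, k] = 0.0
        b = np.append(g0, 1.0)
        try:
            lam = solve(A, b, assume_a="sym", check_finite=False)
        except LinAlgError:
            A[:k, :k] += 1e-10 * max(model.sill, 1.0) * np.eye(k)
            try:
                lam = solve(A, b, assume_a="sym", check_finite=False)
            except LinAlgError as exc:  # pragma: no cover
                raise RuntimeError(
                    f"singular kriging system at cell center {tuple(t)}"
                ) from exc
        preds[c] = lam[:k] @ marks[idx]
    return KrigedSurface(grid, preds.reshape(grid.n_rows, grid.n_cols), model)


__all__ = [
    "SphericalModel",
    "EmpiricalVariogram",
    "empirical_variogram",
    "fit_spherical",
    "PermutationEnvelope",
    "variogram_permutation_envelope",
    "GridSpec",
    "KrigedSurface",
    "ordinary_krige",
]
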