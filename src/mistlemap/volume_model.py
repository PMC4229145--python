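"""Clump-count → mistletoe volume conversion and the female-volume proxy.

Field crews score each tree's mistletoe clumps into six size categories.
Categories 1–5 are valued as spheres of radius 10, 20, 35, 60 and 75 cm;
category 6 collects the elongate clumps, valued as k ≥ 2 sphere volumes of
the largest class.  Per-tree volumes are the count-weighted sums, and the
spatial mark is the natural log of the volume.  Because only a subset of
trees can be sexed, total volume serves as a proxy for female (fruiting)
volume; the proxy strength is quantified by a Pearson correlation with its
companion F statistic on (1, n-2) degrees of freedom.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ClumpSizeScheme:
    """Representative sphere radii (cm) for categories 1-5 and elongate rule."""

    radii_cm: tuple[float, ...] = (10.0, 20.0, 35.0, 60.0, 75.0)
    elongate_multiplier: float = 2.0  # category 6 = k sphere volumes of class 5

    def __post_init__(self) -> None:
        if len(self.radii_cm) != 5:
            raise ValueError("scheme requires exactly five sphere radii")
        if any(b <= a for a, b in zip(self.radii_cm, self.radii_cm[1:])):
            raise ValueError("radii must be strictly increasing")
        if self.elongate_multiplier < 2:
            raise ValueError("elongate multiplier must be >= 2")

    @property
    def n_categories(self) -> int:
        return 6


DEFAULT_SCHEME = ClumpSizeScheme()

#: canonical column order for clump counts in a trees table
COUNT_COLUMNS = ["n_cat1", "n_cat2", "n_cat3", "n_cat4", "n_cat5", "n_elongate"]


def clump_volume(category: int, scheme: ClumpSizeScheme = DEFAULT_SCHEME) -> float:
    """Volume in cm³ of a single clump of the given category (1-6)."""
    if category in (1, 2, 3, 4, 5):
        r = scheme.radii_cm[category - 1]
        return 4.0 / 3.0 * math.pi * r**3
    if category == 6:
        return scheme.elongate_multiplier * clump_volume(5, scheme)
    raise ValueError(f"unknown clump category {category!r}; expected 1..6")


def total_tree_volume(counts, scheme: ClumpSizeScheme = DEFAULT_SCHEME) -> float:
    """Total mistletoe volume (cm³) of one tree from its clump counts.

    ``counts`` is a mapping {category: count} or a length-6 sequence in
    category order.  Counts must be non-negative integers.
    """
    if isinstance(counts, dict):
        items = counts.items()
    else:
        seq = list(counts)
        if len(seq) != 6:
            raise ValueError("count sequence must have six entries (cats 1..6)")
        items = enumerate(seq, start=1)
    total = 0.0
    for cat, cnt in items:
        if cnt != int(cnt) or cnt < 0:
            raise ValueError(f"count for category {cat} must be a non-negative integer")
        total += int(cnt) * clump_volume(cat, scheme)
    return total


def log_volume(volume_cm3) -> np.ndarray | float:
    """Natural-log transform of volume; defined only for volume > 0.

    Every surveyed tree bears mistletoe, so zero volume marks a data error.
    """
    v = np.asarray(volume_cm3, dtype=float)
    if np.any(v <= 0):
        raise ValueError("log_volume requires volume > 0")
    out = np.log(v)
    return float(out) if out.ndim == 0 else out


def add_volume_columns(
    trees: pd.DataFrame, scheme: ClumpSizeScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Append total_volume_cm3 and log_volume columns computed from counts."""
    missing = [c for c in COUNT_COLUMNS if c not in trees.columns]
    if missing:
        raise ValueError(f"trees table lacks count columns: {missing}")
    out = trees.copy()
    vols = np.array(
        [clump_volume(c, scheme) for c in range(1, 7)]
    )  # category order matches COUNT_COLUMNS
    tv = trees[COUNT_COLUMNS].to_numpy(dtype=float) @ vols
    out["total_volume_cm3"] = tv
    # trees without mistletoe get no mark (log undefined at 0)
    out["log_volume"] = np.where(tv > 0, np.log(np.where(tv > 0, tv, 1.0)), np.nan)
    return out


@dataclass(frozen=True)
class ProxyCorrelationResult:
    """Pearson correlation of female vs total volume with its F statistic."""

    n: int
    pearson_r: float
    r_squared: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")


def proxy_correlation(female_volumes, total_volumes) -> ProxyCorrelationResult:
    """Quantify how well total volume predicts female (fruiting) volume.

    Returns Pearson r, r², and the regression F = r²(n-2)/(1-r²) on
    (1, n-2) degrees of freedom.  Requires n ≥ 3 and nonzero variance in
    both measures.
    """
    female = np.asarray(female_volumes, dtype=float)
    total = np.asarray(total_volumes, dtype=float)
    if female.shape != total.shape:
        raise ValueError("female and total volume vectors differ in length")
    n = len(female)
    if n < 3:
        raise ValueError("need at least three trees")
    if np.var(female) == 0 or np.var(total) == 0:
        raise ValueError("zero variance in female or total volumes")
    res = stats.pearsonr(female, total)
    r = float(res.statistic)
    r2 = r * r
    f = r2 * (n - 2) / (1.0 - r2) if r2 < 1.0 else math.inf
    return ProxyCorrelationResult(n, r, r2, f, (1, n - 2), float(res.pvalue))


__all__ = [
    "ClumpSizeScheme",
    "DEFAULT_SCHEME",
    "COUNT_COLUMNS",
    "clump_volume",
    "total_tree_volume",
    "log_volume",
    "add_volume_columns",
    "ProxyCorrelationResult",
    "proxy_correlation",
]
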