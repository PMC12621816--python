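"""Developmental pattern metrics.

For a two-type pattern (t1, t2) the largest connected aggregate is found
under the proximity rule "edge when pairwise distance < 2l"; on it we report

* cell loss ``L = (N - N') / N`` where N' is the aggregate size, and
* morphological asymmetry
  ``A = (D_t1,t2 / D_bar) * (N'_t1 / N_t1) * (N'_t2 / N_t2)``,
  with ``D_t1,t2`` the distance between the type centroids inside the
  aggregate and ``D_bar`` the mean distance of aggregate members to the
  aggregate centroid.  A is zero by convention whenever a type is absent
  from the aggregate or all members coincide.

Twelve 3D shape descriptors characterize the overall aggregate shape from
its convex hull (volume V, surface area S) and principal semi-extents
a >= b >= c (half peak-to-peak ranges along the covariance eigenvectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .population import TYPE_INNER, TYPE_OUTER, CellPopulation

__all__ = [
    "PatternMetrics",
    "ShapeDescriptors",
    "DESCRIPTOR_NAMES",
    "largest_aggregate",
    "cell_loss",
    "morphological_asymmetry",
    "shape_descriptors",
    "evaluate_pattern",
]

DESCRIPTOR_NAMES = (
    "general_sphericity",
    "diameter_sphericity",
    "intercept_sphericity",
    "max_projection_sphericity",
    "hayakawa_roundness",
    "spreading_index",
    "elongation_ratio",
    "pivotability_index",
    "wilson_flatness_index",
    "hayakawa_flatness_ratio",
    "huang_shape_factor",
    "corey_shape_factor",
)


def largest_aggregate(
    population: CellPopulation, threshold: float = 2.0
) -> np.ndarray:
    """Indices of the largest connected aggregate.

    Cells are connected when their pairwise distance is strictly below the
    threshold (default 2l = 2 with the unit cell radius).  Among equally
    large components the one containing the smallest cell index wins.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = population.n_cells
    tree = cKDTree(population.positions)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(
            population.positions[pairs[:, 1]] - population.positions[pairs[:, 0]],
            axis=1,
        )
        pairs = pairs[d < threshold]  # strict inequality
    rows = pairs[:, 0] if pairs.size else np.empty(0, int)
    cols = pairs[:, 1] if pairs.size else np.empty(0, int)
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    max_size = sizes.max()
    # first cell (lowest index) whose component has maximal size
    for idx in range(n):
        if sizes[labels[idx]] == max_size:
            winner = labels[idx]
            break
    return np.flatnonzero(labels == winner)


def cell_loss(population: CellPopulation, aggregate: np.ndarray) -> float:
    """Fraction of cells outside the largest aggregate."""
    n = population.n_cells
    return (n - len(aggregate)) / n


def morphological_asymmetry(
    population: CellPopulation, aggregate: np.ndarray
) -> float:
    """Centroid separation of the two types inside the aggregate, normalized
    by aggregate size and weighted by per-type retention fractions.

    Returns 0 when a type is missing from the aggregate or when all
    aggregate members coincide (degenerate patterns score as unbroken
    symmetry).
    """
    aggregate = np.asarray(aggregate, dtype=int)
    types = population.types
    n_t1 = int(np.sum(types == TYPE_OUTER))
    n_t2 = int(np.sum(types == TYPE_INNER))
    agg_types = types[aggregate]
    kept_t1 = aggregate[agg_types == TYPE_OUTER]
    kept_t2 = aggregate[agg_types == TYPE_INNER]
    if len(kept_t1) == 0 or len(kept_t2) == 0:
        return 0.0
    pos = population.positions
    centroid_t1 = pos[kept_t1].mean(axis=0)
    centroid_t2 = pos[kept_t2].mean(axis=0)
    d_12 = float(np.linalg.norm(centroid_t1 - centroid_t2))
    members = pos[aggregate]
    centroid_all = members.mean(axis=0)
    d_bar = float(np.mean(np.linalg.norm(members - centroid_all, axis=1)))
    if d_bar == 0.0:
        return 0.0
    return (d_12 / d_bar) * (len(kept_t1) / n_t1) * (len(kept_t2) / n_t2)


# ---------------------------------------------------------------------------
# 3D shape descriptors
# ---------------------------------------------------------------------------

@dataclass
class ShapeDescriptors:
    """Twelve named shape descriptor values plus the geometric primitives
    they derive from."""

    values: Dict[str, float]
    semi_extents: Tuple[float, float, float]
    hull_volume: float
    hull_area: float
    degenerate: bool = False


def _principal_semi_extents(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Half peak-to-peak extents along the covariance eigenvectors,
    sorted a >= b >= c."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / len(points)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order]
    proj = centered @ axes
    extents = (proj.max(axis=0) - proj.min(axis=0)) / 2.0
    order2 = np.argsort(extents)[::-1]
    return extents[order2], axes[:, order2]


def shape_descriptors(positions: np.ndarray) -> ShapeDescriptors:
    """Evaluate the twelve 3D shape descriptors of a point aggregate.

    Grain-shape definitions: with hull volume V, hull surface area S and
    principal semi-extents a >= b >= c,

    ========================  =============================
    General Sphericity        pi^(1/3) (6V)^(2/3) / S
    Diameter Sphericity       (6V/pi)^(1/3) / (2a)
    Intercept Sphericity      (bc/a^2)^(1/3)
    Max Projection Sphericity (c^2/(ab))^(1/3)
    Hayakawa Roundness        V / ((4/3) pi a b c)
    Spreading Index           (a - c)/a
    Elongation Ratio          a/b
    Pivotability Index        c/a
    Wilson Flatness Index     (a + b)/(2c)
    Hayakawa Flatness Ratio   c/b
    Huang Shape Factor        c a / b^2
    Corey Shape Factor        c / sqrt(ab)
    ========================  =============================

    Coplanar or collinear inputs set the ``degenerate`` flag; descriptors
    with a finite flat limit take it, the rest are NaN.
    """
    points = np.asarray(positions, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("positions must be an (N, 3) array")
    if len(points) < 4:
        raise ValueError("at least 4 points required")
    extents, _ = _principal_semi_extents(points)
    a, b, c = (float(x) for x in extents)
    degenerate = c <= 1e-12 * max(a, 1.0)
    volume = area = np.nan
    if not degenerate:
        try:
            hull = ConvexHull(points)
            volume, area = float(hull.volume), float(hull.area)
        except QhullError:
            degenerate = True

    nan = float("nan")
    v: Dict[str, float] = {}
    if degenerate:
        v["general_sphericity"] = nan
        v["diameter_sphericity"] = nan
        v["hayakawa_roundness"] = nan
        v["wilson_flatness_index"] = nan
    else:
        v["general_sphericity"] = np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area
        v["diameter_sphericity"] = (6 * volume / np.pi) ** (1 / 3) / (2 * a)
        v["hayakawa_roundness"] = volume / (4.0 / 3.0 * np.pi * a * b * c)
        v["wilson_flatness_index"] = (a + b) / (2 * c)
    v["intercept_sphericity"] = (b * c / a**2) ** (1 / 3)
    v["max_projection_sphericity"] = (c**2 / (a * b)) ** (1 / 3)
    v["spreading_index"] = (a - c) / a
    v["elongation_ratio"] = a / b if b > 0 else nan
    v["pivotability_index"] = c / a
    v["hayakawa_flatness_ratio"] = c / b if b > 0 else nan
    v["huang_shape_factor"] = c * a / b**2 if b > 0 else nan
    v["corey_shape_factor"] = c / np.sqrt(a * b) if a * b > 0 else nan
    return ShapeDescriptors(
        values=v,
        semi_extents=(a, b, c),
        hull_volume=volume,
        hull_area=area,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# combined evaluation
# ---------------------------------------------------------------------------

@dataclass
class PatternMetrics:
    """Full metric set for one configuration."""

    aggregate_members: np.ndarray
    n_kept_outer: int
    n_kept_inner: int
    L: float
    A: float
    shape: Optional[ShapeDescriptors] = None

    def to_row(self) -> Dict[str, float]:
        row = {"L": self.L, "A": self.A}
        if self.shape is not None:
            row.update(self.shape.values)
        return row


def evaluate_pattern(
    population: CellPopulation,
    threshold: float = 2.0,
    with_shape: bool = False,
) -> PatternMetrics:
    """Largest aggregate, cell loss, morphological asymmetry and (optionally)
    the shape descriptors for one population snapshot."""
    agg = largest_aggregate(population, threshold=threshold)
    agg_types = population.types[agg]
    shape = None
    if with_shape and len(agg) >= 4:
        shape = shape_descriptors(population.positions[agg])
    return PatternMetrics(
        aggregate_members=agg,
        n_kept_outer=int(np.sum(agg_types == TYPE_OUTER)),
        n_kept_inner=int(np.sum(agg_types == TYPE_INNER)),
        L=cell_loss(population, agg),
        A=morphological_asymmetry(population, agg),
        shape=shape,
    )
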