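"""Cell populations and aggregate initialization.

A simulated gastruloid is a set of point cells in 3D, each carrying a radius
``l`` (the coarse-grained cell size, 1 length unit by default), a type label
and, for genetically regulated runs, a vector of gene expression levels in
[0, 1].  Two-type runs use the labels ``"o"`` (outer/peripheral) and ``"i"``
(inner/core); genetically regulated runs start every cell as ``"u"``
(undifferentiated) and classes are assigned later from gene state.

The canonical initial condition is a near-spherical aggregate of randomly
packed, mutually contacting cells with a radial prepattern: the peripheral
shell is labeled outer and the core inner, mirroring the inside-outside
asymmetry that seeds axis formation in stem-cell aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "CellPopulation",
    "TYPE_OUTER",
    "TYPE_INNER",
    "TYPE_UNDIFF",
    "TYPE_CODES",
    "init_spherical_aggregate",
    "make_two_cluster_fixture",
    "relabel_by_gene",
]

TYPE_OUTER = "o"
TYPE_INNER = "i"
TYPE_UNDIFF = "u"

#: integer codes used by the force kernels; order matters for the 3x3 tables
TYPE_CODES = {TYPE_OUTER: 0, TYPE_INNER: 1, TYPE_UNDIFF: 2}
_ALLOWED_TYPES = frozenset(TYPE_CODES)


@dataclass
class CellPopulation:
    """Positions, radii, type labels and (optional) gene state of N cells.

    Invariants are checked on construction: finite coordinates, at least one
    cell, labels drawn from {"o", "i", "u"}, and gene levels inside [0, 1].
    """

    positions: np.ndarray
    radii: np.ndarray
    types: np.ndarray
    genes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.types = np.asarray(self.types, dtype="U1")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("population must contain at least one cell")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.radii.shape != (n,):
            raise ValueError("radii must be an (N,) array")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.types.shape != (n,):
            raise ValueError("types must be an (N,) array")
        bad = set(self.types.tolist()) - _ALLOWED_TYPES
        if bad:
            raise ValueError(f"unknown type labels: {sorted(bad)}")
        if self.genes is not None:
            self.genes = np.asarray(self.genes, dtype=float)
            if self.genes.ndim != 2 or self.genes.shape[0] != n:
                raise ValueError("genes must be an (N, G) array")
            if np.any(self.genes < 0) or np.any(self.genes > 1):
                raise ValueError("gene levels must lie in [0, 1]")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_genes(self) -> int:
        return 0 if self.genes is None else self.genes.shape[1]

    def type_codes(self) -> np.ndarray:
        """Integer type codes (o=0, i=1, u=2) for the force kernels."""
        codes = np.empty(self.n_cells, dtype=np.int8)
        for label, code in TYPE_CODES.items():
            codes[self.types == label] = code
        return codes

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            types=self.types.copy(),
            genes=None if self.genes is None else self.genes.copy(),
        )

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tabular view: id, x, y, z, radius, type, gene_1..gene_G."""
        data = {
            "id": np.arange(self.n_cells),
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "radius": self.radii,
            "type": self.types,
        }
        if self.genes is not None:
            for g in range(self.n_genes):
                data[f"gene_{g + 1}"] = self.genes[:, g]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CellPopulation":
        gene_cols = sorted(
            (c for c in frame.columns if c.startswith("gene_")),
            key=lambda c: int(c.split("_")[1]),
        )
        genes = frame[gene_cols].to_numpy(float) if gene_cols else None
        return cls(
            positions=frame[["x", "y", "z"]].to_numpy(float),
            radii=frame["radius"].to_numpy(float),
            types=frame["type"].to_numpy(str),
            genes=genes,
        )

    @classmethod
    def from_csv(cls, path) -> "CellPopulation":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _sample_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform sample of n points inside a ball of the given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _relax_repulsion(
    positions: np.ndarray,
    ball_radius: float,
    d_target: float,
    d_min: float,
    max_steps: int,
    dt: float = 0.1,
) -> np.ndarray:
    """Push overlapping cells apart until no pair is closer than d_min.

    Repulsion-only linear springs act on pairs closer than d_target; positions
    are clamped back into the sampling ball so the aggregate stays compact.
    """
    pos = positions.copy()
    n = pos.shape[0]
    if n < 2:
        return pos
    for _ in range(max_steps):
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=d_target, output_type="ndarray")
        if pairs.size == 0:
            break
        diff = pos[pairs[:, 1]] - pos[pairs[:, 0]]
        dist = np.linalg.norm(diff, axis=1)
        if dist.min() >= d_min:
            break
        # coincident pairs: deterministic +x push on the lower index
        coincident = dist == 0.0
        if np.any(coincident):
            diff[coincident] = np.array([1.0, 0.0, 0.0])
            dist[coincident] = 1e-12
        mag = (d_target - dist) / dist
        push = diff * mag[:, None]
        force = np.zeros_like(pos)
        np.subtract.at(force, pairs[:, 0], push)
        np.add.at(force, pairs[:, 1], push)
        pos += dt * force
        # clamp into the ball
        rad = np.linalg.norm(pos, axis=1)
        outside = rad > ball_radius
        if np.any(outside):
            pos[outside] *= (ball_radius / rad[outside])[:, None]
    return pos


def _merge_components(positions: np.ndarray, threshold: float) -> np.ndarray:
    """Translate stray connected components toward the main one.

    Uses the same proximity rule as the pattern metrics (edge when pairwise
    distance < threshold).  Rarely needed at the default packing density but
    guarantees the single-aggregate postcondition.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pos = positions.copy()
    n = pos.shape[0]
    for _ in range(n):  # each pass merges at least one component
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=threshold, output_type="ndarray")
        if pairs.size:
            d = np.linalg.norm(pos[pairs[:, 1]] - pos[pairs[:, 0]], axis=1)
            pairs = pairs[d < threshold]
        rows = pairs[:, 0] if pairs.size else np.empty(0, int)
        cols = pairs[:, 1] if pairs.size else np.empty(0, int)
        adj = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp == 1:
            break
        sizes = np.bincount(labels)
        main = int(np.argmax(sizes))
        main_mask = labels == main
        main_centroid = pos[main_mask].mean(axis=0)
        # move the closest stray component along the line between centroids
        for comp in range(n_comp):
            if comp == main:
                continue
            mask = labels == comp
            # distance from this component to the main one
            d = np.min(
                np.linalg.norm(
                    pos[mask][:, None, :] - pos[main_mask][None, :, :], axis=2
                )
            )
            if d >= threshold:
                shift = pos[mask].mean(axis=0) - main_centroid
                norm = np.linalg.norm(shift)
                direction = shift / norm if norm > 0 else np.array([1.0, 0, 0])
                pos[mask] -= direction * (d - 0.7 * threshold)
            break
    return pos


def init_spherical_aggregate(
    n_cells: int,
    outer_fraction: float = 0.25,
    cell_radius: float = 1.0,
    packing_fraction: float = 0.5,
    seed: int = 0,
    relax_steps: int = 200,
    n_genes: int = 0,
) -> CellPopulation:
    """Near-spherical aggregate with a radial outer/inner prepattern.

    Cells are sampled uniformly inside a ball of radius
    ``R = cell_radius * (n_cells / packing_fraction)**(1/3)`` and relaxed with
    repulsion-only springs until no pair is closer than one cell radius, so
    the aggregate is a contacting, single connected cluster under the
    2*cell_radius proximity rule.  The ``ceil(outer_fraction * n_cells)``
    cells farthest from the centroid are labeled outer ("o"), the rest inner
    ("i"); radial ties break by cell index.

    With ``n_genes > 0`` the population is returned undifferentiated ("u")
    with every gene at its maximum value 1, the initial condition of the
    genetically regulated runs.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be at least 2")
    if not 0.0 <= outer_fraction <= 1.0:
        raise ValueError("outer_fraction must lie in [0, 1]")
    if cell_radius <= 0:
        raise ValueError("cell_radius must be positive")
    if packing_fraction <= 0:
        raise ValueError("packing_fraction must be positive")

    rng = np.random.default_rng(seed)
    ball_radius = cell_radius * (n_cells / packing_fraction) ** (1.0 / 3.0)
    pos = _sample_ball(rng, n_cells, ball_radius)
    # alternate overlap relaxation and stray-component merging until both
    # postconditions (min spacing >= l, single aggregate under 2l) hold
    for _ in range(10):
        pos = _relax_repulsion(
            pos,
            ball_radius=ball_radius,
            d_target=1.5 * cell_radius,
            d_min=1.0 * cell_radius,
            max_steps=relax_steps,
            dt=0.2,
        )
        merged = _merge_components(pos, threshold=2.0 * cell_radius)
        converged = merged is pos or np.array_equal(merged, pos)
        pos = merged
        if converged:
            break
    pos -= pos.mean(axis=0)

    radii = np.full(n_cells, cell_radius)
    if n_genes > 0:
        types = np.full(n_cells, TYPE_UNDIFF)
        genes = np.ones((n_cells, n_genes))
    else:
        dist = np.linalg.norm(pos - pos.mean(axis=0), axis=1)
        k = math.ceil(outer_fraction * n_cells)
        # sort by decreasing radial distance, ties by index
        order = np.lexsort((np.arange(n_cells), -dist))
        types = np.full(n_cells, TYPE_INNER)
        types[order[:k]] = TYPE_OUTER
        genes = None
    return CellPopulation(positions=pos, radii=radii, types=types, genes=genes)


def make_two_cluster_fixture(
    n1: int,
    n2: int,
    separation: float,
    spread: float = 0.0,
    seed: int = 0,
) -> CellPopulation:
    """Two point clusters: n1 outer cells near the origin, n2 inner cells near
    (separation, 0, 0), each jittered by an isotropic Gaussian of the given
    spread.  Used as an analytic fixture for the pattern metrics."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both clusters need at least one cell")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    n = n1 + n2
    pos = np.zeros((n, 3))
    pos[n1:, 0] = separation
    if spread > 0:
        pos += rng.normal(scale=spread, size=(n, 3))
    types = np.array([TYPE_OUTER] * n1 + [TYPE_INNER] * n2)
    return CellPopulation(positions=pos, radii=np.ones(n), types=types)


def relabel_by_gene(
    population: CellPopulation, gene_index: int, threshold: float
) -> CellPopulation:
    """Map gene state to outer/inner classes: level < threshold -> "o",
    otherwise "i".  Positions and gene values are unchanged."""
    if population.genes is None:
        raise ValueError("population carries no gene matrix")
    if not 0 <= gene_index < population.n_genes:
        raise ValueError("gene_index out of range")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = population.copy()
    level = out.genes[:, gene_index]
    out.types = np.where(level < threshold, TYPE_OUTER, TYPE_INNER).astype("U1")
    return out
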