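"""Genetic-mechanical regulation.

Each cell carries G gene expression levels in [0, 1] that evolve under

* intracellular regulation: signed gene-gene weights feeding a Hill
  nonlinearity,
* intercellular regulation: a distance-decaying morphogen-like cue, the
  signal being the sum over other cells of their source-gene level weighted
  by ``exp(-r / lambda)``,
* leak, first-order degradation and Gaussian noise, with clipping to [0, 1].

The net regulatory input to gene g of cell m is

    u = sum_intra W * G_m + sum_inter W * sum_{k != m} G_k exp(-r_mk / lambda)

(inhibitory edges enter with negative weight); production is
``amplitude * H(u)`` with ``H(u) = u^h / (K^h + u^h)`` for u > 0 and 0
otherwise, so

    dG = dt * (amplitude * H(u) + leak - delta * G) + noise.

Edges may carry a *gate*: a predicate on one of the cell's own genes
(above/below a threshold) that enables the edge cell by cell, which is how
the establishment-stage bistability circuit and the maintenance-stage
locker circuit are switched by the timer gene.

Gene state is read out into mechanics: while a cell's timer gene is still
high it interacts with the homogeneous baseline adhesion and no long-range
force (establishment stage); once the timer falls below its threshold the
cell is classed outer or inner from the class gene and the two-type
adhesion table and directed long-range channels apply (maintenance stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import metrics as _metrics
from .mechanics import (
    IntegratorParams,
    LongRangeParams,
    ShortRangeParams,
    Trajectory,
    _expand_tables,
    _force_kernel,
)
from .population import (
    TYPE_CODES,
    TYPE_INNER,
    TYPE_OUTER,
    TYPE_UNDIFF,
    CellPopulation,
    init_spherical_aggregate,
    relabel_by_gene,
)

__all__ = [
    "Gate",
    "RegulatoryEdge",
    "ReadoutRule",
    "GRNSpec",
    "default_network",
    "gene_update",
    "apply_readouts",
    "run_grn_simulation",
    "GRNTrajectory",
]


@dataclass(frozen=True)
class Gate:
    """Edge-enabling predicate on one of the cell's own genes."""

    gene: int
    op: str  # "above" or "below"
    theta: float

    def __post_init__(self) -> None:
        if self.op not in ("above", "below"):
            raise ValueError("gate op must be 'above' or 'below'")

    def holds(self, genes: np.ndarray) -> np.ndarray:
        level = genes[:, self.gene]
        return level > self.theta if self.op == "above" else level < self.theta


@dataclass(frozen=True)
class RegulatoryEdge:
    """Signed regulation edge; intercellular when ``lam`` is set."""

    source: int
    target: int
    weight: float
    lam: Optional[float] = None  # decay length of the intercellular cue
    gate: Optional[Gate] = None

    @property
    def intercellular(self) -> bool:
        return self.lam is not None


@dataclass
class ReadoutRule:
    """Mapping from gene state to the mechanical interaction tables."""

    timer_gene: int = 0
    timer_threshold: float = 0.5
    class_gene: int = 1
    class_threshold: float = 0.5
    alpha_hom: float = 0.80
    alpha_table: ShortRangeParams = field(
        default_factory=lambda: ShortRangeParams.from_triple(0.72, 0.79, 0.88)
    )
    beta_table: LongRangeParams = field(
        default_factory=lambda: LongRangeParams.single_channel("o", "o", 0.3)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.timer_threshold < 1.0:
            raise ValueError("timer_threshold must lie in (0, 1)")
        if not 0.0 < self.class_threshold < 1.0:
            raise ValueError("class_threshold must lie in (0, 1)")


@dataclass
class GRNSpec:
    """Gene count, regulation edges, kinetic constants and force readouts.

    Per-gene arrays: ``amplitude`` (max regulated production rate),
    ``hill_h``, ``hill_k``, ``leak``, ``degradation``.
    """

    n_genes: int
    edges: List[RegulatoryEdge]
    amplitude: np.ndarray
    hill_h: np.ndarray
    hill_k: np.ndarray
    leak: np.ndarray
    degradation: np.ndarray
    gene_noise_sigma: float = 0.01
    readout: ReadoutRule = field(default_factory=ReadoutRule)

    def __post_init__(self) -> None:
        for name in ("amplitude", "hill_h", "hill_k", "leak", "degradation"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_genes,):
                raise ValueError(f"{name} must have one entry per gene")
            setattr(self, name, arr)
        if np.any(self.hill_h < 1):
            raise ValueError("hill coefficients must be >= 1")
        if np.any((self.hill_k <= 0) | (self.hill_k >= 1)):
            raise ValueError("hill thresholds must lie in (0, 1)")
        if np.any(self.degradation < 0):
            raise ValueError("degradation rates must be non-negative")
        if self.gene_noise_sigma < 0:
            raise ValueError("gene_noise_sigma must be non-negative")
        for e in self.edges:
            for g in (e.source, e.target):
                if not 0 <= g < self.n_genes:
                    raise ValueError(f"edge references missing gene {g}")
            if e.gate is not None and not 0 <= e.gate.gene < self.n_genes:
                raise ValueError(
                    f"gate references missing gene {e.gate.gene}"
                )
            if e.intercellular and e.lam <= 0:
                raise ValueError("intercellular decay length must be positive")
            if not np.isfinite(e.weight):
                raise ValueError("edge weights must be finite")


def default_network(
    beta_oo: float = 0.3,
    gene_noise_sigma: float = 0.01,
) -> GRNSpec:
    """The minimal 3-gene symmetry-breaking network.

    G1 (index 0) is a *timer*: self-activating with strong degradation, it
    decays from its high initial state through the Hill threshold, switching
    the aggregate from the establishment to the maintenance stage.  G1 also
    emits the morphogen-like cue that activates G2 (index 1), so core cells
    with more close neighbors receive more cue than peripheral cells.  A
    mutual-inhibition *bistability* circuit between G2 and G3 (index 2),
    gated ON while the timer is high, amplifies that radial bias into two
    complementary cell states (inner: G2 high / G3 low; outer: the reverse);
    G3 self-activation sustains the outer branch.  A *locker* circuit (G2
    self-activation gated ON once the timer is low) then fixes the inner
    state for the rest of the run.  The readout applies the two-type
    adhesion table and peripheral long-range attraction (beta_o->o > 0) only
    to cells whose timer has elapsed.
    """
    timer = Gate(gene=0, op="above", theta=0.5)
    timer_done = Gate(gene=0, op="below", theta=0.5)
    edges = [
        RegulatoryEdge(source=0, target=0, weight=1.0),             # timer self
        RegulatoryEdge(source=0, target=1, weight=0.15, lam=2.0,
                       gate=timer),                                 # cue G1 -> G2
        RegulatoryEdge(source=2, target=1, weight=-1.0, gate=timer),  # G3 -| G2
        RegulatoryEdge(source=1, target=2, weight=-1.0, gate=timer),  # G2 -| G3
        RegulatoryEdge(source=0, target=2, weight=1.3, gate=timer),   # G1 -> G3
        RegulatoryEdge(source=1, target=1, weight=1.0, gate=timer_done),  # locker
        RegulatoryEdge(source=2, target=2, weight=1.0, gate=timer_done),  # locker
    ]
    return GRNSpec(
        n_genes=3,
        edges=edges,
        amplitude=np.array([0.142, 0.5, 0.5]),
        hill_h=np.array([8.0, 4.0, 4.0]),
        hill_k=np.array([0.7, 0.7, 0.7]),
        leak=np.array([0.0, 0.01, 0.01]),
        degradation=np.array([0.15, 0.2, 0.2]),
        gene_noise_sigma=gene_noise_sigma,
        readout=ReadoutRule(
            beta_table=LongRangeParams.single_channel("o", "o", beta_oo)
        ),
    )


# ---------------------------------------------------------------------------
# gene dynamics
# ---------------------------------------------------------------------------

def _cue_matrix(positions: np.ndarray, lam: float) -> np.ndarray:
    """exp(-r / lambda) kernel between all cell pairs, zero on the diagonal."""
    diff = positions[:, None, :] - positions[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    kernel = np.exp(-dist / lam)
    np.fill_diagonal(kernel, 0.0)
    return kernel


def gene_update(
    population: CellPopulation,
    spec: GRNSpec,
    dt: float,
    rng: np.random.Generator,
    _cue_cache: Optional[Dict[float, np.ndarray]] = None,
) -> np.ndarray:
    """One synchronous update of the gene matrix; returns the new (N, G)
    matrix (all updates computed from the previous step's state)."""
    if population.genes is None:
        raise ValueError("population carries no gene matrix")
    genes = population.genes
    n = population.n_cells
    u = np.zeros((n, spec.n_genes))
    for e in spec.edges:
        if e.intercellular:
            if _cue_cache is not None and e.lam in _cue_cache:
                kernel = _cue_cache[e.lam]
            else:
                kernel = _cue_matrix(population.positions, e.lam)
                if _cue_cache is not None:
                    _cue_cache[e.lam] = kernel
            contrib = e.weight * (kernel @ genes[:, e.source])
        else:
            contrib = e.weight * genes[:, e.source]
        if e.gate is not None:
            mask = e.gate.holds(genes)
            u[mask, e.target] += contrib[mask] if contrib.ndim else contrib
        else:
            u[:, e.target] += contrib
    pos_u = np.maximum(u, 0.0)
    h = spec.hill_h[None, :]
    k = spec.hill_k[None, :]
    hill = np.where(u > 0, pos_u**h / (k**h + pos_u**h), 0.0)
    dg = dt * (
        spec.amplitude[None, :] * hill
        + spec.leak[None, :]
        - spec.degradation[None, :] * genes
    )
    new = genes + dg
    if spec.gene_noise_sigma > 0:
        new = new + rng.normal(scale=spec.gene_noise_sigma, size=new.shape)
    return np.clip(new, 0.0, 1.0)


# ---------------------------------------------------------------------------
# gene -> force readout
# ---------------------------------------------------------------------------

def apply_readouts(
    population: CellPopulation, rule: ReadoutRule
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell mechanical state and the 3x3 interaction tables.

    Returns ``(states, alpha_table, beta_table)``: ``states`` holds the type
    code of every cell (o=0, i=1, u=2 for cells still in the establishment
    stage, i.e. timer gene >= its threshold).  The tables are indexed by
    those codes; any pair involving an establishment-stage cell uses the
    homogeneous baseline adhesion and no long-range force, so mixed-stage
    pairs fall back to the baseline.
    """
    if population.genes is None:
        raise ValueError("population carries no gene matrix")
    genes = population.genes
    timer_high = genes[:, rule.timer_gene] >= rule.timer_threshold
    outer = genes[:, rule.class_gene] < rule.class_threshold
    states = np.where(
        timer_high,
        TYPE_CODES[TYPE_UNDIFF],
        np.where(outer, TYPE_CODES[TYPE_OUTER], TYPE_CODES[TYPE_INNER]),
    ).astype(np.int8)
    alpha3, beta3 = _expand_tables(
        rule.alpha_table.as_table(),
        rule.beta_table.as_table(),
        alpha_hom=rule.alpha_hom,
    )
    return states, alpha3, beta3


# ---------------------------------------------------------------------------
# coupled simulation
# ---------------------------------------------------------------------------

@dataclass
class GRNTrajectory:
    """Snapshots (with gene state) and the asymmetry time series of a
    genetic-mechanical run."""

    snapshots: List[CellPopulation]
    steps: List[int]
    dt: float
    asymmetry: np.ndarray  # A at every recorded step, via the class gene
    asymmetry_steps: np.ndarray

    @property
    def initial(self) -> CellPopulation:
        return self.snapshots[0]

    @property
    def final(self) -> CellPopulation:
        return self.snapshots[-1]

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.steps, dtype=float) * self.dt

    def gene_table(self) -> "np.ndarray":
        """Long-format (step, cell, gene, value) array of recorded states."""
        rows = []
        for s, snap in zip(self.steps, self.snapshots):
            g = snap.genes
            for cell in range(snap.n_cells):
                for gene in range(snap.n_genes):
                    rows.append((s, cell, gene, g[cell, gene]))
        return np.asarray(rows)


def run_grn_simulation(
    spec: GRNSpec,
    population: Optional[CellPopulation] = None,
    integ: Optional[IntegratorParams] = None,
    n_cells: int = 400,
    k_s: float = 1.0,
    cutoff_factor: float = 1.0,
    record_every: int = 25,
    metric_every: int = 25,
    aggregate_threshold: float = 2.0,
    seed: Optional[int] = None,
) -> GRNTrajectory:
    """Coupled genetic-mechanical run from an undifferentiated aggregate.

    Every step: synchronous gene update, gene->force readout, pairwise
    forces, overdamped position step.  Morphological asymmetry is recorded
    every ``metric_every`` steps after classing cells by the readout's class
    gene.  All gene levels start at their maximum (1).
    """
    if integ is None:
        integ = IntegratorParams()
    if seed is not None:
        integ = replace(integ, seed=seed)
    if population is None:
        population = init_spherical_aggregate(
            n_cells=n_cells, seed=integ.seed, n_genes=spec.n_genes
        )
    if population.genes is None:
        raise ValueError("population must carry a gene matrix")
    rng = np.random.default_rng(integ.seed)
    pop = population.copy()
    n_steps = integ.n_steps
    rule = spec.readout
    p_exp = rule.beta_table.p

    def record_A(pp: CellPopulation) -> float:
        classed = relabel_by_gene(pp, rule.class_gene, rule.class_threshold)
        agg = _metrics.largest_aggregate(classed, threshold=aggregate_threshold)
        return _metrics.morphological_asymmetry(classed, agg)

    snapshots = [pop.copy()]
    steps = [0]
    a_series = [record_A(pop)]
    a_steps = [0]
    for kstep in range(1, n_steps + 1):
        cue_cache: Dict[float, np.ndarray] = {}
        pop.genes = gene_update(pop, spec, integ.dt, rng, _cue_cache=cue_cache)
        states, alpha3, beta3 = apply_readouts(pop, rule)
        forces = _force_kernel(
            pop.positions, pop.radii, states, alpha3, beta3,
            k_s, cutoff_factor, p_exp,
        )
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError(f"non-finite forces at step {kstep}")
        pop.positions = pop.positions + integ.dt * forces / integ.gamma
        if integ.noise_sigma > 0 or integ.noise_mean != 0:
            pop.positions = pop.positions + rng.normal(
                loc=integ.noise_mean,
                scale=integ.noise_sigma,
                size=pop.positions.shape,
            )
        if (metric_every and kstep % metric_every == 0) or kstep == n_steps:
            a_series.append(record_A(pop))
            a_steps.append(kstep)
        if (record_every and kstep % record_every == 0) or kstep == n_steps:
            snapshots.append(pop.copy())
            steps.append(kstep)
    return GRNTrajectory(
        snapshots=snapshots,
        steps=steps,
        dt=integ.dt,
        asymmetry=np.asarray(a_series),
        asymmetry_steps=np.asarray(a_steps),
    )
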