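"""Pairwise forces and overdamped noisy Euler integration.

Two interaction channels act between point cells:

* a short-range contact force (effective adhesion/surface tension), linear in
  the pair separation r with zero net force at the balance distance
  ``r_b = alpha * (l_m + l_n)`` and a hard cutoff at
  ``r_c = cutoff_factor * (l_m + l_n)``; smaller alpha means stronger
  effective adhesion;
* an optional directed long-range, chemotaxis-like force of magnitude
  ``|beta| / r**p`` acting beyond the contact range, attractive for
  ``beta > 0`` and repulsive for ``beta < 0``.  The channel is keyed by the
  signaling cell's type and the responding cell's type and is applied to the
  responder only (chemotaxis does not conserve momentum).

Motion is overdamped: each step moves a cell by ``dt * force / gamma`` plus
isotropic Gaussian positional noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit

from .population import (
    TYPE_CODES,
    TYPE_INNER,
    TYPE_OUTER,
    TYPE_UNDIFF,
    CellPopulation,
)

__all__ = [
    "ShortRangeParams",
    "LongRangeParams",
    "IntegratorParams",
    "Trajectory",
    "short_range_force",
    "long_range_force",
    "total_forces",
    "step",
    "run_simulation",
]

_PAIR_KEYS = (("i", "i"), ("o", "o"), ("i", "o"))
_CHANNEL_KEYS = (("i", "i"), ("o", "o"), ("i", "o"), ("o", "i"))


def _normalize_pair_key(key) -> Tuple[str, str]:
    a, b = key
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass
class ShortRangeParams:
    """Symmetric adhesion table keyed by unordered type pair.

    ``alpha`` maps {("i","i"), ("o","o"), ("i","o")} to the dimensionless
    balance-distance factor (0.65-0.95 in the sweeps).  ``k_s`` is the spring
    stiffness and ``cutoff_factor`` the multiple of (l_m + l_n) beyond which
    the contact force vanishes.
    """

    alpha: Dict[Tuple[str, str], float]
    k_s: float = 1.0
    cutoff_factor: float = 1.0

    def __post_init__(self) -> None:
        norm = {}
        for key, value in self.alpha.items():
            nk = _normalize_pair_key(key)
            if nk in norm and norm[nk] != value:
                raise ValueError(f"alpha table is not symmetric at {key}")
            norm[nk] = float(value)
        missing = set(_PAIR_KEYS) - set(norm)
        if missing:
            raise ValueError(f"alpha table missing pairs: {sorted(missing)}")
        for key, value in norm.items():
            if not 0.0 < value < self.cutoff_factor:
                raise ValueError(
                    f"alpha[{key}] = {value} must lie in (0, cutoff_factor)"
                )
        if self.k_s <= 0:
            raise ValueError("k_s must be positive")
        self.alpha = norm

    @classmethod
    def homogeneous(cls, alpha: float, **kwargs) -> "ShortRangeParams":
        return cls(
            alpha={("i", "i"): alpha, ("o", "o"): alpha, ("i", "o"): alpha},
            **kwargs,
        )

    @classmethod
    def from_triple(
        cls, alpha_ii: float, alpha_oo: float, alpha_io: float, **kwargs
    ) -> "ShortRangeParams":
        return cls(
            alpha={
                ("i", "i"): alpha_ii,
                ("o", "o"): alpha_oo,
                ("i", "o"): alpha_io,
            },
            **kwargs,
        )

    def lookup(self, t1: str, t2: str) -> float:
        return self.alpha[_normalize_pair_key((t1, t2))]

    def as_table(self) -> np.ndarray:
        """2x2 alpha table indexed by type code (o=0, i=1)."""
        tab = np.empty((2, 2))
        for a, ca in ((TYPE_OUTER, 0), (TYPE_INNER, 1)):
            for b, cb in ((TYPE_OUTER, 0), (TYPE_INNER, 1)):
                tab[ca, cb] = self.lookup(a, b)
        return tab


@dataclass
class LongRangeParams:
    """Directed long-range table keyed (signaler type -> responder type).

    Positive beta = attraction, negative = repulsion, zero = channel off.
    ``p`` is the distance-decay exponent (2 by default, gravitation-like).
    """

    beta: Dict[Tuple[str, str], float] = field(default_factory=dict)
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError("decay exponent p must be positive")
        norm = {key: 0.0 for key in _CHANNEL_KEYS}
        for key, value in self.beta.items():
            key = (key[0], key[1])
            if key not in norm:
                raise ValueError(f"unknown long-range channel {key}")
            norm[key] = float(value)
        self.beta = norm

    @classmethod
    def off(cls, p: float = 2.0) -> "LongRangeParams":
        return cls(beta={}, p=p)

    @classmethod
    def single_channel(
        cls, signaler: str, responder: str, beta: float, p: float = 2.0
    ) -> "LongRangeParams":
        return cls(beta={(signaler, responder): beta}, p=p)

    def as_table(self) -> np.ndarray:
        """2x2 beta table: rows = signaler code, cols = responder code."""
        tab = np.zeros((2, 2))
        for (sig, resp), value in self.beta.items():
            tab[TYPE_CODES[sig], TYPE_CODES[resp]] = value
        return tab


@dataclass
class IntegratorParams:
    """Overdamped Euler integration constants.

    ``noise_sigma`` is the per-axis Gaussian positional noise per step
    (default 0.02 = dt * kappa_M with kappa_M = 0.1).  The noise has zero
    mean; set ``noise_mean`` for the alternative mean-equals-sigma reading.
    """

    dt: float = 0.2
    t_total: float = 150.0
    gamma: float = 1.0
    noise_sigma: float = 0.02
    noise_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_total < 0:
            raise ValueError("t_total must be non-negative")
        if self.t_total and self.t_total < self.dt:
            raise ValueError("t_total must be at least dt (or zero)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


# ---------------------------------------------------------------------------
# single-pair force laws
# ---------------------------------------------------------------------------

def short_range_force(
    separation: np.ndarray,
    l_m: float,
    l_n: float,
    alpha_mn: float,
    k_s: float = 1.0,
    cutoff_factor: float = 1.0,
) -> np.ndarray:
    """Contact force on cell m from cell n.

    ``separation`` points from m to n.  The force is ``k_s * (r - r_b)``
    along the unit separation vector: attractive above the balance distance
    ``r_b = alpha_mn * (l_m + l_n)``, repulsive below it, and exactly zero
    for ``r >= cutoff_factor * (l_m + l_n)``.
    """
    sep = np.asarray(separation, dtype=float)
    r = float(np.linalg.norm(sep))
    if r == 0.0:
        raise ValueError("coincident cells: separation must be non-zero")
    lsum = l_m + l_n
    if r >= cutoff_factor * lsum:
        return np.zeros(3)
    return k_s * (r - alpha_mn * lsum) * (sep / r)


def long_range_force(
    separation: np.ndarray,
    beta_nm: float,
    p: float = 2.0,
    contact_cutoff: float = 2.0,
) -> np.ndarray:
    """Chemotaxis-like force on the responder m from signaler n.

    Zero inside the contact zone (r < contact_cutoff, where the short-range
    law governs); beyond it the magnitude is ``|beta| / r**p``, directed
    toward the signaler for beta > 0 and away for beta < 0.  Applied to the
    responder only.
    """
    if p <= 0:
        raise ValueError("decay exponent p must be positive")
    sep = np.asarray(separation, dtype=float)
    r = float(np.linalg.norm(sep))
    if r == 0.0:
        raise ValueError("coincident cells: separation must be non-zero")
    if r < contact_cutoff or beta_nm == 0.0:
        return np.zeros(3)
    return (beta_nm / r**p) * (sep / r)


# ---------------------------------------------------------------------------
# population-level forces (numba kernel)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _force_kernel(
    pos: np.ndarray,
    radii: np.ndarray,
    codes: np.ndarray,
    alpha_tab: np.ndarray,
    beta_tab: np.ndarray,
    k_s: float,
    cutoff_factor: float,
    p: float,
) -> np.ndarray:  # pragma: no cover - exercised via total_forces
    n = pos.shape[0]
    out = np.zeros((n, 3))
    for m in range(n):
        cm = codes[m]
        fx = 0.0
        fy = 0.0
        fz = 0.0
        for k in range(n):
            if k == m:
                continue
            dx = pos[k, 0] - pos[m, 0]
            dy = pos[k, 1] - pos[m, 1]
            dz = pos[k, 2] - pos[m, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            lsum = radii[m] + radii[k]
            if r == 0.0:
                # coincident cells: deterministic +x repulsion on the lower
                # index, with the balance-distance magnitude
                mag = k_s * alpha_tab[cm, codes[k]] * lsum
                if m < k:
                    fx += mag
                else:
                    fx -= mag
                continue
            rc = cutoff_factor * lsum
            if r < rc:
                f = k_s * (r - alpha_tab[cm, codes[k]] * lsum) / r
                fx += f * dx
                fy += f * dy
                fz += f * dz
            else:
                beta = beta_tab[codes[k], cm]
                if beta != 0.0:
                    f = beta / r**p / r
                    fx += f * dx
                    fy += f * dy
                    fz += f * dz
        out[m, 0] = fx
        out[m, 1] = fy
        out[m, 2] = fz
    return out


def _expand_tables(
    alpha_tab2: np.ndarray,
    beta_tab2: np.ndarray,
    alpha_hom: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Embed 2x2 (o, i) tables into 3x3 tables including the "u" state.

    Pairs involving an undifferentiated cell use the homogeneous baseline
    ``alpha_hom`` (defaulting to the i-i value) and no long-range force.
    """
    if alpha_hom is None:
        alpha_hom = float(alpha_tab2[1, 1])
    alpha3 = np.full((3, 3), alpha_hom)
    alpha3[:2, :2] = alpha_tab2
    beta3 = np.zeros((3, 3))
    beta3[:2, :2] = beta_tab2
    return alpha3, beta3


def total_forces(
    population: CellPopulation,
    short: ShortRangeParams,
    long: LongRangeParams,
) -> np.ndarray:
    """Net force on every cell: sum of contact and long-range channels.

    Requires a fully typed two-class population (every cell "o" or "i"); the
    genetically regulated runs compute their per-stage tables via
    :func:`gastrosim.grn.apply_readouts` and call the kernel directly.
    """
    if np.any(population.types == TYPE_UNDIFF):
        raise ValueError("total_forces requires every cell typed 'o' or 'i'")
    alpha3, beta3 = _expand_tables(short.as_table(), long.as_table())
    return _force_kernel(
        population.positions,
        population.radii,
        population.type_codes(),
        alpha3,
        beta3,
        short.k_s,
        short.cutoff_factor,
        long.p,
    )


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def step(
    population: CellPopulation,
    forces: np.ndarray,
    integ: IntegratorParams,
    rng: np.random.Generator,
) -> CellPopulation:
    """One overdamped Euler step with per-axis Gaussian positional noise."""
    forces = np.asarray(forces, dtype=float)
    if forces.shape != population.positions.shape:
        raise ValueError("forces must be an (N, 3) array")
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite forces: aborting step")
    new = population.copy()
    new.positions = population.positions + integ.dt * forces / integ.gamma
    if integ.noise_sigma > 0 or integ.noise_mean != 0:
        new.positions = new.positions + rng.normal(
            loc=integ.noise_mean,
            scale=integ.noise_sigma,
            size=new.positions.shape,
        )
    return new


@dataclass
class Trajectory:
    """Recorded snapshots of a simulation run."""

    snapshots: List[CellPopulation]
    steps: List[int]
    dt: float

    @property
    def initial(self) -> CellPopulation:
        return self.snapshots[0]

    @property
    def final(self) -> CellPopulation:
        return self.snapshots[-1]

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.steps, dtype=float) * self.dt

    @property
    def n_steps(self) -> int:
        return self.steps[-1]

    def __len__(self) -> int:
        return len(self.snapshots)


def run_simulation(
    population: CellPopulation,
    short: ShortRangeParams,
    long: LongRangeParams,
    integ: IntegratorParams,
    record_every: Optional[int] = None,
) -> Trajectory:
    """Integrate a two-type population for round(t_total / dt) steps.

    Snapshots are recorded at step 0, every ``record_every`` steps (if set)
    and at the final step.
    """
    if np.any(population.types == TYPE_UNDIFF):
        raise ValueError("run_simulation requires a typed population")
    alpha3, beta3 = _expand_tables(short.as_table(), long.as_table())
    rng = np.random.default_rng(integ.seed)
    n_steps = integ.n_steps

    pos = population.positions.copy()
    radii = population.radii
    codes = population.type_codes()

    def snapshot(p: np.ndarray) -> CellPopulation:
        out = population.copy()
        out.positions = p.copy()
        return out

    snapshots = [snapshot(pos)]
    steps = [0]
    for k in range(1, n_steps + 1):
        forces = _force_kernel(
            pos, radii, codes, alpha3, beta3, short.k_s,
            short.cutoff_factor, long.p,
        )
        if not np.all(np.isfinite(forces)):
            raise FloatingPointError(f"non-finite forces at step {k}")
        pos = pos + integ.dt * forces / integ.gamma
        if integ.noise_sigma > 0 or integ.noise_mean != 0:
            pos = pos + rng.normal(
                loc=integ.noise_mean, scale=integ.noise_sigma, size=pos.shape
            )
        if (record_every and k % record_every == 0) or k == n_steps:
            snapshots.append(snapshot(pos))
            steps.append(k)
    return Trajectory(snapshots=snapshots, steps=steps, dt=integ.dt)
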