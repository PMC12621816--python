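"""Morphogenetic-landscape sweeps.

Enumerates a grid over the three adhesion parameters (alpha_i-i, alpha_o-o,
alpha_i-o) crossed with the long-range settings: the all-beta-zero baseline
and, one at a time, each directed channel x sign x magnitude.  Each grid
point is simulated with several independent noise seeds; cell loss L and
morphological asymmetry A of the final largest aggregate summarize each
replicate.  Ranking, feasibility (A > 1 and L < 0.1) and top-fraction
statistics reproduce the landscape analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mechanics import (
    IntegratorParams,
    LongRangeParams,
    ShortRangeParams,
    run_simulation,
)
from .metrics import cell_loss, largest_aggregate, morphological_asymmetry
from .population import init_spherical_aggregate

__all__ = [
    "SweepSpec",
    "ParameterPoint",
    "SweepResult",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_BETA_MAGNITUDES",
    "enumerate_grid",
    "replicate_seed",
    "evaluate_point",
    "run_sweep",
    "feasible_fraction",
    "top_fraction_stats",
]

#: 13 adhesion values, 0.650 to 0.950 in steps of 0.025
DEFAULT_ALPHA_GRID: Tuple[float, ...] = tuple(
    np.round(np.arange(0.650, 0.951, 0.025), 3)
)

#: logarithmic-like ladder of 10 long-range magnitudes
DEFAULT_BETA_MAGNITUDES: Tuple[float, ...] = (
    0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0,
)

#: directed channels in enumeration order (signaler, responder)
DEFAULT_CHANNELS: Tuple[Tuple[str, str], ...] = (
    ("i", "i"), ("o", "o"), ("i", "o"), ("o", "i"),
)


@dataclass(frozen=True)
class ParameterPoint:
    """One grid point: adhesion triple plus at most one active long-range
    channel (channel None = adhesion-only baseline)."""

    index: int
    alpha_ii: float
    alpha_oo: float
    alpha_io: float
    channel: Optional[Tuple[str, str]] = None
    sign: int = 0
    magnitude: float = 0.0

    @property
    def beta(self) -> float:
        return self.sign * self.magnitude if self.channel else 0.0

    def channel_label(self) -> str:
        if self.channel is None:
            return "none"
        return f"{self.channel[0]}->{self.channel[1]}"

    def short_params(self, k_s: float = 1.0, cutoff_factor: float = 1.0):
        return ShortRangeParams.from_triple(
            self.alpha_ii, self.alpha_oo, self.alpha_io,
            k_s=k_s, cutoff_factor=cutoff_factor,
        )

    def long_params(self, p: float = 2.0) -> LongRangeParams:
        if self.channel is None or self.beta == 0.0:
            return LongRangeParams.off(p=p)
        return LongRangeParams.single_channel(*self.channel, self.beta, p=p)


@dataclass
class SweepSpec:
    """Grid definition plus the per-point simulation conditions."""

    alpha_values: Sequence[float] = DEFAULT_ALPHA_GRID
    beta_channels: Sequence[Tuple[str, str]] = DEFAULT_CHANNELS
    beta_signs: Sequence[int] = (1, -1)
    beta_magnitudes: Sequence[float] = DEFAULT_BETA_MAGNITUDES
    include_baseline: bool = True
    n_replicates: int = 5
    n_cells: int = 1500
    outer_fraction: float = 0.25
    dt: float = 0.2
    t_total: float = 150.0
    noise_sigma: float = 0.02
    k_s: float = 1.0
    cutoff_factor: float = 1.0
    p: float = 2.0
    aggregate_threshold: float = 2.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        alphas = list(self.alpha_values)
        if not alphas:
            raise ValueError("alpha_values must be non-empty")
        if any(not 0.0 < a < 1.0 for a in alphas):
            raise ValueError("alpha values must lie in (0, 1)")
        if any(b >= a for a, b in zip(alphas[1:], alphas[:-1])):
            raise ValueError("alpha_values must be strictly increasing")
        if any(m <= 0 for m in self.beta_magnitudes):
            raise ValueError("beta magnitudes must be strictly positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    def adhesion_only(self) -> "SweepSpec":
        """Copy of this spec restricted to the all-beta-zero baseline."""
        from dataclasses import replace

        return replace(self, beta_channels=(), include_baseline=True)


def enumerate_grid(spec: SweepSpec) -> List[ParameterPoint]:
    """Deterministic enumeration: alpha triples in lexicographic order
    (alpha_i-i, alpha_o-o, alpha_i-o), then baseline, then channel x sign x
    magnitude (magnitudes ascending)."""
    beta_settings: List[Tuple[Optional[Tuple[str, str]], int, float]] = []
    if spec.include_baseline:
        beta_settings.append((None, 0, 0.0))
    for channel in spec.beta_channels:
        for sign in spec.beta_signs:
            for mag in spec.beta_magnitudes:
                beta_settings.append((tuple(channel), sign, mag))
    if not beta_settings:
        raise ValueError("grid has no long-range settings and no baseline")
    points = []
    idx = 0
    for a_ii, a_oo, a_io in itertools.product(
        spec.alpha_values, spec.alpha_values, spec.alpha_values
    ):
        for channel, sign, mag in beta_settings:
            points.append(
                ParameterPoint(
                    index=idx,
                    alpha_ii=float(a_ii),
                    alpha_oo=float(a_oo),
                    alpha_io=float(a_io),
                    channel=channel,
                    sign=sign,
                    magnitude=mag,
                )
            )
            idx += 1
    return points


def replicate_seed(base_seed: int, point_index: int, replicate: int) -> int:
    """Deterministic 31-bit seed for one replicate of one grid point."""
    ss = np.random.SeedSequence([int(base_seed), int(point_index), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))


def evaluate_point(
    point: ParameterPoint,
    spec: SweepSpec,
    seeds: Optional[Sequence[int]] = None,
) -> Dict[str, object]:
    """Run all replicates of one grid point and score the final states.

    Returns a flat row dict with per-replicate A/L values, their means and
    the seeds used.  Simulation failures are recorded in the ``error``
    field rather than raised, so a sweep survives isolated bad points.
    """
    if seeds is None:
        seeds = [
            replicate_seed(spec.base_seed, point.index, rep)
            for rep in range(spec.n_replicates)
        ]
    short = point.short_params(k_s=spec.k_s, cutoff_factor=spec.cutoff_factor)
    long = point.long_params(p=spec.p)
    a_vals: List[float] = []
    l_vals: List[float] = []
    error = ""
    for seed in seeds:
        try:
            pop = init_spherical_aggregate(
                n_cells=spec.n_cells,
                outer_fraction=spec.outer_fraction,
                seed=seed,
            )
            integ = IntegratorParams(
                dt=spec.dt,
                t_total=spec.t_total,
                noise_sigma=spec.noise_sigma,
                seed=seed,
            )
            traj = run_simulation(pop, short, long, integ)
            final = traj.final
            agg = largest_aggregate(final, threshold=spec.aggregate_threshold)
            a_vals.append(morphological_asymmetry(final, agg))
            l_vals.append(cell_loss(final, agg))
        except FloatingPointError as exc:  # pragma: no cover - defensive
            error = str(exc)
            a_vals.append(np.nan)
            l_vals.append(np.nan)
    row: Dict[str, object] = {
        "point_index": point.index,
        "alpha_ii": point.alpha_ii,
        "alpha_oo": point.alpha_oo,
        "alpha_io": point.alpha_io,
        "channel": point.channel_label(),
        "sign": point.sign,
        "magnitude": point.magnitude,
        "beta": point.beta,
        "mean_A": float(np.nanmean(a_vals)),
        "mean_L": float(np.nanmean(l_vals)),
        "error": error,
    }
    for rep, (a, l, s) in enumerate(zip(a_vals, l_vals, seeds)):
        row[f"A_rep{rep}"] = a
        row[f"L_rep{rep}"] = l
        row[f"seed_rep{rep}"] = s
    return row


@dataclass
class SweepResult:
    """One row per evaluated grid point."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SweepResult":
        return cls(table=pd.read_csv(path, keep_default_na=False,
                                     na_values=[""]))


def run_sweep(
    spec: SweepSpec,
    points: Optional[Sequence[ParameterPoint]] = None,
    existing: Optional[SweepResult] = None,
    progress: bool = False,
) -> SweepResult:
    """Evaluate every grid point (optionally resuming a partial result).

    Replicate seeds depend only on (base_seed, point_index, replicate), so
    completed rows are reproduced bit-for-bit regardless of execution order
    and resuming never changes previously computed rows.
    """
    if points is None:
        points = enumerate_grid(spec)
    done: Dict[int, Dict] = {}
    if existing is not None:
        done = {
            int(r["point_index"]): dict(r)
            for _, r in existing.table.iterrows()
        }
    rows = []
    iterator: Iterable[ParameterPoint] = points
    if progress:
        try:
            from tqdm import tqdm  # optional nicety

            iterator = tqdm(points)
        except ImportError:  # pragma: no cover
            pass
    for point in iterator:
        if point.index in done:
            rows.append(done[point.index])
        else:
            rows.append(evaluate_point(point, spec))
    return SweepResult(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# landscape statistics
# ---------------------------------------------------------------------------

def _select_channel(table: pd.DataFrame, restrict_to_channel) -> pd.DataFrame:
    if restrict_to_channel is None:
        return table
    if restrict_to_channel == "none":
        return table[table["channel"] == "none"]
    if isinstance(restrict_to_channel, tuple):
        label = f"{restrict_to_channel[0]}->{restrict_to_channel[1]}"
    else:
        label = str(restrict_to_channel)
    return table[table["channel"] == label]


def feasible_fraction(
    result: SweepResult,
    a_min: float = 1.0,
    l_max: float = 0.1,
    restrict_to_channel=None,
) -> float:
    """Fraction of rows (within the selected long-range setting) achieving
    robust symmetry breaking: mean A > a_min and mean L < l_max."""
    table = _select_channel(result.table, restrict_to_channel)
    if len(table) == 0:
        raise ValueError("no rows selected")
    ok = (table["mean_A"] > a_min) & (table["mean_L"] < l_max)
    return float(ok.mean())


def top_fraction_stats(result: SweepResult, fraction: float = 0.01) -> Dict:
    """Statistics of the top-A fraction of the landscape.

    Rows are ranked by mean A descending (ties keep enumeration order); the
    selection share with an active attractive o->o channel and the mean +/-
    SD of each adhesion parameter are reported.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    table = result.table
    order = np.lexsort((table["point_index"].to_numpy(),
                        -table["mean_A"].to_numpy()))
    k = int(np.ceil(fraction * len(table)))
    top = table.iloc[order[:k]]
    oo_positive = (top["channel"] == "o->o") & (top["beta"] > 0)
    stats: Dict = {
        "n_selected": k,
        "share_oo_attraction": float(oo_positive.mean()),
        "min_A": float(top["mean_A"].min()),
        "max_A": float(top["mean_A"].max()),
    }
    for col in ("alpha_ii", "alpha_oo", "alpha_io"):
        stats[f"{col}_mean"] = float(top[col].mean())
        stats[f"{col}_sd"] = float(top[col].std(ddof=0))
    return stats
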