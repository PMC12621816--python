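"""Configuration, snapshot and manifest I/O.

One flat config schema (YAML or JSON) drives both the CLI and the library;
defaults reproduce the reference simulation conditions (1500 cells, 25%
outer, dt = 0.2, T = 150, positional noise 0.02, 5 replicates).  Unknown
keys are rejected by name, so typos fail loudly.  Every run writes a
manifest JSON recording the full config, every seed consumed, the tool
version and wall-clock time, from which the run can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .grn import Gate, GRNSpec, ReadoutRule, RegulatoryEdge, default_network
from .mechanics import IntegratorParams, LongRangeParams, ShortRangeParams
from .population import CellPopulation

__all__ = [
    "RunConfig",
    "PopulationConfig",
    "MechanicsConfig",
    "OutputConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "grn_spec_to_dict",
    "grn_spec_from_dict",
    "write_snapshot",
    "read_snapshot",
    "write_manifest",
]

SCHEMA_VERSION = 1


@dataclass
class PopulationConfig:
    n_cells: int = 1500
    outer_fraction: float = 0.25
    cell_radius: float = 1.0
    packing_fraction: float = 0.5
    seed: int = 0


@dataclass
class MechanicsConfig:
    alpha_ii: float = 0.75
    alpha_oo: float = 0.75
    alpha_io: float = 0.75
    beta_ii: float = 0.0
    beta_oo: float = 0.0
    beta_io: float = 0.0
    beta_oi: float = 0.0
    k_s: float = 1.0
    cutoff_factor: float = 1.0
    p: float = 2.0
    dt: float = 0.2
    t_total: float = 150.0
    gamma: float = 1.0
    noise_sigma: float = 0.02
    noise_mean: float = 0.0

    def short_params(self) -> ShortRangeParams:
        return ShortRangeParams.from_triple(
            self.alpha_ii, self.alpha_oo, self.alpha_io,
            k_s=self.k_s, cutoff_factor=self.cutoff_factor,
        )

    def long_params(self) -> LongRangeParams:
        return LongRangeParams(
            beta={
                ("i", "i"): self.beta_ii,
                ("o", "o"): self.beta_oo,
                ("i", "o"): self.beta_io,
                ("o", "i"): self.beta_oi,
            },
            p=self.p,
        )

    def integrator_params(self, seed: int) -> IntegratorParams:
        return IntegratorParams(
            dt=self.dt,
            t_total=self.t_total,
            gamma=self.gamma,
            noise_sigma=self.noise_sigma,
            noise_mean=self.noise_mean,
            seed=seed,
        )


@dataclass
class OutputConfig:
    directory: str = "."
    record_every: int = 0
    format: str = "csv"  # csv or ply


@dataclass
class RunConfig:
    mode: str = "two_type"  # "two_type" or "grn"
    population: PopulationConfig = field(default_factory=PopulationConfig)
    mechanics: MechanicsConfig = field(default_factory=MechanicsConfig)
    grn: Optional[dict] = None  # GRNSpec document; None = default network
    outputs: OutputConfig = field(default_factory=OutputConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("two_type", "grn"):
            raise ValueError("mode must be 'two_type' or 'grn'")

    def grn_spec(self) -> GRNSpec:
        if self.grn is None:
            return default_network()
        return grn_spec_from_dict(self.grn)


def _build_block(cls, data: dict, prefix: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(data) - known
    if unknown:
        key = sorted(unknown)[0]
        raise ValueError(f"unknown config key: {prefix}.{key}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig; errors name the bad key."""
    data = dict(data or {})
    known = {"mode", "population", "mechanics", "grn", "outputs"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]}")
    cfg = RunConfig(
        mode=data.get("mode", "two_type"),
        population=_build_block(
            PopulationConfig, data.get("population", {}) or {}, "population"
        ),
        mechanics=_build_block(
            MechanicsConfig, data.get("mechanics", {}) or {}, "mechanics"
        ),
        grn=data.get("grn"),
        outputs=_build_block(
            OutputConfig, data.get("outputs", {}) or {}, "outputs"
        ),
    )
    m = cfg.mechanics
    for name in ("alpha_ii", "alpha_oo", "alpha_io"):
        value = getattr(m, name)
        if not 0.0 < value < 1.0:
            raise ValueError(
                f"mechanics.{name} = {value} outside the valid range (0, 1)"
            )
    if cfg.population.n_cells < 2:
        raise ValueError("population.n_cells must be at least 2")
    if not 0.0 <= cfg.population.outer_fraction <= 1.0:
        raise ValueError("population.outer_fraction outside [0, 1]")
    if cfg.mode == "two_type" and cfg.grn is not None:
        raise ValueError("grn block given but mode is 'two_type'")
    # constructing the params objects runs their own validation
    m.short_params()
    m.long_params()
    m.integrator_params(seed=cfg.population.seed)
    if cfg.mode == "grn":
        cfg.grn_spec()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    out = {
        "mode": cfg.mode,
        "population": dataclasses.asdict(cfg.population),
        "mechanics": dataclasses.asdict(cfg.mechanics),
        "outputs": dataclasses.asdict(cfg.outputs),
    }
    if cfg.grn is not None:
        out["grn"] = cfg.grn
    return out


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config file into a validated RunConfig."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# GRNSpec documents
# ---------------------------------------------------------------------------

def grn_spec_to_dict(spec: GRNSpec) -> dict:
    edges = []
    for e in spec.edges:
        doc = {
            "source": e.source,
            "target": e.target,
            "weight": e.weight,
            "type": "inter" if e.intercellular else "intra",
        }
        if e.intercellular:
            doc["lambda"] = e.lam
        if e.gate is not None:
            doc["gate"] = {
                "gene": e.gate.gene, "op": e.gate.op, "theta": e.gate.theta
            }
        edges.append(doc)
    r = spec.readout
    return {
        "n_genes": spec.n_genes,
        "edges": edges,
        "amplitude": spec.amplitude.tolist(),
        "hill_h": spec.hill_h.tolist(),
        "hill_k": spec.hill_k.tolist(),
        "leak": spec.leak.tolist(),
        "degradation": spec.degradation.tolist(),
        "gene_noise_sigma": spec.gene_noise_sigma,
        "readout": {
            "timer_gene": r.timer_gene,
            "timer_threshold": r.timer_threshold,
            "class_gene": r.class_gene,
            "class_threshold": r.class_threshold,
            "alpha_hom": r.alpha_hom,
            "alpha_ii": r.alpha_table.lookup("i", "i"),
            "alpha_oo": r.alpha_table.lookup("o", "o"),
            "alpha_io": r.alpha_table.lookup("i", "o"),
            "beta": {
                f"{s}->{t}": v for (s, t), v in r.beta_table.beta.items() if v
            },
            "p": r.beta_table.p,
        },
    }


def grn_spec_from_dict(data: dict) -> GRNSpec:
    edges = []
    for doc in data["edges"]:
        gate = None
        if doc.get("gate"):
            g = doc["gate"]
            gate = Gate(gene=g["gene"], op=g["op"], theta=g["theta"])
        lam = doc.get("lambda") if doc.get("type", "intra") == "inter" else None
        edges.append(
            RegulatoryEdge(
                source=doc["source"],
                target=doc["target"],
                weight=doc["weight"],
                lam=lam,
                gate=gate,
            )
        )
    rdoc = data.get("readout", {})
    beta = {}
    for key, value in rdoc.get("beta", {}).items():
        sig, resp = key.split("->")
        beta[(sig, resp)] = value
    readout = ReadoutRule(
        timer_gene=rdoc.get("timer_gene", 0),
        timer_threshold=rdoc.get("timer_threshold", 0.5),
        class_gene=rdoc.get("class_gene", 1),
        class_threshold=rdoc.get("class_threshold", 0.5),
        alpha_hom=rdoc.get("alpha_hom", 0.80),
        alpha_table=ShortRangeParams.from_triple(
            rdoc.get("alpha_ii", 0.72),
            rdoc.get("alpha_oo", 0.79),
            rdoc.get("alpha_io", 0.88),
        ),
        beta_table=LongRangeParams(beta=beta, p=rdoc.get("p", 2.0)),
    )
    return GRNSpec(
        n_genes=data["n_genes"],
        edges=edges,
        amplitude=np.asarray(data["amplitude"], float),
        hill_h=np.asarray(data["hill_h"], float),
        hill_k=np.asarray(data["hill_k"], float),
        leak=np.asarray(data["leak"], float),
        degradation=np.asarray(data["degradation"], float),
        gene_noise_sigma=data.get("gene_noise_sigma", 0.01),
        readout=readout,
    )


# ---------------------------------------------------------------------------
# snapshots and manifests
# ---------------------------------------------------------------------------

def write_snapshot(population: CellPopulation, path, format: str = "csv") -> None:
    """Write one population snapshot as CSV (lossless round-trip) or as an
    ASCII PLY point cloud with per-vertex type code and gene scalars."""
    path = Path(path)
    if format == "csv":
        population.to_csv(path)
    elif format == "ply":
        _write_ply(population, path)
    else:
        raise ValueError(f"unsupported snapshot format: {format}")


def read_snapshot(path) -> CellPopulation:
    return CellPopulation.from_csv(path)


def _write_ply(population: CellPopulation, path: Path) -> None:
    n = population.n_cells
    gene_props = [
        f"property float gene_{g + 1}" for g in range(population.n_genes)
    ]
    header = "\n".join(
        [
            "ply",
            "format ascii 1.0",
            f"comment gastrosim {__version__} cell snapshot",
            f"element vertex {n}",
            "property float x",
            "property float y",
            "property float z",
            "property float radius",
            "property uchar type_code",
            *gene_props,
            "end_header",
        ]
    )
    codes = population.type_codes()
    lines = [header]
    for m in range(n):
        x, y, z = population.positions[m]
        parts = [f"{x:.8g}", f"{y:.8g}", f"{z:.8g}",
                 f"{population.radii[m]:.8g}", str(int(codes[m]))]
        if population.genes is not None:
            parts.extend(f"{v:.8g}" for v in population.genes[m])
        lines.append(" ".join(parts))
    path.write_text("\n".join(lines) + "\n")


def write_manifest(
    path,
    config: dict,
    seeds: List[int],
    wall_clock_s: float,
    extra: Optional[dict] = None,
) -> None:
    """Run manifest: everything needed to regenerate the run."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool": "gastrosim",
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "wall_clock_s": wall_clock_s,
        "seeds": [int(s) for s in seeds],
        "config": config,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, default=float))
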