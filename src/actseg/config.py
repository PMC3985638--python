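"""Run configuration: one canonical, schema-validated description of a run.

Every simulation is fully specified by a RunConfig: genome (karyotype +
gene track + activity assignment), force field, confinement geometry, loop
preset, schedule and a single top-level seed.  Unknown keys are rejected,
every default is materialized into the echoed config, and all randomness
fans out from the top-level seed into named sub-streams (genome, loops,
init, dynamics) so a (config, seed) pair reproduces a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import genome_model as gm
from .dynamics import DEFAULT_DT, Schedule
from .loops import LoopSet, generate_loops, loop_presets
from .potentials import ForceField, Geometry

__all__ = ["RunConfig", "load_config", "save_config", "build_system", "ConfigError"]


class ConfigError(ValueError):
    """Configuration schema violation; message lists every offending key."""


@dataclass
class GenomeConfig:
    karyotype: str = "default"  # "default" or a CSV path (name,length_mb,copies)
    track: str = "fixture"  # "fixture", "synthesize", or a BED-like path
    default_mean: float = gm.DEFAULT_UNCONSTRAINED_MEAN
    shape_sigma: float = 1.0
    constraints: dict = field(default_factory=lambda: dict(gm.DEFAULT_DENSITY_CONSTRAINTS))
    mode: str = "inhomogeneous"  # activity mode
    active_fraction: float = gm.DEFAULT_ACTIVE_FRACTION
    T_a: float = gm.DEFAULT_T_A


@dataclass
class GeometryConfig:
    kind: str = "sphere"
    R0: float = 10.0
    aspect: float = 1.0


@dataclass
class LoopConfig:
    preset: str | None = None  # "low" | "mid" | "high"
    p_loop: float | None = None  # explicit probability overrides the preset


@dataclass
class NEConfig:
    enabled: bool = False


@dataclass
class ScheduleConfig:
    n_steps: int = 0
    dt: float = DEFAULT_DT
    n_burnin: int | None = None  # default: 10% of n_steps
    sample_every: int = 1
    max_drift: float = 1.0  # instability-guard threshold (monomer diameters)
    n_relax: int = 0  # steepest-descent iterations before dynamics


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    forcefield: ForceField = field(default_factory=ForceField)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    loops: LoopConfig = field(default_factory=LoopConfig)
    ne: NEConfig = field(default_factory=NEConfig)
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    out: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolved_schedule(self, seed: int | None = None) -> Schedule:
        sc = self.schedule
        burnin = sc.n_burnin if sc.n_burnin is not None else sc.n_steps // 10
        return Schedule(
            n_steps=sc.n_steps,
            dt=sc.dt,
            n_burnin=burnin,
            sample_every=sc.sample_every,
            seed=seed,
            max_drift=sc.max_drift,
            n_relax=sc.n_relax,
        )


_SECTION_TYPES = {
    "genome": GenomeConfig,
    "forcefield": ForceField,
    "geometry": GeometryConfig,
    "loops": LoopConfig,
    "ne": NEConfig,
    "schedule": ScheduleConfig,
}


def _from_mapping(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    bad: list[str] = []
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in top_fields:
            bad.append(key)
    kwargs: dict = {}
    for section, cls in _SECTION_TYPES.items():
        sub = data.get(section, {})
        if sub is None:
            sub = {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = [f"{section}.{k}" for k in sub if k not in names]
        bad.extend(unknown)
        if not unknown:
            kwargs[section] = cls(**{k: v for k, v in sub.items() if k in names})
    if bad:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "out" in data:
        kwargs["out"] = data["out"]
    cfg = RunConfig(**kwargs)
    if cfg.schedule.n_steps <= 0:
        raise ConfigError("schedule.n_steps must be a positive integer")
    cfg.resolved_schedule()  # validates dt / burnin / cadence
    if cfg.loops.preset is not None and cfg.loops.preset not in loop_presets():
        raise ConfigError(f"loops.preset must be one of {sorted(loop_presets())}")
    if cfg.genome.mode not in ("inhomogeneous", "homogeneous", "equilibrium"):
        raise ConfigError("genome.mode must be inhomogeneous|homogeneous|equilibrium")
    if cfg.geometry.kind not in ("sphere", "ellipsoid"):
        raise ConfigError("geometry.kind must be sphere|ellipsoid")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_mapping(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    """Echo the fully-defaulted config (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def derive_seeds(seed: int) -> dict[str, int]:
    """Fan a top-level seed out into named, independent sub-stream seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("genome", "loops", "init", "dynamics")
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
        for name, child in zip(names, children)
    }


def _load_karyotype(spec: str) -> list[gm.ChromosomeSpec]:
    if spec == "default":
        return gm.default_karyotype()
    import pandas as pd

    df = pd.read_csv(spec)
    return [
        gm.ChromosomeSpec(str(r["name"]), int(r["length_mb"]), int(r.get("copies", 2)))
        for _, r in df.iterrows()
    ]


def build_system(config: RunConfig):
    """Materialize (table, loops, geometry, forcefield, schedule, seeds)."""
    seeds = derive_seeds(config.seed)
    karyotype = _load_karyotype(config.genome.karyotype)

    g = config.genome
    if g.track == "fixture":
        track = gm.default_gene_track()
    elif g.track == "synthesize":
        track = gm.synthesize_gene_track(
            karyotype,
            density_constraints=g.constraints,
            default_mean=g.default_mean,
            shape_sigma=g.shape_sigma,
            seed=seeds["genome"],
        )
    else:
        track = gm.load_gene_track(g.track)

    table = gm.build_monomer_table(karyotype, track)
    table = gm.assign_activity(table, g.mode, g.active_fraction, g.T_a)

    ff = config.forcefield
    if config.geometry.kind == "sphere":
        geometry = Geometry.sphere(config.geometry.R0)
    else:
        geometry = Geometry.ellipsoid(config.geometry.aspect, config.geometry.R0)

    p_loop = config.loops.p_loop
    if p_loop is None and config.loops.preset is not None:
        p_loop = loop_presets()[config.loops.preset]
    loopset = (
        generate_loops(table, p_loop, ff, seed=seeds["loops"])
        if p_loop
        else LoopSet.empty()
    )

    schedule = config.resolved_schedule(seed=seeds["dynamics"])
    return table, loopset, geometry, ff, schedule, seeds
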