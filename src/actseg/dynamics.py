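"""Overdamped Langevin (Euler–Maruyama) dynamics with per-monomer temperatures.

The model's equation of motion for monomer i is the explicit Euler
discretization of over-damped motion:

    r_i(t + dt) = r_i(t) + (dt / zeta) F_i + sqrt(2 k_B T_i dt / zeta) eta_i

where ``F_i`` collects all deterministic forces (bonds, loops, Gaussian
core, wall, optional NE attraction) and ``eta_i`` are independent standard
normal 3-vectors, uncorrelated across monomers and components.  ``T_i`` is
the per-monomer effective temperature: T_eq for inactive monomers and T_a
for active ones.  With inhomogeneous T_i the steady state is NOT an
equilibrium state — that non-equilibrium drive is what segregates gene-dense
from gene-poor chromatin.

There is no inertia, no hydrodynamic coupling and no thermostat: the model
is defined by its discrete update rule.  A guard aborts if the deterministic
drift of any monomer exceeds one monomer diameter in a single step, the
signature of a force-field/time-step mismatch (the noise term is unbounded
by construction and is not guarded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .genome_model import MonomerTable
from .loops import LoopSet
from .potentials import ForceField, Geometry, surface_distance, total_energies

__all__ = [
    "Schedule",
    "SimulationState",
    "RunResult",
    "noise_scale",
    "initialize_random",
    "euler_step",
    "simulate",
    "run",
    "ne_switch_protocol",
    "DEFAULT_DT",
]

#: Model time step in tau units (printed convention of the source model).
DEFAULT_DT = 0.01

#: Drag coefficient; constant for all monomers in reduced units.
ZETA = 1.0

# cap on doubles in one pre-generated noise block (memory bound ~190 MB)
_MAX_NOISE_DOUBLES = 24_000_000


@dataclass(frozen=True)
class Schedule:
    """Integration schedule: step size, length, burn-in and sampling cadence.

    ``max_drift`` is the instability-guard threshold in units of the monomer
    diameter: the run aborts if the deterministic drift of an interior
    monomer exceeds it in one step.  The default (1 diameter) suits loop-free
    runs; runs with permanent loop springs at high activity need ~10, because
    a critically-damped loop spring (2 k_loop dt / zeta <= 1) legitimately
    produces large single-step drifts that are self-limiting, not unstable.
    ``n_relax`` steepest-descent iterations remove initial overlaps and
    loop-spring stretch before dynamics start.
    """

    n_steps: int
    dt: float = DEFAULT_DT
    n_burnin: int = 0
    sample_every: int = 1
    seed: int | None = None
    max_drift: float = 1.0
    n_relax: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_burnin >= self.n_steps:
            raise ValueError("n_burnin must be smaller than n_steps")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.max_drift <= 0:
            raise ValueError("max_drift must be positive")
        if self.n_relax < 0:
            raise ValueError("n_relax must be non-negative")

    @property
    def n_frames(self) -> int:
        return (self.n_steps - self.n_burnin) // self.sample_every


@dataclass
class SimulationState:
    """Monomer coordinates + elapsed time + reproducible RNG state."""

    positions: np.ndarray  # (N, 3) float64
    time: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def copy(self) -> "SimulationState":
        return SimulationState(
            positions=self.positions.copy(), time=self.time, rng=_clone_rng(self.rng)
        )


def _clone_rng(rng: np.random.Generator) -> np.random.Generator:
    clone = np.random.default_rng(0)
    clone.bit_generator.state = rng.bit_generator.state
    return clone


@dataclass
class RunResult:
    """Sampled trajectory plus provenance for a single run."""

    frames: list[np.ndarray]
    times: list[float]
    table: MonomerTable
    loops: LoopSet | None
    geometry: Geometry
    forcefield: ForceField
    report: dict


def noise_scale(T_i: float, zeta: float = ZETA, dt: float = DEFAULT_DT) -> float:
    """Per-component displacement std-dev of the noise term in one step.

    sqrt(2 k_B T_i dt / zeta), with k_B = 1 in reduced units.  Scales as
    sqrt(T), so the active/passive displacement ratio is sqrt(T_a / T_eq).
    """
    if T_i < 0:
        raise ValueError("T_i must be non-negative")
    if zeta <= 0 or dt <= 0:
        raise ValueError("zeta and dt must be positive")
    return float(np.sqrt(2.0 * T_i * dt / zeta))


def initialize_random(
    geometry: Geometry,
    table: MonomerTable,
    seed: int | None = None,
    r0: float = 1.0,
) -> SimulationState:
    """Lay each chain down as a compact random walk inside the geometry.

    Chain starts are uniform over the confinement volume; successive
    monomers sit at exactly ``r0`` from their predecessor, with step
    directions re-drawn until the candidate stays inside (falling back to a
    step toward the center, which always re-enters for our convex shapes).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    pos = np.empty((n, 3))
    a, b, c = geometry.axes
    half = np.array([a, b, c])
    for sl in table.chain_slices():
        # uniform start by rejection from the bounding box
        while True:
            start = rng.uniform(-half, half)
            if surface_distance(start, geometry) < 0:
                break
        pos[sl.start] = start
        for i in range(sl.start + 1, sl.stop):
            prev = pos[i - 1]
            placed = False
            for _ in range(500):
                u = rng.standard_normal(3)
                u /= np.linalg.norm(u)
                cand = prev + r0 * u
                if surface_distance(cand, geometry) < 0:
                    pos[i] = cand
                    placed = True
                    break
            if not placed:
                # step inward along -prev; for a convex body this re-enters
                u = -prev / np.linalg.norm(prev)
                pos[i] = prev + r0 * u
    return SimulationState(positions=pos, time=0.0, rng=rng)


class IntegrationError(RuntimeError):
    """Deterministic drift exceeded one monomer diameter in a single step."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(
            f"integration aborted at step {step} (t = {time:.4g}): deterministic "
            "drift of a monomer exceeded sigma in one step — the time step is "
            "too large for these force-field parameters"
        )


def _advance(
    state: SimulationState,
    table: MonomerTable,
    loops: LoopSet | None,
    geometry: Geometry,
    ff: ForceField,
    dt: float,
    n_steps: int,
    ne_on: bool,
    zeta: float = ZETA,
    max_drift: float = 1.0,
) -> None:
    """Advance ``state`` in place by ``n_steps`` Euler–Maruyama steps."""
    from .potentials import _bond_arrays, _check_finite

    n = len(table)
    _check_finite(state.positions)
    bi, bj, bk = _bond_arrays(table, loops, ff)
    a, b, c = geometry.axes
    amp = np.sqrt(2.0 * table.T_eff * dt / zeta)
    active = np.ascontiguousarray(table.is_active)
    pos = np.ascontiguousarray(state.positions)
    exp_table = _kernels.make_exp_table(ff.sigma, ff.r_cut)

    max_chunk = max(1, _MAX_NOISE_DOUBLES // (3 * n))
    done = 0
    while done < n_steps:
        k = min(max_chunk, n_steps - done)
        noise = state.rng.standard_normal((k, n, 3))
        status = _kernels.integrate_chunk(
            pos, noise, amp, dt / zeta, ff.sigma, max_drift * ff.sigma,
            bi, bj, bk, ff.r0, ff.V0, ff.r_cut,
            geometry.kind_code, geometry.R0, a, b, c, ff.k_wall,
            ne_on, ff.eps_ne, ff.lambda_ne, active, exp_table,
        )
        if status >= 0:
            raise IntegrationError(done + status, state.time + (done + status) * dt)
        done += k
    state.positions = pos
    state.time += n_steps * dt


def euler_step(
    state: SimulationState,
    table: MonomerTable,
    loops: LoopSet | None,
    geometry: Geometry,
    ff: ForceField,
    dt: float = DEFAULT_DT,
    ne_on: bool = False,
    max_drift: float = 1.0,
) -> SimulationState:
    """One Euler–Maruyama step, in place; returns the advanced state."""
    _advance(state, table, loops, geometry, ff, dt, 1, ne_on, max_drift=max_drift)
    return state


def relax(
    state: SimulationState,
    table: MonomerTable,
    loops: LoopSet | None,
    geometry: Geometry,
    ff: ForceField,
    n_iter: int = 200,
    max_step: float = 0.2,
    ne_on: bool = False,
) -> SimulationState:
    """Steepest-descent pre-relaxation with a trust-radius displacement cap.

    Removes initial monomer overlaps and, in particular, the large initial
    stretch of freshly drawn loop springs (random anchors can start many
    diameters apart) before stochastic dynamics begin.  Each iteration moves
    every monomer along its force, with the displacement norm capped at
    ``max_step`` monomer diameters.  Deterministic; does not touch the RNG.
    """
    from .potentials import total_forces

    for _ in range(n_iter):
        f = total_forces(state.positions, table, loops, geometry, ff, ne_on=ne_on)
        disp = f * (DEFAULT_DT / ZETA)
        norm = np.linalg.norm(disp, axis=1)
        big = norm > max_step * ff.sigma
        if big.any():
            disp[big] *= (max_step * ff.sigma / norm[big])[:, None]
        state.positions = state.positions + disp
    return state


def simulate(
    table: MonomerTable,
    loops: LoopSet | None,
    geometry: Geometry,
    ff: ForceField,
    schedule: Schedule,
    ne_on: bool = False,
    state: SimulationState | None = None,
    init_seed: int | None = None,
    collect_energies: bool = True,
) -> RunResult:
    """Run one trajectory: burn-in, then sample frames at a fixed cadence.

    Frames are stored every ``schedule.sample_every`` steps after
    ``schedule.n_burnin`` discarded steps.  Deterministic given the seeds.
    """
    if state is None:
        state = initialize_random(geometry, table, seed=init_seed, r0=ff.r0)
        state.rng = np.random.default_rng(schedule.seed)
    frames: list[np.ndarray] = []
    times: list[float] = []
    energy_trace: list[dict[str, float]] = []
    containment: list[float] = []
    md = schedule.max_drift

    if schedule.n_relax:
        relax(state, table, loops, geometry, ff, n_iter=schedule.n_relax, ne_on=ne_on)
    if schedule.n_burnin:
        _advance(state, table, loops, geometry, ff, schedule.dt, schedule.n_burnin,
                 ne_on, max_drift=md)
    remaining = schedule.n_steps - schedule.n_burnin
    n_blocks = remaining // schedule.sample_every
    for _ in range(n_blocks):
        _advance(state, table, loops, geometry, ff, schedule.dt, schedule.sample_every,
                 ne_on, max_drift=md)
        frames.append(state.positions.copy())
        times.append(state.time)
        r = np.array([surface_distance(p, geometry) for p in state.positions])
        containment.append(float(np.mean(r < 0)))
        if collect_energies:
            energy_trace.append(
                total_energies(state.positions, table, loops, geometry, ff, ne_on)
            )
    tail = remaining - n_blocks * schedule.sample_every
    if tail:
        _advance(state, table, loops, geometry, ff, schedule.dt, tail, ne_on, max_drift=md)

    report = {
        "n_steps": schedule.n_steps,
        "n_burnin": schedule.n_burnin,
        "sample_every": schedule.sample_every,
        "dt": schedule.dt,
        "seed": schedule.seed,
        "init_seed": init_seed,
        "n_frames": len(frames),
        "ne_on": ne_on,
        "containment_fraction": containment,
        "energy_trace": energy_trace,
        "final_time": state.time,
    }
    return RunResult(
        frames=frames,
        times=times,
        table=table,
        loops=loops,
        geometry=geometry,
        forcefield=ff,
        report=report,
    )


def run(config) -> RunResult:
    """Build the system described by a :class:`~actseg.config.RunConfig` and run it.

    All randomness fans out from ``config.seed`` into named sub-streams
    (genome synthesis, loop drawing, initialization, dynamics), so identical
    (config, seed) pairs give bitwise-identical trajectories.
    """
    from .config import build_system

    table, loopset, geometry, ff, schedule, seeds = build_system(config)
    state = initialize_random(geometry, table, seed=seeds["init"], r0=ff.r0)
    state.rng = np.random.default_rng(seeds["dynamics"])
    result = simulate(
        table, loopset, geometry, ff, schedule, ne_on=config.ne.enabled, state=state
    )
    result.report["seeds"] = seeds
    result.report["config"] = config.to_dict()
    return result


def ne_switch_protocol(
    table: MonomerTable,
    loops: LoopSet | None,
    geometry: Geometry,
    ff: ForceField,
    ensemble: Sequence[SimulationState],
    snapshot_steps: Sequence[int],
    dt: float = DEFAULT_DT,
    n_init: int = 1,
    n_bins: int = 25,
    chromosomes: Sequence[str] | None = None,
    ne_on: bool = True,
    max_drift: float = 1.0,
) -> dict[int, dict]:
    """Track S(R) relaxation after switching the NE attraction on at t = 0.

    ``ensemble`` must hold at least ``n_init`` independent steady states of
    the *passive*-confinement system; the selective NE attraction is enabled
    at t = 0 and the radial distribution (per requested chromosome, or
    pooled) is recomputed at each step count in ``snapshot_steps``, averaged
    over the ensemble.  With ``ne_on=False`` this is a null perturbation and
    the series is time-invariant up to noise.
    """
    from .analysis import activity_profile, radial_S

    if len(ensemble) < n_init:
        raise ValueError(
            f"ensemble of {len(ensemble)} states is smaller than n_init = {n_init}"
        )
    states = [s.copy() for s in ensemble[:n_init]]
    snapshot_steps = sorted(int(s) for s in snapshot_steps)
    if snapshot_steps and snapshot_steps[0] < 0:
        raise ValueError("snapshot steps must be non-negative")

    def _snapshot(step: int) -> dict:
        frames = [s.positions for s in states]
        out: dict = {"step": step, "time": step * dt}
        sel = chromosomes if chromosomes is not None else [None]
        out["S"] = {
            (chrom or "all"): radial_S(frames, table, chromosome=chrom,
                                       geometry=geometry, n_bins=n_bins)
            for chrom in sel
        }
        out["activity"] = activity_profile(frames, table, geometry=geometry, n_bins=n_bins)
        return out

    results: dict[int, dict] = {}
    current = 0
    if snapshot_steps and snapshot_steps[0] == 0:
        results[0] = _snapshot(0)
        snapshot_steps = snapshot_steps[1:]
    for target in snapshot_steps:
        for s in states:
            _advance(s, table, loops, geometry, ff, dt, target - current, ne_on,
                     max_drift=max_drift)
        current = target
        results[target] = _snapshot(target)
    return results
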