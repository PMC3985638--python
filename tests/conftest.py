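"""Shared fixtures.

The scaled test system is 8 chains x 100 monomers (one diploid-genome-like
melt at the same volume fraction as the full 6098-monomer nucleus, i.e.
sphere radius R0 = 10 * (800/6098)^(1/3) ~ 5.08 sigma), with 10% of monomers
active at T_a = 20.  Chain c0 is synthesized gene-rich (62 genes/Mb, like
chromosome 19) and chain c1 gene-poor (18.6 genes/Mb, like chromosome 18) so
chain-level positioning can be checked; the rest sit in between.

The long stochastic runs used by the acceptance tests are session-scoped so
each is integrated exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from actseg import (
    ChromosomeSpec,
    ForceField,
    Geometry,
    Schedule,
    assign_activity,
    build_monomer_table,
    generate_loops,
    loop_presets,
    simulate,
    synthesize_gene_track,
)

FULL_N = 6098
SCALED_N = 800
SCALED_R0 = 10.0 * (SCALED_N / FULL_N) ** (1.0 / 3.0)
SCALED_SEEDS = (11, 12, 13, 14, 15)


@pytest.fixture(scope="session")
def ff() -> ForceField:
    return ForceField()


def make_scaled_table(mode: str = "inhomogeneous"):
    karyotype = [ChromosomeSpec(f"c{i}", 100, copies=1) for i in range(8)]
    track = synthesize_gene_track(
        karyotype,
        density_constraints={"c0": 62.0, "c1": 18.6},
        default_mean=25.0,
        seed=2024,
    )
    table = build_monomer_table(karyotype, track)
    return assign_activity(table, mode, active_fraction=0.10, T_a=20.0)


@pytest.fixture(scope="session")
def scaled_table():
    return make_scaled_table()


@pytest.fixture(scope="session")
def scaled_geometry() -> Geometry:
    return Geometry.sphere(SCALED_R0)


@pytest.fixture(scope="session")
def passive_runs(scaled_table, scaled_geometry, ff):
    """Five independent 2e5-step runs of the scaled active system (no NE)."""
    results = []
    for seed in SCALED_SEEDS:
        schedule = Schedule(
            n_steps=200_000, n_burnin=150_000, sample_every=10_000, seed=seed
        )
        results.append(
            simulate(
                scaled_table, None, scaled_geometry, ff, schedule,
                init_seed=seed + 100, collect_energies=False,
            )
        )
    return results


@pytest.fixture(scope="session")
def ne_runs(passive_runs, scaled_table, scaled_geometry, ff):
    """NE-attraction continuations of the passive steady states (switch-on)."""
    from actseg.dynamics import SimulationState

    results = []
    for seed, base in zip(SCALED_SEEDS, passive_runs):
        state = SimulationState(
            positions=base.frames[-1].copy(),
            time=0.0,
            rng=np.random.default_rng(seed + 500),
        )
        schedule = Schedule(
            n_steps=25_000, n_burnin=15_000, sample_every=5_000, seed=seed + 500
        )
        results.append(
            simulate(
                scaled_table, None, scaled_geometry, ff, schedule,
                ne_on=True, state=state, collect_energies=False,
            )
        )
    return results


@pytest.fixture(scope="session")
def equilibrium_run(scaled_geometry, ff):
    """Scaled system at thermal equilibrium (every monomer at T_eq)."""
    table = make_scaled_table("equilibrium")
    schedule = Schedule(n_steps=50_000, n_burnin=20_000, sample_every=3_000, seed=21)
    return simulate(
        table, None, scaled_geometry, ff, schedule,
        init_seed=121, collect_energies=False,
    )


@pytest.fixture(scope="session")
def loop_run(scaled_table, scaled_geometry, ff):
    """Scaled inhomogeneous-activity run with high-preset permanent loops."""
    loops = generate_loops(scaled_table, loop_presets()["high"], ff, seed=31)
    schedule = Schedule(
        n_steps=50_000, n_burnin=20_000, sample_every=3_000, seed=32,
        max_drift=10.0, n_relax=300,
    )
    return simulate(
        scaled_table, loops, scaled_geometry, ff, schedule,
        init_seed=131, collect_energies=False,
    )
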