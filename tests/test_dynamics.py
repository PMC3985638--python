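import math

import numpy as np
import pytest

from actseg import (
    ChromosomeSpec,
    ForceField,
    Geometry,
    Schedule,
    assign_activity,
    build_monomer_table,
    euler_step,
    initialize_random,
    ne_switch_protocol,
    noise_scale,
    simulate,
    synthesize_gene_track,
)
from actseg.dynamics import IntegrationError, SimulationState, relax
from actseg.loops import generate_loops


def _chain_table(n_chains=4, length=20, mode="equilibrium", seed=0):
    kar = [ChromosomeSpec(f"c{i}", length, copies=1) for i in range(n_chains)]
    table = build_monomer_table(kar, synthesize_gene_track(kar, seed=seed))
    return assign_activity(table, mode, active_fraction=0.1, T_a=20.0)


class TestNoiseScale:
    def test_zero_temperature_is_noiseless(self):
        assert noise_scale(0.0, 1.0, 0.01) == 0.0

    def test_closed_form(self):
        assert noise_scale(1.0, 1.0, 0.01) == pytest.approx(math.sqrt(0.02))
        assert noise_scale(1.0, 1.0, 0.01) == pytest.approx(0.141421, abs=1e-6)

    def test_active_passive_ratio_is_sqrt_t(self):
        ratio = noise_scale(20.0) / noise_scale(1.0)
        assert ratio == pytest.approx(math.sqrt(20.0), abs=1e-12)
        assert ratio == pytest.approx(4.4721, abs=1e-4)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            noise_scale(-1.0)
        with pytest.raises(ValueError):
            noise_scale(1.0, zeta=0.0)


class TestInitialization:
    @pytest.mark.parametrize("geo", [Geometry.sphere(6.0), Geometry.ellipsoid(0.3, 6.0)])
    def test_all_monomers_start_inside(self, geo):
        from actseg.potentials import surface_distance

        table = _chain_table()
        state = initialize_random(geo, table, seed=1)
        assert all(surface_distance(p, geo) < 0 for p in state.positions)

    def test_bond_lengths_exact_at_start(self):
        table = _chain_table()
        state = initialize_random(Geometry.sphere(6.0), table, seed=2)
        i, j = table.backbone_bonds()
        d = np.linalg.norm(state.positions[i] - state.positions[j], axis=1)
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_different_seeds_differ(self):
        table = _chain_table()
        geo = Geometry.sphere(6.0)
        a = initialize_random(geo, table, seed=1).positions
        b = initialize_random(geo, table, seed=2).positions
        assert not np.array_equal(a, b)

    def test_same_seed_identical(self):
        table = _chain_table()
        geo = Geometry.sphere(6.0)
        a = initialize_random(geo, table, seed=3).positions
        b = initialize_random(geo, table, seed=3).positions
        assert np.array_equal(a, b)


class TestEulerStep:
    def test_noiseless_forceless_step_leaves_positions(self):
        kar = [ChromosomeSpec("c", 1, copies=1)]
        table = build_monomer_table(kar, synthesize_gene_track(kar, seed=0))
        table.T_eff[:] = 0.0  # deterministic limit
        geo = Geometry.sphere(10.0)
        state = SimulationState(np.zeros((1, 3)), 0.0, np.random.default_rng(0))
        euler_step(state, table, None, geo, ForceField())
        assert np.array_equal(state.positions, np.zeros((1, 3)))
        assert state.time == pytest.approx(0.01)

    def test_deterministic_drift_is_dt_times_force(self):
        # two bonded monomers at separation 2 r0, T = 0: one-step displacement
        # equals dt * (bond + pair force) exactly
        from actseg.potentials import bond_force, gaussian_core_force

        kar = [ChromosomeSpec("c", 2, copies=1)]
        table = build_monomer_table(kar, synthesize_gene_track(kar, seed=0))
        table.T_eff[:] = 0.0
        ff = ForceField()
        geo = Geometry.sphere(100.0)
        pos = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        state = SimulationState(pos.copy(), 0.0, np.random.default_rng(0))
        euler_step(state, table, None, geo, ff, dt=0.01)
        f = bond_force(2.0, ff) + gaussian_core_force(2.0, ff)
        expected_dx = 0.01 * (-f)  # monomer 0 is pulled toward +x by the bond
        assert state.positions[0, 0] == pytest.approx(expected_dx, rel=1e-6)
        assert state.positions[1, 0] == pytest.approx(2.0 - expected_dx, rel=1e-6)

    def test_unstable_timestep_aborts_with_step_index(self):
        kar = [ChromosomeSpec("c", 2, copies=1)]
        table = build_monomer_table(kar, synthesize_gene_track(kar, seed=0))
        ff = ForceField(k_bond=5000.0)  # k dt >> 2: divergent
        geo = Geometry.sphere(10.0)
        pos = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        state = SimulationState(pos, 0.0, np.random.default_rng(0))
        with pytest.raises(IntegrationError) as err:
            for _ in range(10):
                euler_step(state, table, None, geo, ff)
        assert err.value.step >= 0


class TestSimulate:
    def test_frame_arithmetic(self):
        table = _chain_table(2, 10)
        geo = Geometry.sphere(5.0)
        sch = Schedule(n_steps=1000, n_burnin=200, sample_every=100, seed=0)
        assert sch.n_frames == 8
        res = simulate(table, None, geo, ForceField(), sch, init_seed=1)
        assert len(res.frames) == 8
        assert res.times[-1] == pytest.approx(1000 * 0.01)

    def test_identical_seeds_give_bitwise_identical_trajectories(self):
        table = _chain_table(2, 10)
        geo = Geometry.sphere(5.0)
        sch = Schedule(n_steps=400, n_burnin=100, sample_every=100, seed=7)
        r1 = simulate(table, None, geo, ForceField(), sch, init_seed=3)
        r2 = simulate(table, None, geo, ForceField(), sch, init_seed=3)
        for f1, f2 in zip(r1.frames, r2.frames):
            assert np.array_equal(f1, f2)

    def test_equilibrium_wall_penetration_is_shallow(self):
        from actseg.potentials import surface_distance

        table = _chain_table(4, 25, mode="equilibrium")
        geo = Geometry.sphere(3.55)  # same volume fraction as the full system
        sch = Schedule(n_steps=4000, n_burnin=2000, sample_every=500, seed=5)
        res = simulate(table, None, geo, ForceField(), sch, init_seed=6)
        depths = []
        for f in res.frames:
            s = np.array([surface_distance(p, geo) for p in f])
            depths.extend(s[s > 0])
        assert np.mean(depths) < 0.5 if depths else True
        # small system has a large surface/volume ratio; most monomers inside
        assert np.mean(res.report["containment_fraction"]) > 0.7

    def test_report_carries_energy_trace_and_schedule(self):
        table = _chain_table(2, 10)
        geo = Geometry.sphere(5.0)
        sch = Schedule(n_steps=300, n_burnin=100, sample_every=100, seed=1)
        res = simulate(table, None, geo, ForceField(), sch, init_seed=2)
        assert len(res.report["energy_trace"]) == len(res.frames)
        assert {"bond", "pair", "wall", "ne"} <= set(res.report["energy_trace"][0])
        assert res.report["dt"] == 0.01

    def test_relax_removes_initial_loop_stretch(self):
        table = _chain_table(4, 25, mode="inhomogeneous")
        ff = ForceField()
        geo = Geometry.sphere(3.55)
        loops = generate_loops(table, 0.3, ff, seed=8)
        assert len(loops) > 0
        state = initialize_random(geo, table, seed=9)
        d0 = np.linalg.norm(
            state.positions[loops.i] - state.positions[loops.j], axis=1
        ).max()
        relax(state, table, loops, geo, ff, n_iter=300)
        d1 = np.linalg.norm(
            state.positions[loops.i] - state.positions[loops.j], axis=1
        ).max()
        assert d1 < d0
        assert d1 < 2.5  # springs near rest length after descent


class TestFluctuationDissipation:
    def test_tethered_monomer_variance_matches_equipartition(self):
        """A monomer in a harmonic trap at T_eq has positional variance
        k_B T / k per component to within 5% (trap realized as the confining
        wall of a point-sized sphere; k dt = 0.05 keeps the Euler
        discretization bias below 3%)."""
        kar = [ChromosomeSpec("c", 1, copies=1)]
        table = build_monomer_table(kar, synthesize_gene_track(kar, seed=0))
        table = assign_activity(table, "equilibrium")
        k_trap = 5.0
        ff = ForceField(k_wall=k_trap)
        geo = Geometry.sphere(1e-9)  # wall potential ~ (k/2) |r|^2
        state = SimulationState(np.zeros((1, 3)), 0.0, np.random.default_rng(0))
        sch = Schedule(n_steps=200_000, n_burnin=20_000, sample_every=10, seed=1)
        res = simulate(table, None, geo, ff, sch, state=state, collect_energies=False)
        samples = np.concatenate([f for f in res.frames], axis=0)
        var = samples.var(axis=0).mean()  # pooled over x, y, z
        assert var == pytest.approx(1.0 / k_trap, rel=0.05)


class TestNESwitchProtocol:
    def _prepared(self):
        table = _chain_table(4, 25, mode="inhomogeneous")
        ff = ForceField()
        geo = Geometry.sphere(3.55)
        states = []
        for k in range(3):
            res = simulate(
                table, None, geo, ff,
                Schedule(n_steps=2000, n_burnin=1000, sample_every=1000, seed=40 + k),
                init_seed=50 + k, collect_energies=False,
            )
            states.append(
                SimulationState(res.frames[-1], 0.0, np.random.default_rng(60 + k))
            )
        return table, ff, geo, states

    def test_small_ensemble_rejected(self):
        table, ff, geo, states = self._prepared()
        with pytest.raises(ValueError, match="smaller than"):
            ne_switch_protocol(table, None, geo, ff, states[:1], [0, 100], n_init=3)

    def test_t0_snapshot_matches_passive_state(self):
        table, ff, geo, states = self._prepared()
        out = ne_switch_protocol(
            table, None, geo, ff, states, [0, 500], n_init=3, n_bins=10
        )
        from actseg.analysis import radial_S

        ref = radial_S([s.positions for s in states], table, geometry=geo, n_bins=10)
        assert np.allclose(out[0]["S"]["all"].value, ref.value)

    def test_null_perturbation_is_time_invariant_within_noise(self):
        table, ff, geo, states = self._prepared()
        out = ne_switch_protocol(
            table, None, geo, ff, states, [0, 1000], n_init=3, n_bins=6, ne_on=False
        )
        v0 = out[0]["S"]["all"].value
        v1 = out[1000]["S"]["all"].value
        # same steady state: profiles agree to within a loose sampling band
        assert np.abs(v1 - v0).max() < 0.25
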