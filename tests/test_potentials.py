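import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from actseg import ChromosomeSpec, build_monomer_table, generate_loops, synthesize_gene_track
from actseg.genome_model import assign_activity
from actseg.potentials import (
    ForceField,
    Geometry,
    bond_energy,
    bond_force,
    ellipsoid_axes,
    gaussian_core_energy,
    gaussian_core_force,
    ne_energy,
    ne_force,
    surface_distance,
    total_forces,
    total_forces_direct,
    wall_energy,
    wall_force,
)


@pytest.fixture(scope="module")
def ff():
    return ForceField()


def brute_force_surface_distance(point, geometry, n_theta=240, n_phi=480):
    """Oracle: dense surface mesh scan + local refinement of the nearest point."""
    a, b, c = geometry.axes
    th = np.linspace(0, np.pi, n_theta)
    ph = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    q = np.stack(
        [a * np.sin(TH) * np.cos(PH), b * np.sin(TH) * np.sin(PH), c * np.cos(TH)], -1
    )
    d2 = ((q - np.asarray(point)) ** 2).sum(-1)
    k = np.unravel_index(np.argmin(d2), d2.shape)
    x0 = np.array([TH[k], PH[k]])

    def dist(angles):
        t, p = angles
        qq = np.array([a * np.sin(t) * np.cos(p), b * np.sin(t) * np.sin(p), c * np.cos(t)])
        return float(np.linalg.norm(qq - point))

    res = minimize(dist, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-14})
    d = res.fun
    inside = (point[0] / a) ** 2 + (point[1] / b) ** 2 + (point[2] / c) ** 2 <= 1.0
    return -d if inside else d


class TestBond:
    def test_rest_length_is_force_free(self, ff):
        assert bond_energy(ff.r0, ff) == 0.0
        assert bond_force(ff.r0, ff) == 0.0

    def test_closed_form_value(self):
        ff10 = ForceField(k_bond=10.0, r0=1.0)
        assert bond_energy(2.0, ff10) == pytest.approx(5.0, abs=1e-14)

    @settings(max_examples=30, deadline=None)
    @given(d=st.floats(0.0, 2.0))
    def test_symmetry_about_rest_length(self, d):
        ff = ForceField()
        assert bond_energy(d, ff) == pytest.approx(bond_energy(2 * ff.r0 - d, ff), abs=1e-12)


class TestGaussianCore:
    def test_zero_separation_value_is_v0_up_to_shift(self, ff):
        e0 = gaussian_core_energy(0.0, ff)
        assert e0 == pytest.approx(ff.V0 - ff.pair_shift, abs=1e-14)
        assert abs(e0 - ff.V0) < 0.02 * ff.V0  # truncation shift is percent level

    def test_closed_form_at_one_sigma(self):
        ff2 = ForceField(V0=2.0, sigma=1.0)
        expected = 2.0 * math.exp(-0.5) - ff2.pair_shift
        assert gaussian_core_energy(1.0, ff2) == pytest.approx(expected, abs=1e-14)
        assert 2.0 * math.exp(-0.5) == pytest.approx(1.2131, abs=1e-4)

    def test_zero_beyond_cutoff(self, ff):
        assert gaussian_core_energy(10.0 * ff.sigma, ff) == 0.0
        assert gaussian_core_force(10.0 * ff.sigma, ff) == 0.0

    def test_energy_continuous_at_cutoff(self, ff):
        eps = 1e-9
        below = gaussian_core_energy(ff.r_cut - eps, ff)
        assert abs(below) < 1e-8


class TestWallAndGeometry:
    def test_inside_sphere_is_energy_free(self, ff):
        geo = Geometry.sphere(10.0)
        assert wall_energy(np.array([3.0, 0.0, 4.0]), geo, ff) == 0.0  # |r| = 5

    def test_outside_sphere_closed_form(self):
        ff100 = ForceField(k_wall=100.0)
        geo = Geometry.sphere(10.0)
        assert wall_energy(np.array([11.0, 0.0, 0.0]), geo, ff100) == pytest.approx(50.0)

    def test_energy_continuous_at_surface(self, ff):
        geo = Geometry.sphere(10.0)
        for eps in (1e-3, 1e-5, 1e-7):
            e = wall_energy(np.array([10.0 + eps, 0.0, 0.0]), geo, ff)
            assert e <= 0.5 * ff.k_wall * (2 * eps) ** 2

    def test_sphere_signed_distance(self):
        geo = Geometry.sphere(10.0)
        assert surface_distance(np.array([0.0, 7.0, 0.0]), geo) == pytest.approx(-3.0)

    def test_ellipsoid_axis_point_on_surface(self):
        geo = Geometry.ellipsoid(3.0, 10.0)
        a = geo.axes[0]
        assert surface_distance(np.array([a, 0.0, 0.0]), geo) == pytest.approx(0.0, abs=1e-10)

    def test_ellipsoid_center_depth_is_min_axis(self):
        geo = Geometry.ellipsoid(0.3, 10.0)
        assert surface_distance(np.zeros(3), geo) == pytest.approx(-min(geo.axes))

    @pytest.mark.parametrize("aspect", [0.3, 3.0])
    def test_ellipsoid_distance_matches_brute_force(self, aspect):
        geo = Geometry.ellipsoid(aspect, 10.0)
        rng = np.random.default_rng(5)
        a, b, c = geo.axes
        for _ in range(12):
            p = rng.uniform(-1.3, 1.3, 3) * np.array([a, b, c])
            s = surface_distance(p, geo)
            s_ref = brute_force_surface_distance(p, geo)
            assert s == pytest.approx(s_ref, abs=1e-6)

    def test_axes_sphere_limit(self):
        assert ellipsoid_axes(1.0, 10.0) == pytest.approx((10.0, 10.0, 10.0))

    def test_axes_prolate_closed_form(self):
        a, b, c = ellipsoid_axes(3.0, 10.0)
        assert a == b == pytest.approx(10.0 * 3 ** (-1 / 3), abs=1e-10)
        assert a == pytest.approx(6.9336, abs=1e-4)
        assert c == pytest.approx(20.8008, abs=1e-4)

    def test_invalid_aspect_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_axes(-1.0, 10.0)

    @settings(max_examples=40, deadline=None)
    @given(aspect=st.floats(0.05, 20.0), R0=st.floats(0.5, 50.0))
    def test_volume_preserved_for_any_aspect(self, aspect, R0):
        a, b, c = ellipsoid_axes(aspect, R0)
        assert a * b * c == pytest.approx(R0**3, rel=1e-12)

    def test_equipotential_at_equal_surface_distance(self, ff):
        # two points in different directions, bisected to the same outside distance
        geo = Geometry.ellipsoid(0.3, 10.0)
        rng = np.random.default_rng(2)
        target = 0.7
        energies = []
        for _ in range(4):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)

            def f(t):
                return surface_distance(t * u, geo) - target

            lo, hi = 0.1, 50.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                lo, hi = (mid, hi) if f(mid) < 0 else (lo, mid)
            p = 0.5 * (lo + hi) * u
            energies.append(wall_energy(p, geo, ff))
        assert np.ptp(energies) <= 1e-6 * max(energies)


class TestNEInteraction:
    def test_inactive_feels_only_confinement(self, ff):
        geo = Geometry.sphere(10.0)
        p = np.array([5.0, 0.0, 0.0])
        assert ne_energy(p, False, geo, ff) == 0.0

    def test_active_well_depth_at_surface(self):
        ff4 = ForceField(eps_ne=4.0)
        geo = Geometry.sphere(10.0)
        p = np.array([10.0, 0.0, 0.0])
        assert ne_energy(p, True, geo, ff4) == pytest.approx(-4.0)

    def test_attraction_negligible_far_from_surface(self, ff):
        geo = Geometry.sphere(50.0)
        p = np.array([50.0 - 10.0 * ff.lambda_ne, 0.0, 0.0])
        assert abs(ne_energy(p, True, geo, ff)) < 1e-10 * ff.eps_ne

    def test_minimum_is_on_the_surface(self, ff):
        geo = Geometry.sphere(10.0)
        radii = np.linspace(8.0, 11.0, 301)
        e = [ne_energy(np.array([r, 0.0, 0.0]), True, geo, ff) for r in radii]
        assert radii[int(np.argmin(e))] == pytest.approx(10.0, abs=0.01)


def _central_diff(fun, p, h=1e-6):
    g = np.zeros(3)
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = h
        g[k] = (fun(p + dp) - fun(p - dp)) / (2 * h)
    return -g


class TestForcesAreGradients:
    @pytest.mark.parametrize("geo_kind", ["sphere", "oblate", "prolate"])
    def test_wall_force_matches_gradient(self, ff, geo_kind):
        geo = {
            "sphere": Geometry.sphere(10.0),
            "oblate": Geometry.ellipsoid(0.3, 10.0),
            "prolate": Geometry.ellipsoid(3.0, 10.0),
        }[geo_kind]
        rng = np.random.default_rng(1)
        for _ in range(8):
            p = rng.uniform(-1.2, 1.2, 3) * np.array(geo.axes)
            if abs(surface_distance(p, geo)) < 0.05:
                continue
            f = wall_force(p, geo, ff)
            g = _central_diff(lambda q: wall_energy(q, geo, ff), p)
            assert np.allclose(f, g, atol=1e-5 * max(1.0, np.linalg.norm(f)))

    @pytest.mark.parametrize("geo_kind", ["sphere", "prolate"])
    def test_ne_force_matches_gradient(self, ff, geo_kind):
        geo = Geometry.sphere(10.0) if geo_kind == "sphere" else Geometry.ellipsoid(3.0, 10.0)
        rng = np.random.default_rng(3)
        for _ in range(8):
            p = rng.uniform(-1.1, 1.1, 3) * np.array(geo.axes)
            f = ne_force(p, True, geo, ff)
            g = _central_diff(lambda q: ne_energy(q, True, geo, ff), p)
            assert np.allclose(f, g, atol=1e-4 * max(1.0, np.linalg.norm(f)))

    @settings(max_examples=25, deadline=None)
    @given(d=st.floats(0.01, 2.9))
    def test_pair_force_is_radial_derivative(self, d):
        ff = ForceField()
        h = 1e-7
        g = -(gaussian_core_energy(d + h, ff) - gaussian_core_energy(d - h, ff)) / (2 * h)
        assert gaussian_core_force(d, ff) == pytest.approx(g, rel=1e-5, abs=1e-8)


def _small_system(n_chains=8, length=25, seed=0, p_loop=0.2):
    kar = [ChromosomeSpec(f"c{i}", length, copies=1) for i in range(n_chains)]
    table = build_monomer_table(kar, synthesize_gene_track(kar, seed=seed))
    table = assign_activity(table, "inhomogeneous", 0.1, 20.0)
    ff = ForceField()
    loops = generate_loops(table, p_loop, ff, seed=seed + 1)
    return table, loops, ff


class TestTotalForces:
    def test_single_central_monomer_is_force_free(self):
        kar = [ChromosomeSpec("c", 1, copies=1)]
        table = build_monomer_table(kar, synthesize_gene_track(kar, seed=0))
        geo = Geometry.sphere(10.0)
        f = total_forces(np.zeros((1, 3)), table, None, geo, ForceField())
        assert np.allclose(f, 0.0)

    def test_two_bonded_monomers_match_closed_form(self):
        kar = [ChromosomeSpec("c", 2, copies=1)]
        table = build_monomer_table(kar, synthesize_gene_track(kar, seed=0))
        ff = ForceField()
        geo = Geometry.sphere(100.0)
        pos = np.array([[0.0, 0.0, 0.0], [2.0 * ff.r0, 0.0, 0.0]])
        f = total_forces(pos, table, None, geo, ff)
        expected = bond_force(2 * ff.r0, ff) + gaussian_core_force(2 * ff.r0, ff)
        # monomer 0 sits at smaller x: restoring bond pulls it to +x,
        # repulsive core pushes it to -x; net radial force along -x is `expected`
        assert f[0, 0] == pytest.approx(-expected, rel=1e-6)
        assert np.allclose(f[0], -f[1], atol=1e-12)

    def test_newtons_third_law_without_walls(self):
        table, loops, ff = _small_system()
        geo = Geometry.sphere(1000.0)  # walls never touched
        rng = np.random.default_rng(4)
        pos = rng.uniform(-5, 5, (len(table), 3))
        f = total_forces(pos, table, loops, geo, ff)
        assert np.abs(f.sum(axis=0)).max() <= 1e-9

    def test_non_finite_coordinate_names_monomer(self):
        table, loops, ff = _small_system()
        geo = Geometry.sphere(10.0)
        pos = np.zeros((len(table), 3))
        pos[17, 1] = np.nan
        with pytest.raises(ValueError, match="17"):
            total_forces(pos, table, loops, geo, ff)

    @pytest.mark.parametrize("ne_on", [False, True])
    def test_accelerated_path_equals_direct_double_loop(self, ne_on):
        table, loops, ff = _small_system()
        geo = Geometry.sphere(4.0)
        rng = np.random.default_rng(9)
        for _ in range(3):
            pos = rng.uniform(-4.5, 4.5, (len(table), 3))
            fast = total_forces(pos, table, loops, geo, ff, ne_on=ne_on)
            ref = total_forces_direct(pos, table, loops, geo, ff, ne_on=ne_on)
            assert np.abs(fast - ref).max() <= 1e-10
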