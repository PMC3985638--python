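"""Numba kernels: pairwise forces (cell-list and direct), ellipsoid geometry,
and the Euler–Maruyama integration inner loop.

All formulas here mirror the scalar reference implementations in
:mod:`actseg.potentials`; the cell-list path is validated against the direct
O(N^2) double loop in the test suite.  Kernels use plain float64 scalars so
that the direct and cell-list paths differ only in pair enumeration order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# geometry kind codes
GEOM_SPHERE = 0
GEOM_ELLIPSOID = 1

# maximum cells per dimension (keeps the grid bounded for huge boxes)
_MAX_CELLS = 48


# ---------------------------------------------------------------------------
# Ellipsoid nearest point / signed surface distance
# ---------------------------------------------------------------------------


@njit(cache=True)
def _root_F(a2x, a2y, a2z, px, py, pz, t):
    """F(t) = sum_i (a_i p_i / (a_i^2 + t))^2 - 1 for the Lagrange parameter."""
    s = 0.0
    if px != 0.0:
        r = a2x * px * px / ((a2x + t) * (a2x + t))
        s += r
    if py != 0.0:
        s += a2y * py * py / ((a2y + t) * (a2y + t))
    if pz != 0.0:
        s += a2z * pz * pz / ((a2z + t) * (a2z + t))
    return s - 1.0


@njit(cache=True)
def _solve_t(a2x, a2y, a2z, px, py, pz, t_floor):
    """Newton-with-bisection root of F on (t_floor, inf).  Returns (t, ok)."""
    # bracket: just above the pole F -> +inf; expand upward until F < 0
    lo = t_floor + 1e-14 * max(1.0, abs(t_floor))
    f_lo = _root_F(a2x, a2y, a2z, px, py, pz, lo)
    if f_lo < 0.0:
        return lo, f_lo > -1e-9  # root at/below floor: degenerate input
    hi = max(1.0, abs(t_floor))
    for _ in range(200):
        if _root_F(a2x, a2y, a2z, px, py, pz, hi) < 0.0:
            break
        hi *= 4.0
    t = 0.5 * (lo + hi)
    for _ in range(200):
        f = _root_F(a2x, a2y, a2z, px, py, pz, t)
        if f > 0.0:
            lo = t
        else:
            hi = t
        # Newton step from derivative of F (strictly decreasing)
        df = 0.0
        if px != 0.0:
            df += -2.0 * a2x * px * px / ((a2x + t) ** 3)
        if py != 0.0:
            df += -2.0 * a2y * py * py / ((a2y + t) ** 3)
        if pz != 0.0:
            df += -2.0 * a2z * pz * pz / ((a2z + t) ** 3)
        t_new = t - f / df if df != 0.0 else 0.5 * (lo + hi)
        if not (lo < t_new < hi):
            t_new = 0.5 * (lo + hi)
        if abs(t_new - t) < 1e-14 * max(1.0, abs(t)) and abs(f) < 1e-12:
            return t_new, True
        t = t_new
    return t, abs(_root_F(a2x, a2y, a2z, px, py, pz, t)) < 1e-9


@njit(cache=True)
def ellipsoid_nearest(a, b, c, px, py, pz):
    """Nearest point on the ellipsoid surface and signed distance.

    Returns ``(qx, qy, qz, s, ok)`` with ``s`` negative inside.  Works for
    interior and exterior points; exact-zero coordinates are handled by
    comparing the in-plane critical point with the off-plane branch.
    """
    sx = 1.0 if px >= 0.0 else -1.0
    sy = 1.0 if py >= 0.0 else -1.0
    sz = 1.0 if pz >= 0.0 else -1.0
    x, y, z = abs(px), abs(py), abs(pz)
    a2, b2, c2 = a * a, b * b, c * c

    inside = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0

    if x == 0.0 and y == 0.0 and z == 0.0:
        # center: nearest point is the pole of the shortest axis
        m = min(a, min(b, c))
        if m == a:
            return sx * a, 0.0, 0.0, -m, True
        elif m == b:
            return 0.0, sy * b, 0.0, -m, True
        return 0.0, 0.0, sz * c, -m, True

    # pole of F: smallest a_i^2 among axes with a nonzero coordinate
    t_floor = 1e300
    if x != 0.0 and a2 < t_floor:
        t_floor = a2
    if y != 0.0 and b2 < t_floor:
        t_floor = b2
    if z != 0.0 and c2 < t_floor:
        t_floor = c2
    t_floor = -t_floor

    best_d2 = 1e300
    bqx = bqy = bqz = 0.0
    any_ok = False

    t, ok = _solve_t(a2, b2, c2, x, y, z, t_floor)
    if ok:
        qx = a2 * x / (a2 + t)
        qy = b2 * y / (b2 + t)
        qz = c2 * z / (c2 + t)
        d2 = (x - qx) ** 2 + (y - qy) ** 2 + (z - qz) ** 2
        if d2 < best_d2:
            best_d2 = d2
            bqx, bqy, bqz = qx, qy, qz
        any_ok = True

    # off-plane branches for exact-zero coordinates (t = -a_k^2)
    if x == 0.0:
        den_y = b2 - a2
        den_z = c2 - a2
        if (y == 0.0 or den_y != 0.0) and (z == 0.0 or den_z != 0.0):
            qy = b2 * y / den_y if y != 0.0 else 0.0
            qz = c2 * z / den_z if z != 0.0 else 0.0
            rem = 1.0 - (qy / b) ** 2 - (qz / c) ** 2
            if rem >= 0.0:
                qx = a * math.sqrt(rem)
                d2 = qx * qx + (y - qy) ** 2 + (z - qz) ** 2
                if d2 < best_d2:
                    best_d2 = d2
                    bqx, bqy, bqz = qx, qy, qz
                any_ok = True
    if y == 0.0:
        den_x = a2 - b2
        den_z = c2 - b2
        if (x == 0.0 or den_x != 0.0) and (z == 0.0 or den_z != 0.0):
            qx = a2 * x / den_x if x != 0.0 else 0.0
            qz = c2 * z / den_z if z != 0.0 else 0.0
            rem = 1.0 - (qx / a) ** 2 - (qz / c) ** 2
            if rem >= 0.0:
                qy = b * math.sqrt(rem)
                d2 = (x - qx) ** 2 + qy * qy + (z - qz) ** 2
                if d2 < best_d2:
                    best_d2 = d2
                    bqx, bqy, bqz = qx, qy, qz
                any_ok = True
    if z == 0.0:
        den_x = a2 - c2
        den_y = b2 - c2
        if (x == 0.0 or den_x != 0.0) and (y == 0.0 or den_y != 0.0):
            qx = a2 * x / den_x if x != 0.0 else 0.0
            qy = b2 * y / den_y if y != 0.0 else 0.0
            rem = 1.0 - (qx / a) ** 2 - (qy / b) ** 2
            if rem >= 0.0:
                qz = c * math.sqrt(rem)
                d2 = (x - qx) ** 2 + (y - qy) ** 2 + qz * qz
                if d2 < best_d2:
                    best_d2 = d2
                    bqx, bqy, bqz = qx, qy, qz
                any_ok = True

    d = math.sqrt(best_d2)
    s = -d if inside else d
    return sx * bqx, sy * bqy, sz * bqz, s, any_ok


@njit(cache=True)
def surface_distance_kernel(kind, R0, a, b, c, px, py, pz):
    """Signed distance to the bounding surface (negative inside)."""
    if kind == GEOM_SPHERE:
        return math.sqrt(px * px + py * py + pz * pz) - R0
    qx, qy, qz, s, ok = ellipsoid_nearest(a, b, c, px, py, pz)
    if not ok:
        return math.nan
    return s


# ---------------------------------------------------------------------------
# Force accumulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _add_bond_forces(pos, bond_i, bond_j, bond_k, r0, forces):
    for m in range(bond_i.shape[0]):
        i = bond_i[m]
        j = bond_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-12:
            continue  # coincident: restoring direction undefined
        coef = -bond_k[m] * (d - r0) / d
        forces[i, 0] += coef * dx
        forces[i, 1] += coef * dy
        forces[i, 2] += coef * dz
        forces[j, 0] -= coef * dx
        forces[j, 1] -= coef * dy
        forces[j, 2] -= coef * dz


@njit(cache=True)
def _add_boundary_forces(
    pos, forces, kind, R0, ax, ay, az, k_wall, ne_on, eps_ne, lam_ne, active
):
    n = pos.shape[0]
    inv_lam2 = 1.0 / (lam_ne * lam_ne) if lam_ne > 0.0 else 0.0
    for i in range(n):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        if kind == GEOM_SPHERE:
            r = math.sqrt(x * x + y * y + z * z)
            s = r - R0
            if s > 0.0 and r > 0.0:
                coef = -k_wall * s / r
                forces[i, 0] += coef * x
                forces[i, 1] += coef * y
                forces[i, 2] += coef * z
            if ne_on and active[i] and r > 0.0:
                # p - q = (s/r) * p for the sphere
                coef = -eps_ne * inv_lam2 * math.exp(-0.5 * s * s * inv_lam2) * (s / r)
                forces[i, 0] += coef * x
                forces[i, 1] += coef * y
                forces[i, 2] += coef * z
        else:
            w = (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2
            need_ne = ne_on and active[i]
            if w > 1.0 or need_ne:
                qx, qy, qz, s, ok = ellipsoid_nearest(ax, ay, az, x, y, z)
                if not ok:
                    continue
                if s > 0.0:
                    forces[i, 0] += -k_wall * (x - qx)
                    forces[i, 1] += -k_wall * (y - qy)
                    forces[i, 2] += -k_wall * (z - qz)
                if need_ne:
                    coef = -eps_ne * inv_lam2 * math.exp(-0.5 * s * s * inv_lam2)
                    forces[i, 0] += coef * (x - qx)
                    forces[i, 1] += coef * (y - qy)
                    forces[i, 2] += coef * (z - qz)


_EXP_TABLE_N = 4096


@njit(cache=True)
def make_exp_table(sigma, rcut):
    """Tabulate exp(-d^2 / 2 sigma^2) on a uniform grid of d^2 in [0, rcut^2].

    The pair kernels interpolate this table linearly (absolute error below
    2e-7), so the cell-list and direct paths evaluate bit-identical pair
    coefficients; the scalar reference functions keep the analytic exp.
    """
    table = np.empty(_EXP_TABLE_N + 1)
    inv2s2 = 0.5 / (sigma * sigma)
    for k in range(_EXP_TABLE_N + 1):
        d2 = rcut * rcut * k / _EXP_TABLE_N
        table[k] = math.exp(-d2 * inv2s2)
    return table


@njit(cache=True, inline="always")
def _exp_interp(table, u):
    # u = d^2 / rcut^2 in [0, 1)
    x = u * _EXP_TABLE_N
    k = int(x)
    f = x - k
    return table[k] + f * (table[k + 1] - table[k])


@njit(cache=True)
def _add_pair_forces_direct(pos, V0, sigma, rcut, exp_table, forces):
    n = pos.shape[0]
    rcut2 = rcut * rcut
    inv_rc2 = 1.0 / rcut2
    v0s2 = V0 / (sigma * sigma)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rcut2:
                coef = v0s2 * _exp_interp(exp_table, d2 * inv_rc2)
                forces[i, 0] += coef * dx
                forces[i, 1] += coef * dy
                forces[i, 2] += coef * dz
                forces[j, 0] -= coef * dx
                forces[j, 1] -= coef * dy
                forces[j, 2] -= coef * dz


@njit(cache=True)
def _zsort_incremental(pos, order):
    """Insertion-sort ``order`` by z coordinate (amortized O(N) when the
    permutation is already nearly sorted, as it is between Langevin steps)."""
    n = order.shape[0]
    for k in range(1, n):
        o = order[k]
        zv = pos[o, 2]
        j = k - 1
        while j >= 0 and pos[order[j], 2] > zv:
            order[j + 1] = order[j]
            j -= 1
        order[j + 1] = o


@njit(cache=True)
def _add_pair_forces_window(pos, V0, sigma, rcut, exp_table, order,
                            xs, ys, zs, fxs, fys, fzs, buf, forces):
    """Pair forces via a z-sorted window list (the accelerated pair path).

    Particles are kept sorted by z (``order``, maintained incrementally by
    the caller); for each particle only the contiguous run of partners with
    z within the cutoff is scanned, in two phases — a vectorizable distance
    pass into ``buf``, then the force pass over the hits.  Workspace arrays
    are caller-provided so the integrator reuses them across steps.  Each
    pair is visited once, so action-reaction is exact, and the summation
    order is fixed by the permutation, preserving bitwise determinism.
    """
    n = pos.shape[0]
    rcut2 = rcut * rcut
    inv_rc2 = 1.0 / rcut2
    v0s2 = V0 / (sigma * sigma)
    for k in range(n):
        i = order[k]
        xs[k] = pos[i, 0]
        ys[k] = pos[i, 1]
        zs[k] = pos[i, 2]
        fxs[k] = 0.0
        fys[k] = 0.0
        fzs[k] = 0.0
    for a in range(n - 1):
        za = zs[a]
        e = a + 1
        while e < n and zs[e] - za < rcut:
            e += 1
        xa = xs[a]
        ya = ys[a]
        m = e - (a + 1)
        for t in range(m):
            b = a + 1 + t
            dx = xa - xs[b]
            dy = ya - ys[b]
            dz = za - zs[b]
            buf[t] = dx * dx + dy * dy + dz * dz
        ax = 0.0
        ay = 0.0
        az = 0.0
        for t in range(m):
            d2 = buf[t]
            if d2 < rcut2:
                b = a + 1 + t
                coef = v0s2 * _exp_interp(exp_table, d2 * inv_rc2)
                dx = xa - xs[b]
                dy = ya - ys[b]
                dz = za - zs[b]
                ax += coef * dx
                ay += coef * dy
                az += coef * dz
                fxs[b] -= coef * dx
                fys[b] -= coef * dy
                fzs[b] -= coef * dz
        fxs[a] += ax
        fys[a] += ay
        fzs[a] += az
    for k in range(n):
        i = order[k]
        forces[i, 0] += fxs[k]
        forces[i, 1] += fys[k]
        forces[i, 2] += fzs[k]


@njit(cache=True)
def _add_pair_forces_cells(pos, V0, sigma, rcut, exp_table, forces):
    """Accelerated pair forces with self-contained workspace (one-off calls)."""
    n = pos.shape[0]
    order = np.argsort(pos[:, 2]).astype(np.int64)
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    fxs = np.empty(n)
    fys = np.empty(n)
    fzs = np.empty(n)
    buf = np.empty(n)
    _add_pair_forces_window(pos, V0, sigma, rcut, exp_table, order,
                            xs, ys, zs, fxs, fys, fzs, buf, forces)


@njit(cache=True)
def compute_forces(
    pos,
    bond_i,
    bond_j,
    bond_k,
    r0,
    V0,
    sigma,
    rcut,
    kind,
    R0,
    ax,
    ay,
    az,
    k_wall,
    ne_on,
    eps_ne,
    lam_ne,
    active,
    use_cells,
    exp_table,
):
    """All deterministic forces: bonds+loops, Gaussian core, wall, NE."""
    forces = np.zeros_like(pos)
    _add_bond_forces(pos, bond_i, bond_j, bond_k, r0, forces)
    if V0 != 0.0:
        if use_cells:
            _add_pair_forces_cells(pos, V0, sigma, rcut, exp_table, forces)
        else:
            _add_pair_forces_direct(pos, V0, sigma, rcut, exp_table, forces)
    if k_wall != 0.0 or ne_on:
        _add_boundary_forces(
            pos, forces, kind, R0, ax, ay, az, k_wall, ne_on, eps_ne, lam_ne, active
        )
    return forces


@njit(cache=True)
def compute_energies(
    pos,
    bond_i,
    bond_j,
    bond_k,
    r0,
    V0,
    sigma,
    rcut,
    kind,
    R0,
    ax,
    ay,
    az,
    k_wall,
    ne_on,
    eps_ne,
    lam_ne,
    active,
):
    """(bond, pair, wall, NE) energies; pair part uses the shifted cutoff."""
    e_bond = 0.0
    for m in range(bond_i.shape[0]):
        i = bond_i[m]
        j = bond_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        e_bond += 0.5 * bond_k[m] * (d - r0) ** 2

    e_pair = 0.0
    n = pos.shape[0]
    rcut2 = rcut * rcut
    inv2s2 = 0.5 / (sigma * sigma)
    shift = V0 * math.exp(-rcut2 * inv2s2)
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rcut2:
                e_pair += V0 * math.exp(-d2 * inv2s2) - shift

    e_wall = 0.0
    e_ne = 0.0
    inv_lam2 = 1.0 / (lam_ne * lam_ne) if lam_ne > 0.0 else 0.0
    for i in range(n):
        s = surface_distance_kernel(kind, R0, ax, ay, az, pos[i, 0], pos[i, 1], pos[i, 2])
        if s > 0.0:
            e_wall += 0.5 * k_wall * s * s
        if ne_on and active[i]:
            e_ne += -eps_ne * math.exp(-0.5 * s * s * inv_lam2)
    return e_bond, e_pair, e_wall, e_ne


@njit(cache=True)
def _is_inside(kind, R0, ax, ay, az, x, y, z):
    if kind == GEOM_SPHERE:
        return x * x + y * y + z * z <= R0 * R0
    return (x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2 <= 1.0


@njit(cache=True)
def integrate_chunk(
    pos,
    noise,
    noise_amp,
    dt_over_zeta,
    sigma,
    guard_dist,
    bond_i,
    bond_j,
    bond_k,
    r0,
    V0,
    rcut,
    kind,
    R0,
    ax,
    ay,
    az,
    k_wall,
    ne_on,
    eps_ne,
    lam_ne,
    active,
    exp_table,
):
    """Advance ``pos`` in place by ``noise.shape[0]`` Euler–Maruyama steps.

    ``noise`` is (K, N, 3) standard normals; ``noise_amp`` the per-monomer
    displacement std-dev sqrt(2 k_B T_i dt / zeta).  Returns -1 on success or
    the 0-based step index at which the deterministic drift of any monomer
    inside the confinement exceeded ``guard_dist`` (time step too large for
    the force field).  Monomers outside the boundary are exempt: with
    k_wall*dt/zeta <= 1 the wall drift is self-limiting — it can be large
    after a deep noise excursion but never carries the monomer past the
    surface.
    """
    n = pos.shape[0]
    sigma2 = guard_dist * guard_dist
    # persistent workspace: z-order is maintained incrementally across steps
    order = np.argsort(pos[:, 2]).astype(np.int64)
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    fxs = np.empty(n)
    fys = np.empty(n)
    fzs = np.empty(n)
    buf = np.empty(n)
    forces = np.empty((n, 3))
    for step in range(noise.shape[0]):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        _add_bond_forces(pos, bond_i, bond_j, bond_k, r0, forces)
        if V0 != 0.0:
            _zsort_incremental(pos, order)
            _add_pair_forces_window(pos, V0, sigma, rcut, exp_table, order,
                                    xs, ys, zs, fxs, fys, fzs, buf, forces)
        if k_wall != 0.0 or ne_on:
            _add_boundary_forces(
                pos, forces, kind, R0, ax, ay, az, k_wall, ne_on, eps_ne,
                lam_ne, active,
            )
        for i in range(n):
            gx = dt_over_zeta * forces[i, 0]
            gy = dt_over_zeta * forces[i, 1]
            gz = dt_over_zeta * forces[i, 2]
            if gx * gx + gy * gy + gz * gz > sigma2 and _is_inside(
                kind, R0, ax, ay, az, pos[i, 0], pos[i, 1], pos[i, 2]
            ):
                return step
            amp = noise_amp[i]
            pos[i, 0] += gx + amp * noise[step, i, 0]
            pos[i, 1] += gy + amp * noise[step, i, 1]
            pos[i, 2] += gz + amp * noise[step, i, 2]
    return -1
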