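"""Deterministic interactions of the confined chromatin melt.

Four ingredients, all in reduced units (monomer diameter sigma = 1 length,
k_B T_eq = 1 energy, drag zeta = 1, so time is measured in tau = zeta
sigma^2 / k_B T_eq):

* harmonic backbone bonds, U = (k/2)(d - r0)^2, enforcing chain connectivity
  (loop springs reuse this form with a 10x stiffer constant);
* a Gaussian-core pair repulsion, U = V0 exp(-d^2 / 2 sigma^2), the standard
  soft potential for interpenetrating coarse-grained polymer blobs (energy-
  shifted to zero at the cutoff so the truncation is continuous);
* harmonic confinement by the nuclear envelope: zero inside the nucleus,
  (k_wall/2) d_out^2 outside, with d_out the Euclidean distance to the
  bounding surface — so for ellipsoidal nuclei all points at a common
  surface distance experience the same potential;
* an optional short-ranged NE attraction acting on active monomers only,
  U = -eps_ne exp(-s^2 / 2 lambda_ne^2) with s the signed surface distance;
  its minimum sits exactly on the envelope, modelling selective tethering of
  a monomer subset to the lamina.

Numerical defaults are chosen for stability of the explicit Euler update at
the model time step dt = 0.01 tau: a harmonic stiffness k is stable only
while k_eff * dt / zeta < 2, where k_eff can reach ~4x the bond constant for
internal chain modes and ~12x at loop anchors.  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .genome_model import MonomerTable

__all__ = [
    "ForceField",
    "Geometry",
    "ellipsoid_axes",
    "bond_energy",
    "bond_force",
    "gaussian_core_energy",
    "gaussian_core_force",
    "wall_energy",
    "wall_force",
    "surface_distance",
    "ne_energy",
    "ne_force",
    "total_forces",
    "total_forces_direct",
]


@dataclass(frozen=True)
class ForceField:
    """All interaction constants in reduced units.

    Attributes
    ----------
    k_bond : backbone spring constant (energy/length^2).
    r0 : bond rest length; equals the monomer diameter.
    V0 : Gaussian-core amplitude, of order k_B T_eq.
    sigma : Gaussian-core width = monomer diameter.
    k_wall : harmonic confinement stiffness (energy/length^2).
    loop_k_multiplier : loop springs are this multiple of ``k_bond``.
    eps_ne : NE attraction well depth (energy); must exceed the active
        temperature scale for peripheral tethering to win against noise.
    lambda_ne : NE attraction range (length).
    r_cut : pair-interaction cutoff (length).
    """

    k_bond: float = 5.0
    r0: float = 1.0
    V0: float = 2.0
    sigma: float = 1.0
    k_wall: float = 100.0
    loop_k_multiplier: float = 10.0
    eps_ne: float = 80.0
    lambda_ne: float = 1.0
    r_cut: float = 3.0

    def __post_init__(self) -> None:
        for name in ("k_bond", "r0", "V0", "sigma", "k_wall", "eps_ne", "lambda_ne", "r_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ForceField.{name} must be positive")
        if self.loop_k_multiplier < 1:
            raise ValueError("loop_k_multiplier must be >= 1")
        if self.r_cut < 3 * self.sigma:
            raise ValueError("r_cut must be >= 3 sigma")

    @property
    def pair_shift(self) -> float:
        """Energy shift making the truncated Gaussian core continuous."""
        return self.V0 * math.exp(-self.r_cut**2 / (2 * self.sigma**2))


def ellipsoid_axes(aspect: float, R0: float) -> tuple[float, float, float]:
    """Volume-preserving ellipsoid-of-revolution semi-axes.

    Two equal semi-axes a = b and c = aspect * a with a^2 c = R0^3, so the
    ellipsoid volume equals that of the sphere of radius ``R0`` exactly.
    aspect > 1 gives a prolate (elongated), aspect < 1 an oblate (flattened)
    nucleus.
    """
    if aspect <= 0:
        raise ValueError(f"aspect must be positive, got {aspect}")
    a = R0 * aspect ** (-1.0 / 3.0)
    return a, a, aspect * a


@dataclass(frozen=True)
class Geometry:
    """Sphere or volume-matched ellipsoid confinement.

    ``R0`` is always the volume-equivalent sphere radius; for ellipsoids the
    semi-axes satisfy a*b*c = R0^3.
    """

    kind: str
    R0: float
    axes: tuple[float, float, float]

    @classmethod
    def sphere(cls, R0: float) -> "Geometry":
        if R0 <= 0:
            raise ValueError("R0 must be positive")
        return cls(kind="sphere", R0=R0, axes=(R0, R0, R0))

    @classmethod
    def ellipsoid(cls, aspect: float, R0: float) -> "Geometry":
        if R0 <= 0:
            raise ValueError("R0 must be positive")
        return cls(kind="ellipsoid", R0=R0, axes=ellipsoid_axes(aspect, R0))

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        a, b, c = self.axes
        if min(a, b, c) <= 0:
            raise ValueError("semi-axes must be positive")
        if abs(a * b * c - self.R0**3) > 1e-9 * self.R0**3:
            raise ValueError("ellipsoid volume does not match the reference sphere")

    @property
    def kind_code(self) -> int:
        return _kernels.GEOM_SPHERE if self.kind == "sphere" else _kernels.GEOM_ELLIPSOID

    @property
    def max_inside_depth(self) -> float:
        """Largest possible interior depth (attained at the center)."""
        return self.R0 if self.kind == "sphere" else min(self.axes)

    def contains(self, point: np.ndarray) -> bool:
        return surface_distance(point, self) < 0.0


# ---------------------------------------------------------------------------
# Scalar reference forms (tests check the kernels against these)
# ---------------------------------------------------------------------------


def bond_energy(d: float, ff: ForceField, k: float | None = None) -> float:
    """Harmonic bond energy (k/2)(d - r0)^2; pass ``k`` for loop springs."""
    if d < 0:
        raise ValueError("separation must be non-negative")
    kk = ff.k_bond if k is None else k
    return 0.5 * kk * (d - ff.r0) ** 2


def bond_force(d: float, ff: ForceField, k: float | None = None) -> float:
    """Radial bond force -dU/dd; positive pushes the pair apart."""
    if d < 0:
        raise ValueError("separation must be non-negative")
    kk = ff.k_bond if k is None else k
    return -kk * (d - ff.r0)


def gaussian_core_energy(d: float, ff: ForceField) -> float:
    """Truncated-and-shifted Gaussian-core pair energy.

    ``V0 exp(-d^2/2 sigma^2) - shift`` for d < r_cut, zero beyond, with the
    shift chosen so the energy is continuous at the cutoff.  The zero-
    separation value is V0 up to the (percent-level) shift.
    """
    if d < 0:
        raise ValueError("separation must be non-negative")
    if d >= ff.r_cut:
        return 0.0
    return ff.V0 * math.exp(-(d**2) / (2 * ff.sigma**2)) - ff.pair_shift


def gaussian_core_force(d: float, ff: ForceField) -> float:
    """Radial Gaussian-core force -dU/dd (always repulsive, zero past cutoff)."""
    if d < 0:
        raise ValueError("separation must be non-negative")
    if d >= ff.r_cut:
        return 0.0
    return ff.V0 * d / ff.sigma**2 * math.exp(-(d**2) / (2 * ff.sigma**2))


def surface_distance(point: np.ndarray, geometry: Geometry) -> float:
    """Signed Euclidean distance to the bounding surface (negative inside).

    Sphere: ``|r| - R0`` exactly.  Ellipsoid: nearest-point solve (Newton on
    the Lagrange parameter, bisection-safeguarded) converged to <=1e-10.
    """
    p = np.asarray(point, dtype=np.float64)
    a, b, c = geometry.axes
    s = _kernels.surface_distance_kernel(
        geometry.kind_code, geometry.R0, a, b, c, p[0], p[1], p[2]
    )
    if math.isnan(s):
        raise RuntimeError(f"ellipsoid nearest-point solve failed for point {p}")
    return float(s)


def wall_energy(point: np.ndarray, geometry: Geometry, ff: ForceField) -> float:
    """Confinement energy: zero inside, (k_wall/2) d_out^2 outside."""
    s = surface_distance(point, geometry)
    return 0.5 * ff.k_wall * s**2 if s > 0 else 0.0


def wall_force(point: np.ndarray, geometry: Geometry, ff: ForceField) -> np.ndarray:
    """Confinement force vector -grad wall_energy (points back inside)."""
    p = np.asarray(point, dtype=np.float64)
    a, b, c = geometry.axes
    if geometry.kind == "sphere":
        r = float(np.linalg.norm(p))
        s = r - geometry.R0
        if s <= 0 or r == 0:
            return np.zeros(3)
        return -ff.k_wall * s / r * p
    qx, qy, qz, s, ok = _kernels.ellipsoid_nearest(a, b, c, p[0], p[1], p[2])
    if not ok:
        raise RuntimeError(f"ellipsoid nearest-point solve failed for point {p}")
    if s <= 0:
        return np.zeros(3)
    return -ff.k_wall * (p - np.array([qx, qy, qz]))


def ne_energy(
    point: np.ndarray, is_active: bool, geometry: Geometry, ff: ForceField
) -> float:
    """Wall energy plus, for active monomers, the NE attraction well.

    Inactive monomers feel only the repulsive confinement; active monomers
    additionally gain ``-eps_ne exp(-s^2 / 2 lambda_ne^2)``, minimal exactly
    on the envelope surface.
    """
    e = wall_energy(point, geometry, ff)
    if is_active:
        s = surface_distance(point, geometry)
        e += -ff.eps_ne * math.exp(-(s**2) / (2 * ff.lambda_ne**2))
    return e


def ne_force(
    point: np.ndarray, is_active: bool, geometry: Geometry, ff: ForceField
) -> np.ndarray:
    """Force vector of :func:`ne_energy` (wall + selective NE attraction)."""
    p = np.asarray(point, dtype=np.float64)
    f = wall_force(p, geometry, ff)
    if is_active:
        a, b, c = geometry.axes
        if geometry.kind == "sphere":
            r = float(np.linalg.norm(p))
            if r == 0:
                return f
            s = r - geometry.R0
            pq = (s / r) * p  # p - (nearest surface point)
        else:
            qx, qy, qz, s, ok = _kernels.ellipsoid_nearest(a, b, c, p[0], p[1], p[2])
            if not ok:
                raise RuntimeError(f"ellipsoid nearest-point solve failed for point {p}")
            pq = p - np.array([qx, qy, qz])
        f = f - ff.eps_ne / ff.lambda_ne**2 * math.exp(-(s**2) / (2 * ff.lambda_ne**2)) * pq
    return f


# ---------------------------------------------------------------------------
# System-level force assembly
# ---------------------------------------------------------------------------


def _bond_arrays(table: MonomerTable, loops, ff: ForceField):
    bi, bj = table.backbone_bonds()
    bk = np.full(len(bi), ff.k_bond, dtype=np.float64)
    if loops is not None and len(loops):
        bi = np.concatenate([bi, loops.i])
        bj = np.concatenate([bj, loops.j])
        bk = np.concatenate([bk, loops.k_spring])
    return bi.astype(np.int64), bj.astype(np.int64), bk


def _check_finite(positions: np.ndarray) -> None:
    bad = np.nonzero(~np.isfinite(positions).all(axis=1))[0]
    if len(bad):
        raise ValueError(f"non-finite coordinates for monomer id {int(bad[0])}")


def total_forces(
    positions: np.ndarray,
    table: MonomerTable,
    loops,
    geometry: Geometry,
    ff: ForceField,
    ne_on: bool = False,
    use_cells: bool = True,
) -> np.ndarray:
    """Per-monomer force vectors: bonds + loops + Gaussian core + wall (+ NE).

    Pairwise terms are cell-list accelerated by default and obey
    action-reaction exactly; set ``use_cells=False`` for the direct O(N^2)
    reference path.
    """
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    if positions.shape != (len(table), 3):
        raise ValueError("positions must be (N, 3) matching the monomer table")
    _check_finite(positions)
    bi, bj, bk = _bond_arrays(table, loops, ff)
    a, b, c = geometry.axes
    return _kernels.compute_forces(
        positions, bi, bj, bk, ff.r0, ff.V0, ff.sigma, ff.r_cut,
        geometry.kind_code, geometry.R0, a, b, c, ff.k_wall,
        ne_on, ff.eps_ne, ff.lambda_ne,
        np.ascontiguousarray(table.is_active),
        use_cells,
        _kernels.make_exp_table(ff.sigma, ff.r_cut),
    )


def total_forces_direct(
    positions: np.ndarray,
    table: MonomerTable,
    loops,
    geometry: Geometry,
    ff: ForceField,
    ne_on: bool = False,
) -> np.ndarray:
    """O(N^2) reference evaluation of :func:`total_forces`."""
    return total_forces(positions, table, loops, geometry, ff, ne_on, use_cells=False)


def total_energies(
    positions: np.ndarray,
    table: MonomerTable,
    loops,
    geometry: Geometry,
    ff: ForceField,
    ne_on: bool = False,
) -> dict[str, float]:
    """Energy breakdown (bond, pair, wall, ne) for run reports."""
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    _check_finite(positions)
    bi, bj, bk = _bond_arrays(table, loops, ff)
    a, b, c = geometry.axes
    e_bond, e_pair, e_wall, e_ne = _kernels.compute_energies(
        positions, bi, bj, bk, ff.r0, ff.V0, ff.sigma, ff.r_cut,
        geometry.kind_code, geometry.R0, a, b, c, ff.k_wall,
        ne_on, ff.eps_ne, ff.lambda_ne,
        np.ascontiguousarray(table.is_active),
    )
    return {"bond": e_bond, "pair": e_pair, "wall": e_wall, "ne": e_ne}
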