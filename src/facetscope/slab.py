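"""Periodic surface slabs for Miller planes.

For a plane (hkl) the minimal repeating surface unit is the primitive
basis (u, v) of the rank-2 sublattice of lattice vectors lying in the
plane, Lagrange–Gauss reduced so the u–v parallelogram has minimal area
(the reticular area, V_cell / d_hkl).  The slab thickness vector w is
the unit-cell body diagonal (extended when that is thinner than two
molecular layers), and the slab contains every whole molecule of the
tiled crystal whose centre of geometry falls in the half-open box.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .crystal_io import Crystal, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceSpec",
    "SlabBox",
    "Slab",
    "plane_lattice_basis",
    "d_spacing",
    "build_slab",
    "wrap_lateral",
]


def wrap_lateral(coords, u, v) -> np.ndarray:
    """Wrap points laterally into the base u–v tile (z untouched).

    u and v must lie in the z = 0 plane (slab frame).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float)).copy()
    B = np.array([[u[0], v[0]], [u[1], v[1]]])
    st = np.linalg.solve(B, coords[:, :2].T)
    st -= np.floor(st)
    coords[:, :2] = (B @ st).T
    return coords

#: tolerance used to snap centroid box coordinates onto the [0,1) boundary
SNAP = 1e-8


@dataclass(frozen=True)
class SurfaceSpec:
    """Miller plane (h, k, l) plus a termination offset in Å along the normal."""

    hkl: tuple
    offset: float = 0.0

    def __post_init__(self):
        h, k, l = (int(x) for x in self.hkl)
        if (h, k, l) == (0, 0, 0):
            raise ValueError("Miller indices (0,0,0) do not define a plane")
        g = math.gcd(math.gcd(abs(h), abs(k)), abs(l))
        object.__setattr__(self, "hkl", (h // g, k // g, l // g))


def d_spacing(cell, hkl) -> float:
    """Interplanar spacing d_hkl from the reciprocal metric (Å)."""
    h, k, l = hkl
    if (h, k, l) == (0, 0, 0):
        raise ValueError("Miller indices (0,0,0) do not define a plane")
    g = cell.reciprocal_matrix @ np.array([h, k, l], dtype=float)
    return 1.0 / float(np.linalg.norm(g))


def plane_normal(cell, hkl) -> np.ndarray:
    """Outward unit normal of (hkl): direction of h a* + k b* + l c*."""
    g = cell.reciprocal_matrix @ np.array(hkl, dtype=float)
    return g / np.linalg.norm(g)


def _integer_plane_basis(hkl) -> tuple[np.ndarray, np.ndarray]:
    """Primitive integer basis of {p in Z^3 : h p1 + k p2 + l p3 = 0}."""
    h, k, l = (int(x) for x in hkl)
    if (k, l) == (0, 0):
        # plane normal along a*; reduced hkl means h = +/-1
        return np.array([0, 1, 0]), np.array([0, 0, 1])
    d = math.gcd(abs(k), abs(l))
    v1 = np.array([0, l // d, -k // d])
    # alpha*k + beta*l = d  (extended Euclid)
    alpha, beta = _bezout(k, l, d)
    v2 = np.array([-d, h * alpha, h * beta])
    # invariant: v1 x v2 == (h, k, l), hence the basis is primitive
    assert tuple(np.cross(v1, v2)) == (h, k, l)
    return v1, v2


def _bezout(k: int, l: int, d: int) -> tuple[int, int]:
    a, b = abs(k), abs(l)
    x0, x1, y0, y1 = 1, 0, 0, 1
    while b:
        q, a, b = a // b, b, a % b
        x0, x1 = x1, x0 - q * x1
        y0, y1 = y1, y0 - q * y1
    # a == gcd, k*x0*sgn(k) + l*y0*sgn(l) == gcd
    alpha = x0 * (1 if k >= 0 else -1)
    beta = y0 * (1 if l >= 0 else -1)
    assert k * alpha + l * beta == d
    return alpha, beta


def plane_lattice_basis(cell, hkl) -> tuple[np.ndarray, np.ndarray]:
    """Minimal-area in-plane lattice vectors (u, v) in Cartesian Å.

    (u, v) generate the full in-plane sublattice, are Lagrange–Gauss
    reduced (|u| <= |v|, |u.v| <= |u|^2 / 2) and oriented so u x v points
    along the outward plane normal.
    """
    if tuple(int(x) for x in hkl) == (0, 0, 0):
        raise ValueError("Miller indices (0,0,0) do not define a plane")
    f1, f2 = _integer_plane_basis(hkl)
    M = cell.matrix
    u, v = M @ f1.astype(float), M @ f2.astype(float)
    # Lagrange–Gauss reduction in the Euclidean metric
    while True:
        if np.dot(u, u) > np.dot(v, v):
            u, v = v, u
        t = round(np.dot(u, v) / np.dot(u, u))
        if t == 0:
            break
        v = v - t * u
    n = plane_normal(cell, hkl)
    if np.dot(np.cross(u, v), n) < 0:
        v = -v
    return u, v


@dataclass
class SlabBox:
    """Parallelepiped spanned by u, v (in-plane) and w (thickness), Cartesian Å."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    origin: np.ndarray
    normal: np.ndarray

    @property
    def projected_area(self) -> float:
        """Reticular area |u x v| (Å²)."""
        return float(np.linalg.norm(np.cross(self.u, self.v)))

    @property
    def thickness(self) -> float:
        return float(np.dot(self.w, self.normal))

    @property
    def span_matrix(self) -> np.ndarray:
        return np.column_stack([self.u, self.v, self.w])


@dataclass
class Slab:
    """Molecules of the tiled crystal inside one periodic surface box.

    Coordinates are in the slab frame: outward normal along +z, box origin
    at (0,0,0), surface (top face) plane at z = w·n̂.
    """

    spec: SurfaceSpec
    box: SlabBox
    molecules: list
    source: Crystal

    @property
    def atoms(self) -> list:
        """Flat list of AtomSite across molecules (stable order)."""
        return [a for m in self.molecules for a in m.atoms]

    def atom_coords(self) -> np.ndarray:
        return np.array([a.cart_xyz for a in self.atoms])

    def atom_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def surface_z(self) -> float:
        return self.box.thickness


def _molecule_extent_along(crystal: Crystal, n: np.ndarray) -> float:
    ext = 0.0
    for m in crystal.molecules:
        z = np.array([np.dot(a.cart_xyz, n) for a in m.atoms])
        ext = max(ext, float(z.max() - z.min()) if len(z) > 1 else 0.0)
    return ext


def build_slab(crystal: Crystal, spec: SurfaceSpec, min_layers: int = 2) -> Slab:
    """Build the periodic slab for ``spec`` (Å offset along the outward normal).

    The thickness vector is the cell body diagonal a+b+c (sign-flipped to
    point along the outward normal; extended by integer multiples when
    thinner than ``min_layers`` molecular extents).  Molecules are selected
    by their centre of geometry with half-open [0,1) box coordinates, then
    re-expressed in a frame with the outward normal along +z.
    """
    cell = crystal.cell
    hkl = spec.hkl
    n = plane_normal(cell, hkl)
    u, v = plane_lattice_basis(cell, hkl)
    d = d_spacing(cell, hkl)

    w = cell.matrix @ np.array([1.0, 1.0, 1.0])
    if abs(np.dot(w, n)) < 1e-9:
        # degenerate: body diagonal lies in the plane; fall back to d * normal
        # stacked to a comparable thickness
        w = n * max(d, np.linalg.norm(w))
    if np.dot(w, n) < 0:
        w = -w
    extent = _molecule_extent_along(crystal, n)
    mult = 1
    while np.dot(w * mult, n) < min_layers * max(extent, 1e-6):
        mult += 1
    if mult > 1:
        logger.info("slab thickness extended to %d body diagonals", mult)
        w = w * mult

    offset = spec.offset % d
    # top face (surface plane) sits at `offset` along the normal
    origin = n * (offset - np.dot(w, n))

    B = np.column_stack([u, v, w])
    Binv = np.linalg.inv(B)
    Mcell = cell.matrix
    corners_frac = np.array(
        [np.linalg.solve(Mcell, origin + i * u + j * v + k * w)
         for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    lo = np.floor(corners_frac.min(axis=0)).astype(int) - 1
    hi = np.ceil(corners_frac.max(axis=0)).astype(int) + 1

    selected: list[Molecule] = []
    for mol in crystal.molecules:
        c0 = mol.centroid
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    delta = Mcell @ np.array([i, j, k], dtype=float)
                    stq = Binv @ (c0 + delta - origin)
                    stq = np.where(np.abs(stq - np.round(stq)) < SNAP, np.round(stq), stq)
                    # lateral coordinates half-open [0,1); thickness coordinate
                    # top-inclusive (0,1] so a centroid exactly on the
                    # termination plane sits at the slab top, not its bottom copy
                    if (
                        stq[0] >= 0.0 and stq[0] < 1.0
                        and stq[1] >= 0.0 and stq[1] < 1.0
                        and stq[2] > 0.0 and stq[2] <= 1.0
                    ):
                        selected.append(mol.translated(delta))
    if not selected:
        raise ValueError(
            "no molecule centroid falls inside the slab box; "
            "increase min_layers to thicken the slab"
        )

    # rotate into the slab frame: e3 = normal, e1 along u
    e3 = n
    e1 = u / np.linalg.norm(u)
    e2 = np.cross(e3, e1)
    R = np.vstack([e1, e2, e3])

    def to_frame(p):
        return R @ (np.asarray(p, dtype=float) - origin)

    frame_mols = []
    for mol in selected:
        delta_mols = Molecule(
            [type(a)(a.element, a.label, a.frac_xyz, to_frame(a.cart_xyz),
                     a.vdw_radius, a.covalent_radius) for a in mol.atoms],
            list(mol.bonds),
        )
        frame_mols.append(delta_mols)

    box = SlabBox(
        u=R @ u, v=R @ v, w=R @ w,
        origin=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
    )
    return Slab(spec=spec, box=box, molecules=frame_mols, source=crystal)
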