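"""Crystal structures from CIF: cells, symmetry, bonds and whole molecules.

A :class:`Crystal` holds one unit cell's worth of *whole* molecules:
symmetry is expanded, bonds are perceived from covalent radii with
periodic (minimum-image) wrap, and molecules cut by the cell boundary are
completed by lattice translation so that every centre of geometry is
meaningful.  Centroids are unweighted means of atom positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "SymmetryOp",
    "AtomSite",
    "Bond",
    "Molecule",
    "Crystal",
    "load_radius_table",
    "default_radius_table",
    "perceive_bonds",
    "read_cif",
    "write_cif",
]

#: extra reach added to the sum of covalent radii when perceiving bonds (Å)
BOND_TOLERANCE = 0.4

#: two expanded sites closer than this are the same atom (special position)
DUPLICATE_TOLERANCE = 0.5


def load_radius_table(path) -> dict[str, float]:
    """Read a plain-text ``element  radius`` two-column table."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sym, r = line.split()
        table[sym] = float(r)
    return table


def _packaged_table(name: str) -> dict[str, float]:
    with resources.as_file(resources.files("facetscope.data") / name) as p:
        return load_radius_table(p)


def default_radius_table() -> dict[str, tuple[float, float]]:
    """Element -> (vdw, covalent) radii in Å (Bondi/Alvarez + Cordero)."""
    vdw = _packaged_table("vdw_radii.txt")
    cov = _packaged_table("covalent_radii.txt")
    return {el: (vdw[el], cov[el]) for el in vdw if el in cov}


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell; lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")

    @property
    def matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix (columns are a, b, c vectors)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        vfac = math.sqrt(max(0.0, 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * vfac / sg],
            ]
        )

    @property
    def inv_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.matrix)))

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """Columns are the reciprocal vectors a*, b*, c* (crystallographic, no 2π)."""
        return self.inv_matrix.T

    def to_cartesian(self, frac) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix.T

    def to_fractional(self, cart) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.inv_matrix.T


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operation in the fractional basis: x -> rot @ x + tran."""

    rot: tuple  # 3x3 nested tuple of ints
    tran: tuple  # 3 floats (fractions of the cell)

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymmetryOp":
        rot = tuple(tuple(int(round(v / gemmi.Op.DEN)) for v in row) for row in op.rot)
        tran = tuple(v / gemmi.Op.DEN for v in op.tran)
        return cls(rot, tran)

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @property
    def rot_array(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    def apply(self, frac) -> np.ndarray:
        return self.rot_array @ np.asarray(frac, dtype=float) + np.asarray(self.tran)


@dataclass
class AtomSite:
    element: str
    label: str
    frac_xyz: np.ndarray
    cart_xyz: np.ndarray
    vdw_radius: float
    covalent_radius: float


@dataclass(frozen=True)
class Bond:
    """Bond i-j; ``shift`` is the lattice translation applied to j's cell copy."""

    i: int
    j: int
    shift: tuple = (0, 0, 0)
    order: float = 1.0
    aromatic: bool = False


@dataclass
class Molecule:
    atoms: list  # of AtomSite, Cartesian coordinates unwrapped (whole molecule)
    bonds: list  # of Bond (indices into ``atoms``; shifts resolved, i.e. (0,0,0))

    @property
    def centroid(self) -> np.ndarray:
        return np.mean([a.cart_xyz for a in self.atoms], axis=0)

    def translated(self, delta) -> "Molecule":
        delta = np.asarray(delta, dtype=float)
        atoms = [
            AtomSite(a.element, a.label, a.frac_xyz.copy(), a.cart_xyz + delta,
                     a.vdw_radius, a.covalent_radius)
            for a in self.atoms
        ]
        return Molecule(atoms, list(self.bonds))


@dataclass
class Crystal:
    cell: UnitCell
    symmetry: list  # of SymmetryOp
    molecules: list  # of Molecule, whole, one cell's worth
    space_group_label: str = "P 1"

    @property
    def n_atoms(self) -> int:
        return sum(len(m.atoms) for m in self.molecules)


# ---------------------------------------------------------------------------
# bond perception

_NEIGHBOR_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
)


def perceive_bonds(atoms, cell: UnitCell, tolerance: float = BOND_TOLERANCE):
    """Periodic covalent-radius bond perception.

    Atoms i, j bond when some minimum-image distance is at most
    ``cov_i + cov_j + tolerance``.  H–H pairs never bond.  Returns a list
    of :class:`Bond` whose ``shift`` is the lattice image of j used.
    """
    n = len(atoms)
    if n == 0:
        return []
    frac = np.array([a.frac_xyz for a in atoms], dtype=float)
    cov = np.array([a.covalent_radius for a in atoms])
    is_h = np.array([a.element == "H" for a in atoms])
    M = cell.matrix
    bonds = []
    degree = np.zeros(n, dtype=int)
    for i in range(n):
        diff = frac[np.newaxis, i] - frac  # j -> i in fractional space
        base = np.round(diff)
        # search the 27 neighbouring images around the rounded offset
        for shift in _NEIGHBOR_SHIFTS:
            d_frac = diff - (base + shift)  # = frac_i - (frac_j + image)
            d_cart = d_frac @ M.T
            dist = np.linalg.norm(d_cart, axis=1)
            cut = cov[i] + cov + tolerance
            hits = np.where((dist <= cut) & (dist > 1e-6))[0]
            for j in hits:
                if is_h[i] and is_h[j]:
                    continue
                if j < i or (j == i):
                    continue
                img = tuple(int(x) for x in (base[j] + shift))
                bonds.append(Bond(i, int(j), img))
    # deduplicate identical (i, j, shift) from overlapping image search
    bonds = sorted(set(bonds), key=lambda b: (b.i, b.j, b.shift))
    for b in bonds:
        degree[b.i] += 1
        degree[b.j] += 1
    if np.any(degree > 8):
        k = int(np.argmax(degree))
        raise ValueError(
            f"atom {atoms[k].label} has {degree[k]} bonds; geometry looks corrupt"
        )
    return bonds


def _assemble_molecules(atoms, bonds, cell: UnitCell):
    """Group bonded atoms and unwrap across periodic boundaries (BFS)."""
    n = len(atoms)
    adj: dict[int, list] = {i: [] for i in range(n)}
    for b in bonds:
        adj[b.i].append((b.j, np.array(b.shift)))
        adj[b.j].append((b.i, -np.array(b.shift)))
    seen = [False] * n
    molecules = []
    for start in range(n):
        if seen[start]:
            continue
        shifts = {start: np.zeros(3)}
        order = [start]
        seen[start] = True
        queue = [start]
        while queue:
            cur = queue.pop(0)
            for nxt, sh in adj[cur]:
                if not seen[nxt]:
                    seen[nxt] = True
                    shifts[nxt] = shifts[cur] + sh
                    order.append(nxt)
                    queue.append(nxt)
        mol_atoms = []
        index_of = {g: k for k, g in enumerate(order)}
        for g in order:
            a = atoms[g]
            frac = a.frac_xyz + shifts[g]
            mol_atoms.append(
                AtomSite(a.element, a.label, frac, cell.to_cartesian(frac),
                         a.vdw_radius, a.covalent_radius)
            )
        mol_bonds = []
        for b in bonds:
            if b.i in index_of and b.j in index_of:
                expected = shifts[b.i] + np.array(b.shift)
                if np.allclose(expected, shifts[b.j]):
                    mol_bonds.append(Bond(index_of[b.i], index_of[b.j]))
        if len(mol_atoms) == 1:
            warnings.warn(
                f"atom {mol_atoms[0].label} has no bonds; kept as a single-atom molecule"
            )
        molecules.append(Molecule(mol_atoms, mol_bonds))
    return molecules


# ---------------------------------------------------------------------------
# CIF reading / writing

_SYMOP_TAGS = (
    "_symmetry_equiv_pos_as_xyz",
    "_space_group_symop_operation_xyz",
)
_SG_NAME_TAGS = (
    "_symmetry_space_group_name_H-M",
    "_space_group_name_H-M_alt",
)


def _read_symmetry(block) -> tuple[list, str]:
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        triplets = list(col)
        if not triplets:
            val = block.find_value(tag)
            if val:
                triplets = [val]
        if triplets:
            ops = [SymmetryOp.from_gemmi(gemmi.Op(gemmi.cif.as_string(t))) for t in triplets]
            label = block.find_value(_SG_NAME_TAGS[0]) or block.find_value(_SG_NAME_TAGS[1])
            label = gemmi.cif.as_string(label) if label else "P 1"
            return ops, label
    for tag in _SG_NAME_TAGS:
        val = block.find_value(tag)
        if val:
            name = gemmi.cif.as_string(val)
            sg = gemmi.SpaceGroup(name)
            ops = [SymmetryOp.from_gemmi(op) for op in sg.operations()]
            return ops, name
    return [SymmetryOp.identity()], "P 1"


def _strip_label(label: str) -> str:
    """'C12A' -> element guess from leading letters ('C' here, 'Cl' for 'Cl1')."""
    head = ""
    for ch in label:
        if ch.isalpha():
            head += ch
        else:
            break
    if len(head) >= 2 and head[:2].capitalize() in _KNOWN_ELEMENTS:
        return head[:2].capitalize()
    return head[:1].upper()


_KNOWN_ELEMENTS = {
    "He", "Li", "Be", "Ne", "Na", "Mg", "Al", "Si", "Cl", "Ar", "Ca",
    "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Xe",
}


def read_cif(path, radius_table=None, bond_tolerance: float = BOND_TOLERANCE) -> Crystal:
    """Read a CIF into a symmetry-expanded, bond-perceived :class:`Crystal`.

    Molecules cut by the cell boundary are completed by lattice translation.
    Atom ordering is deterministic: by (site label, symmetry-op index).
    """
    radius_table = radius_table or default_radius_table()
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    cell_vals = {}
    for key in ("a", "b", "c", "alpha", "beta", "gamma"):
        raw = block.find_value(f"_cell_length_{key}") or block.find_value(f"_cell_angle_{key}")
        if raw is None:
            raise ValueError(f"CIF {path} is missing _cell_*_{key}")
        cell_vals[key] = gemmi.cif.as_number(raw)
    cell = UnitCell(**cell_vals)

    ops, sg_label = _read_symmetry(block)

    labels = [gemmi.cif.as_string(v) for v in block.find_loop("_atom_site_label")]
    if not labels:
        raise ValueError(f"CIF {path} has no atom sites")
    symbols = [gemmi.cif.as_string(v) for v in block.find_loop("_atom_site_type_symbol")]
    if len(symbols) != len(labels):
        symbols = [_strip_label(lab) for lab in labels]
    fx = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_fract_x")]
    fy = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_fract_y")]
    fz = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_fract_z")]

    asym = sorted(zip(labels, symbols, fx, fy, fz), key=lambda t: t[0])

    expanded = []
    for lab, sym, x, y, z in asym:
        sym = sym.strip().capitalize() if len(sym) > 1 else sym.strip().upper()
        # strip oxidation-state suffixes such as 'O2-'
        sym = "".join(ch for ch in sym if ch.isalpha()).capitalize()
        if sym not in radius_table:
            raise ValueError(f"unknown element symbol '{sym}' (site {lab})")
        vdw, cov = radius_table[sym]
        for op_idx, op in enumerate(ops):
            frac = op.apply((x, y, z)) % 1.0
            expanded.append((lab, op_idx, sym, frac, vdw, cov))

    # drop duplicates from special positions (distance < DUPLICATE_TOLERANCE)
    kept = []
    kept_frac = []
    M = cell.matrix
    for lab, op_idx, sym, frac, vdw, cov in expanded:
        dup = False
        for f2 in kept_frac:
            d = frac - f2
            d -= np.round(d)
            if np.linalg.norm(M @ d) < DUPLICATE_TOLERANCE:
                dup = True
                break
        if dup:
            continue
        kept.append((lab, op_idx, sym, frac, vdw, cov))
        kept_frac.append(frac)

    atoms = [
        AtomSite(sym, f"{lab}_{op_idx}" if len(ops) > 1 else lab,
                 np.asarray(frac), cell.to_cartesian(frac), vdw, cov)
        for lab, op_idx, sym, frac, vdw, cov in kept
    ]
    bonds = perceive_bonds(atoms, cell, bond_tolerance)
    molecules = _assemble_molecules(atoms, bonds, cell)
    return Crystal(cell, ops, molecules, sg_label)


def write_cif(crystal: Crystal, path) -> None:
    """Write the crystal as a P1 CIF (all molecules, fractional coordinates)."""
    if not crystal.molecules:
        raise ValueError("refusing to write an empty Crystal")
    c = crystal.cell
    lines = [
        "data_facetscope",
        f"_cell_length_a {c.a:.6f}",
        f"_cell_length_b {c.b:.6f}",
        f"_cell_length_c {c.c:.6f}",
        f"_cell_angle_alpha {c.alpha:.6f}",
        f"_cell_angle_beta {c.beta:.6f}",
        f"_cell_angle_gamma {c.gamma:.6f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "x,y,z",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    k = 0
    for mol in crystal.molecules:
        for a in mol.atoms:
            frac = c.to_fractional(a.cart_xyz)
            lines.append(
                f"{a.element}{k + 1} {a.element} {frac[0]:.6f} {frac[1]:.6f} {frac[2]:.6f}"
            )
            k += 1
    Path(path).write_text("\n".join(lines) + "\n")
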