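"""Surface chemistry descriptors for a slab.

Counts hydrogen-bond donors/acceptors/unsatisfied donors and aromatic
bonds among *surface* atoms per projected area, sums Ertl fragment
contributions (TPSA) and PEOE (Gasteiger) partial charges over surface
atoms, and detects surface-terminating functional groups with a
configurable substructure-query library.

Molecular perception (bond orders, aromaticity, hybridization) is
delegated to RDKit; the PEOE charge iteration itself is implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdDetermineBonds, rdMolDescriptors
from rdkit.Geometry import Point3D

from .crystal_io import Molecule
from .slab import Slab

__all__ = [
    "HBondCriteria",
    "FacetChemistry",
    "GroupQuery",
    "load_group_library",
    "to_rdkit",
    "find_hbonds",
    "surface_hb_counts",
    "densities",
    "gasteiger_charges",
    "surface_tgc",
    "surface_tpsa",
    "find_surface_groups",
    "facet_chemistry",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond rule: D-H...A with H...A within the vdW sum.

    Defaults follow common crystallographic practice: donors N and O that
    carry a hydrogen, acceptors N, O, S and F, and a D-H...A angle of at
    least 120 degrees.
    """

    donor_elements: frozenset = frozenset({"N", "O"})
    acceptor_elements: frozenset = frozenset({"N", "O", "S", "F"})
    min_dha_angle: float = 120.0
    vdw_margin: float = 0.0

    def __post_init__(self):
        if not (90.0 < self.min_dha_angle <= 180.0):
            raise ValueError("min_dha_angle must lie in (90, 180]")
        if not self.donor_elements or not self.acceptor_elements:
            raise ValueError("element sets must be non-empty")


@dataclass
class FacetChemistry:
    """All per-facet chemistry scalars (densities per projected Å²)."""

    density_hbd: float
    density_hba: float
    density_unsat_hbd: float
    density_aromatic_bonds: float
    tpsa: float
    total_gasteiger_charge: float
    tgc_per_area: float
    functional_groups: list  # of (name, count)

    def as_dict(self) -> dict:
        return {
            "density_hbd": self.density_hbd,
            "density_hba": self.density_hba,
            "density_unsat_hbd": self.density_unsat_hbd,
            "density_aromatic_bonds": self.density_aromatic_bonds,
            "tpsa": self.tpsa,
            "total_gasteiger_charge": self.total_gasteiger_charge,
            "tgc_per_area": self.tgc_per_area,
            "functional_groups": [list(t) for t in self.functional_groups],
        }


@dataclass(frozen=True)
class GroupQuery:
    name: str
    smarts: str

    @property
    def pattern(self):
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"malformed SMARTS for group '{self.name}': {self.smarts}")
        return patt


def load_group_library(path=None) -> list[GroupQuery]:
    """Load a functional-group query library (JSON), default the shipped one."""
    if path is None:
        data = (resources.files("facetscope.data") / "group_library.json").read_text()
    else:
        data = open(path).read()
    raw = json.loads(data)
    queries = [GroupQuery(g["name"], g["smarts"]) for g in raw["groups"]]
    names = [q.name for q in queries]
    if len(set(names)) != len(names):
        raise ValueError("group names must be unique in the library")
    for q in queries:
        q.pattern  # validates at load time
    return queries


# ---------------------------------------------------------------------------
# RDKit bridge

def to_rdkit(molecule: Molecule, charge: int = 0):
    """RDKit Mol (bond orders, aromaticity perceived) from a Molecule.

    Connectivity comes from the crystal's perceived bonds; bond orders are
    assigned from the 3-D geometry.  Falls back to all-single bonds with a
    warning when order assignment fails.
    """
    rw = Chem.RWMol()
    for a in molecule.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    conf = Chem.Conformer(rw.GetNumAtoms())
    for i, a in enumerate(molecule.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.cart_xyz)))
    rw.AddConformer(conf)
    for b in molecule.bonds:
        rw.AddBond(b.i, b.j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    try:
        rdDetermineBonds.DetermineBondOrders(mol, charge=charge)
        Chem.SanitizeMol(mol)
    except Exception:
        warnings.warn("bond-order assignment failed; keeping single bonds")
        for at in mol.GetAtoms():
            at.SetNoImplicit(True)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return mol


@dataclass
class _SlabChemInfo:
    rdkit_mols: list
    offsets: list  # flat index of first atom of each molecule


def _annotate(slab: Slab) -> _SlabChemInfo:
    mols, offsets, k = [], [], 0
    for m in slab.molecules:
        offsets.append(k)
        mols.append(to_rdkit(m))
        k += len(m.atoms)
    return _SlabChemInfo(mols, offsets)


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBond:
    donor: int      # flat atom indices into slab.atoms
    hydrogen: int
    acceptor: int
    image: tuple    # (i, j) lattice shift of the acceptor in u, v


def _lateral_fracs(slab: Slab, coords: np.ndarray) -> np.ndarray:
    u, v = slab.box.u, slab.box.v
    B = np.array([[u[0], v[0]], [u[1], v[1]]])
    return np.linalg.solve(B, coords[:, :2].T).T


def find_hbonds(slab: Slab, criteria: HBondCriteria = HBondCriteria()) -> list:
    """All intra-slab D-H...A triples, periodic images in u and v included."""
    atoms = slab.atoms
    coords = slab.atom_coords()
    elements = [a.element for a in atoms]
    vdw = slab.atom_radii()
    u, v = slab.box.u.copy(), slab.box.v.copy()
    u[2] = v[2] = 0.0

    # molecule id and bonded-pairs set, in flat indexing
    mol_id = np.zeros(len(atoms), dtype=int)
    bonded: set[tuple[int, int]] = set()
    k = 0
    for mi, m in enumerate(slab.molecules):
        mol_id[k:k + len(m.atoms)] = mi
        for b in m.bonds:
            bonded.add((k + b.i, k + b.j))
            bonded.add((k + b.j, k + b.i))
        k += len(m.atoms)

    dh_pairs = sorted({
        (d, h) for d, h in bonded
        if elements[d] in criteria.donor_elements and elements[h] == "H"
    })
    acceptors = [i for i, el in enumerate(elements) if el in criteria.acceptor_elements]
    if not any(el == "H" for el in elements):
        warnings.warn("structure has no hydrogens; zero donors")
        return []

    st = _lateral_fracs(slab, coords)
    out = []
    for d, h in dh_pairs:
        for a_idx in acceptors:
            base = np.round(st[h] - st[a_idx])
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    img = base + (di, dj)
                    a_pos = coords[a_idx] + img[0] * u + img[1] * v
                    if (a_idx == d or (h, a_idx) in bonded) and img[0] == 0 and img[1] == 0:
                        continue
                    ha = a_pos - coords[h]
                    dist = np.linalg.norm(ha)
                    if dist < 1e-6 or dist > vdw[h] + vdw[a_idx] + criteria.vdw_margin:
                        continue
                    hd = coords[d] - coords[h]
                    cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * dist)
                    angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if angle >= criteria.min_dha_angle:
                        out.append(HBond(d, h, a_idx, (int(img[0]), int(img[1]))))
    return out


def aromatic_bond_pairs(slab: Slab, info: _SlabChemInfo | None = None) -> list:
    """Flat-index pairs of atoms joined by an aromatic bond."""
    info = info or _annotate(slab)
    pairs = []
    for off, mol in zip(info.offsets, info.rdkit_mols):
        for b in mol.GetBonds():
            if b.GetIsAromatic():
                pairs.append((off + b.GetBeginAtomIdx(), off + b.GetEndAtomIdx()))
    return pairs


def surface_hb_counts(slab: Slab, surface_atoms: set, hbonds: list,
                      info: _SlabChemInfo | None = None,
                      criteria: HBondCriteria = HBondCriteria()):
    """(n_hbd, n_hba, n_unsat_hbd, n_aromatic_bonds) per u-v tile.

    A donor is exposed only when its hydrogen is itself a surface atom; an
    acceptor counts when the accepting atom is a surface atom; an aromatic
    bond counts when both of its atoms are surface atoms.
    """
    atoms = slab.atoms
    elements = [a.element for a in atoms]
    mol_bonded: set[tuple[int, int]] = set()
    k = 0
    for m in slab.molecules:
        for b in m.bonds:
            mol_bonded.add((k + b.i, k + b.j))
            mol_bonded.add((k + b.j, k + b.i))
        k += len(m.atoms)

    dh_pairs = sorted({
        (d, h) for d, h in mol_bonded
        if elements[d] in criteria.donor_elements and elements[h] == "H"
    })
    h_in_bond = {hb.hydrogen for hb in hbonds}

    exposed_dh = [(d, h) for d, h in dh_pairs if h in surface_atoms]
    n_hbd = len(exposed_dh)
    n_unsat = sum(1 for d, h in exposed_dh if h not in h_in_bond)
    n_hba = sum(
        1 for i, el in enumerate(elements)
        if el in criteria.acceptor_elements and i in surface_atoms
    )
    arom = aromatic_bond_pairs(slab, info)
    n_arom = sum(1 for i, j in arom if i in surface_atoms and j in surface_atoms)
    return n_hbd, n_hba, n_unsat, n_arom


def densities(counts, projected_area: float):
    """Per-area densities (counts / projected Å²)."""
    if projected_area <= 0:
        raise ValueError("projected area must be positive")
    return tuple(c / projected_area for c in counts)


# ---------------------------------------------------------------------------
# PEOE (Gasteiger) charges

# Orbital electronegativity coefficients chi(q) = a + b q + c q^2 per
# element and hybridization (sigma framework).
_PEOE_PARAMS = {
    ("H", "*"): (7.17, 6.24, -0.56),
    ("C", "SP3"): (7.98, 9.18, 1.88),
    ("C", "SP2"): (8.79, 9.32, 1.51),
    ("C", "SP"): (10.39, 9.45, 0.73),
    ("N", "SP3"): (11.54, 10.82, 1.36),
    ("N", "SP2"): (12.87, 11.15, 0.85),
    ("N", "SP"): (15.68, 11.70, -0.27),
    ("O", "SP3"): (14.18, 12.92, 1.39),
    ("O", "SP2"): (17.07, 13.79, 0.47),
    ("F", "*"): (14.66, 13.85, 2.31),
    ("Cl", "*"): (11.00, 9.69, 1.35),
    ("Br", "*"): (10.08, 8.47, 1.16),
    ("I", "*"): (9.90, 7.96, 0.96),
    ("S", "*"): (10.14, 9.13, 1.38),
}
#: hydrogen's cation electronegativity is special-cased in the original scheme
_H_CATION_CHI = 20.02


def gasteiger_charges(molecule: Molecule, n_iterations: int = 6,
                      damping: float = 0.5, rdkit_mol=None) -> np.ndarray:
    """PEOE partial charges: iterative partial equalization of orbital
    electronegativity with geometrically damped transfers.

    Per iteration k (1-based) the charge moved across each bond is
    ``(chi_hi - chi_lo) / chi_plus(lo) * damping**k`` where ``chi_plus`` is
    the cation electronegativity of the less electronegative atom.
    Charges sum to the molecular formal charge.
    """
    mol = rdkit_mol if rdkit_mol is not None else to_rdkit(molecule)
    n = mol.GetNumAtoms()
    abc = np.empty((n, 3))
    for i, at in enumerate(mol.GetAtoms()):
        el = at.GetSymbol()
        hyb = str(at.GetHybridization())
        key = (el, "*") if (el, "*") in _PEOE_PARAMS else (el, hyb)
        if key not in _PEOE_PARAMS:
            # noble gases and unhybridised singletons carry no PEOE flow
            if at.GetDegree() == 0:
                abc[i] = (0.0, 1.0, 0.0)
                continue
            raise ValueError(f"no PEOE parameters for element {el} ({hyb})")
        abc[i] = _PEOE_PARAMS[key]
    chi_plus = abc.sum(axis=1)
    for i, at in enumerate(mol.GetAtoms()):
        if at.GetSymbol() == "H":
            chi_plus[i] = _H_CATION_CHI
    q = np.array([at.GetFormalCharge() for at in mol.GetAtoms()], dtype=float)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    for k in range(1, n_iterations + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        dq = np.zeros(n)
        for i, j in bonds:
            if chi[i] == chi[j]:
                continue
            lo, hi = (i, j) if chi[i] < chi[j] else (j, i)
            t = (chi[hi] - chi[lo]) / chi_plus[lo] * damping**k
            dq[lo] += t
            dq[hi] -= t
        q += dq
    return q


def surface_tgc(slab: Slab, surface_atoms: set, charges: np.ndarray):
    """(TGC, TGC / projected area): summed charge of surface atoms."""
    tgc = float(sum(charges[i] for i in surface_atoms))
    return tgc, tgc / _projected_area(slab)


def slab_charges(slab: Slab, info: _SlabChemInfo | None = None,
                 n_iterations: int = 6) -> np.ndarray:
    """Per-atom PEOE charges across all slab molecules (flat indexing)."""
    info = info or _annotate(slab)
    parts = [
        gasteiger_charges(m, n_iterations=n_iterations, rdkit_mol=rm)
        for m, rm in zip(slab.molecules, info.rdkit_mols)
    ]
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# TPSA

def surface_tpsa(slab: Slab, surface_atoms: set,
                 info: _SlabChemInfo | None = None) -> float:
    """Sum of Ertl polar-fragment contributions over surface atoms (Å²)."""
    info = info or _annotate(slab)
    total = 0.0
    for off, mol in zip(info.offsets, info.rdkit_mols):
        contribs = rdMolDescriptors._CalcTPSAContribs(mol)
        for i, c in enumerate(contribs):
            if c and (off + i) in surface_atoms:
                total += c
    return float(total)


# ---------------------------------------------------------------------------
# functional groups

def find_surface_groups(slab: Slab, surface_atoms: set, library=None,
                        info: _SlabChemInfo | None = None) -> list:
    """Surface-terminating functional groups as (name, count).

    Each symmetry-distinct atom mapping counts once; a group instance is
    surface terminating when at least one of its atoms is a surface atom.
    Contained smaller groups are reported alongside larger ones.
    """
    library = library if library is not None else load_group_library()
    if not library:
        raise ValueError("group library is empty")
    info = info or _annotate(slab)
    out = []
    for query in library:
        patt = query.pattern
        count = 0
        for off, mol in zip(info.offsets, info.rdkit_mols):
            for match in mol.GetSubstructMatches(patt, uniquify=True):
                if any((off + i) in surface_atoms for i in match):
                    count += 1
        if count:
            out.append((query.name, count))
    return out


def _projected_area(slab: Slab) -> float:
    return slab.box.projected_area


def facet_chemistry(slab: Slab, surface_atoms: set,
                    criteria: HBondCriteria = HBondCriteria(),
                    library=None, n_iterations: int = 6) -> FacetChemistry:
    """All chemistry descriptors of one facet in a single pass."""
    info = _annotate(slab)
    hbonds = find_hbonds(slab, criteria)
    counts = surface_hb_counts(slab, surface_atoms, hbonds, info, criteria)
    area = _projected_area(slab)
    d_hbd, d_hba, d_unsat, d_arom = densities(counts, area)
    charges = slab_charges(slab, info, n_iterations=n_iterations)
    tgc, tgc_area = surface_tgc(slab, surface_atoms, charges)
    tpsa = surface_tpsa(slab, surface_atoms, info)
    groups = find_surface_groups(slab, surface_atoms, library, info)
    return FacetChemistry(
        density_hbd=d_hbd,
        density_hba=d_hba,
        density_unsat_hbd=d_unsat,
        density_aromatic_bonds=d_arom,
        tpsa=tpsa,
        total_gasteiger_charge=tgc,
        tgc_per_area=tgc_area,
        functional_groups=groups,
    )
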