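"""Hydrogen bonds, densities, PEOE charges, TPSA and functional groups."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from facetscope import SurfaceSpec, build_slab
from facetscope import chemistry as chem
from facetscope.crystal_io import AtomSite, Bond, Molecule, default_radius_table
from facetscope.slab import Slab, SlabBox

RADII = default_radius_table()


def atom(element, xyz):
    vdw, cov = RADII[element]
    xyz = np.asarray(xyz, dtype=float)
    return AtomSite(element, element, xyz.copy(), xyz, vdw, cov)


def open_box_slab(molecules, a=20.0):
    """A roomy orthogonal box for hand-built geometries."""
    box = SlabBox(
        u=np.array([a, 0.0, 0.0]), v=np.array([0.0, a, 0.0]),
        w=np.array([0.0, 0.0, a]), origin=np.zeros(3),
        normal=np.array([0.0, 0.0, 1.0]),
    )
    return Slab(SurfaceSpec((0, 0, 1), 0.0), box, molecules, None)


def hydroxyl(origin, h_toward):
    """O-H group: O at origin, H 0.97 Å toward ``h_toward``."""
    origin = np.asarray(origin, dtype=float)
    d = np.asarray(h_toward, dtype=float) - origin
    d = d / np.linalg.norm(d)
    return Molecule([atom("O", origin), atom("H", origin + 0.97 * d)],
                    [Bond(0, 1)])


class TestFindHbonds:
    def test_linear_contact_at_1p8_is_a_bond(self):
        donor = hydroxyl((0, 0, 0), (1, 0, 0))
        acceptor = hydroxyl((0.97 + 1.8, 0, 0), (0.97 + 1.8 + 0.6, 0, 0.77))
        slab = open_box_slab([donor, acceptor])
        hbs = chem.find_hbonds(slab)
        assert len(hbs) == 1
        hb = hbs[0]
        assert (hb.donor, hb.hydrogen, hb.acceptor) == (0, 1, 2)

    def test_distant_pair_is_not_a_bond(self):
        donor = hydroxyl((0, 0, 0), (1, 0, 0))
        acceptor = hydroxyl((0.97 + 4.0, 0, 0), (0.97 + 4.6, 0, 0.77))
        slab = open_box_slab([donor, acceptor])
        assert chem.find_hbonds(slab) == []

    def test_catemer_every_donor_satisfied(self, catemer_crystal):
        slab = build_slab(catemer_crystal, SurfaceSpec((0, 0, 1), 0.0))
        hbs = chem.find_hbonds(slab)
        donors = {
            (off + b.i) if m.atoms[b.i].element != "H" else (off + b.j)
            for off, m in zip(_offsets(slab), slab.molecules)
            for b in m.bonds
            if {m.atoms[b.i].element, m.atoms[b.j].element} == {"O", "H"}
        }
        satisfied = {hb.donor for hb in hbs}
        assert donors and donors <= satisfied

    def test_catemer_matches_exhaustive_triple_enumeration(self, catemer_crystal):
        slab = build_slab(catemer_crystal, SurfaceSpec((0, 0, 1), 0.0))
        got = {(hb.donor, hb.hydrogen, hb.acceptor, hb.image)
               for hb in chem.find_hbonds(slab)}
        assert got == _brute_force_hbonds(slab)

    def test_toyacid_has_no_intra_slab_bond(self, toyacid_slab):
        assert chem.find_hbonds(toyacid_slab) == []


def _offsets(slab):
    offs, k = [], 0
    for m in slab.molecules:
        offs.append(k)
        k += len(m.atoms)
    return offs


def _brute_force_hbonds(slab, min_angle=120.0):
    """Independent triple loop over all D-H x A x lattice images."""
    atoms = slab.atoms
    coords = slab.atom_coords()
    u, v = slab.box.u.copy(), slab.box.v.copy()
    u[2] = v[2] = 0.0
    bonded = set()
    k = 0
    for m in slab.molecules:
        for b in m.bonds:
            bonded.add((k + b.i, k + b.j))
            bonded.add((k + b.j, k + b.i))
        k += len(m.atoms)
    out = set()
    for d, h in sorted(bonded):
        if atoms[d].element not in {"N", "O"} or atoms[h].element != "H":
            continue
        for a_idx, a in enumerate(atoms):
            if a.element not in {"N", "O", "S", "F"}:
                continue
            for i in range(-2, 3):
                for j in range(-2, 3):
                    if (i, j) == (0, 0) and (a_idx == d or (h, a_idx) in bonded):
                        continue
                    pos = coords[a_idx] + i * u + j * v
                    ha = pos - coords[h]
                    dist = np.linalg.norm(ha)
                    if dist < 1e-6 or dist > atoms[h].vdw_radius + a.vdw_radius:
                        continue
                    hd = coords[d] - coords[h]
                    cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * dist)
                    if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= min_angle:
                        out.add((d, h, a_idx, (i, j)))
    return out


class TestSurfaceCounts:
    def test_toyacid_one_unsatisfied_donor_per_tile(self, toyacid_slab, toyacid_surface):
        hbs = chem.find_hbonds(toyacid_slab)
        n_hbd, n_hba, n_unsat, n_arom = chem.surface_hb_counts(
            toyacid_slab, toyacid_surface, hbs)
        assert n_hbd == 1 and n_unsat == 1
        assert n_hba == 2  # both oxygens exposed
        assert n_arom == 0

    def test_flat_ring_six_aromatic_bonds(self, flatring_crystal):
        slab = build_slab(flatring_crystal, SurfaceSpec((0, 0, 1), 0.0))
        from facetscope.topology import classify_surface_atoms, compute_topology
        surface = classify_surface_atoms(slab, compute_topology(slab))
        _, _, _, n_arom = chem.surface_hb_counts(slab, surface, [])
        assert n_arom == 6

    def test_aromatic_bond_needs_both_atoms_on_surface(self, flatring_crystal):
        slab = build_slab(flatring_crystal, SurfaceSpec((0, 0, 1), 0.0))
        carbons = [i for i, a in enumerate(slab.atoms) if a.element == "C"]
        half = set(carbons[:3])  # pretend the other half is buried
        _, _, _, n_arom = chem.surface_hb_counts(slab, half, [])
        arom_pairs = chem.aromatic_bond_pairs(slab)
        expected = sum(1 for i, j in arom_pairs if i in half and j in half)
        assert n_arom == expected < 6

    def test_unsat_never_exceeds_donors(self, catemer_crystal):
        slab = build_slab(catemer_crystal, SurfaceSpec((0, 0, 1), 0.0))
        from facetscope.topology import classify_surface_atoms, compute_topology
        surface = classify_surface_atoms(slab, compute_topology(slab))
        hbs = chem.find_hbonds(slab)
        n_hbd, _, n_unsat, _ = chem.surface_hb_counts(slab, surface, hbs)
        assert n_unsat <= n_hbd


class TestDensities:
    def test_division(self):
        assert chem.densities((2, 4, 2, 16), 200.0) == (0.010, 0.020, 0.010, 0.080)

    def test_zero_counts(self):
        assert chem.densities((0, 0, 0, 0), 50.0) == (0, 0, 0, 0)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            chem.densities((1,), 0.0)

    def test_intensive_under_supercell_doubling(self, toyacid_crystal, tmp_path):
        """A 2x1 supercell leaves every density unchanged."""
        from facetscope import read_cif, write_cif
        from facetscope.crystal_io import Crystal, UnitCell
        c = toyacid_crystal
        doubled_cell = UnitCell(2 * c.cell.a, c.cell.b, c.cell.c, 90, 90, 90)
        mols = [m.translated((0, 0, 0)) for m in c.molecules]
        mols += [m.translated((c.cell.a, 0, 0)) for m in c.molecules]
        big = Crystal(doubled_cell, c.symmetry, mols)
        p = tmp_path / "double.cif"
        write_cif(big, p)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            big = read_cif(p)
        from facetscope.topology import classify_surface_atoms, compute_topology
        for crystal, n_expect in ((c, 1), (big, 2)):
            slab = build_slab(crystal, SurfaceSpec((0, 0, 1), 0.0))
            surface = classify_surface_atoms(slab, compute_topology(slab))
            hbs = chem.find_hbonds(slab)
            counts = chem.surface_hb_counts(slab, surface, hbs)
            assert counts[2] == n_expect  # unsat donors scale with the tile
            dens = chem.densities(counts, slab.box.projected_area)
            if n_expect == 1:
                base = dens
        assert np.allclose(dens, base, atol=1e-12)


class TestGasteigerCharges:
    def test_neutral_molecule_sums_to_zero(self, toyacid_crystal):
        q = chem.gasteiger_charges(toyacid_crystal.molecules[0])
        assert abs(q.sum()) < 1e-6

    def test_methane_symmetry(self):
        t = 1.09 / np.sqrt(3)
        mol = Molecule(
            [atom("C", (0, 0, 0)), atom("H", (t, t, t)), atom("H", (t, -t, -t)),
             atom("H", (-t, t, -t)), atom("H", (-t, -t, t))],
            [Bond(0, 1), Bond(0, 2), Bond(0, 3), Bond(0, 4)],
        )
        q = chem.gasteiger_charges(mol)
        assert np.allclose(q[1:], q[1], atol=1e-10)
        assert q[0] == pytest.approx(-4 * q[1], abs=1e-10)

    def test_matches_reference_peoe_implementation(self, toyacid_crystal):
        """Hydroxyl-H charge agrees with RDKit's PEOE at matched settings."""
        mol = toyacid_crystal.molecules[0]
        rd = chem.to_rdkit(mol)
        AllChem.ComputeGasteigerCharges(rd, nIter=6)
        ref = np.array([float(a.GetProp("_GasteigerCharge")) for a in rd.GetAtoms()])
        mine = chem.gasteiger_charges(mol, n_iterations=6, rdkit_mol=rd)
        assert np.abs(mine - ref).max() < 1e-3
        # the hydroxyl hydrogen is the most positive atom
        oh_h = [i for i, a in enumerate(mol.atoms) if a.element == "H"
                and any({mol.atoms[b.i].element, mol.atoms[b.j].element} == {"O", "H"}
                        and i in (b.i, b.j) for b in mol.bonds)][0]
        assert mine[oh_h] > 0.25

    def test_missing_parameters_name_the_element(self):
        si = Molecule([atom("Si", (0, 0, 0)), atom("H", (1.48, 0, 0))], [Bond(0, 1)])
        with pytest.raises(ValueError, match="Si"):
            chem.gasteiger_charges(si)

    def test_surface_tgc_all_exposed_neutral_is_zero(self, toyacid_slab):
        charges = chem.slab_charges(toyacid_slab)
        all_atoms = set(range(len(toyacid_slab.atoms)))
        tgc, _ = chem.surface_tgc(toyacid_slab, all_atoms, charges)
        assert abs(tgc) < 1e-6

    def test_surface_tgc_single_exposed_hydroxyl_h(self, toyacid_slab):
        charges = chem.slab_charges(toyacid_slab)
        mol = toyacid_slab.molecules[0]
        oh_h = next(
            i for b in mol.bonds for i in (b.i, b.j)
            if mol.atoms[i].element == "H"
            and {mol.atoms[b.i].element, mol.atoms[b.j].element} == {"O", "H"}
        )
        tgc, per_area = chem.surface_tgc(toyacid_slab, {oh_h}, charges)
        assert tgc == pytest.approx(charges[oh_h])
        assert tgc > 0
        assert per_area == pytest.approx(tgc / toyacid_slab.box.projected_area)

    def test_surface_tgc_matches_direct_sum(self, toyacid_slab, toyacid_surface):
        charges = chem.slab_charges(toyacid_slab)
        tgc, _ = chem.surface_tgc(toyacid_slab, toyacid_surface, charges)
        assert tgc == pytest.approx(sum(charges[i] for i in toyacid_surface), abs=1e-12)


class TestSurfaceTPSA:
    def test_hydrocarbon_surface_is_zero(self, flatring_crystal):
        slab = build_slab(flatring_crystal, SurfaceSpec((0, 0, 1), 0.0))
        assert chem.surface_tpsa(slab, set(range(len(slab.atoms)))) == 0.0

    def test_hydroxyl_plus_carbonyl_fragments(self, toyacid_slab):
        """Exposed O-H (20.23) and carbonyl O (17.07) sum to 37.30 Å²."""
        oxygens = {i for i, a in enumerate(toyacid_slab.atoms) if a.element == "O"}
        assert chem.surface_tpsa(toyacid_slab, oxygens) == pytest.approx(37.30, abs=0.01)

    def test_extensive_in_tile_intensive_per_area(self, toyacid_slab, toyacid_surface):
        tpsa = chem.surface_tpsa(toyacid_slab, toyacid_surface)
        assert tpsa == pytest.approx(37.30, abs=0.01)  # whole COOH exposed


class TestSurfaceGroups:
    def test_toyacid_carboxylic_acid_on_surface(self, toyacid_slab, toyacid_surface):
        groups = dict(chem.find_surface_groups(toyacid_slab, toyacid_surface))
        assert groups.get("uncharged carboxylic acid") == 1

    def test_buried_acid_absent_from_surface_groups(self, layered_crystal):
        slab = build_slab(layered_crystal, SurfaceSpec((0, 0, 1), 0.0))
        from facetscope.topology import classify_surface_atoms, compute_topology
        surface = classify_surface_atoms(slab, compute_topology(slab))
        groups = dict(chem.find_surface_groups(slab, surface))
        assert "uncharged carboxylic acid" not in groups
        assert groups.get("methyl") == 1

    def test_ibuprofen_whole_molecule_match_set(self):
        """The query library finds every group of the ibuprofen skeleton,
        with methyls inside the isopropyl counted separately."""
        mol = Chem.AddHs(Chem.MolFromSmiles("CC(C)Cc1ccc(cc1)C(C)C(=O)O"))
        counts = {}
        for q in chem.load_group_library():
            n = len(mol.GetSubstructMatches(q.pattern, uniquify=True))
            if n:
                counts[q.name] = n
        assert counts == {
            "methyl": 3,
            "i-propyl": 1,
            "aliphatic-aromatic methylene": 1,
            "tertiary C-H": 2,
            "uncharged carboxylic acid": 1,
        }

    def test_malformed_query_rejected_at_load(self, tmp_path):
        p = tmp_path / "lib.json"
        p.write_text('{"groups": [{"name": "bad", "smarts": "[[["}]}')
        with pytest.raises(ValueError, match="bad"):
            chem.load_group_library(p)

    def test_empty_library_rejected(self, toyacid_slab):
        with pytest.raises(ValueError):
            chem.find_surface_groups(toyacid_slab, {0}, [])


class TestFacetChemistry:
    def test_invariants_on_toyacid(self, toyacid_slab, toyacid_surface):
        fc = chem.facet_chemistry(toyacid_slab, toyacid_surface)
        assert fc.density_unsat_hbd <= fc.density_hbd
        assert fc.density_hbd >= 0 and fc.density_hba >= 0
        assert fc.tpsa >= 0
        assert fc.density_hba == pytest.approx(2 * fc.density_hbd)
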