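"""Deterministic synthetic crystal fixtures with hand-computable answers.

Each fixture is a small P1 molecular crystal designed so that one stage of
the surface analysis has a value that can be checked by construction:

* ``noble_cubic``  — one Ar-like atom in a cubic cell: pure geometry and
  topology (projected areas, sphere heights).
* ``toyacid``      — a formic-acid-like molecule in a rectangular cell with
  the hydroxyl hydrogen exposed on (001): surface chemistry, one
  unsatisfied donor per tile.
* ``catemer``      — the same molecule in a sheared cell whose b
  translation places the carbonyl oxygen exactly 1.9 Å from the hydroxyl
  hydrogen at a straight O-H...O angle: every donor satisfied.
* ``flatring``     — a benzene-like planar ring parallel to (001): six
  aromatic bonds per tile, all surface terminating.
* ``layered_polar`` — a carboxylic-acid layer buried beneath a methane
  layer: occlusion; the acid is absent from the (001) surface groups.

Geometry is exact and code-generated; ``seed`` is recorded for provenance
but the constructions are deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FIXTURE_KINDS = ("noble_cubic", "toyacid", "catemer", "flatring", "layered_polar")


@dataclass
class FixtureManifest:
    name: str
    cif_path: str
    seed: int
    expected: dict

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"name": self.name, "cif_path": self.cif_path, "seed": self.seed,
             "expected": self.expected}, indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "FixtureManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["name"], d["cif_path"], d["seed"], d["expected"])


def _cell_matrix(a, b, c, alpha, beta, gamma):
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
    return np.array([
        [a, b * cg, c * cb],
        [0, b * sg, c * (ca - cb * cg) / sg],
        [0, 0, c * v / sg],
    ])


def _write_p1_cif(path, cell, atoms) -> None:
    """atoms: list of (element, cartesian xyz); cell: (a,b,c,al,be,ga)."""
    M = _cell_matrix(*cell)
    Minv = np.linalg.inv(M)
    lines = [
        "data_fixture",
        f"_cell_length_a {cell[0]:.6f}",
        f"_cell_length_b {cell[1]:.6f}",
        f"_cell_length_c {cell[2]:.6f}",
        f"_cell_angle_alpha {cell[3]:.6f}",
        f"_cell_angle_beta {cell[4]:.6f}",
        f"_cell_angle_gamma {cell[5]:.6f}",
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
    for idx, (el, xyz) in enumerate(atoms):
        f = Minv @ np.asarray(xyz, dtype=float)
        lines.append(f"{el}{idx + 1} {el} {f[0]:.6f} {f[1]:.6f} {f[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _formic_acid(origin, updown: float = 1.0):
    """Formic-acid-like molecule in the xz plane; O-H tilted toward +z
    (updown=+1) or -z.  Returns [(element, xyz), ...]."""
    ox, oy, oz = origin
    s = updown
    atoms = [
        ("C", (ox, oy, oz)),
        ("O", (ox + 1.049, oy, oz - 0.605 * s)),            # C=O
        ("O", (ox, oy, oz + 1.34 * s)),                     # C-O(H)
        ("H", (ox - 0.944, oy, oz - 0.545 * s)),            # C-H
        ("H", (ox + 0.97 * math.sin(math.radians(74)), oy,
               oz + (1.34 + 0.97 * math.cos(math.radians(74))) * s)),  # O-H
    ]
    return atoms


def make_fixture(kind: str, seed: int = 0, out_dir=".") -> FixtureManifest:
    """Write ``<kind>.cif`` and ``<kind>_manifest.json`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind '{kind}'; known: {FIXTURE_KINDS}")
    cif = out_dir / f"{kind}.cif"

    if kind == "noble_cubic":
        cell = (5.0, 5.0, 5.0, 90.0, 90.0, 90.0)
        _write_p1_cif(cif, cell, [("Ar", (0.0, 0.0, 0.0))])
        expected = {
            "n_molecules": 1,
            "n_bonds": 0,
            "projected_area_001": 25.0,
            "sphere_top_above_surface": 1.88,  # vdW radius of Ar
        }

    elif kind == "toyacid":
        cell = (6.0, 5.0, 8.0, 90.0, 90.0, 90.0)
        _write_p1_cif(cif, cell, _formic_acid((3.0, 2.5, 4.0)))
        expected = {
            "n_molecules": 1,
            "n_bonds": 4,                     # C=O, C-O, O-H, C-H
            "projected_area_001": 30.0,
            "n_unsat_hbd_001": 1,             # exposed O-H, no intra-slab bond
            "n_hbonds": 0,
            "surface_groups_001": ["uncharged carboxylic acid"],
            "tpsa_fragments": {"hydroxyl": 20.23, "carbonyl": 17.07},
        }

    elif kind == "catemer":
        # shear b so the +b image of the carbonyl O sits exactly 1.9 Å from
        # the hydroxyl H along the O-H direction (angle 180 degrees)
        mol = [
            ("C", (2.0, 2.5, 4.0)),
            ("O", (2.0 - 0.605, 2.5 - 1.048, 4.0)),   # C=O
            ("O", (3.34, 2.5, 4.0)),                  # C-O(H)
            ("H", (2.0 - 0.545, 2.5 + 0.944, 4.0)),   # C-H
        ]
        oh_dir = np.array([math.cos(math.radians(74)), math.sin(math.radians(74)), 0.0])
        o2 = np.array(mol[2][1])
        h2 = o2 + 0.97 * oh_dir
        mol.append(("H", tuple(h2)))
        o1 = np.array(mol[1][1])
        b_vec = (h2 + 1.9 * oh_dir) - o1
        b_len = float(np.linalg.norm(b_vec))
        gamma = math.degrees(math.acos(b_vec[0] / b_len))
        cell = (7.5, b_len, 9.0, 90.0, 90.0, gamma)
        _write_p1_cif(cif, cell, mol)
        expected = {
            "n_molecules": 1,
            "n_bonds": 4,
            "hbond_ha_distance": 1.9,
            "hbond_dha_angle": 180.0,
            "every_donor_satisfied": True,
        }

    elif kind == "flatring":
        cell = (7.5, 7.5, 7.0, 90.0, 90.0, 90.0)
        atoms = []
        for i in range(6):
            ang = math.radians(60 * i)
            atoms.append(("C", (3.75 + 1.39 * math.cos(ang),
                                3.75 + 1.39 * math.sin(ang), 3.5)))
        for i in range(6):
            ang = math.radians(60 * i)
            atoms.append(("H", (3.75 + 2.47 * math.cos(ang),
                                3.75 + 2.47 * math.sin(ang), 3.5)))
        _write_p1_cif(cif, cell, atoms)
        expected = {
            "n_molecules": 1,
            "n_aromatic_bonds_001": 6,       # ring parallel to the surface
            "projected_area_001": 56.25,
        }

    elif kind == "layered_polar":
        # carboxylic acid buried under a close ethane layer: the widest
        # lateral clearance (tile centre, 2*sqrt(2) Å from the C columns)
        # is below the 1.7+1.2 Å carbon-to-probe-centre reach
        a = 4.0
        cell = (a, a, 13.0, 90.0, 90.0, 90.0)
        atoms = _formic_acid((2.0, 2.0, 3.0))
        ch = 1.09
        s3 = math.sin(math.radians(109.471))
        c3 = math.cos(math.radians(109.471))
        z1, z2 = 7.5, 7.5 + 1.54
        atoms.append(("C", (0.0, 0.0, z1)))
        atoms.append(("C", (0.0, 0.0, z2)))
        for phi in (0.0, 120.0, 240.0):   # lower tripod points down
            atoms.append(("H", (ch * s3 * math.cos(math.radians(phi)),
                                ch * s3 * math.sin(math.radians(phi)),
                                z1 + ch * c3)))
        for phi in (60.0, 180.0, 300.0):  # staggered upper tripod points up
            atoms.append(("H", (ch * s3 * math.cos(math.radians(phi)),
                                ch * s3 * math.sin(math.radians(phi)),
                                z2 - ch * c3)))
        _write_p1_cif(cif, cell, atoms)
        expected = {
            "n_molecules": 2,
            "surface_groups_001_absent": ["uncharged carboxylic acid"],
            "surface_groups_001_present": ["methyl"],
        }

    manifest = FixtureManifest(kind, str(cif), seed, expected)
    manifest.write(out_dir / f"{kind}_manifest.json")
    return manifest
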