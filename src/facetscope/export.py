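"""Plain-text export helpers: slabs as extended XYZ, meshes as OBJ,
heights as CSV, particle shapes as OFF."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def slab_to_xyz(slab, path) -> None:
    """Extended XYZ: element, Cartesian Å, molecule id."""
    lines = [str(sum(len(m.atoms) for m in slab.molecules)),
             f"slab hkl={slab.spec.hkl} offset={slab.spec.offset}"]
    for mid, mol in enumerate(slab.molecules):
        for a in mol.atoms:
            x, y, z = a.cart_xyz
            lines.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f} {mid}")
    Path(path).write_text("\n".join(lines) + "\n")


def mesh_to_obj(mesh, path) -> None:
    lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.nodes]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def heights_to_csv(mesh, path) -> None:
    lines = ["x,y,h"]
    for (x, y, _z), h in zip(mesh.nodes, mesh.heights):
        lines.append(f"{x:.6f},{y:.6f},{h:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def shape_to_off(shape, path) -> None:
    faces = [idx for _lab, idx in shape.faces]
    lines = ["OFF", f"{len(shape.vertices)} {len(faces)} 0"]
    lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in shape.vertices]
    lines += [f"{len(f)} " + " ".join(map(str, f)) for f in faces]
    Path(path).write_text("\n".join(lines) + "\n")
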