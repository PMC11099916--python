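"""Particle morphologies and facet-weighted particle descriptors.

A morphology is specified per {hkl} family by a perpendicular growth
distance; the particle is the Wulff-style intersection of half-spaces
n̂·x <= g over all symmetry mates of each family (Laue-group expansion:
the rotational parts of the space group plus inversion).  The facet
representation F_r of a family is its share of the particle surface area,
and a particle descriptor is the F_r-weighted average of per-area facet
descriptors — a convex combination of the facet values.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

import gemmi

from .crystal_io import UnitCell
from .slab import plane_normal

__all__ = [
    "MorphologySpec",
    "ParticleShape",
    "FacetRepresentation",
    "ParticleDescriptors",
    "expand_family",
    "wulff_shape",
    "facet_representation",
    "particle_descriptors",
    "read_morphology_cif",
    "family_label",
]


def family_label(hkl) -> str:
    return "{" + " ".join(str(int(x)) for x in hkl) + "}"


@dataclass
class MorphologySpec:
    """Per-family growth distances plus the cell/symmetry they refer to."""

    cell: UnitCell
    symmetry: list            # of SymmetryOp
    families: list            # of (hkl tuple, perpendicular distance)

    def __post_init__(self):
        for hkl, dist in self.families:
            if tuple(int(x) for x in hkl) == (0, 0, 0):
                raise ValueError("{0 0 0} is not a face family")
            if dist <= 0:
                raise ValueError("growth distances must be positive")


@dataclass
class ParticleShape:
    vertices: np.ndarray      # (n, 3)
    faces: list               # of (family label, vertex index list)
    family_areas: dict        # label -> total area
    total_area: float
    aspect_ratio: float


@dataclass
class FacetRepresentation:
    fractions: dict           # label -> F_r, sums to 1

    def __post_init__(self):
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"facet fractions sum to {s}, not 1")


@dataclass
class ParticleDescriptors:
    values: dict              # descriptor name -> weighted value


def expand_family(cell: UnitCell, symmetry, hkl) -> list:
    """Symmetry-equivalent plane normals of {hkl} under the Laue group.

    Miller indices transform with the inverse-transpose of the rotational
    part; inversion is always included (Friedel).  Duplicates are removed.
    """
    hkl = tuple(int(x) for x in hkl)
    if hkl == (0, 0, 0):
        raise ValueError("{0 0 0} is not a face family")
    rots = {tuple(map(tuple, op.rot)) for op in symmetry}
    laue = set()
    for r in rots:
        laue.add(r)
        laue.add(tuple(tuple(-x for x in row) for row in r))
    if len(laue) <= 2:
        warnings.warn("identity-only symmetry: family reduces to the plane and its Friedel mate")
    mates = set()
    v = np.array(hkl, dtype=float)
    for r in laue:
        m = np.linalg.inv(np.array(r, dtype=float)).T
        mate = m @ v
        mate_int = np.rint(mate).astype(int)
        assert np.allclose(mate, mate_int, atol=1e-9)
        mates.add(tuple(mate_int))
    return sorted(mates)


def _polygon_area(verts: np.ndarray, normal: np.ndarray) -> float:
    c = verts.mean(axis=0)
    total = np.zeros(3)
    # order vertices by angle around the centroid in the face plane
    ref = verts[0] - c
    ref /= np.linalg.norm(ref)
    other = np.cross(normal, ref)
    ang = np.arctan2((verts - c) @ other, (verts - c) @ ref)
    order = np.argsort(ang)
    pv = verts[order]
    for i in range(len(pv)):
        total += np.cross(pv[i] - c, pv[(i + 1) % len(pv)] - c)
    return 0.5 * float(np.linalg.norm(total)), order


def wulff_shape(spec: MorphologySpec) -> ParticleShape:
    """Intersection of half-spaces n̂·x <= g over all family mates."""
    normals, dists, labels = [], [], []
    for hkl, g in spec.families:
        lab = family_label(hkl)
        for mate in expand_family(spec.cell, spec.symmetry, hkl):
            normals.append(plane_normal(spec.cell, mate))
            dists.append(g)
            labels.append(lab)
    normals = np.array(normals)
    dists = np.array(dists, dtype=float)

    # boundedness: the normals must surround the origin
    try:
        hull_dirs = ConvexHull(normals)
    except QhullError as exc:
        raise ValueError(
            "half-space intersection is unbounded: face normals do not span "
            f"3-D ({exc.args[0].splitlines()[0] if exc.args else exc})"
        ) from exc
    if np.any(hull_dirs.equations[:, 3] > -1e-9):
        open_dirs = normals[np.unique(hull_dirs.simplices[hull_dirs.equations[:, 3] > -1e-9])]
        raise ValueError(
            "half-space intersection is unbounded; add faces covering "
            f"directions near {np.round(-hull_dirs.equations[:, :3][hull_dirs.equations[:, 3] > -1e-9], 3).tolist()}"
        )

    halfspaces = np.column_stack([normals, -dists])
    try:
        hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    except QhullError as exc:  # pragma: no cover - guarded above
        raise ValueError(f"half-space intersection failed: {exc}") from exc
    verts = np.unique(np.round(hs.intersections, 9), axis=0)
    scale = float(np.abs(verts).max())

    faces = []
    family_areas: dict[str, float] = {}
    for idx, (n, g, lab) in enumerate(zip(normals, dists, labels)):
        on_face = np.where(np.abs(verts @ n - g) < 1e-9 * max(1.0, scale) + 1e-12)[0]
        if len(on_face) < 3:
            continue  # tangent or beyond: face has no area
        area, order = _polygon_area(verts[on_face], n)
        if area < 1e-12 * scale**2:
            continue
        faces.append((lab, on_face[order].tolist()))
        family_areas[lab] = family_areas.get(lab, 0.0) + area

    total = float(sum(family_areas.values()))
    # aspect ratio: ratio of the largest to smallest caliper width measured
    # along the normals of the expressed faces (1.0 for a cube)
    face_normals = [n for n, lab in zip(normals, labels) if lab in family_areas]
    widths = [float((verts @ n).max() - (verts @ n).min()) for n in face_normals]
    aspect = float(max(widths) / min(widths))
    return ParticleShape(verts, faces, family_areas, total, aspect)


def facet_representation(shape: ParticleShape) -> FacetRepresentation:
    """F_r(i) = A_i / sum_j A_j per family."""
    if shape.total_area <= 0:
        raise ValueError("particle has zero surface area")
    return FacetRepresentation(
        {lab: a / shape.total_area for lab, a in shape.family_areas.items()}
    )


def particle_descriptors(rep: FacetRepresentation, facet_values: dict) -> ParticleDescriptors:
    """D_p = sum_i F_r(i) * d_i for every descriptor.

    ``facet_values``: family label -> {descriptor name: per-area value}.
    Descriptors must already be intensive (normalized per projected area).
    """
    missing = [lab for lab in rep.fractions if lab not in facet_values]
    if missing:
        raise ValueError(f"missing facet descriptors for families: {missing}")
    names = set()
    for d in facet_values.values():
        names.update(d)
    out = {}
    for name in sorted(names):
        out[name] = float(sum(
            fr * facet_values[lab].get(name, 0.0) for lab, fr in rep.fractions.items()
        ))
    return ParticleDescriptors(out)


# ---------------------------------------------------------------------------
# morphology file input

_FACE_TAGS = ("_exptl_crystal_face_index_h", "_exptl_crystal_face_index_k",
              "_exptl_crystal_face_index_l", "_exptl_crystal_face_perp_dist")


def read_morphology_cif(path, cell: UnitCell, symmetry) -> MorphologySpec:
    """Read a morphology CIF: a loop of h, k, l and perpendicular distance."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    cols = [list(block.find_loop(t)) for t in _FACE_TAGS]
    if not all(cols) or len({len(c) for c in cols}) != 1:
        raise ValueError(f"{path} has no complete face loop ({', '.join(_FACE_TAGS)})")
    families = [
        ((int(gemmi.cif.as_number(h)), int(gemmi.cif.as_number(k)),
          int(gemmi.cif.as_number(l))), gemmi.cif.as_number(dd))
        for h, k, l, dd in zip(*cols)
    ]
    return MorphologySpec(cell, list(symmetry), families)


def read_morphology_json(path, cell: UnitCell, symmetry) -> MorphologySpec:
    raw = json.loads(open(path).read())
    families = [(tuple(int(x) for x in f["hkl"]), float(f["distance"]))
                for f in raw["families"]]
    return MorphologySpec(cell, list(symmetry), families)
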