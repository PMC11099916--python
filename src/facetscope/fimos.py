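"""Interaction-probability fields over a surface, hotspots, weighted counts.

A pluggable interaction library maps (functional group, probe) pairs to a
geometric placement rule: an ideal probe distance from an anchor atom
along a local direction, a cone half-angle, a peak probability (% above
random) and a Gaussian radial width.  Field values on the probe-accessible
grid combine contributions from all surface-group anchors by maximum
("only unique interactions"); hotspots are 26-connected clusters of
supra-threshold points, scored by their peak value, and the weighted
hotspot count is the sum of hotspot peaks (optionally per projected area).

The shipped toy library is synthetic (plausible hydrogen-bond and
hydrophobic lobes); it is not derived from any structural database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .chemistry import _annotate, load_group_library
from .slab import Slab, wrap_lateral

__all__ = [
    "ProbeDef",
    "FieldRule",
    "InteractionLibrary",
    "Hotspot",
    "FimosResult",
    "load_interaction_library",
    "compute_fields",
    "cluster_hotspots",
    "weighted_hotspot_count",
    "fimos_analysis",
]


@dataclass(frozen=True)
class ProbeDef:
    name: str
    exclusion_radius: float = 0.0

    def __post_init__(self):
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")


@dataclass(frozen=True)
class FieldRule:
    """Placement rule for one (group, probe) pair."""

    group: str
    probe: str
    anchor_atom: int          # index into the group query's atom mapping
    direction_from: int | None  # pattern atom the direction points away from
    distance: float           # ideal anchor->probe distance, Å
    half_angle: float         # cone half-angle, degrees
    peak: float               # % above random at the ideal placement
    width: float              # Gaussian radial width, Å

    def __post_init__(self):
        if self.peak < 0 or self.width <= 0:
            raise ValueError("peak must be >= 0 and width > 0")


@dataclass
class InteractionLibrary:
    probes: list  # of ProbeDef
    rules: list   # of FieldRule

    def probe_names(self):
        return [p.name for p in self.probes]

    def rules_for(self, probe: str):
        if probe not in self.probe_names():
            raise ValueError(
                f"probe '{probe}' not in library; known probes: {self.probe_names()}"
            )
        return [r for r in self.rules if r.probe == probe]


def load_interaction_library(path=None) -> InteractionLibrary:
    """Load an interaction-field library (JSON); default the toy library."""
    if path is None:
        data = (resources.files("facetscope.data") / "toy_interaction_library.json").read_text()
    else:
        data = open(path).read()
    raw = json.loads(data)
    probes = [ProbeDef(p["name"], p.get("exclusion_radius", 0.0)) for p in raw["probes"]]
    rules = [
        FieldRule(r["group"], r["probe"], r["anchor_atom"], r.get("direction_from"),
                  r["distance"], r["half_angle"], r["peak"], r["width"])
        for r in raw["rules"]
    ]
    return InteractionLibrary(probes, rules)


@dataclass
class Hotspot:
    points: np.ndarray   # (n, 3) member grid points, Cartesian
    values: np.ndarray   # (n,) member field values
    peak: float
    centroid: np.ndarray


@dataclass
class FimosResult:
    probe: str
    hotspots: list
    weighted_hotspot_count: float
    normalized_whc: float
    threshold: float


@dataclass
class FieldGrid:
    """Scalar interaction field sampled on the accessible grid."""

    values: np.ndarray     # (nu+1, nv+1, nz+1)
    accessible: np.ndarray  # same shape, bool
    points: np.ndarray     # (nu+1, nv+1, nz+1, 3) Cartesian
    projected_area: float


def _group_anchor_geometry(slab: Slab, info, rule: FieldRule):
    """(anchor position, unit direction) per matched group instance."""
    from rdkit import Chem

    library = load_group_library()
    by_name = {q.name: q for q in library}
    if rule.group not in by_name:
        raise ValueError(f"rule references unknown group '{rule.group}'")
    patt = by_name[rule.group].pattern
    out = []
    for off, mol, m in zip(info.offsets, info.rdkit_mols, slab.molecules):
        conf = mol.GetConformer()
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            anchor = np.array(conf.GetAtomPosition(match[rule.anchor_atom]))
            if rule.direction_from is None:
                direction = np.array([0.0, 0.0, 1.0])
            else:
                frm = np.array(conf.GetAtomPosition(match[rule.direction_from]))
                d = anchor - frm
                nd = np.linalg.norm(d)
                direction = d / nd if nd > 1e-9 else np.array([0.0, 0.0, 1.0])
            out.append((anchor, direction))
    return out


def compute_fields(slab: Slab, probe: ProbeDef | str, library: InteractionLibrary,
                   grid_spacing: float = 0.3, probe_radius: float = 1.2,
                   surface_atoms: set | None = None) -> FieldGrid:
    """Interaction field for ``probe`` on the probe-accessible grid.

    Contributions of all anchors combine by maximum; points inside the
    material (clearance below the probe radius) are excluded.
    """
    probe_name = probe.name if isinstance(probe, ProbeDef) else probe
    rules = library.rules_for(probe_name)
    probe_def = next(p for p in library.probes if p.name == probe_name)
    info = _annotate(slab)

    u2, v2 = slab.box.u.copy(), slab.box.v.copy()
    u2[2] = v2[2] = 0.0
    coords = wrap_lateral(slab.atom_coords(), u2, v2)
    radii = slab.atom_radii()
    h = grid_spacing
    z_top = float((coords[:, 2] + radii).max() + 2 * probe_radius + 2 * h)
    z_bot = float(slab.box.thickness / 2.0)
    nu = max(3, int(np.ceil(np.linalg.norm(u2) / h)))
    nv = max(3, int(np.ceil(np.linalg.norm(v2) / h)))
    nz = max(3, int(np.ceil((z_top - z_bot) / h)))
    dz = (z_top - z_bot) / nz
    si = np.arange(nu + 1) / nu
    tj = np.arange(nv + 1) / nv
    zk = z_bot + np.arange(nz + 1) * dz
    S, T, Z = np.meshgrid(si, tj, zk, indexing="ij")
    pts = S[..., None] * u2 + T[..., None] * v2
    pts[..., 2] += Z
    flat = pts.reshape(-1, 3)

    images = [i * u2 + j * v2 for i in (-1, 0, 1) for j in (-1, 0, 1)]
    tiled = np.concatenate([coords + im for im in images])
    if probe_def.exclusion_radius > 0:
        # probe-specific hard-sphere exclusion: probe centres may approach
        # atoms to hydrogen-bonding range, closer than the vdW+probe reach
        dist, _ = cKDTree(tiled).query(flat, workers=-1)
        accessible = (dist >= probe_def.exclusion_radius).reshape(nu + 1, nv + 1, nz + 1)
    else:
        tiled_r = np.tile(radii, 9)
        D = np.full(len(flat), np.inf)
        for r in np.unique(np.round(tiled_r, 6)):
            sel = np.abs(tiled_r - r) < 1e-6
            dist, _ = cKDTree(tiled[sel]).query(flat, workers=-1)
            D = np.minimum(D, dist - r)
        accessible = (D >= probe_radius).reshape(nu + 1, nv + 1, nz + 1)

    anchors = []
    for rule in rules:
        for anchor, direction in _group_anchor_geometry(slab, info, rule):
            if surface_atoms is not None and not _anchor_on_surface(
                slab, info, rule, anchor, surface_atoms
            ):
                continue
            anchors.append((rule, anchor, direction))

    values = np.zeros(len(flat))
    cos_cut = {id(r): np.cos(np.radians(r.half_angle)) for r, _, _ in anchors}
    for rule, anchor, direction in anchors:
        for im in images:
            a = anchor + im
            rel = flat - a
            dist = np.linalg.norm(rel, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = (rel @ direction) / np.where(dist > 1e-9, dist, np.inf)
            contrib = rule.peak * np.exp(-((dist - rule.distance) ** 2) / (2 * rule.width**2))
            contrib = np.where(cosang >= cos_cut[id(rule)], contrib, 0.0)
            values = np.maximum(values, contrib)
    values = values.reshape(nu + 1, nv + 1, nz + 1)
    values[~accessible] = 0.0
    return FieldGrid(values, accessible, pts,
                     float(np.linalg.norm(np.cross(u2, v2))))


def _anchor_on_surface(slab, info, rule, anchor, surface_atoms) -> bool:
    # anchor coincides with an atom position; map by nearest atom index
    coords = slab.atom_coords()
    idx = int(np.argmin(np.linalg.norm(coords - anchor, axis=1)))
    return idx in surface_atoms


def cluster_hotspots(grid: FieldGrid, threshold: float = 50.0) -> list:
    """26-connected supra-threshold clusters, ordered by descending peak
    then lexicographic centroid."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = grid.values >= threshold
    if not mask.any():
        return []
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    # merge labels across the duplicated periodic seams
    from .topology import _periodic_union

    merge = _periodic_union(labels)
    lut = np.arange(labels.max() + 1)
    for k, v in merge.items():
        lut[k] = v
    canon = lut[labels]
    out = []
    for lab in np.unique(canon):
        if lab == 0:
            continue
        sel = canon == lab
        pts = grid.points[sel]
        vals = grid.values[sel]
        out.append(Hotspot(pts, vals, float(vals.max()), pts.mean(axis=0)))
    out.sort(key=lambda hs: (-hs.peak, tuple(np.round(hs.centroid, 6))))
    return out


def weighted_hotspot_count(hotspots: list, projected_area: float):
    """(whc, whc / projected area): sum of hotspot peak probabilities."""
    if projected_area <= 0:
        raise ValueError("projected area must be positive")
    whc = float(sum(hs.peak for hs in hotspots))
    return whc, whc / projected_area


def fimos_analysis(slab: Slab, probe, library: InteractionLibrary | None = None,
                   threshold: float = 50.0, grid_spacing: float = 0.3,
                   surface_atoms: set | None = None) -> FimosResult:
    """Field + clustering + weighted count for one probe."""
    library = library or load_interaction_library()
    grid = compute_fields(slab, probe, library, grid_spacing,
                          surface_atoms=surface_atoms)
    hotspots = cluster_hotspots(grid, threshold)
    whc, nwhc = weighted_hotspot_count(hotspots, grid.projected_area)
    name = probe.name if isinstance(probe, ProbeDef) else probe
    return FimosResult(name, hotspots, whc, nwhc, threshold)
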