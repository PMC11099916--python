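# Methods

This note records the model assumptions, numerical choices and known
limitations behind facetscope's surface and particle descriptors.

## Slab construction

A surface is (hkl, offset): the Miller plane fixes the orientation, the
offset (Å along the outward normal, taken modulo the interplanar spacing
d_hkl) selects which parallel termination of the structure is cut. The
outward normal is the direction of the reciprocal vector h**a**\* +
k**b**\* + l**c**\*.

The in-plane basis is constructed exactly: the integer kernel of
(h, k, l)·**p** = 0 has the primitive basis v₁ = (0, l/g, −k/g),
v₂ = (−g, hα, hβ) with g = gcd(k, l) and kα + lβ = g (v₁×v₂ = (h,k,l)
guarantees primitivity); the Cartesian images are then Lagrange–Gauss
reduced, which for a rank-2 lattice yields the minimum-area cell, and
oriented so **u**×**v** points outward. The thickness vector is the cell
body diagonal **a**+**b**+**c** (sign-flipped toward the outward normal),
extended by integer multiples when it is thinner than two molecular
extents along the normal, so a probe can never reach through the slab.

Molecule selection is by centre of geometry with half-open box
coordinates: [0,1) in the two lateral directions and (0,1] along the
thickness. The top-inclusive thickness convention matters only when a
centroid lies exactly on the termination plane — common in
exact-coordinate synthetic crystals — and then keeps that molecule at the
analysed top face instead of substituting its lattice copy at the bottom;
tiling still covers each molecule exactly once, so per-area densities are
well defined. Coordinates within 1e-8 of a box boundary are snapped
before the test.

## Contact-surface topology

Defaults: probe radius 1.2 Å, grid spacing 0.3 Å. The clearance field
D(g) = min over atoms of (|g − a| − r_vdW) is sampled on a grid spanning
one u–v tile laterally (with minimum-image wrap; atoms are first wrapped
laterally into the base tile) and vertically from above the highest van
der Waals sphere plus a probe diameter down to a fixed plane 1 Å past the
slab mid-plane. Probe centres are points with D ≥ r_probe 26-connected to
the open region above the slab (periodic seams are merged by union-find
on the duplicated boundary columns). Because the bottom face of the slab
is a truncation artifact, the field generator appends downward
w-translates of the slab contents so the material continues below the
analysed face.

The contact surface is the set of points at probe-radius distance from
the probe-centre region. Numerically, the probe-centre isosurface
{D = r_probe} is first sampled as a point cloud by linear interpolation
of D along grid edges that cross the level (D is smooth with |∇D| ≈ 1, so
the crossing error is second order); the contact field is then the
distance to that cloud minus the probe radius, marched at zero. This
construction was chosen over a distance transform of the binary
probe-centre mask, whose staircase error is first order and visibly
inflates the surface area at 0.3 Å spacing; with the interpolated cloud
the toyacid fixture's true area changes by about 0.3% when the grid is
halved to 0.15 Å. Only the mesh component reachable from above (the one
containing the highest vertex) is kept: side walls, the bottom sheet and
enclosed pockets are excluded from the true area.

The vertical extent of the grid is h-independent by design: deep
inter-molecular grooves are cut at the same plane at every resolution,
which is what makes grid-convergence statements meaningful. Descriptors
of surfaces whose grooves reach that depth therefore include wall area
down to the cut; this is stated behaviour, not noise.

Surface atoms are atoms with at least one mesh node within
r_vdW + grid_spacing/2 of their centre (minimum image in u, v).

## Roughness

Node heights are measured along the outward normal about the
triangle-area-weighted mean plane, so the weighted mean height is zero by
construction (area weighting is robust to non-uniform triangulation; on
marching-cubes meshes it differs from the plain mean by well under the
grid spacing). With σ² the weighted mean of h²: rmsd = σ, skewness =
⟨h³⟩/σ³, kurtosis = ⟨h⁴⟩/σ⁴ in the Pearson convention, whose normal
reference value is 3 — "sharper than normal" height distributions score
above 3. Rugosity is true area over projected (reticular) area; it is 1.0
exactly for a planar mesh and ≥ 1 always. Degenerate (constant-height)
inputs report rmsd 0 with skewness and kurtosis flagged as 0.

## Surface chemistry

Hydrogen bonds use a geometric rule: donor elements N, O carrying an
explicit hydrogen; acceptor elements N, O, S, F; H···A within the sum of
van der Waals radii; D–H···A ≥ 120°; acceptors in neighbouring u, v
image tiles included; an atom covalently bonded to the hydrogen never
accepts from it. All four pieces are configurable, since different
packages draw these defaults slightly differently. A donor counts as
exposed only when its hydrogen is itself a surface atom — the hydrogen is
what an external partner can reach — and an exposed donor is unsatisfied
when its hydrogen is in no intra-slab bond. Acceptors are counted per
atom (not per lone pair); aromatic bonds count when both atoms are
surface atoms. Densities divide by the projected area, as does the total
Gasteiger charge; the projected (not true) area is used throughout for
consistency.

Bond orders, aromaticity, hybridisation and the per-atom Ertl TPSA
fragment contributions come from RDKit (connectivity is perceived
in-package from covalent radii with a 0.4 Å tolerance and periodic
minimum image; geometries with an atom bearing more than eight bonds are
rejected as corrupt). TPSA restricted to a surface sums the fragment
contributions of surface atoms only; S/P contributions are off by default
(N/O chemistry covers the shipped fixtures and the ibuprofen use case).

PEOE (Gasteiger) charges are computed in-package: χ(q) = a + bq + cq² per
element/hybridisation with the classic sigma-framework coefficients,
charge transferred across each bond per iteration k scaled by
(χ_hi − χ_lo)/χ⁺_lo · 0.5^k, hydrogen's cation electronegativity
special-cased at 20.02; six iterations by default (the method's classic
setting; RDKit's implementation at matched iteration count agrees to
machine precision and serves as the test oracle). Charges conserve the
molecular formal charge exactly.

Functional groups are SMARTS queries over the explicit-hydrogen molecular
graph; matches are counted once per distinct atom set, a group instance
is surface-terminating when any of its atoms is a surface atom, and
contained groups are reported alongside their containers (a methyl inside
an isopropyl counts as both). The shipped library covers i-propyl,
methyl, aliphatic–aromatic methylene, tertiary C–H and the uncharged
carboxylic acid; it is a plain JSON file and fully replaceable.

## Interaction hotspots

The hotspot machinery is data-agnostic: a library maps (group, probe)
pairs to a placement rule — ideal distance from an anchor atom along a
local bond direction (or the surface normal), cone half-angle, peak
probability (% above random) and Gaussian radial width. Field values on
the grid combine anchor contributions by maximum ("only unique
interactions"); summing is deliberately not the default because combined
probabilities are not additive. Grid points are excluded by a per-probe
hard-sphere exclusion radius (probe centres legitimately approach donor
hydrogens to ~1.9 Å, inside the vdW+probe reach that defines the
topology's accessibility — the two notions are distinct on purpose).
Hotspots are 26-connected supra-threshold clusters (default threshold 50%
above random), scored by their peak value and reported in deterministic
order; the weighted hotspot count is the sum of peaks, optionally per
projected area.

The shipped library is synthetic: chemically plausible hydrogen-bond and
hydrophobic lobes for five standard probes, intended for tests and
demonstrations. It is not derived from any structural database, and
absolute hotspot values from it carry no empirical meaning; only the
machinery's invariants (threshold monotonicity, max combination,
intensivity of the normalised count) and relative comparisons do.

## Morphology and particle descriptors

{hkl} families expand under the Laue group — the rotational parts of the
space-group operations plus inversion (Friedel) — with Miller indices
transforming by the inverse-transpose of the rotation. The particle is
the intersection of half-spaces n̂·x ≤ g over all mates (scipy's
half-space intersection; unbounded specifications are rejected with the
uncovered directions named). Face polygons are assembled per half-space,
ordered angularly, and measured exactly; tangent families receive no
area. The facet representation divides each family's area by the total,
and particle descriptors are the F_r-weighted averages of per-area facet
values, hence convex combinations. The aspect ratio is the largest over
smallest caliper width along expressed face normals (1.0 for a cube).
Facet descriptors default to offset 0.00 Å per family, overridable per
family in the run configuration.

## Fixtures

The synthetic fixtures are constructed so one stage each has an answer
known by construction: `noble_cubic` (a single Ar-like atom, cubic 5 Å
cell) for pure geometry; `toyacid` (formic-acid-like molecule, hydroxyl H
exposed on (001), no intra-slab hydrogen bond) for chemistry;
`catemer` (the same molecule in a sheared cell whose b translation puts
the carbonyl O exactly 1.9 Å from the hydroxyl H at 180°) for the
hydrogen-bond rule; `flatring` (benzene-like ring parallel to (001)) for
aromatic densities; `layered_polar` (acid buried beneath an ethane layer
whose widest lateral clearance, 2√2 Å at the tile centre, is below the
1.7+1.2 Å carbon-to-probe reach) for occlusion. They emulate exact,
clash-free, small-molecule packings; they do not emulate disorder,
thermal motion, conformational flexibility or the dense packing of real
organic crystals, so passing fixture tests validates the machinery, not
predictions about any particular real surface.

## Limitations

Surfaces are ideal bulk terminations: no relaxation, reconstruction or
energy-based termination choice. Charge states are taken as drawn
(neutral by default); pKa effects are out of scope. Roughness descriptors
of very open packings depend on the stated depth cut. The published
ibuprofen worked-example values can only be checked against the actual
IBPRAC crystal structure, which users must retrieve themselves (free
per-entry access from its database of record); the corresponding
acceptance test reports exactly that when the file is absent.
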