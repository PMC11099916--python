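# facetscope

Crystal-surface analysis for particle engineering: from a crystal
structure (CIF) and a set of Miller planes, facetscope builds periodic
surface slabs, computes the van der Waals contact-surface topology with a
rolling probe on a grid, quantifies the chemistry and roughness each
facet exposes, scores interaction hotspots from a pluggable field
library, and combines the per-facet values into whole-particle
descriptors weighted by a Wulff-style morphology.

It is aimed at formulators and particle engineers who want quantitative,
structure-derived surface descriptors — e.g. to compare how a block-like
and a lath-like habit of the same compound expose polar groups, and hence
to anticipate processing behaviour such as punch sticking — without
molecular-dynamics or lattice-energy machinery.

## The method

For a plane (hkl) at a termination offset Δ (Å along the outward normal),
the **slab** is the minimal periodic box: in-plane lattice vectors
**u**, **v** chosen as the Lagrange–Gauss-reduced primitive basis of the
in-plane sublattice (so |**u**×**v**| is the reticular area V/d_hkl), and
a thickness vector **w** equal to the cell body diagonal. Whole molecules
whose centres of geometry lie in the box are kept.

The **topology** is a mesh of nodes on the contact surface (Barbour): a
probe of radius 1.2 Å on a 0.3 Å grid; grid points with clearance
D(g) = min_a(|g−a| − r_vdW(a)) ≥ r_probe that connect to the open space
above the slab are probe centres, and the contact surface is the locus at
probe-radius distance from that region, triangulated marching-cubes
style with periodic wrap in **u**, **v**. Surface atoms are those in
contact with mesh nodes.

Per facet, with A = |**u**×**v**| the projected area:

* densities of hydrogen-bond donors, acceptors, *unsatisfied* donors
  (donor H exposed but in no intra-slab bond) and aromatic bonds, in
  counts/Å²;
* TPSA (sum of Ertl fragment coefficients over surface-exposed polar
  fragments, Å²) and TGC (total Gasteiger/PEOE charge of surface atoms,
  also per area);
* surface-terminating functional groups from a SMARTS query library;
* roughness: rugosity = true/projected area (1.0 for a perfectly smooth
  surface), and the rmsd, skewness and Pearson kurtosis of node heights
  about the mean plane;
* interaction hotspots: probability-above-random fields placed by a
  pluggable (group, probe) rule library, combined per grid point by
  maximum, clustered 26-connectedly above a threshold; the weighted
  hotspot count is the sum of hotspot peaks.

For a particle, each {hkl} family is expanded under the Laue group, the
shape is the intersection of half-spaces at per-family growth distances,
and the facet representation F_r(i) = A_i / Σ_j A_j weights the per-area
facet descriptors into particle descriptors D_p = Σ_i F_r(i) · d_i — a
convex combination of the facet values.

## Worked example

The shipped `toyacid` fixture is a formic-acid-like P1 crystal whose
hydroxyl hydrogen points out of the (001) surface:

```bash
facetscope fixture --kind toyacid --out-dir demo
facetscope facet --cif demo/toyacid.cif --hkl 0 0 1
```

prints (abridged):

```json
{
  "projected_area": 30.0,
  "roughness": {"rugosity": 1.6815, "rmsd": 1.1287,
                "skewness": 0.2148, "kurtosis": 1.8308},
  "chemistry": {
    "density_hbd": 0.03333, "density_hba": 0.06667,
    "density_unsat_hbd": 0.03333, "density_aromatic_bonds": 0.0,
    "tpsa": 37.3, "total_gasteiger_charge": -0.0,
    "functional_groups": [["uncharged carboxylic acid", 1]]
  }
}
```

Reading: one donor O–H and two acceptor oxygens are exposed per 30 Å²
tile (acceptor:donor density 2:1); the donor is unsatisfied (no intra-slab
hydrogen bond), so it remains available to external partners. The TPSA is
exactly the hydroxyl (20.23) plus carbonyl (17.07) fragment coefficients.
All five atoms are surface atoms, so the summed PEOE charge is zero (a
neutral molecule), and the rugosity 1.68 reflects the deep inter-molecular
grooves of this deliberately open toy packing.

Other subcommands: `facetscope slab` (extended-XYZ export),
`facetscope particle --cif S --morph M.cif` (morphology CIF face loop or
JSON; `--compare` emits a block-vs-lath delta table), `facetscope fimos`
(hotspots per probe).

To analyse a real structure such as ibuprofen polymorph 1, obtain the
crystal structure from its database of record (CSD refcode IBPRAC, free
per-entry access) and run the same commands against it; the acceptance
test for the published surface values looks for it at
`data/external/IBPRAC.cif`.

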