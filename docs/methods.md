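# Methods

## Scientific question

In the larval zebrafish lower jaw, a collagen-XI mutant (modelling a human
collagenopathy) differs from wild type in two coupled ways: the *shape* of the
jaw joint changes (broader Meckel's-cartilage neck and head, reduced joint
space between Meckel's cartilage and palatoquadrate, protruding chondrocytes)
and the *material properties* of the cartilage change (higher Young's modulus
measured by AFM nanoindentation). This package separates the two contributions
with a 2x2 factorial of finite-element models: each combination of {wt, mutant}
jaw shape and {wt, mutant} cartilage stiffness is solved for jaw closure and
opening, and the strain environment at the joint interzones is compared.

## Synthetic geometry

No raw confocal stacks are available, so geometry is generated parametrically
from the five quantities the morphometric suite measures (all in micrometres;
voxels isotropic, default 1 um):

| parameter        | wt   | mutant | carries                                   |
|------------------|------|--------|-------------------------------------------|
| neck_width       | 6    | 10     | MC narrowing before the joint head         |
| head_width       | 10   | 14     | MC (and PQ) terminal broadening            |
| joint_space      | 6    | 2      | MC-PQ interzone gap                        |
| element_length   | 48   | 48     | overall MC scale                           |
| element_radius   | 4    | 4      | shaft cross-section                        |

Absolute 7 dpf dimensions are not tabulated anywhere public; the values above
are scaled study conditions chosen once so a full factorial solves in minutes
on one CPU, with the wt-mutant contrasts in the directions observed in vivo.
Widths are even multiples of the voxel size and element axes sit on voxel
boundaries, so every parameter is recovered *exactly* by the measurement
operators (the generator snaps the palatoquadrate to the realised Meckel's-head
surface so the joint space is exact by construction). An optional geometry seed
jitters only the non-measured layout quantities (shaft length +/-3%, lateral
joint offset +/-5%) to emulate specimen variation.

The jaw is reduced to capsule/rod primitives: two mirrored Meckel's rods
meeting at the midline symphysis, each with a neck and a spherical joint head;
paired palatoquadrate rods whose anterior terminal is also head-width broad
(both rudiment terminals enlarge in the mutant); and a transverse ceratohyal
bar joined to the palatoquadrate posterior ends. Joint gaps are filled with an
explicit **interzone tissue** label — biologically the immature,
col2a1a-expressing cells of the interzone — whose column spans the
articulating surfaces. This matters twice: it makes the model a single
connected body (so the anatomical anchoring suffices), and it makes the joint
hinge stiffness scale with the articulating geometry (broader mutant head ->
larger contact area; narrower joint space -> shorter column), which is the
geometric carrier of the mutant's focal-strain phenotype.

What the generator does *not* emulate: fluorescence optics (PSF, attenuation,
anisotropic voxels), organic cross-section variation, the branchial arches and
other non-load-bearing elements, and any nonlinearity of real interzone tissue.
Passing tests therefore demonstrate correctness of the measurement and
solution operators and internal consistency of the factorial logic on idealised
geometry — not anatomical fidelity to any individual larva.

## Imaging chain

Rendering is a two-level forward model (background/foreground grey means 30 and
200, additive Gaussian noise, default sd 10, clipped to [0, 255]); microscope
noise was never characterised, so Gaussian is the minimal stand-in. Otsu
thresholding uses a 256-bin histogram regardless of bit depth (bit-exact,
verified against an exhaustive between-class-variance search). Binary
smoothing is an isotropic Gaussian (sigma 1 voxel) on the {0,1} field with a
0.5 re-threshold — the voxel-space equivalent of one-pixel mesh smoothing. It
removes isolated voxels and is idempotent to <1% on flat-surfaced bodies;
on capsule surfaces each extra pass erodes ~1.4% of foreground (curvature
rounding), which is why the pipeline applies it exactly once.

The two-material split relabels cartilage within distance `d` of a joint plane
(jaw joints, symphysis; planes normal to the anteroposterior axis) as
*immature*, the remainder *hypertrophic*; the two sets partition the cartilage
exactly. How much geometry was cut into the original near-joint meshes was
never quantified; `d` defaults to 15% of the element length and is a surfaced
config parameter.

## AFM / DMT estimation

Force curves follow the Derjaguin-Muller-Toporov contact model
`F = (4/3) E* sqrt(R) delta^(3/2) - F_adh`, `E* = E/(1-nu^2)`. The fit is
linear least squares on the `delta^(3/2)` regressor — closed form, so a full
256 x 256 map (65,536 curves) fits in seconds as one matrix solve. Curves are
assumed pre-aligned (contact point at delta = 0); contact-point detection is
out of scope. Poisson's ratio was never measured for this tissue; nu = 0.3 is
the package default and every report carries it. The *relative method*
calibrates an effective sqrt(R) scale factor against reference samples of
known modulus (stiff graphite-like 18 GPa, soft PDMS-like 2.5 MPa), absorbing
tip-radius/spring-constant systematics; because force scales with
`E* sqrt(R)`, a 4x radius miscalibration is recovered as a scale of exactly 2.
Maps aggregate by the root-mean-square mean (>= arithmetic mean, equality iff
constant); pixels with non-physical fits are excluded, and a map with >10%
failures is rejected.

## Finite elements

One trilinear 8-node hexahedron per cartilage voxel (shared nodes on shared
faces), 2x2x2 Gauss quadrature (exact for this element on a cube), isotropic
linear elasticity per region. Units are um / uN / MPa, so 1 MPa = 1 uN/um^2
and no conversion constants appear. Because every element is the same cube,
the element stiffness is computed once per material region and the global
matrix assembled in a single vectorized scatter. Dirichlet rows are
eliminated; the reduced system is solved by a sparse LU factorization
(deterministic; an exactly singular factor or an out-of-tolerance residual is
reported as missing rigid-body constraints). Strains are displacement
gradients at element centroids; principal strains E_Max >= E_Mid >= E_Min are
eigenvalues of the symmetric strain tensor. Small-strain theory and a single
linear solve per step are used throughout: reported strains are ~1e-2 and the
materials are modelled as linear elastic, so geometric nonlinearity is
excluded by design (displacement magnitudes under the placeholder loads should
be read comparatively, not literally). Voxel meshes are used directly — no
surface wrap or tetrahedralization — which is robust, deterministic and
adequate for comparative strain patterns.

Verification: patch test (linear boundary displacement reproduces constant
strain to 1e-10), uniaxial bar against FL/EA within 1%, reaction equilibrium
to 1e-8 relative, exact load- and material-scaling laws, monotone convergence
of the clamped-bar error under refinement, and the single-element stiffness
against an independent symbolic integration.

## Jaw model and loads

Boundary conditions follow the anatomical anchoring: every node of the
ceratohyal is fixed in all axes; palatoquadrate-base nodes (posterior 2 voxels
of each PQ) are fixed in y and z. Muscles are point loads at the mesh node
nearest the insertion (tolerance 2 voxels), directed along the unit vector
insertion -> origin; per-muscle local coordinate frames are realised
implicitly by constructing the force vector directly from those points. The
real magnitudes and attachment coordinates live in prior kinematic work and
are not recoverable here, so the shipped values are placeholders (2 uN per
muscle per side) with anatomy-driven directions: the jaw opener pulls its
anterior-shaft insertion ventrally (slightly posteriorly) — opening is a
ventral rotation of the lower jaw about the jaw joints — and the adductor
pulls the mid-shaft dorsally for closure. Every shipped comparison (orderings,
effect ratios, displacement monotonicity) is invariant to the absolute
magnitude, which only sets the strain scale.

## Factorial analysis

The headline quantity is the element-volume-weighted mean of E_Max over the
**joint interzone** (all interzone tissue; the Meckel's-symphysis and
jaw-joint sub-means are also reported per cell, since the mutant phenotype is
precisely that strain focalizes at the jaw joints). Main effects are mean
absolute cell contrasts:

    shape effect    = mean over materials of |mean(wt shape) - mean(mutant shape)|
    material effect = mean over shapes    of |mean(wt mats)  - mean(mutant mats)|

This effect definition is the package's own (the underlying biology is usually
argued by comparing cell means narratively); it is symmetric, unitful and
reported alongside the raw cell means. Material presets: immature cartilage
4.15 MPa (wt) vs 7.4 MPa (mutant) — AFM means; hypertrophic 6.0 vs 19.0 MPa —
config assumptions encoding the reported four-fold wt-mutant difference in
mature regions (only the difference relation is constrained by measurement;
the wt base value is an assumption, flagged in `configs/materials.yaml`).

On the shipped presets the factorial reproduces, deterministically and across
geometry seeds, the orderings the in-vivo work reports: wt-shape joint
interzones carry higher mean E_Max than mutant-shape ones under *both*
material sets; the shape main effect exceeds the material main effect
(ratio ~1.4); and at fixed shape the stiffer mutant materials strictly reduce
opening displacement. A per-cell strain-spread fraction (elements with E_Max
above 10% of that cell's joint mean) is computed and reported but its
direction is not asserted: normalizing by each cell's own (much larger) wt
joint mean makes the wt fraction slightly the smaller one on this geometry.

## Numerical and policy choices

- Determinism: all randomness flows from one seed through named CRC32-keyed
  substreams; no stage touches global random state. Two runs of the pipeline
  from one config are byte-identical (the run log, which carries wall-clock
  timings, is the single exception).
- Degenerate inputs fail loudly and specifically: constant images, empty
  masks/regions, missing labels, unplaceable loads, insufficient constraints,
  all-failed maps.
- Surface distances use the voxel-centre metric minus one voxel (each voxel is
  a cube of material); protrusions are 26-connected components with a 5-voxel
  size floor; widths are slab extents at landmark planes supplied by the
  generator (in vivo they are placed by eye on 3D renders).
- Problem sizes: default factorial meshes are ~14k (wt) / ~18k (mutant)
  elements (~50-65k DOF), solving in ~2 s per step; these sizes were chosen
  once as the package's study conditions.

## Known limitations

Anatomical fidelity is deliberately coarse (planar capsule skeleton, no
perichondrium, no muscle tissue); absolute strain and displacement values are
placeholder-load-dependent and should only be compared across cells; contact
between articulating surfaces is not modelled (the interzone column stands in
for it); adult bone and stress-based failure analyses are out of scope.
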