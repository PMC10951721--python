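# Methods

## The model in one paragraph

The arterial wall of an aorta–carotid network is treated as a
single-layered, isotropic, linear-elastic solid under small strains.
A uniform pulse pressure is applied as a dead traction on the lumen
surface, all vessel truncations are fully clamped, and the static
response is solved per material case. Compliance is the
pressure-normalized lumen volume change, C = ΔV/ΔP, evaluated per
vascular region; stiffness sweeps raise the aortic Young's modulus with
the carotid wall fixed, and the change in carotid compliance isolates
the purely geometric (load-path) coupling between aorta and branches.

## Synthetic anatomy

The geometry generator replaces a patient-specific lumen
reconstruction with a parametric idealization that preserves the
topology of the human aortic tree: ascending aorta (lumen radius
12.5 mm tapering to 11.5 mm, length 65 mm), arch (semicircle, 25 mm
centerline radius of curvature), descending aorta (tapering to 9 mm,
117 mm), brachiocephalic trunk (6 → 4.5 mm radius) splitting into the
right common carotid and right subclavian, left common carotid and left
subclavian arising directly from the arch, and both carotids
bifurcating into internal/external branches. Wall thicknesses are
literature values: aorta 2.6 mm, brachiocephalic 1.5 mm, carotids and
subclavians 1.0 mm. Lumen radii, lengths, attachment fractions and
branch directions are implementation defaults chosen once to be
anatomically representative for an adult; all are exposed in
`DEFAULT_PARAMS` (mm) and overridable. Lateral branches leave their
parent along the local surface normal and curve toward their anatomical
direction over their length, which keeps the root mount well-posed.

What this emulates: the regional layout, size hierarchy, and the two
distinct carotid supply routes (direct-from-arch vs via the
brachiocephalic). What it does not: patient-specific curvature and
caliber variation, non-circular lumina, vessel taper irregularity,
perivascular tethering, and axial pre-stretch. Consequently the
absolute compliances are representative rather than patient-matched,
and percent changes — which are ratios — are the quantities to trust.

## Meshing and junction treatment

Each branch is swept as a thick-walled tube on a structured
(station × radial × circumferential) grid with parallel-transport
(minimal-twist) frames; cells inherit the branch's region label, and
inner/outer/opening facet sets are recorded. The pinned study
resolution is (n_circ, n_axial/mm, n_radial) = (16, 0.35, 2): 6 912
hexahedra, 10 704 nodes, a deliberate desk-scale discretization whose
discretization error largely cancels in the case-to-case ratios the
study reports.

End-to-end continuations (ascending|arch|descending, trunk|right
carotid, common|internal carotid) share the interface node ring —
literally watertight. Lateral branches are butt-mounted: the root node
annulus is projected onto the parent's outer surface (the saddle curve
of a pipe welded on a tank, blended out over ~3 child radii) and every
root node is bonded to the parent surface by a bilinear multi-point tie
constraint, eliminated exactly before the solve. This is the standard
bonded-interface treatment for non-conforming structural meshes and was
chosen over conforming T-junction hexahedral meshing, which is not
tractable at this scope; the cost is that the parent wall under a
branch ostium is not opened, so ostial stress concentration and hole
dilation are not represented (see Limitations).

Self-intersecting sweeps (centerline bend radius below the outer tube
radius) are rejected with the branch name; every mesh is validated for
positive corner Jacobians, finite coordinates and connectivity.

## Finite elements

8-node isoparametric hexahedra, 2×2×2 Gauss quadrature, with
mean-dilatation B-bar (selective reduced integration): the volumetric
rows of the strain-displacement operator are replaced by their
element-volume average. At ν = 0.45 full integration exhibits mild
volumetric locking; B-bar keeps the coarse-mesh pressurized-tube
solution within a few percent of the closed form (the test suite pins
this). Full integration remains selectable. Pressure is a dead load
consistently integrated on the undeformed inner surface (no follower
update — consistent with geometric linearity). The linear systems
(~32 k unknowns at study resolution) are solved by sparse LU; the
relative residual is checked against the solver tolerance (1e-9).

Verification oracle: the plane-strain Lamé thick-walled-cylinder
solution. A clamped tube's interior converges to it as length grows
(the clamped-edge boundary layer decays over ~√(a·t)); at 160 mm length
and study-like cross-section resolution the mid-length FEM displacement
is within ~1 % and refines with observed order ≈ 2 in a pure
plane-strain ring configuration.

Transient mode integrates M ü + K u = f(t) with Newmark-β (consistent
mass, wall density 1100 kg/m³ by default — a typical arterial tissue
value). Parameters outside the unconditional-stability region
(γ ≥ 1/2, 2β ≥ γ) are refused unless forced. Because the model is
linear and the study's observables depend only on the pressure
amplitude, the default pipeline is quasi-static: the transient mode
exists for fidelity checks (a slow raised-cosine load reproduces the
static peak to 0.1 %), and the default γ = 1/2 integrator is
energy-conserving, so ring-down studies need γ > 1/2 for algorithmic
damping.

## Volumes, compliance and stress

Each region's lumen is closed by fan caps at its end rings (generated
on the fly). Caps at welded interfaces are shared with opposite
orientation by the two neighbours, so volume swept by interface motion
transfers between regions and regional ΔV adds up exactly to the whole
model. The cap at a lateral root lies on the parent's outer wall and
moves with it; its swept volume is attributed to the parent (upstream)
region, so a branch's ΔV reflects its own wall motion, not the parent's.

ΔV is evaluated to **first order in displacement** (the linearized
divergence-theorem expression). This makes compliance exactly linear:
C(PP1) = C(PP2) to machine precision, modulus doubling halves C
exactly, and percent changes are pressure-independent — the invariants
the test suite asserts. The exact displaced-surface volume (with its
quadratic correction, ~u/a ≈ 3 % here) remains available through
`enclosed_volume`; mixing the two definitions would make compliance
spuriously pressure-dependent in a model that is linear by assumption.

Total deformation is the Euclidean norm √(Ux²+Uy²+Uz²) (the only
norm-consistent reading of the component formula). Von Mises stress is
√(3 J₂) from centroid Cauchy stresses recovered with the B-bar-
consistent operator. Local compliance maps report the outward-normal
displacement difference per ΔP at inner-surface nodes — a radial
distensibility surrogate, isolated behind one function so alternative
local definitions can be swapped in.

## Pressure levels

PP1 defaults to 5594 Pa: the stated 42 mmHg converts to 5599.5 Pa and
the figure-level sources print 5594 Pa, so the lone 5994 Pa mention is
taken as a transposition; PP2 defaults to 7639 Pa (57 mmHg) with the
7369 Pa variant selectable. Since compliance is exactly
pressure-independent here, this choice affects absolute ΔV only, not
any percent change. The diastolic baseline defaults to 0 Pa; a nonzero
baseline is accepted and verifiably leaves compliance unchanged.

## Sweep design and reported aggregates

Uniform sweep: aortic E ∈ {0.8, 1.0, 1.2, 1.4, 1.6} MPa everywhere in
the aorta. Regional sweep: (ascending, arch, descending) triples from
(0.8, 0.9, 1.0) to (1.6, 1.7, 1.8) MPa, including the two
non-monotone descending entries, kept exactly as tabulated.
Unspecified branch moduli (brachiocephalic, subclavians) default to
the carotid value, 1.0 MPa. Percent changes are case 5 vs case 1
(reference case 1). Reported aggregates: `aorta` (three segments),
`left_carotid`/`right_carotid` (common+internal+external),
`aorta_carotid`, `whole_model` (all twelve regions).

## What the linear model can and cannot show

Three structural ceilings follow from linearity and are visible in the
results:

1. **~50 % ceiling on aortic compliance loss.** With the aortic
   modulus exactly doubled, aortic compliance halves up to the small
   geometric coupling (we measure 50.1 %); aggregates that include the
   weakly-responding carotids land *below* the aorta's own decline
   (aorta+carotid 47.5 %, whole model 45.3 %). An aggregate's percent
   change is a ΔV-weighted mean of its parts and cannot exceed the
   largest component change.
2. **Flat stress trend.** For pressure loading, uniform stiffness
   scaling leaves stress unchanged (u ∝ 1/E, σ = E·B·u); only weak
   mixed trends from aorta/branch heterogeneity survive. On this
   anatomy the whole-model peak von Mises stress (at the arch)
   *decreases* by ~0.7 % across the uniform sweep while
   ascending/descending segment peaks rise by ~0.3–0.5 %.
3. **Pressure-independent percentages.** Every percent change is
   identical at PP1 and PP2.

The carotid response is pure load-path coupling: the left common
carotid, mounted on the moving arch, loses ~11 % of its compliance
across the uniform sweep; the right, fed through the compliant
brachiocephalic trunk, is essentially decoupled (<1 %). The left >
right ordering is robust on this anatomy; the *magnitude* of the right
carotid response depends strongly on brachiocephalic length and caliber
and on the absent ostial coupling, and should be read qualitatively.

## Limitations

- No ostium is cut into the parent wall at tied junctions, omitting
  hole-dilation coupling and ostial stress concentration.
- No hyperelasticity, anisotropy, residual stress, perivascular
  support, or fluid–structure interaction; pressure is spatially
  uniform and quasi-static.
- Clamped openings are an idealization; near-opening regions carry
  boundary-layer artifacts (the synthetic branch lengths keep these
  away from the regions being compared).
- Single geometry by design: no population variability. The geometry
  jitter hook exists for robustness checks, not for inference.
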