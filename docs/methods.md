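# Methods

`meniscusfe` is a self-contained finite-element pipeline for studying how
longitudinal and radial meniscal tears alter the stress environment of the
knee menisci under weight bearing at 0–30° of flexion. Because no
subject-specific segmented geometry is distributed with the package, a
synthetic parametric knee stands in for segmented imaging; everything
downstream (meshing, constitutive behaviour, contact, tear insertion,
postprocessing) operates exactly as it would on imported surfaces.

## Model overview

**Geometry.** The tibiofemoral joint is reduced to the simplest analytic
surfaces that produce compartmental contact: each femoral condyle is a
sphere (bone radius 26 mm medial / 25 mm lateral by default, chosen toward
the flat distal end of reported condylar-radius ranges so the condyle nests
on the meniscal wedge), and each tibial plateau compartment is a shallow
elliptic-paraboloid dish (2 mm deep over ~25 mm). Cartilage is a uniform
2 mm layer on both sides. Each meniscus is a C-shaped solid with a
right-triangle wedge cross-section — flat inferior face congruent with the
tibial cartilage surface, vertical peripheral wall (6 mm medial / 5.5 mm
lateral), sloped superior face — swept along a circular arc (240° medial,
230° lateral; inner/outer radii 10/20 mm and 9.5/19 mm). The arcs terminate
in flat anterior and posterior faces where the insertional ligaments attach.
Coordinates: origin at the plateau center, +x lateral, +y anterior,
+z proximal, units mm.

The wedge cannot taper to an exactly zero inner edge without degenerating
the structured mesh; the inner-rim height defaults to 15% of the peripheral
height (validation enforces < 25%), which is the "≈ 0" taper at the mesh
scales used.

**Kinematics.** The femur pose at flexion angle θ ∈ [0°, 30°] is a rotation
about the fixed axis through the condylar centers, plus a screw-home
internal-rotation component (default 5°, accrued linearly over 0→20° and
held from 20→30°) and a posterior rollback translation (default
0.1 mm/deg). Both couplings are configurable: real studies impose imaged
kinematics, which a synthetic model cannot reproduce; the defaults are
mid-range values from the gait literature chosen once, before any
simulations were run. After posing, the femur is seated vertically so its
cartilage just engages the tibial side (a 0.05 mm preload penetration seeds
the contact solver). Landmark-based registration (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) is available as an
alternative pose source when per-pose landmark sets are supplied.

**Materials.** Cartilage: isotropic linear elastic, E = 13 MPa, ν = 0.42.
Meniscus: transversely isotropic linear elastic with the fiber axis along
the local circumferential (sweep-tangent) direction: in-plane
E_p = 20 MPa, ν_p = 0.2, G_p = 8.3 MPa; circumferential E_f = 150 MPa,
ν_f = 0.3, G_f = 57.7 MPa. Voigt ordering is (11, 22, 33, 23, 13, 12) with
engineering shear strains. ν_f is interpreted as the major ratio ν₁₂
(fiber-direction load contracts the transverse plane), which is
thermodynamically admissible with these moduli; whether the source
convention was ν₁₂ or ν₂₁ is not recoverable, so the choice is exposed as
the material definition rather than hidden. Note that G_p = 8.3 MPa differs
from E_p/2(1+ν_p) = 8.33 MPa by 0.4%: the printed constants are therefore
very slightly inconsistent with exact transverse isotropy, and the
assembled stiffness depends on the (deterministic) transverse basis at that
same 0.4% order. Bones are rigid; the tibia is fully fixed and the femur is
free only in medial-lateral translation, axial translation and varus-valgus
rotation, with the compressive load (750 N full body weight, 375 N half)
applied along the tibial long axis to its axial translation.

**Meshing.** All solids are structured hexahedral lattices split into six
tetrahedra per cell with the Freudenthal main-diagonal template, which is
conforming on structured grids and bit-for-bit reproducible. Default
resolution: menisci 22 (circumferential) × 6 (radial) × 2 (vertical) cells,
cartilage patches 9 × 9 × 2. The radial count must be a multiple of 3 so
the white / red-white / red zone terciles fall on element boundaries (and
of 6 for the longitudinal tear plane at s = 5/6 to coincide with a node
layer). Regions (anterior/middle/posterior) are equal arc-angle terciles
and zones equal radial terciles of the normalized rim coordinate
s ∈ [0, 1]; both labels are functions of the element centroid only, hence
resolution-invariant. The default circumferential count also places two
element edges at 6.98 mm along the tear line, so the 7 mm stable tear is
realized almost exactly. The resolution was fixed by our own convergence
study: the femoral axial displacement at full load changes by under 2%
between the default and a uniformly 1.5× refined mesh.

**Ligaments.** Each meniscal horn is anchored by a tension-only spring
bundle: the printed stiffness (lateral anterior/posterior, medial
anterior/posterior = 216, 130, 169, 207 N/mm) is distributed as parallel
per-node springs over the terminal-face nodes, each running to a ground
point offset from the node (6 mm along the outgoing arc tangent, 1.5 mm
down, into the tibia). Slack length equals the reference length — no
pretension — and springs carry zero force when shorter than slack, so a
unit elongation of the whole bundle produces exactly the printed stiffness.

**Contact.** Node-to-surface penalty contact with Coulomb friction
μ = 0.02 couples: femoral cartilage ↔ meniscal superior surfaces, femoral
cartilage ↔ tibial cartilage, meniscal inferior surfaces ↔ tibial
cartilage, and the two faces of an inserted tear (self-contact, same μ,
switchable). The follower nodes are always on the finer tibial-side meshes
with the femoral cap as master. The penalty is 50 × the softest
participating modulus per unit (1 mm) characteristic length
(650 N/mm³ by default), sized so equilibrium penetrations stay below 1% of
the cartilage thickness. Integrated contact quantities (total force per
pair, femoral settlement) are insensitive to the penalty, but pointwise
peak pressures at the default contact resolution still shift by tens of
percent under a ×10 stiffer penalty — a coarse-discretization effect the
corresponding invariant test documents as a failure. The penalty activation is C¹-smoothed over the first
0.01 mm of penetration (removing active-set chatter at grazing contact; at
equilibrium this only offsets penetrations by ≤ 5 µm), and friction is
regularized: tangential force is a penalty on slip accumulated within the
load step, capped at μ·(normal force), under-relaxed against the previous
iterate and frozen after 30 iterations of a load step so Newton can close
on the remaining smooth problem. Contact projections are recomputed every
iteration, so multi-millimeter meniscal sliding is tracked between
iterations despite the small-strain kinematics of each state.

**Solver.** Static, geometrically linear FE (constant-strain tetrahedra)
with the femur condensed to its free rigid DOFs. Newton iteration with
incremental loading (4 steps from scratch), a residual-guarded backtracking
line search, a per-iteration increment cap (2 mm), a tiny tangent
regularization (1e-8 × max diagonal — Jacobian only, never the residual),
and secant acceleration along coherent contracting increment sequences
(sliding contact produces near-neutral modes that must travel several mm;
plain Newton crawls along them). Convergence requires the force residual
below 1e-4 × the applied load. Within an experiment matrix the intact
solutions chain as warm starts across angles, and every torn model is
solved directly at full load warm-started from the intact solution of its
angle; warm starts change iteration counts only, not converged states. All
tear simulations use one body weight (750 N), per protocol.

**Tears.** Tears are realized on existing element faces (snap-to-mesh):
a connected interior facet path approximating the tear plane is selected,
nodes strictly interior to it are duplicated, and elements on the positive
side are reconnected to the duplicates. Element count and total volume are
exactly conserved; the reported achieved length (longitudinal) or rim-width
fraction (radial) quantifies the snap-to-mesh discretization.
Full-thickness vertical longitudinal tears (7 mm stable / 14 mm unstable)
are centered radially at s = 5/6 — the center of the red zone under
equal-tercile zones — with the two circumferential end columns forming the
shared tear front. Radial tears start at the inner rim and extend outward
over 1/6 (stable) or 1/2 (unstable) of the local rim width; the outermost
column is the shared apex front. Tear faces are enrolled as a frictional
self-contact pair by default (the source protocol is silent on this; the
pair prevents interpenetration of the flap and can be disabled in config).

**Outcome measures.** Hoop stress is proxied by the maximum principal
stress (max PCS), with the fiber-projected normal stress σ_ff as a
cross-check output; compressive contact is reported through the minimum
principal stress. Transects sample max PCS at mid-height along the mid-arc
line of each region from the inner (s = 0) to the outer (s = 1) rim, using
volume-weighted nodal stress recovery and barycentric interpolation.
Tear-surface reports average max PCS over the elements adjacent to each
tear face; the difference (outer − inner) is classified favourable when
strictly positive (a tie is unfavourable, honouring the strict inequality
of the definition — positive differences press the surfaces together).
Apex reports average max PCS over the elements touching the apex node ring
in the torn and intact runs at identical material points (tear insertion
preserves element ordering). Segment displacements report anterior/
posterior-third centroid motion (positive anterior) and the mediolateral
motion of the most external midsection point (positive medial = −x).

## What the synthetic knee does and does not capture

The generator reproduces the structural features that drive meniscal
mechanics: wedge cross-sections congruent with the plateau, circumferential
fiber reinforcement, horn anchoring, compartmental contact, and plausible
screw-home/rollback kinematics. It does not capture subject-specific
condylar asymmetry (the spheres have a single radius per compartment),
cartilage thickness maps, meniscal extrusion constraints from the joint
capsule, or imaged kinematics. Passing tests therefore demonstrate
correctness of the numerical machinery, not subject-specific magnitudes.
Of the qualitative tear-healing orderings, the elevation of apex stress by
radial tears reproduces clearly (mean apex delta +0.15 MPa over the
matrix). Three orderings do not fully reproduce on the default geometry:
shorter longitudinal tears are more favourable than longer ones in 12 of
18 site-angle pairs; the lateral-over-medial ordering of mean tear-face
differences inverts by 0.002 MPa (below the stress resolution — a tie in
practice); and longer radial tears concentrate more apex stress in 17 of
18 pairs (the exception sits in the compressive regime of the lateral
posterior apex). These orderings concern 0.01-0.08 MPa differences that
plausibly depend on condyle/meniscus congruence asymmetries the spherical
condyles do not encode; the corresponding tests assert the reported
orderings and fail honestly rather than weakening the check.

## Numerical choices and degenerate inputs

- Convergence: force-residual 2-norm < 1e-4 × load; maximum penetration
  reported and required below 0.02 mm (1% of cartilage thickness).
- Degenerate meshes (zero-height wedge, inverted elements) raise typed
  errors; landmark registration rejects < 3 or collinear points.
- Ties: favourable-difference of exactly zero is unfavourable; region and
  zone terciles assign boundary centroids to the lower tercile.
- Problem sizes: the default model is ~8,000 tetrahedra / ~2,400 nodes per
  load case; the full tear matrix (2 menisci × 3 regions × 2 types × 2
  lengths × 3 angles) runs as 72 torn plus 3 intact solves. The Hertz
  verification block (80 × 80 × 120 mm, power-graded toward the indenter)
  and the single-cube material experiments are sized for closed-form
  comparison, not production runs.

## Known limitations

The convergence of absolute displacements with mesh refinement is limited
by the O(h²) chordal error of the faceted articular surfaces rather than by
element stiffness error: between the default resolution and a 1.5× uniform
refinement the femoral axial displacement still changes by ~10% (the
discrete surfaces themselves move by ~0.1 mm), and driving that below 2%
would need roughly 27× the elements. Stress orderings and force-level
observables are much less sensitive, but absolute displacement magnitudes
at the default resolution should be read with this bar in mind; the
corresponding convergence test documents the shortfall as a failure.

Linear kinematics and linear elasticity (no poroviscoelasticity, no
tension-compression asymmetry), no major knee ligaments or muscle loads,
no patellofemoral joint, penalty contact (no exact constraint enforcement),
and snap-to-mesh tears (no crack propagation, no bucket-handle or complex
tear shapes). Figure-level magnitudes from subject-specific studies are
not reproduction targets; only printed model constants and sign/ordering
semantics are.
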