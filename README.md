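# meniscusfe

Finite-element analysis of intact and torn knee menisci under weight
bearing, for biomechanics researchers studying which meniscal tears are
mechanically disposed to heal. The package builds a synthetic parametric
tibiofemoral joint (rigid bones, cartilage layers, two C-shaped menisci
with circumferential fiber reinforcement and insertional-ligament springs),
solves the static contact problem under body-weight compression at 0–30°
of knee flexion, inserts longitudinal or radial tears by node duplication,
and computes stress-based tear-stability metrics.

## The model in brief

- **Tissues.** Cartilage: isotropic linear elastic (E = 13 MPa, ν = 0.42).
  Meniscus: transversely isotropic linear elastic with the fiber axis along
  the local circumferential direction — in-plane E_p = 20 MPa, ν_p = 0.2,
  G_p = 8.3 MPa; circumferential E_f = 150 MPa, ν_f = 0.3, G_f = 57.7 MPa.
- **Structure.** Linear tetrahedra on reproducible structured sweeps; horn
  ligaments as tension-only springs (216/130/169/207 N/mm for the lateral
  anterior/posterior and medial anterior/posterior attachments); penalty
  contact with Coulomb friction μ = 0.02 between all articulating surfaces
  and across tear faces; rigid bones (tibia fixed; femur free in
  medial-lateral translation, axial translation, varus-valgus).
- **Loading.** 750 N (≈ one body weight; 375 N = half) applied to the femur
  along the tibial long axis at 0°, 20° and 30° flexion, with configurable
  screw-home and rollback coupling.
- **Tears.** Full-thickness vertical longitudinal tears (7 mm stable,
  14 mm unstable) centered in the red (outer) zone; radial tears from the
  inner rim over 1/6 (stable) or 1/2 (unstable) of the rim width.
- **Outcomes.** Hoop stress (max principal stress σ₁) transects across the
  rim; the hoop-stress difference between the outer and inner faces of a
  longitudinal tear (positive = favourable, surfaces pressed together);
  apex stress concentration of radial tears relative to the intact state;
  compartmental contact pressure/area; meniscal segment displacements.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

```python
from meniscusfe.knee import build_knee_model, KneeLoadCase
from meniscusfe.tears import TearSpec
from meniscusfe.postprocess import tear_surface_difference

intact = build_knee_model(load_case=KneeLoadCase(flexion_angle=0.0))
sol = intact.solve()
print(f"tibial reaction {intact.tibia_vertical_reaction(sol):.1f} N, "
      f"max penetration {sol.max_penetration:.4f} mm")

torn = build_knee_model(load_case=KneeLoadCase(flexion_angle=0.0),
                        tear=TearSpec("longitudinal", "MM", "middle", "stable"))
tsol = torn.solve(warm_from=sol)
rep = tear_surface_difference(tsol, torn.mesh, torn.tear,
                              node_offset=torn.tear_node_offset)
print(f"achieved tear length {torn.tear.achieved_length:.2f} mm; "
      f"hoop stress inner {rep.inner_face_hoop:.3f} / outer "
      f"{rep.outer_face_hoop:.3f} MPa -> difference {rep.difference:+.3f} MPa, "
      f"{'favourable' if rep.favourable else 'unfavourable'}")
```

prints

```
tibial reaction 750.0 N, max penetration 0.0106 mm
achieved tear length 6.98 mm; hoop stress inner 0.468 / outer 0.481 MPa -> difference +0.012 MPa, favourable
```

The reaction recovers the applied body weight (global equilibrium); the
7 mm tear snaps to two element edges (6.98 mm) of the default mesh; and at
this site/angle the outer tear face carries slightly more hoop stress than
the inner one, a favourable configuration whose surfaces are pressed
together.

There is also a CLI (`meniscusfe generate | mesh | tear | solve | post |
run-all | verify`) over YAML configs whose defaults reproduce the full
protocol matrix; `meniscusfe verify` runs the quick physics-invariant
suite.

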