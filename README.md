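# embryo3d

Serial-section spatial transcriptomics (Slide-seq and kin) measures
transcriptome-wide expression on 10-µm bead arrays, one 2D section at a time.
Each section lands on its array with an unknown rotation, shift and possibly a
mirror flip, so the 3D context — tissue shapes, volumes, expression gradients
along body axes — is lost.  `embryo3d` rebuilds it.  It is aimed at
developmental biologists and computational groups working with sectioned
spot-based spatial data who want a "virtual embryo": a registered 3D bead
cloud that can be measured and queried like a specimen.

The toolkit covers, end to end:

- **Registration.** Consecutive sections are rendered as per-cell-state
  Gaussian density images; the rigid transform (angle θ, translation t, flip
  F) between sections maximizes the normalized cross-correlation
  `Σ_s ⟨D_s^A, (R_θ F) D_s^B + t⟩ / (‖D^A‖‖D^B‖)` over an exhaustive 1° angle
  grid with FFT translation search, refined to 0.1°; pairwise transforms are
  composed outward from the middle section.
- **Tissue geometry.** Per-section tissue footprints are alpha shapes of the
  tissue's beads (bead-radius–corrected); footprints are morphed between
  sections by signed-distance interpolation and integrated over z into
  volumes (reported in 10³ µm³), plus OBJ surface meshes.
- **Virtual in situ hybridization.** Any gene rendered as a normalized 3D
  expression field; dual-gene overlays; expression profiles in equal-width
  bins along an arbitrary axis (origin, direction, inclination, rotation).
- **Localization score.** Per gene and tissue,
  `score = log2(V_tissue / V_expr)` with `V_expr` the alpha-shape volume of
  the expressing beads: 0 for ubiquitous expression, ~3 for a gene confined
  to an eighth of its tissue — a ranking of spatial restriction.
- **Axis profiling.** Principal-curve arclength (AP) and convex-hull distance
  (DV) coordinates; a negative-binomial quasi-likelihood trend test
  (`log µ = β₀ + β₁·s + log lib`, moderated dispersions, QL F-test, BH FDR,
  selection at FDR < 0.01 and |log2FC| > 0.05); DTW clustering of bin
  profiles into spatial modules (k = 8, Sakoe–Chiba band) with trend-test
  module expansion; boundary-distance gene screens (300 µm).
- **Spatial RNA velocity summaries.** Grid-averaged vectors (50 × 50 µm grid,
  50 nearest neighbours), per-bead velocity length and cosine confidence, and
  connected low-velocity regions.
- **Synthetic embryos.** A seeded generator of ellipsoidal-tissue embryos
  with planted expression patterns (uniform, gradients, focal spots,
  staggered Hox-like modules), NB count noise, planted velocity/pseudotime
  fields, and sectioning with known rigid perturbations — ground truth for
  every estimator above.

## Worked example

Simulate a 600-µm three-tissue embryo, cut it into 10-µm sagittal sections at
30-µm intervals with random per-section perturbations (rotations up to ±20°,
shifts up to ±100 µm, 10% mirror flips), register it blind, and measure it:

```python
from embryo3d import (generate_embryo, slice_embryo, register_stack,
                      registration_report, tissue_volume)
from embryo3d.synthetic import default_embryo_spec
from embryo3d.registration import compose_true_reference_transforms

truth = generate_embryo(default_embryo_spec(seed=0))
stack, applied = slice_embryo(truth, thickness=10, gap=30,
                              max_rot=20, max_trans=100, flip_prob=0.1, seed=0)
print(f"{stack.n_slices} sections, {sum(a.n_beads for a in stack.arrays)} beads")

registered = register_stack(stack)
report = registration_report(
    registered.transforms,
    compose_true_reference_transforms(applied, registered.reference_index),
    [a.coords.mean(axis=0) for a in stack.arrays],
)
print(f"median angle error:       {report.angle_error_deg.median():.2f} deg")
print(f"median translation error: {report.translation_error_um.median():.1f} um")
print(f"flips detected:           {int(report.flip_correct.sum())}/{len(report)}")

for tissue in ("trunk", "neural_tube", "heart"):
    rep = tissue_volume(registered, tissue)
    print(f"{tissue:<12s} {rep.volume_1e3_um3:9.0f} x10^3 um^3  ({rep.n_beads} beads)")
```

Output:

```
15 sections, 37375 beads
median angle error:       0.48 deg
median translation error: 5.9 um
flips detected:           15/15
trunk            95233 x10^3 um^3  (23657 beads)
neural_tube      33974 x10^3 um^3  (8314 beads)
heart            18304 x10^3 um^3  (5404 beads)
```

The registration errors compare the estimated composed transforms against the
transforms actually applied during sectioning; the volumes integrate
alpha-shape footprints (with signed-distance–interpolated virtual sections in
the 30-µm gaps) over z.

The same pipeline is available from the shell:

```sh
embryo3d simulate --out sim/ --seed 0
embryo3d register --in sim/stack.h5ad --out registered.h5ad
embryo3d volume --in registered.h5ad --tissue heart --out volumes.tsv
embryo3d vish --in registered.h5ad --gene focal0 --out field.tsv
```

Every command writes a provenance JSON (version, parameters, input checksums)
next to its outputs.

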