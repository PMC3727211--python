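# msheadem

Multiscale head-model construction and RF electromagnetic/SAR analysis
around deep-brain-stimulation (DBS) implants.

## The problem

Patients with implanted DBS leads are often denied MRI because the scanner's
RF field couples to the conductive lead (the antenna effect) and can heat the
tissue around the electrode contacts. Numerical safety assessments usually
model the head on a uniform ≥1 mm grid — but the structures that matter near
the electrode (the globus pallidus internus and the sub-millimetre medullary
laminae around it, and the contact/insulation geometry of the lead itself)
live below that resolution. `msheadem` implements the full chain needed to
quantify what that resolution costs:

1. **Two-resolution anatomy.** A 1 mm whole-head label model is refined in
   the basal ganglia by a 0.2 mm atlas through *atlas-based segmentation*:
   landmark similarity alignment (orthogonal Procrustes over AC/PC/fissure
   landmarks), then per-structure non-rigid surface registration with a
   hierarchical iterative-closest-point scheme over cubic B-spline free-form
   deformations (FFD),

       T(x) = Σ_l Σ_m Σ_n B_l(u) B_m(v) B_n(w) φ_{i+l, j+m, k+n},

   on control lattices of spacing 20, 10, 5, 3, 1, 0.5 mm, followed by label
   propagation through the inverse transform. Accuracy is scored by centroid
   distance (Dc), percent match PM = 100·TP/(TP+FN) and positive predictive
   value P+ = 100·TP/(TP+FP).
2. **Implant and dielectrics.** A four-contact lead (cubic-spline
   centerline, insulation tube, cylindrical contacts joined by a continuous
   core) is voxelised into the model; every structure receives its RF
   conductivity/permittivity (grey matter σ = 0.58 S/m, εr = 73.51; white
   matter 0.34/52.53; Pt/Ir conductor 4·10⁶ S/m; urethane insulation
   10⁻¹⁰ S/m, εr = 3) on a graded rectilinear Yee mesh: uniform 0.2 mm cells
   in a region of interest around the contacts, 1 mm cells elsewhere.
3. **FDTD + SAR.** A finite-difference time-domain Maxwell solver (lossy
   media, perfect conductors, 7-layer convolutional PML, circularly
   polarised plane-wave drive in a scattered-field formulation, −40 dB
   steady-state criterion, single-frequency DFT phasor extraction) yields
   the E-field; SAR = σ|E|²/2ρ maps are reported raw, cube-averaged over
   1 g and 10 g of tissue, and whole-head, normalised so the no-implant
   model dissipates 3.2 W/kg.

Because no paired in-vivo/ex-vivo datasets can ship with the code, every
experiment runs on an analytic ellipsoidal phantom with nuclei and
sub-voxel laminae and a *known* synthetic warp, so registration, propagation
and the resolution comparison are all validated against exact ground truth.
See `docs/methods.md` for the models, defaults and limitations.

## Worked example

```python
import numpy as np
from msheadem import (default_head_spec, make_head_phantom, make_micro_atlas,
                      fit_similarity_landmarks, NonRigidICP, extract_surface,
                      LabelVolume)

spec = default_head_spec(seed=0)
head, landmarks = make_head_phantom(spec, spacing_mm=1.0)   # the 1 mm model
fine, _ = make_head_phantom(spec, spacing_mm=0.2)           # ground truth
atlas = make_micro_atlas(fine, warp_amplitude_mm=2.0,
                         warp_spacing_mm=10.0, seed=7, head_landmarks=landmarks)

sim = fit_similarity_landmarks(atlas.landmarks, landmarks)

def surface(vol, labels):
    m = np.isin(vol.labels, labels)
    return extract_surface(LabelVolume(m.astype(np.int16), vol.spacing, vol.origin), 1)

source = surface(atlas.volume, [11]).transformed(sim.apply)  # putamen analogue
target = surface(head, [11])
result = NonRigidICP(source, target, max_iter=15, max_points=3000).fit()
print(result.summary())
```

prints the coarse-to-fine registration table (numbers from this exact run):

```
Hierarchical non-rigid ICP registration
===============================================
 level  spacing (mm)  iters   RMSE (mm)
  init             -      -      0.6368
     0         20.00     11      0.1355
     1         10.00      3      0.1228
     2          5.00      2      0.1169
     3          3.00      2      0.1090
     4          1.00      4      0.0945
     5          0.50      3      0.0801
===============================================
points: 3000
```

i.e. the synthetic two-octave warp is recovered to well below the voxel
scale, and the surface RMSE is already near its floor at the 3 mm lattice.

The full experiment — registration, label propagation, lead embedding, the
three field simulations and the SAR comparison — runs from one config:

```bash
msheadem run-all --seed 0 --outdir scratch/demo
```

and writes `report.json` with the per-level Dc table, PM/P+ scores, SAR
peaks (raw / 1 g / 10 g / whole-head) for the uniform and multiscale models,
and the electrode |E| profiles with their extrema counts.

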