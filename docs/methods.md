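# Methods

This note documents the models, numerical choices and limitations behind
`msheadem`. The package studies a single question: how does the spatial
resolution of an anatomical model around a deep-brain-stimulation (DBS)
implant change the computed RF electric field and specific absorption rate
(SAR) during MRI, comparing a uniform ~1 mm model with a multiscale model
whose implant neighbourhood is refined to 0.2 mm through atlas-based
segmentation.

## 1. Synthetic two-resolution anatomy

Real paired in-vivo / ex-vivo datasets are not redistributable, so every
experiment runs on an analytic phantom with exact ground truth:

* **Head phantom.** Nested ellipsoidal shells (skin 1.5 mm, skull 2 mm,
  CSF 1.5 mm, white-matter core) with four grey-matter blobs standing in for
  the caudate, putamen, GPe and GPi, and two thin white-matter laminae
  (0.4 mm and 0.3 mm) separating putamen/GPe and GPe/GPi. Labels are
  assigned at voxel centres, innermost primitive wins. The default outer
  semiaxes are (16, 19, 17) mm — a deliberately reduced-scale head chosen so
  that whole-domain field simulations at 0.2 mm finish in minutes on one
  CPU. The laminae thickness sits between the fine (0.2 mm) and coarse
  (1 mm) voxel sizes, and their mid-planes lie on integer millimetre
  coordinates while 1 mm voxel centres lie on half-integers: rasterising the
  same geometry therefore *provably* loses the laminae at 1 mm and preserves
  them at 0.2 mm, reproducing the resolution effect that motivates
  multiscale modelling.
* **Micro atlas.** The nuclei region is resampled at 0.2 mm under a known
  transform `W = T_ffd ∘ S`: a random similarity misalignment `S` (≤8°,
  ±6 % scale, ±3 mm) followed by a random free-form deformation. The warp
  carries two octaves of detail — bounded uniform control displacements of
  amplitude `a` on a `δ` lattice plus `a/2` on the `δ/2` lattice (defaults
  `a = 2 mm`, `δ = 10 mm`) — so a coarse-to-fine registration recovers it
  progressively rather than in a single level. The ground-truth transform is
  returned as one control grid on the fine lattice via exact dyadic B-spline
  subdivision. The amplitude bound `a < δ/2` keeps the warp fold-free.
* What the generator does **not** emulate: MRI intensities and
  intensity-dependent segmentation errors, inter-subject anatomical
  variability, partial-volume effects, or rater disagreement. Passing tests
  therefore demonstrate correctness of the *pipeline machinery* under known
  ground truth, not segmentation accuracy on real brains.

## 2. Registration engine

* **Landmark similarity fit.** Closed-form orthogonal-Procrustes with
  isotropic scale on three named landmarks (AC/PC/fissure-apex analogues);
  centroids align exactly, rotation/scale minimise the summed squared
  landmark displacement. Collinear triplets are rejected.
* **Free-form deformation.** The classic uniform cubic B-spline FFD: the
  displacement at `x` is the tensor-product interpolation of the 4×4×4
  neighbouring control displacements, with lattice coordinates `x/δ`. The
  basis is a partition of unity (constant fields translate rigidly) and has
  local support (one control point influences a 4δ cube); both properties
  are tested against a brute-force polynomial evaluator.
* **Scattered fit.** Control displacements solve a ridge-damped least-squares
  problem. The solver uses exact sparse factorisations: the normal equations
  when the lattice is small, the equivalent dual form
  `c = Aᵀ (A Aᵀ + λI)⁻¹ d` when controls outnumber samples. The default
  damping inside the ICP is `λ = 0.1`: with (near-)duplicate surface samples
  the undamped system is severely ill-conditioned and produces control
  displacements orders of magnitude above the physical deformation (the
  classic local-oscillation failure of fine FFD lattices); `λ = 0.1` keeps
  fitted control increments bounded by the data scale while changing the
  fitted field at the sample points by well under the mesh discretisation
  error. `fit_ffd_scattered` itself defaults to a nearly-neutral `λ = 1e-6`
  for pure interpolation uses.
* **Hierarchical non-rigid ICP.** Spacing schedule 20, 10, 5, 3, 1, 0.5 mm.
  Each level is initialised with the previous level's field (B-spline
  prefiltered resampling onto the finer lattice; constants reproduce
  exactly) and iterates nearest-neighbour correspondence (KD-tree, floating
  vertices against a subdivided target surface) with a scattered fit of the
  *increment* on that level's lattice, so the smooth inherited field is
  preserved away from the data. Iterations stop when the RMSE change drops
  below 1e-3 mm (at most 50, 15 in the pipeline fixture); the best iterate
  is kept, which makes the per-level RMSE non-increasing in practice. Target
  subdivision approximates point-to-surface correspondence when the
  reference mesh comes from 1 mm voxels. Floating vertex sets are
  deterministically subsampled (default ≤6000, 3000 in the pipeline) to
  bound cost.
* **Label propagation.** Pull-back through the inverse composite transform,
  computed by fixed-point iteration on `z = y − u(z)` (tolerance 0.05 mm);
  nearest-neighbour atlas lookup; small structures and laminae painted last
  so thin detail survives conflicts; voxels mapping outside the atlas keep
  the target label.
* **Scores.** Centroid distance (Dc), percent match `PM = 100·TP/(TP+FN)`
  and positive predictive value `P+ = 100·TP/(TP+FP)`, all against the
  analytic fine-grid ground truth. On the default fixture the registration
  performance (Dc) saturates at the 3 mm lattice level — finer levels change
  the mean Dc by under a tenth of the affine misalignment — while the
  surface RMSE ends well below 0.5 mm.

## 3. Electrical model

* Dielectric properties at the simulated frequency are config data; the
  bundled table uses the standard 128 MHz literature values: grey matter
  σ = 0.58 S/m, εr = 73.51; white matter σ = 0.34 S/m, εr = 52.53; skin
  0.52 / 65.4; cortical bone 0.067 / 14.7; CSF 2.14 / 84. Nuclei map to grey
  matter, medullary laminae to white matter. The implant is a
  platinum/iridium conductor (σ = 4·10⁶ S/m) with urethane insulation
  (σ = 1e-10 S/m, εr = 3). Mass densities are bundled defaults (brain 1040,
  skin 1100, bone 1900, CSF 1010 kg/m³, otherwise 1000) — not part of the
  dielectric literature table. Properties are linear, nondispersive and
  isotropic; no Cole-Cole dispersion, no white-matter anisotropy.
* **Lead.** A natural cubic spline through config-supplied control points,
  re-parameterised by arc length; four cylindrical contacts laid out from
  the distal tip with insulation gaps; the conducting core is continuous
  (the contacts are wired together). `LeadSpec` defaults to a commercial
  four-contact layout (1.5 mm contacts, 1.5 mm spacing, 1.27 mm diameter);
  the reduced-scale pipeline fixture scales this to 1 mm contacts and gaps
  with a 1.27 mm outer diameter and flush (exposed) contacts. Voxelisation
  classifies each cell centre by radial distance and arc position, and cells
  traversed by the centerline are always conductor so the staircased wire
  never breaks into disconnected segments, at any resolution.
* **Grids.** The multiscale mesh is a graded rectilinear Yee grid: uniform
  0.2 mm cells across the region of interest around the contact array,
  geometric transition (adjacent-cell ratio ≤ 1.5) to uniform 1 mm cells
  elsewhere, one global timestep. This realises "fine region embedded in a
  coarse head" in the meshing paradigm of commercial FDTD codes without true
  subgridding, and it is unconditionally consistent.

## 4. FDTD solver

* Leapfrog Yee updates with lossy-dielectric E-coefficients; materials are
  averaged onto E edges (4 adjacent cells, replicate padding at walls — the
  mirror-symmetric choice); cells at σ ≥ 1e5 S/m are perfect conductors with
  tangential E forced exactly.
* Timestep: `dt = safety / (c √(Σ 1/dx_min²))` with safety 0.99, then
  rounded down so one period is an integer number of steps.
* **Boundaries.** 7-layer convolutional PML (cubic polynomial σ grading,
  κ = 1, small constant CFS α, σ_max scaled by the local refractive index so
  material-backed layers stay matched), terminated by a PEC wall. Optional
  per-axis magnetic-wall (PMC) boundaries turn a thin column into an exact
  1-D waveguide; the dispersion/Fresnel/PML validation fixtures use this.
  Measured performance: vacuum phase-velocity error −0.3 % at 20 cells/λ,
  normal-incidence boundary reflection ≈ −60 dB with 7 layers, Fresnel
  reflection for εr = 4 within ~1.3 % at 40 cells/λ.
* **Sources.** The birdcage-like drive is an idealised circularly polarised
  plane wave realised in a *scattered-field formulation*: the incident wave
  (with a 2-period raised-cosine ramp, retarded time handled exactly) is
  analytic everywhere; the solver advances only the scattered field, driven
  by equivalent currents `J = σE_inc + (ε−ε₀)∂E_inc/∂t` where material
  differs from vacuum, and PEC edges enforce `E_scat = −E_inc`. In vacuum
  the total field is therefore the ideal uniform rotating plane wave. Soft
  additive sources (source plane, point dipole, quadrature dipole ring) are
  available for validation fixtures and linear-polarisation experiments.
* **Steady state.** The run stops when the per-period change of total
  in-tissue electric energy falls below −40 dB (or at max periods, flagged
  unconverged); phasors are then extracted by a single-frequency DFT over
  one further full period and interpolated to cell centres; implant-PEC
  cells are exactly zero in the output. Energy growth beyond 10× the running
  maximum raises an instability error.

## 5. SAR analysis

* E phasors are peak amplitudes, so raw SAR is `σ|E|²/(2ρ)` per cell; SAR is
  not computed in air or in the space occupied by the implant.
* 1 g / 10 g averages use IEEE/IEC-style cube growing: per tissue cell, a
  centred physical cube grows through a deterministic geometric ladder
  (factor 1.07 from half the smallest cell) until the enclosed tissue mass
  reaches the target; averaged SAR = enclosed power / enclosed mass. Cells
  whose cube cannot reach the target inside the domain are flagged invalid.
  No partial-cell mass correction is applied (bias below one cell shell);
  the implementation is verified against exhaustive search on small grids.
* Whole-volume ("whole-head") SAR is total absorbed power over total tissue
  mass; the bookkeeping identity Σ(SAR·mass) = SAR_w·mass_total holds to
  1e-9 relative. All field sets are scaled by one factor
  `√(3.2 / SAR_w,no-implant)` so the no-implant model dissipates exactly
  3.2 W/kg whole-head.
* Model comparison: |E| peak locations compared in world millimetres (grids
  of different resolution are commensurable), probe-point differences
  (mean ± sd), and |E| profiles along lines parallel to the electrode with
  extrema counting (runs of equal values are compressed so the zero plateau
  inside a contact counts as one minimum).

## 6. The desk-scale study conditions

The packaged experiment (`PipelineConfig` defaults, also behind
`msheadem run-all` and `scripts/acceptance.py`) runs the full chain at a
reduced scale chosen once:

* phantom as in §1; uniform grid 1 mm; multiscale fine region 0.2 mm over a
  ~5×5×12 mm box around the contact array; 7 PML layers + 3 mm vacuum
  margin;
* drive frequency 2.45 GHz for the field comparison. At the reduced phantom
  scale this keeps the per-period step count (≈1070 at 0.2 mm) and the
  total run time tractable on one CPU while preserving the physics that
  matters here — a conductive lead much longer than the fine structures
  around it, tissue loss, and sub-millimetre anatomical detail near the
  contacts. 128 MHz remains the package default for `SimulationParams`.
* three simulations (uniform+implant, multiscale+implant, uniform
  no-implant), normalised to SAR_w = 3.2 W/kg for the no-implant case.

Observed behaviour matches the physics the study targets: the multiscale
model resolves the four contacts as zero-field minima with field maxima at
the contact/insulation interfaces, its raw peak SAR near the electrode is
several-fold the uniform model's, and the whole-head SAR differs by only a
few percent between the two models.

## 7. Known limitations

* The phantom is ellipsoid-based; no realistic coil geometry (the drive is
  an idealised CP wave), no neck truncation effects, no thermal/bioheat
  modelling.
* Surface correspondence is one-way nearest-neighbour without trimming by
  default (a trim fraction is available).
* The cube-averaging mass ladder makes averaged SAR reproducible but
  discretises the cube size in 7 % steps.
* float32 field arithmetic bounds the achievable convergence floor around
  −100 dB; the −40 dB criterion is far above it.
* Only one PMC axis is supported (sufficient for the 1-D validation modes).
* Under grid refinement (1 mm → 0.5 mm) of a small lossy sphere, the
  volume-averaged interior |E| changes by ~3 % while single-point probes
  change by ~6 % — pointwise values next to staircased boundaries converge
  more slowly than regional averages, which is why the model comparisons
  report peaks over the region of interest rather than single fixed voxels.
* At a few seeds the fitted deformation is locally non-invertible near the
  lattice support edge; the affected voxels (a small fraction) keep the
  target's label during propagation instead of aborting the run.
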