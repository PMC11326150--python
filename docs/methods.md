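# Methods

## Pipeline overview

`brainmech` maps a time-resolved displacement field of the brain to
voxelwise strain, strain rate, and hyperelastic stress, then aggregates
those fields over labeled regions. The stages, in execution order:

1. **Ingest.** The displacement series is read from a 5D NIfTI
   `(nx, ny, nz, nt, 3)` (or three 4D component files). Components are
   interpreted in world (scanner) millimetres by default; a `voxel`
   convention applies the affine's 3×3 block to voxel-index offsets.
   Frame 0 is the reference configuration (diastole).
2. **Reslice.** Tissue and atlas label volumes arriving on their own grids
   are nearest-neighbour resampled onto the displacement grid through a
   supplied world-to-world 4×4 affine (FLIRT-style text matrix). Nearest
   neighbour is the only interpolation that cannot invent labels; the label
   set is preserved by construction, and target voxels outside the source
   extent become background.
3. **Trim.** Voxels outside the brain mask (label 0) are set to NaN. NaN is
   the single invalidity marker throughout: gradients, statistics and
   exports all skip NaNs, so masks propagate without separate bookkeeping.
4. **Downscale.** Amplified acquisitions exaggerate motion by a large
   factor, so one global scalar s = target / M rescales every component of
   every frame, where M is the maximum displacement magnitude over all
   finite voxels and frames. The target defaults to 0.187 mm (187 μm), a
   literature value for peak cardiac-driven brain displacement. A single
   subject-level factor (rather than per-frame factors) preserves the
   relative temporal dynamics. "Maximum over all orientations" is read as
   the Euclidean vector norm; a component-wise maximum is available via
   `downscale_norm="component_max"` since the convention is not fixed by
   the measurement itself.
5. **Mechanics.** See below.
6. **Regions.** Scalar fields are summarized per atlas label (count, mean,
   sample SD, median, p5/p95) and exported as long-format CSV for violin
   plots. Strain summaries are conventionally discussed in percent; the
   exported values are raw mm/mm and the examples multiply by 100.

## Kinematics

The displacement U(x) is treated as an Eulerian field: it lives on the
deformed configuration the scanner images. Under that convention the
*inverse* deformation gradient is what the spatial gradient delivers
directly, F⁻¹ = I − ∇U, and F is obtained by voxelwise 3×3 inversion.
This choice makes phantom ground truth exact (phantoms are constructed as
Eulerian fields) and avoids the reference/current ambiguity entirely.

∇U is computed per index axis with second-order central differences where
both neighbours are finite, first-order one-sided differences at mask
boundaries, and invalidation (NaN) where no finite neighbour exists along
some axis. Index-space derivatives are mapped to world derivatives through
the inverse of the affine's 3×3 block, so oblique grids are handled; for
an axis-aligned grid this is division by the voxel spacing. Both stencils
are exact for affine displacement fields, which is why uniform-stretch
phantoms are recovered to machine precision on every in-mask voxel; for
smooth fields the interior error is O(h²), verified by grid-refinement
tests (error ratio ≥ 3.5 when spacing halves).

Voxels where det(I − ∇U) ≤ 1e-8 or cond(I − ∇U) > 1e8 are invalidated and
counted rather than raised on: a handful of degenerate voxels (typically at
mask edges of noisy data) should not abort a subject. Both thresholds are
exposed on `PipelineConfig`.

Green-Lagrange strain defaults to the conventional E = ½(FᵀF − I); a
`paper` convention computes FᵀF − I without the half, since both forms
appear in the applied literature and the choice rescales reported strains
by exactly 2. The applied convention is logged with every run.

Strain rate uses periodic central differences over the cardiac cycle,
Ė(t_k) = (E(t_{k+1}) − E(t_{k−1}))/(2Δt) with wrap-around and
Δt = cycle_duration / n_t. Periodicity is the natural boundary condition
for cardiac-gated data; the cycle duration defaults to 1.0 s and is
configurable because heart rate is subject-specific. At least three
frames are required.

## Constitutive model

White and gray matter are modeled as isotropic, compressible Mooney-Rivlin
solids with the isochoric/volumetric split

W = (G/2)(Ī₁ − 3) + K[(J² − 1)/4 − (ln J)/2],  Ī₁ = J^(−2/3) tr(FᵀF),

whose volumetric term is polyconvex and vanishes with zero slope at J = 1.
Cauchy stress is the closed-form derivative

σ = (1/J)(∂W/∂F)Fᵀ = (G/J)·dev(B̄) + (K/2)(J − 1/J)·I,  B̄ = J^(−2/3)FFᵀ.

The analytic form is used in production for speed and accuracy; a
numerical central-difference (1/J)(∂W/∂F)Fᵀ exists only as an independent
test oracle, which agrees with the closed form to relative error < 1e-5
over 1000 random deformation gradients with J ∈ [0.9, 1.1]. In the
small-strain limit the model reduces to isotropic linear elasticity with
μ = G and λ = K − 2G/3, checked at ‖∇U‖ = 1e-4 to 1% relative.

Default moduli (kPa): WM G = 0.624, GM G = 1.10, CSF G = 0.50;
WM/GM K = 5.00e4, CSF K = 2.1e6. The near-incompressible bulk moduli mean
small volumetric strains dominate stress magnitudes — a feature of the
model, not a bug, and the reason von Mises (deviatoric) stress is the
preferred scalar. CSF is excluded from stress and energy by default
(NaN), because displacement estimates inside the ventricles are
unreliable; its constants are retained in the table and `include_csf=True`
re-enables it. Per-label material tables are possible by editing the CSV,
but per-tissue-class assignment is the default granularity.

## Temporal modes

`full_history` evaluates every cardiac phase. `single_timepoint` selects
the frame maximizing the in-mask 90th percentile (configurable) of either
displacement magnitude or von Mises strain, ties broken to the earliest
frame, and restricts all outputs to it. The percentile is computed per
frame over finite in-mask voxels with linear interpolation between order
statistics — per frame rather than pooled, since a pooled percentile
could not rank frames.

## Phantoms: what they emulate and what they do not

Phantom displacement fields stand in for subject acquisitions in all
tests. They emulate: the 5D layout and grid metadata of amplified-MRI
output, amplified (up to 25×) then downscaled amplitude handling,
pulsatile sin²(πt/T) amplitude modulation with a motion-free diastolic
reference frame, concentric CSF/GM/WM tissue shells, atlas-style labels
carved into the white-matter core, and (optionally) seeded Gaussian
displacement noise. Their strain and stress ground truths are exact
because the displacement expressions are differentiated analytically.

They do not emulate: realistic brain geometry or sulcal folding, spatially
heterogeneous pulsation (ventricular wall concentration of strain),
through-plane partial-volume effects, registration error between label and
displacement grids, or CSF flow. Passing tests therefore demonstrate the
correctness of the numerics — differentiation, inversion, constitutive
law, masking, statistics — on fields of realistic magnitude, not the
fidelity of any subject-specific result.

Phantom defaults: 1.2 mm isotropic spacing (the acquisition resolution of
cine-FIESTA brain protocols), 16–31 phases when a full cycle is simulated,
0.187 mm-scale amplitudes, fixed seed 20240801 for composite noise. Test
problem sizes (12³–32³ grids, ≤ 20 phases) are chosen as the smallest
grids on which the checked properties are non-trivial: the convergence
and recovery results are resolution-independent by construction.

## Numerical choices and edge cases

- Percentiles use linear interpolation (numpy default) over finite values.
- Region SD is the sample (n−1) estimator; a single-voxel region reports
  NaN spread rather than 0.
- Downscaling a field with no finite nonzero displacement is an error (the
  scale would be undefined); downscaling twice is a no-op (s = 1).
- Symmetric tensor fields are validated to ‖T − Tᵀ‖ ≤ 1e-10 and stored
  with exact symmetrization after products.
- NIfTI tensor export packs symmetric tensors as 6 trailing channels
  (xx, yy, zz, xy, xz, yz), general tensors as 9 row-major; VTK export
  writes legacy ASCII STRUCTURED_POINTS with a 9-component tensor array,
  one frame per file.
- The bundled 133-entry atlas lookup (background + 132 anatomical labels)
  follows the BrainCOLOR naming convention used by SLANT-style
  segmenters; it is a synthetic reconstruction of that convention shipped
  so atlas ids resolve to names without running any external tool. The
  built-in `vascular_dementia` region set contains the 12 left/right ids
  of the caudate, cerebral white matter, hippocampus, pallidum, putamen
  and thalamus proper.

## Known limitations

- Isotropic material model only; anisotropic fiber-reinforced white-matter
  models (and hence axonal strain along diffusion directions) are out of
  scope.
- The downscaling target is a cohort-level literature value, not a
  subject-specific calibration; all reported magnitudes inherit that
  scaling.
- Registration (computing the world-to-world affine) is consumed as an
  input, never estimated; segmentation quality is likewise inherited.
- The strain-rate differencing assumes the acquisition covers exactly one
  periodic cardiac cycle.
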