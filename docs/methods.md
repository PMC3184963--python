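# Methods

## The measurement model

Fluorescent microangiography fills perfused vessel lumina with fluorescent
microspheres, so a confocal z-stack of the green channel is, up to imaging
degradation, an indicator function of the vascular lumen. The quantification
therefore reduces to voxel bookkeeping plus one geometric model:

**Capillary volume.** A voxel is lumen-positive when its green intensity
exceeds a recorded threshold. Capillary volume is the product of the
positive pixel area in each optical section and the section spacing,
`V_cap = Σ_z A_z·Δz`, which is identically `N·dx·dy·dz` for `N` positive
voxels. The identity is exercised against an independently written per-slice
oracle in the tests. Default geometry: `dx = dy = 0.73 µm` (a typical value
for a 20× objective at zoom 2; the lateral pitch is *never* assumed
silently — it is read from a JSON sidecar or an explicit override),
`Δz = 0.8141 µm`.

**Glomerular volume.** The tuft envelope is modelled as a solid ellipsoid,
`V = 4πabc/3`. How `a, b, c` are to be extracted from a stack is
underdetermined, so the package makes the rule explicit and configurable
(`MeasureConfig.envelope`):

- `hull` (default): the solid convex hull of the in-ROI lumen voxels,
  moment-matched to an ellipsoid. The hull's centroid and second-moment
  tensor are computed exactly by tetrahedral decomposition and the semi-axes
  are `√(5λᵢ)`; for a voxelized solid ellipsoid this recovers the generating
  semi-axes (tested to 5% over random orientations at the anisotropic native
  voxel geometry). The hull is the natural envelope because the tuft surface
  is defined by its outermost capillary loops and the tuft is approximately
  convex. A morphological-closing variant (`closing`, metric ball via
  Euclidean distance transforms) and a fit of the supplied ROI itself
  (`roi`) are available; closing alone is *not* the default because at
  physiological lumen fractions the closed mask remains a partly hollow
  shell, whose second moments overestimate the semi-axes by up to √(5/3).
- `roi` is the right choice when the envelope is annotated independently of
  the vessels, e.g. when isolating the effect of glomerular enlargement at
  fixed capillary geometry (density then scales exactly as f⁻³ with
  enlargement f).

**Densities.** Glomerular capillary density is the quotient
`V_cap / V_glomerulus` (dimensionless, in [0, 1]; a quotient above 1 is
rejected as a mask/fit inconsistency). Peritubular capillary density is the
lumen volume fraction of the cortical field after the glomerular tufts have
been excluded from both the vessel mask and the field — mirroring the
negative-pen-tool workflow. Per-animal aggregation is the arithmetic mean
over the six evaluated glomeruli, the animal being the unit of analysis.

## Segmentation defaults

- Threshold: Otsu on the green channel per stack, with a fixed-threshold
  escape hatch; the resolved threshold is always logged. A constant image
  under Otsu is an error that advises the fixed mode.
- Connectivity 26 for component labelling (lattice-based; volumes are
  metric through the voxel volume, labelling is not anisotropy-corrected,
  matching common practice).
- Despeckling: components below 27 voxels (≈ one 3×3×3 clump) are removed —
  a conservative guard against isolated bead-clump artifacts. Overridable,
  and logged with removed counts.

## The phantom generator

No public image data exist for this preparation, so correctness is
established on synthetic stacks with exact ground truth. The generator is a
first-class, tested module; its defaults *are* the study conditions used by
the validation suite.

**Glomerulus kind.** Capillary loops are perturbed-circle arcs on spherical
shells inside the tuft ellipsoid (semi-axes default (75, 70, 64) µm →
envelope ≈ 1.4×10⁶ µm³). 60% of loops sit just under the envelope surface —
in vivo the outermost loops define the tuft surface, and this makes the
envelope observable from the lumen mask — and the rest populate the
interior. Loops are added until the rasterised lumen volume reaches a
requested pre-dropout capillary density (default 0.30, i.e.
≈ 4.2×10⁵ µm³, sized to the 2–5×10⁵ µm³ range established for rat glomeruli
by electron-microscopic morphometry); an unreachable target is an error
after a bounded number of loops. Tube radii are Gaussian around 3.5 µm
(σ 0.5 µm). Connectivity of the loop set is guaranteed constructively: if
the rasterised union is disconnected, straight connector tubes
(afferent/efferent-like bridges) are added until one component remains.

**Segmental dropout.** Each loop is split into 8 arcs; dropout removes whole
arcs — not scattered voxels — until the removed fraction of the *rasterised*
volume reaches the target. Removal is accounted with per-voxel coverage
counts so that tube overlaps do not bias the realised fraction (a naive
analytic-measure accounting under-delivers dropout by ~8 points at 50%
dropout). Truth volumes are always voxel count × voxel volume, exactly.

**Enlargement.** The truth ellipsoid scales by the enlargement factor f
exactly (volume by f³). By default the loops are generated inside the
enlarged envelope (`loops_follow_enlargement=True`), so an enlarged
glomerulus also carries more capillary volume — the SNx preset
(f = 1.4, dropout 0.35; cortex dropout 0.5) thereby reproduces the disease
pattern: glomerular volume ↑, capillary volume ↑, both densities ↓. With
`loops_follow_enlargement=False` the capillary geometry is frozen in the
un-enlarged tuft, isolating pure envelope growth.

**Cortex kind.** An anastomotic plexus of wandering spline tubes (half start
on an existing tube, creating junctions) grown until the lumen fraction of
the field outside the glomerular ROIs reaches `plexus_density`
(default 0.05 ± 0.005). Embedded glomerular tufts (scaled to 35% of the
default tuft so several fit a 190×190×120 µm field) are placed by rejection
sampling with an exact ellipsoid-disjointness test; their ROI masks are part
of the truth manifest so the exclusion workflow can be exercised. The plexus
is carved out of the ROIs, making ROI exclusion recover the plexus volume
exactly on the true mask.

**Imaging model.** Green = mask × multiplicative speckle (smoothed Gaussian
field, grain 1.5 µm, amplitude 0.35 — the beads are far below voxel size, so
granular texture, not individual spheres, is the observable) convolved with
an anisotropic Gaussian PSF (σ_xy 0.6 µm, σ_z 1.2 µm) plus additive Gaussian
noise (σ 6 of 255); red = uniform autofluorescence (level 30) over the
parenchyma (outside the tuft for glomerulus kind, outside the vessels for
cortex kind), same PSF and noise. 8-bit by default, clipped to the dynamic
range. Everything is a pure function of (params, seed): identical inputs
give byte-identical stacks.

**What the phantom does not emulate.** Real acquisitions show
depth-dependent attenuation, bead clumping and perfusion failure modes,
anisotropic PSF asymmetries and tissue autofluorescence bleed-through into
the green channel; vessels are idealised constant-radius tubes without
diameter tapering or true glomerular lobulation. Passing tests therefore
demonstrate that the *measurement chain* is correct and unbiased under a
realistic noise model — not that segmentation would be this accurate on
arbitrary real data.

## 2D immunostain comparator

Sections are composed and analysed in haematoxylin/eosin/DAB absorbance
space with the published stain vectors (scikit-image's `rgb2hed`). Stain
positivity is a recorded threshold on the deconvolved DAB channel (default
0.15 absorbance units; a hue-gate fallback exists for non-standard
chromogens). The synthetic section generator scatters elliptical DAB blobs
until the stained fraction is within 0.5 points of target and reports the
exact realised fraction; noise is modelled as stain-density heterogeneity in
absorbance space, under which recovery stays within 1 point.

## Scoring and statistics

- `GSI = Σᵢ i·Fᵢ/100` with `Fᵢ` the percentage of (conventionally 80)
  glomeruli at grade i ∈ {0..4} (0 normal; 1: ≤25% sclerotic area; 2:
  25–50%; 3: 50–75%; 4: 75–100%). Linear in the distribution, bounded
  [0, 4]; grading itself is visual and supplied as input.
- Skew-distributed endpoints are summarised as geometric mean ×/÷ tolerance
  factor with `tf = exp(SEM of ln x)` — an SEM-like multiplicative band; this
  definition is an explicit interpretation of the ×/÷ convention.
- Group comparisons use the equal-variance two-sample Student's t-test
  (Welch behind a flag), two-sided, significance at p < 0.05; skewed mode
  log-transforms first and is tested to agree exactly with the normal-mode
  test on the logs.

## Cohort simulation and problem sizes

The cohort driver re-enacts the two-arm design: 5 animals per arm, 6
glomeruli per animal, one cortical field per animal. Between-animal
variability is lognormal jitter on tuft size (CV 5%) and capillary density
target (CV 5%) plus clipped Gaussian jitter on dropout (σ 0.03); the healthy
arm keeps dropout at zero. All seeds derive from the single config seed, and
a rerun of the same config is byte-identical.

Single-phantom validation (volume recovery, Dice, dropout monotonicity,
enlargement scaling) runs at the native voxel geometry
(0.73 × 0.73 × 0.8141 µm). Replicated cohort studies (100 effect replicates,
50 null replicates) use a decimated "coarse" geometry (3.5 µm isotropic)
with the same µm-scale morphology and imaging model — the package's chosen
problem size for ensemble statistics, where the endpoints are contrasts and
p-values rather than absolute recovery. At the coarse geometry the
segmentation bias on thin tubes is ≈ 7% (symmetric across arms); at the
native geometry capillary-volume recovery is within ≈ 1% and Dice ≥ 0.93.

## Numerical choices and degenerate inputs

- Tube rasterisation stamps metric balls (radius rounded to 0.1 µm) along
  centerlines resampled at half the smallest voxel pitch; anisotropy is
  honoured via the physical spacing.
- Ellipsoid fits require ≥ 4 non-coplanar foreground voxels; planar or
  collinear sets raise a degeneracy error naming the smallest moment.
  Hull fits subsample point clouds above 60 000 voxels deterministically.
- Empty ROIs in the glomerular evaluation are excluded from the per-animal
  mean with a warning and a logged count; an all-empty evaluation is an
  error.
- Dropout 0 is the identity (same object), dropout 1 the empty network.
- `geometric_summary` requires n ≥ 2 strictly positive values; constant data
  give tolerance factor exactly 1.

## Known limitations

- The ellipsoid-envelope model understates volumes of strongly lobulated or
  concave tufts; the hull is convex by construction.
- Peritubular density is a volume fraction of the *evaluated* field;
  it is not stereologically corrected for section thickness effects.
- The IHC comparator assumes standard DAB/haematoxylin chemistry; stain
  normalisation across slides is out of scope.
- Connected-component labelling is lattice-topological, not metric; at
  highly anisotropic spacings 26-connectivity can bridge voxels that are
  metrically distant.
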