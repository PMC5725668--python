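# Methods

`carti3d` quantifies the 3D morphology of mouse articular cartilage from
dual-channel autofluorescence block-face ("cut'n view") image stacks. This
note documents the models, the numerical choices, and what the synthetic
phantom does and does not emulate.

## Imaging model and calibration

A block-face acquisition yields an inherently co-registered stack per
fluorescence channel: the ultraviolet (UV) channel, in which mineralized
subchondral bone autofluoresces strongly while cartilage and the opacified
embedding medium stay dark, and the near-infrared Cy5 channel, in which
articular cartilage is the *darkest* structure — below both bone and
background. Default calibration is 1.218 µm/pixel in-plane and 5 µm cutting
thickness; 2,000 µm of cutting depth therefore produces 400 sections.
Analysis runs on an isotropic 5 µm grid; in-plane downsampling uses
area-based local-mean resampling (`skimage.transform.resize_local_mean`),
which preserves constants and does not alias. Axis order is `(z, y, x)` with
`z` the cutting depth, `y` anterior-posterior, `x` medial-lateral; a
`medial_side` flag maps the low- or high-x half to the medial compartment,
since left and right limbs mirror and the mounting convention is the
operator's choice.

## Segmentation chain

Bone (UV): Gaussian smoothing (`sigma_bone`, default 5 µm = one voxel) →
Otsu threshold (256 histogram bins over the observed range, foreground
above threshold, ties resolved toward the lowest maximizing threshold) →
binary closing-then-opening with a digital ball (`morph_radius`, default
10 µm; the closing/opening composition is idempotent) → cavity filling
(6-connectivity, so enclosed marrow-like voids become part of the mask and
the mask encloses *all* bone tissue) → removal of components below
`min_component` (default 1,000 voxels).

Cartilage (Cy5): voxels inside the bone mask are saturated to the stack
maximum ("mask subtraction": bone cannot survive the subsequent inversion)
→ Gaussian smoothing (`sigma_cartilage`, 5 µm) → inversion `v → max − v`,
making cartilage the brightest class → Otsu threshold → components kept only
if they lie within `adjacency_margin` (default 25 µm) of the bone surface
and exceed `min_component` voxels. The adjacency filter operationalizes
"articular cartilage is a layer on bone" and rejects dark distractors
floating in the background; setting the margin to infinity disables it.

One numerical choice deserves emphasis: the cartilage Otsu threshold is
computed from the histogram of voxels *outside* the bone mask (the threshold
still applies to the whole inverted volume). After saturation and inversion
the full histogram is trimodal — bone pinned at zero, background in the
middle, cartilage on top — and with bone occupying half the volume the
between-class criterion would otherwise split bone against everything else,
classifying the entire non-bone volume as cartilage. Restricting the
histogram to the subtracted (non-bone) voxels restores the bimodal
background/cartilage problem the threshold is meant to solve. With no
exclusion mask the operator is the textbook Otsu threshold.

Both thresholds, all component counts and every parameter in use are
written to the log, so a run is auditable after the fact.

## VOI mapping

The cartilage mask is projected along `z`; the projection is split at its
centroid's x-coordinate (robust to off-center mounting), and each half
contributes its largest 4-connected component as the compartment footprint.
If the projection forms a single connected component the sample presents
only one plateau and the missing compartment is reported as an error rather
than splitting one structure in two. Each volume-of-interest is an
axis-aligned box of fixed physical size — 500 µm medial-lateral × 800 µm
anterior-posterior by default, i.e. 100 × 160 voxels at 5 µm — centered on
its footprint centroid, clipped (with a log entry) if it would leave the
volume, and spanning the full stack in `z`; the cartilage mask itself
limits where thickness is averaged. Centering on the *cartilage* footprint
is the default because cartilage is the quantified tissue and a fully
eroded plateau still yields a stable centroid from its surviving margin
ring; a config flag (`voi_anchor`) is reserved for bone-anchored placement.
Placement is deterministic and translation-equivariant, and the physical
VOI size is identical across samples — the property that makes thickness
averages comparable between animals.

## Local thickness

Thickness at a voxel is the diameter of the largest sphere that fits
entirely inside the structure and contains the voxel — the standard
model-independent definition in bone and cartilage histomorphometry. It is
computed as exact Euclidean distance transform → reduction to the distance
ridge (centers whose sphere is contained in a neighbour's sphere are
dropped; this does not change the result) → sphere inflation, painting
diameters largest-first. Discrete conventions: the radius at a center is
the distance to the nearest *background voxel center*, spheres cover voxels
strictly closer than the radius, and all comparisons are done on integral
squared distances, so there is no floating-point tie ambiguity. Under this
convention a slab an even number of voxels thick measures exactly its true
thickness, an odd slab measures one voxel high, and digital balls measure
their diameter to within one voxel — the discretization limit of a
center-based sphere model. The mask is padded with background before the
transform, so spheres are bounded by the structure itself, never truncated
by the image edge. The VOI mean is volume-weighted (over cartilage voxels,
not surface points), and spheres may extend beyond the VOI as long as they
stay inside the mask; an empty VOI∩cartilage intersection — the
full-erosion case — reports mean 0 over 0 voxels by definition.

## Group statistics

Per compartment: one-way ANOVA with Tukey HSD post-hoc across groups
(`scipy.stats.f_oneway` / `tukey_hsd`; unbalanced designs get the
Tukey-Kramer adjustment), and two-tailed paired Student's t-tests for
matched contralateral/operated limb pairs (`scipy.stats.ttest_rel`). All
p values are clipped to [0, 1]. Degenerate inputs take limiting values with
an explicit warning: identical pairs give (t = 0, p = 1); zero-variance
nonzero differences give (t = ±inf, p = 0).

## The phantom: what it emulates, and what it does not

The phantom is a simplified tibial epiphysis: a solid bone block whose top
surface carries two gently domed plateaus (cosine dome, default 20 µm
relief) separated by a notch groove (40 µm), with a cartilage layer draped
over each plateau (defaults: medial 60 µm, lateral 80 µm). Channel
intensities are tissue means (8-bit scale: UV bone 200 / cartilage 30 /
background 20; Cy5 bone 180 / background 90 / cartilage 25 — values chosen
to respect the qualitative contrast ordering of the imaging method, with a
mildly fluorescent background because the opacified embedding reduces but
does not null its signal) plus additive Gaussian noise (default sd 10,
about 15% of the Cy5 cartilage-background contrast), clipped at zero.
Optional osteoarthritic features: an elliptical medial lesion in which the
cartilage is reduced to a residual thickness (0 = full-thickness erosion
down to the bone plate) and a marginal medial osteophyte (hemispherical
bone bump with a thin cartilage cap).

Cartilage is voxelized as per-column vertical extent below the continuous
bone surface. On flat plateaus this is exactly the surface-normal
thickness, which gives closed-form ground truth (a 50 µm layer at 5 µm
voxels is exactly a 10-voxel slab); on the gentle default domes the
vertical and normal thickness differ by under 2%. The layer additionally
carries a linear anterior-posterior thickness gradient (default 10 µm
peak-to-peak across the VOI length). This serves two purposes: real
cartilage is not uniformly thick, and the gradient spans exactly one
two-voxel quantization period of the sphere-based thickness measure, so
the VOI average responds continuously to sub-voxel thickness changes
instead of snapping to whole voxel layers. Without it, simulated
between-animal differences quantize and paired t-tests become badly
conservative; with it, null cohorts reject at the nominal rate.

The generator's reported "true" VOI mean is the voxel-weighted mean column
thickness inside the nominal VOI — the quantity a volume-weighted local
thickness measurement estimates on a thin draped layer — and agrees with a
brute-force sphere-fitting oracle within one voxel on flat-plateau
phantoms.

Not emulated: trabecular microarchitecture, optical point-spread and
sub-surface bleed-through, chondrocyte cellularity (not visible in these
channels), and intensity statistics of any real instrument — tissue levels
are free parameters, and all tests treat them as such. Passing phantom
tests therefore demonstrates the correctness of the computational chain
under the stated contrast ordering, not instrument-specific performance.

## Cohort simulations and study sizes

Paired cohorts emulate the surgical design: per animal one contralateral
limb (no lesion) and one operated limb with a full-erosion medial lesion
sized to cover the whole VOI (elliptical radii 0.8 × the VOI extents,
centered on the plateau footprint — so the mapped medial VOI lies inside
the lesion), the lateral compartment spared. Per-limb, per-compartment
thickness is jittered with sd 4 µm around the base values (5-7% biological
variation). Group size n = 4 pairs matches the study design the pipeline
is built for.

Simulation studies (detection power over 100 cohorts, type-I calibration
over 200) run the *full* imaging pipeline per sample on a scaled-down
phantom — grid 40 × 64 × 96 voxels at 5 µm with a proportionally smaller
100 × 160 µm VOI — keeping every geometric ratio that matters (VOI inside
plateau footprint, lesion covering the VOI, cartilage 12-16 voxels thick).
Single-sample checks (parameter recovery, Dice against truth) use the
full-size phantom (56 × 272 × 360 voxels, i.e. 1.8 mm medial-lateral — the
scale of a real tibial plateau) with the standard 500 × 800 µm VOI. These sizes are the package's simulation design; they were chosen so
the whole validation battery runs on a laptop-class single core.

## Known limitations

- Thickness is sphere-based; surface-normal (ray-cast) variants are out of
  scope, as are cartilage volume and surface-area outcomes.
- The segmentation assumes the qualitative contrast ordering above;
  channels with inverted contrast are rejected by the phantom validator but
  cannot be detected in real data.
- Otsu thresholds are computed volume-wise (3D), not per slice.
- The morphological step is closing-then-opening; other operator orders are
  not configurable.
- Compartment splitting assumes the two plateaus project to separate
  connected components; a segmentation that bridges them across the notch
  would be mis-split (the log records the split line for QC).
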