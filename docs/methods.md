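# Methods

## Pipeline model

The package treats tumor conspicuity across viewing directions as a
measurable, reconstructible quantity. Let `S` be the SUV volume on an
anisotropic grid (default 2.04 × 2.04 × 3.00 mm) and `M_θ` the binary 2D
tumor mask predicted on the maximum intensity projection at angle `θ`.
Backprojecting `M_θ` (extrusion along the ray direction followed by
inverse rotation) gives a binary volume `B_θ`; the segmentation prior is

    P = clip_floor( normalize( S · Σ_θ B_θ ) )

where the sum runs over the 18 angles of the schedule [−90°, 90°) at 10°
steps, `normalize` divides by the global maximum, and `clip_floor` zeroes
voxels below the 5th percentile of the strictly positive values. A voxel
scores high when many views agree it belongs to a lesion *and* its uptake
is high; single-view streak artifacts score low and are largely removed
by the noise floor.

### Assumptions

- CT and SUV share one grid (the preprocessing stage resamples to a
  common spacing; linear interpolation for intensities, nearest-neighbour
  for labels).
- Tissue decomposition sees raw HU. Its windows (bone ≥ 200; lean
  [−29, 150]; adipose [−190, −30]; air < −190) extend beyond the model
  clip window [−100, 250], so classification runs before clipping. The
  (150, 200) HU gap between lean and bone is left unassigned on purpose:
  those voxels carry no tissue channel but remain visible in the original
  channels.
- Rotation is about the craniocaudal (z) axis with the reduction along
  the anterior-posterior (y) axis, i.e. angle 0 is a coronal MIP. The
  rotation operates in index space; in-plane spacing is isotropic in the
  default grid, so no spacing-aware correction is applied.

## Numerical choices

**Rotation and padding.** Volumes are padded in-plane to the diagonal
(plus a 2-voxel margin) before rotation, so no content ever leaves the
frame at oblique angles. Angles that are multiples of 90° are exact array
transpositions — no interpolation, giving exact test anchors at 0° and
−90°. Oblique angles use first-order (linear) resampling around the
in-plane center `((P−1)/2, (P−1)/2)`.

**Mask-mode projection is conservative by construction.** Projected
ground truth (and any mask-mode MIP) rotates the binary volume with
linear interpolation and marks every strictly positive projected pixel as
foreground. With nearest-neighbour forward rotation an isolated
foreground voxel can vanish (an input voxel need not be the nearest
neighbour of any output pixel); with the linear → (>0) rule, every
foreground voxel contributes positive weight to the output pixel nearest
its rotated position, and the nearest-neighbour *inverse* rotation used
by backprojection therefore provably recovers every foreground voxel at
every angle. This is what makes the round-trip containment property —
every truth voxel reaches the full overlap count of 18 under an oracle 2D
segmenter — exact rather than approximate. The cost is a sub-voxel
dilation halo on projected masks at oblique angles.

**Backprojection** uses nearest-neighbour inverse rotation so per-angle
contributions stay binary and the 0–18 overlap count semantics stay
well-defined before SUV weighting.

**Prior normalization order.** The fused volume is divided by its global
maximum first; the percentile floor is applied second, computed over the
strictly positive voxels only (the vast majority of voxels lie outside
every extrusion and are exactly zero, so an all-voxel percentile would
remove nothing; an all-voxel mode is available via
`finalize_prior(..., positive_only=False)`). The cut is strict
(`value < floor`), so a 0th-percentile floor removes nothing and a
5th-percentile floor removes exactly the bottom 5% of distinct positive
values. An all-zero fused volume returns an all-zero prior without
division errors.

**Masked-channel normalization.** The tissue-wise SUV channels are mapped
to [0, 1] through the fixed [0, 15] SUV window (keeping uptake comparable
across scans); the tissue-wise CT channels use an affine map over each
channel's occupied HU range, since no fixed window is meaningful across
the four tissue classes. Both choices are confined to
`make_tissue_channels` and can be bypassed with `normalize=False`.

**Surface distances.** Surface voxels are mask voxels with at least one
face-adjacent (6-neighbourhood) background voxel; the volume boundary
counts as background. Distances are Euclidean between surface voxel
centers in physical mm. HD95 pools both directed distance sets before
taking the 95th percentile; ASD is the mean over the same pooled
multiset. Either mask empty ⇒ the distance is undefined and reported as
NaN with a warning. Dice of two empty masks is 1.0 (one empty, one not:
0.0) so cohort loops never divide by zero.

**Lesion extraction and detection.** Components use 27-connectivity;
volume is voxel count × spacing product; components of ≤ 0.3 ml are
discarded from *both* truth and prediction. A truth lesion is detected
when the predicted mask overlaps it in at least one voxel (the most
permissive defensible reading; a fractional-overlap threshold is a
parameter). Recall and precision ratios with empty denominators are NaN,
not errors.

**Wilcoxon comparison.** Paired, two-sided, zero differences dropped;
the exact null distribution is used for n ≤ 25 (verified against full
enumeration of sign patterns), the normal approximation above.

## The phantom generator

The generator emulates the structure the pipeline relies on, not PET
physics. Defaults (chosen once, as representative of whole-body FDG
studies): 64³ voxels at 2.04 × 2.04 × 3.00 mm; an elliptic-cylinder body
(semi-axes 55 × 42 mm) with an adipose outer shell (−100 HU), a lean core
(40 HU) and a bone spine column (400 HU) in air (−800 HU), CT noise 10 HU;
soft-tissue background SUV 1.0 with noise SD 0.05, near-zero uptake
outside the body; one bladder-like physiologic hot spot at SUV 6 that is
*not* ground truth; lesions as ellipsoids (isotropic-mm radii converted
to anisotropic voxel radii via the spacing), radius 5–11 mm, uptake
2.5–8, placed fully inside the body without mutual overlap, with a
bounded-retry error naming the lesion that failed to fit.

The `hard_case_config` preset fixes the lesion list to (9 mm, SUV 4),
(5 mm ≈ 0.5 ml, SUV 3) and (8 mm, SUV 1.6) over background 1.0 — one
sub-1 ml lesion and one barely-avid lesion per phantom, the two failure
modes the prior is meant to rescue. Test suites run it on 48³ grids with
body semi-axes 40 × 34 mm so the body fits the smaller field of view.

What the phantom does **not** model: reconstruction (Poisson sinogram)
noise and partial-volume blur, organ-level anatomy and physiologic uptake
patterns beyond one hot spot, respiratory motion, and inter-patient field
-of-view variation. Passing tests therefore demonstrate the geometric and
statistical correctness of the pipeline — containment, overlap counting,
metric definitions, direction of the prior's effect — not clinical
segmentation accuracy on patient data.

## The reference segmenters are instruments

The 2D threshold segmenter (cut on the SUVorgMIP channel) and the oracle
segmenter (replays projected truth) exist to exercise and bound the
geometry: with the oracle, the prior must localize every lesion (score
1.0), which upper-bounds any trainable backend on the same scan. The 3D
reference rule — tumor where SUV ≥ 2.0, lowered to 1.2 where the prior is
positive — is calibrated to the phantom's SUV scale and exists to make
the prior's benefit measurable: the barely-avid (SUV 1.6) lesion is
invisible to the baseline rule and recovered in prior mode, which is the
testable analogue of the direction of effect expected from prior-informed
networks. Neither threshold is a clinical claim; both are parameters.
Neural 2D/3D backends (UNet++-style, 3D UNet / dynUNet / nnUNet) are
registry hooks behind the same contracts and are out of the core test
surface; a template of customary training settings (Dice+Focal loss,
Adam 1e-4, weight decay 1e-5, dropout 0.2, batch size 1 in 2D; 160³
patches with 0.25 overlap in 3D) is recorded in the interface modules.

## Problem sizes

The shipped suites use 48³ hard-case phantoms (20 for prior quality, 12
for the paired baseline-vs-prior comparison), 18 angles each, ≤ 24³
random volumes for the rotation oracle and ≤ 12³ random mask pairs (200)
for the brute-force metric oracles. These sizes exercise every code path
— including anisotropy, padding, and the percentile floor — while keeping
the full suite and the acceptance script each within a couple of minutes
of CPU.

## Known limitations

- The dilation halo of mask-mode projection slightly inflates projected
  truth at oblique angles; 2D Dice against projected truth is
  correspondingly optimistic near lesion rims.
- The prior's SUV weighting means a lesion with uptake at exactly the
  background level would receive prior support but minimal contrast; the
  localization score is rank-based and robust to this, voxel-level prior
  contrast is not.
- `prior_1` vs `prior_2` differ only in which 2D segmenter produced the
  masks; with the deterministic backends shipped here the two modes are
  structurally identical, so comparisons of the two provenances are only
  meaningful with trained backends.
- Physical-space (spacing-aware) in-plane rotation is not implemented;
  it is unnecessary for in-plane-isotropic grids like the default.
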