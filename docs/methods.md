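# Methods

This note documents the models, parameters and numerical choices behind
`pulpseg`, and what its synthetic-phantom validation does and does not
establish.

## Scope and assumptions

The pipeline targets dentate-jaw CBCT volumes acquired in **open-bite
position**: the maxillary and mandibular teeth must not overlap on axial
slices, so that a dark gap separates the dentitions in the sagittal maximum
intensity projection (MIP). Closed-bite scans are rejected with an explicit
error. Axis convention: x = left–right, y = anterior–posterior,
z = inferior–superior; axial slices are constant-z planes. All distances
are in millimetres via the voxel spacing; anisotropic grids are accepted.
Intensities are used only ordinally (pulp dark, dentine/enamel bright), so
no HU calibration is required.

## Arch partition

Hard tissue is thresholded on the sagittal MIP (Otsu by default,
overridable). Above-threshold MIP pixels are split into two seed sets at
the largest empty z-gap; a k-nearest-neighbour classifier (k = 5, odd to
avoid vote ties; Euclidean distance in mm; exact ties resolved by the
nearest seed) labels hard-tissue voxels by their (y, z) coordinates. Voxel
rather than slice classification is used because arch membership only
depends on position relative to the bite gap. The arch curve
y = ax² + bx + c is fitted per arch by weighted least squares on the axial
projection of that arch's hard-tissue voxels, each (x, y) weighted by its
summed projected intensity. The curve's arc-length parameterization is
tabulated on a dense grid and extended ~15 mm beyond the fitted domain so
that end planes can be placed just outside the outermost teeth.

## Separation planes

The plane cost combines a mean-intensity term and a gradient term,

    C(P) = α (1/Nₚ) Σ I(pᵤ) + β Σ I(pᵤ) |∇I(pᵤ)/|I(pᵤ)| × n|,

with α = β = 1 by default. Samples are a regular 32 × 32 grid (Nₚ = 1024)
over ±8 mm in-plane; intensity and gradient are trilinearly interpolated
(gradients by central differences in intensity/mm, one-sided at borders).
The division by |I| is guarded: samples with |I| below 10⁻⁶ of the volume's
intensity range contribute nothing, since the printed form is singular in
air. Samples outside the grid contribute zero to both terms — a plane
sampled mostly outside the volume is therefore artificially cheap, which is
why the pipeline evaluates cost profiles on a z-crop of the arch rather
than tiny padded volumes.

The profile along the curve (0.25 mm stations) is smoothed with a
normalized 11-tap Hanning window (reflect padding; window length 1 is the
identity) to suppress the dips the dark pulp causes inside each tooth.
Strict local minima at least `min_tooth_width` = 4 mm apart (smaller than
any adult mesiodistal width) are kept, lower cost winning on conflicts and
exact ties keeping the earlier station. Each minimum is refined by
exhaustive search over rotations φ₁, φ₂ ∈ [−20°, 20°] in 2° steps about
the x and y axes, ties broken toward smaller |φ₁| then |φ₂|. VOIs are the
axis-aligned boxes between consecutive planes (outward normals); voxels
violating either plane inequality are masked to the volume minimum.

## Pulp segmentation

Grayscale hole filling is reconstruction-by-erosion from a border-anchored
seed; it is extensive and idempotent. The marker takes
diff = fill(I) − I, thresholds the positive values with Otsu, keeps the
connected component containing argmax(diff) and intersects it with a
2 mm ball around that voxel. The valley mask is the hole-filled black
top-hat of the Gaussian-blurred image (σ = 0.15 mm), binarized by Otsu by
default ("positive", i.e. v > 0, is available and exact on noise-free
images but floods under acquisition noise, where the top-hat is positive
nearly everywhere). The structuring element radius is 2.0 mm: it must
exceed the adult pulp-chamber semi-width — with a smaller element the
top-hat responds only near the chamber wall and the hole-filled centre
takes the weak rim minimum, which Otsu then cuts — while canals are far
narrower. Binary reconstruction (dilate-and-mask to the fixed point,
implemented as the union of marker-touching components) yields the raw
pulp. Connectivity is 26-connected in 3D, 8-connected in 2D, everywhere.

By default the morphology runs on the whole 3D VOI; a per-axial-slice mode
is provided (`mode="slice"`). The 3D default is deliberate: a per-slice
Otsu has no cross-slice intensity context, so on cavity-free slices it
binarizes pure noise and the resulting false valleys survive later
filtering. The per-slice mode keeps one marker per slice and hence at most
one canal per slice — usable for single-rooted teeth on clean data.

**Crown masking.** The crown region is located from the segmentation
itself: the chamber slice maximizes the largest single 2D region area, the
root side is the occupied extreme farther from the chamber, and the
crown's apical limit is the last single-region slice moving chamber →
roots. Within crown slices, segmented voxels brighter than the midpoint of
(mean intensity over the unreduced cavity component) and (mean over its
1-voxel shell) are removed; the unreduced component is used for the
statistics because the shell of the reduced marker sits inside the
partial-volume rim and biases the midpoint low. Since pulp is dark, voxels
brighter than the midpoint are dentine leaks, not pulp — the removal
reading of the masking rule.

**Apical guard.** Per-slice areas (crown → apex), normalized by their
maximum and resampled to 100 points, give an area profile; its
central-difference gradient, smoothed with a 5-sample uniform filter, is
compared to a per-class model (elementwise mean and population SD over
reference teeth, the references smoothed with the same filter so the 2-SD
test compares like with like). Only the last fifth (samples 81–100) is
examined; the most coronal sample deviating by more than 2 SD maps
proportionally (floored toward the crown) to a slice, and all slices from
there to the apex are removed. Molars are exempt — their morphology is too
variable to model.

## Tooth segmentation

The pulp mask, dilated one voxel to clear the cavity wall, is meshed by
marching cubes at level 0.5 (closed by construction on the padded array;
normals oriented outward). Deformation parameters: initial profile
half-length L⁰ = 4 mm shrinking by 0.8 per iteration ("hierarchical"
coarse-to-fine — no subdivision hierarchy), 41 samples per profile, at most
15 iterations, step fraction 0.5, Laplacian smoothing weight 0.3,
convergence at mean displacement < 0.01 mm. The boundary score is
D(u) · exp(−u²/2σ²) with D = −dI/du and σ = 1 mm, so outward bright→dark
transitions score positive and nearer ones are preferred; a vertex without
positive evidence (up to interpolation round-off on the intensity scale)
holds its position, as do vertices whose profiles are fully excluded.
Profile points beyond any separation plane (a′x + b′y + c′z − d′ > 0) are
excluded, and samples whose gradient stencil touches an excluded or
out-of-volume sample are not eligible targets — without this, the zero
padding outside the grid manufactures spurious boundaries at the volume
border. Convergence is checked before smoothing, so a converged (or
step-0) input is returned unchanged. After the final iteration any vertex
still violating a plane is projected onto it, making the plane constraint
exact. Voxelization of the closed mesh uses z-ray parity counting with a
deterministic sub-voxel offset to avoid edge-degenerate rays.

## Evaluation

Dice is 2|A∩B|/(|A|+|B|), defined as 1 for two empty masks. ASD extracts
surface voxels (≥1 six-connected complement neighbour, grid border counting
as complement) and pools the nearest-surface distances of both directions
into one mean (pooled rather than mean-of-means; with unequal surface
sizes the two differ). MHD is the two-sample Mahalanobis distance
√(Δμᵀ Σ⁻¹ Δμ) with Σ the size-weighted pooled covariance of the two
surface point clouds; a singular Σ is ridge-regularized
(λ = 10⁻⁶·tr Σ/3) with a warning. Summaries report min/max/mean and
population SD per metric, Dice in percent, stratified by single-rooted
(incisor/canine/premolar), multi-rooted (premolar/molar) and globally;
molars are always multi-rooted, premolars single-rooted unless flagged.
Qualitative review uses a fixed seven-category vocabulary (good, apical
overflow, crown overflow, missing canal, missing canal extremity,
segmentation error, other); assignment is a human judgement — the package
only records and tallies.

## The phantom

Each tooth is a barrel-profile crown (radius tapering to 75% at both ends)
over 1–3 tapered conical roots (radius falling to 20% at the apex);
multi-rooted teeth keep a united root trunk over the coronal 30% of the
root length before furcating, so chamber and furcation are separated by
dentine as in real molars. The pulp is a scaled copy of the crown interior
(chamber, lower 60% of the crown, widened over the canal mouths in
multi-rooted teeth) plus one tapered canal per root ending 0.6 mm short of
the apex (an `open_apex` flag carves the apex open instead). Roots are
embedded in a 1.2 mm bone collar. Default intensities (background 50,
bone 400, dentine 1000, enamel 1400, pulp 120) are abstract units with
CBCT-like contrast ordering. Rendering evaluates solid membership at voxel
centres, then applies Gaussian partial-volume blur (σ = 0.2 mm ≈ 0.47 mm
FWHM, typical CBCT spatial resolution) and additive Gaussian noise from a
single seeded generator (default SD 20 = 2% of dentine). Ground-truth
masks are rendered before degradation. The default study scene places
4 + 4 single-rooted teeth (premolar, canine, incisor, incisor per arch,
2.5 mm crown radius, 2 mm gaps) along the curve y = 0.035x² + 0.3x at
0.25 mm voxels with a 3 mm open-bite gap; true separation planes sit
mid-gap orthogonal to the curve.

What the phantom does **not** emulate: cone-beam reconstruction artifacts
(rings, scatter, beam-hardening streaks from metal), intensity
inhomogeneity, enamel–dentine contrast gradients, periodontal-ligament
space, tooth tilt and rotation, contact points between neighbouring crowns,
or anatomical variability beyond the parametric family above. Passing
phantom tests therefore demonstrates the internal consistency and
robustness-to-noise of the algorithms, not clinical-grade accuracy; on the
phantom the recovered Dice (≈0.90 pulp, ≈0.94 tooth at 2% noise) sits at
the optimistic end of what heterogeneous clinical anatomy would give.

## Numerical choices and degenerate inputs

Trilinear interpolation everywhere; samples outside the voxel-centre hull
read as zero and are flagged. Otsu thresholds on constant inputs are
undefined → empty masks or a no-cavity error, as appropriate. A tooth VOI
without an enclosed dark cavity (solid or fully calcified tooth) raises a
no-cavity error, which the pipeline converts into a per-tooth rejection;
per-tooth failures never abort a case. Determinism: the pipeline contains
no random number generation, and all phantom randomness flows from one
seed, so identical inputs give bitwise-identical masks and meshes.

## Problem sizes used in the test suite

The end-to-end checks run the default 4 + 4 scene (~120 × 70 × 125 voxels
at 0.25 mm); determinism uses a 2 + 2 scene at 0.3 mm voxels; oracle
equivalence uses 12³–16³ random masks (100–200 repetitions) and small
analytic volumes. These sizes keep every property decisive while the full
suite completes in about a minute.

## Known limitations

- Per-slice mode keeps at most one canal per axial slice (single marker),
  so multi-rooted teeth need the 3D mode.
- The crown midpoint threshold trims partial-volume rim voxels whose
  blurred intensity exceeds the pulp/dentine midpoint; at coarse
  resolution this biases pulp volumes slightly low.
- Canal tips below ~1 voxel calibre vanish under partial volume and are
  not recovered ("missing canal extremity" is the expected failure mode).
- The exhaustive rotation refinement dominates runtime
  (21 × 21 cost evaluations per plane); coarser φ steps trade accuracy
  for speed via `PlaneCostParams`.
- Tooth-type identification is not automatic: classes come from
  configuration or ground truth, and the apical-cut model requires
  reference segmentations of the matching class.
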