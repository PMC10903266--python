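# Methods

## Segmentation model

The counting workflow treats a nuclear-stained z-stack as an intensity
landscape. After a 3D Gaussian blur (default σ = 2 voxels, isotropic in
voxel units even under z-anisotropy, since the blur is specified in
pixels; a config flag switches to physical units) and inversion
(`v → (2^bit_depth − 1) − v`), every nucleus is a catchment basin. The
flooding watershed starts from all regional minima whose voxels lie at or
below the intensity bound and floods only within that mask; "one point
below the image minimum" is the flood start, the bound (default 250 on
8-bit data) keeps the bright inverted background out. For 16-bit input
the default bound scales to `65535 − 5·256` with a warning recommending
background profiling, since the appropriate margin depends on the noise
floor of the acquisition.

Intermediate smoothing keeps floating-point precision (the containers
only constrain the intensity *range*, not integrality); this avoids
re-quantization plateaus without changing the algorithm.

**Divide lines.** The watershed engine used (scikit-image) computes basins;
divide lines are carved in a deterministic post-pass: wherever two
different labels are adjacent under the flooding connectivity, the voxel
on the higher-label side becomes background. This guarantees the
separation invariant (no two distinct labels 26-adjacent) with a
one-voxel divide and a documented tie-break. Flooding priority ties are
resolved by the engine's deterministic ordering, so repeated runs are
bit-identical.

**Labeling.** Connected components use 26-connectivity by default
(6-connectivity available) and are renumbered in first-voxel scan order,
which makes component ids independent of library internals. The
size filter (< 10 voxels removed) runs before relabeling, matching the
stated order of the workflow; after relabeling, the maximum of the z
maximum projection *is* the count, and `count_nuclei` refuses
non-consecutive labelings.

**Morphometry.** Label expansion (for volumes and for clone dilation) is
Chebyshev: one full 26-neighborhood shell per step, grown into background
only, nearer label first, exact ties to the lower label id. The metric
follows from the requirement that an isolated label gain one cubic shell
per step; expansion by 1 px refills the inter-label divide space so that
per-label volumes approximate cell volumes. Volumes are
`expanded voxel count × voxel volume (µm³)`; projected area is the
nonzero-pixel count of the z maximum projection times the pixel area.

**Huang threshold.** The optional clone-mask binarization implements
Huang's fuzzy thresholding directly (no installed library provides it):
for each candidate cut the gray levels get fuzzy memberships
`1/(1 + |g − μ_side|/C)` toward their side's mean, and the cut minimizing
the Shannon entropy of the memberships wins (lowest cut on ties;
foreground = values above the cut). The default clone binarization is
`label > 0`, because thresholding a *label* image treats ids as
intensities and can silently drop low-id nuclei; Huang mode is retained
for fidelity with macro pipelines and warns when used.

## Clone model

Nuclei of one clone share a marker, so after marker-channel segmentation
their labels are separated only by divides; 1-px dilation closes those,
and connected components of the binarized result are clones. A nucleus
joins the clone containing the majority of its voxels (ties to the lower
clone id) — a multiply-and-count scheme can split a nucleus lying on a
clone border, majority assignment cannot. Clones under 100 voxels are
removed as noise; clones under 5 cells stay in the table flagged
`discarded` rather than being deleted, so the conservation identity
(per-clone cell counts sum to the marker-channel nucleus count) remains
checkable. The reported clone count includes sub-5-cell clones (they are
excluded only from summary statistics such as mean cells per clone).

Two geometric facts bound when clone recovery can be exact: labels extend
past the nucleus surface to where the blurred edge crosses the watershed
mask cut (a halo of `σ_total · Φ⁻¹(cut/amplitude)` ≈ 4.3 voxels at the
default settings), so two clones fuse when nucleus gaps are below
`2·(dilation+1) + 2·halo` ≈ 12.6 voxels; and a clone splits if a member
sits beyond that reach from its clone-mates. `validation.clone_gap_threshold`
computes this bound from the scene and configuration parameters.

## Twin-spot model

The two marker doses (1× heterozygous, 2× homozygous) are multiplied by a
smooth regional staining field, so absolute brightness is ambiguous: a
heterozygous nucleus in a strong-field region outshines a homozygous one
in a weak-field region. Classification therefore relies on *local*
contrast. Per segmented object the feature table holds intensity
statistics (mean, sd, min, max, quartiles and a robust peak p99) over the
object's voxels, the same statistics over a neighborhood — all voxels
within 50 px of the object centroid in-plane, across all z, minus the
object itself — per-statistic object/neighborhood ratios, mean
difference, and two core-contrast features. The neighborhood is defined
around the object centroid because object-level classification needs an
object-level context; 50 px comfortably exceeds a nucleus diameter while
staying below the field's correlation length, so the context is local
yet stable.

Two feature-design points deserve their own account. First, `rel_peak`:
the object's core intensity (`obj_core`, the mean of its ~60 brightest
voxels — shot-noise-averaged, insensitive to how much dim basin surround
an object carries) divided by the lower quartile of the core intensities
of the *objects* whose centroids fall inside the neighborhood radius.
Watershed basins carry several times more dim surround than nucleus
(diluting means), and an 8-bit in-tissue background quantizes to 1–2 gray
levels (pinning voxel-level neighborhood medians), so neither is a usable
local dose reference; neighboring nuclei are. Because single-dose nuclei
are the local majority everywhere — every homozygous clone has an
unmarked twin beside it, so marked clones cannot dominate a neighborhood
— the lower quartile of neighbor cores tracks the field at the
single-dose level, and `rel_peak` sits near 1 for heterozygous and near 2
for homozygous objects regardless of position.

Second, the classifier's default inputs are deliberately few: three
redundant dose-contrast estimates (`rel_peak`, `ratio_p99`, `ratio_mean`)
plus the apparent object size (`fwhm_voxels`, voxels above half the
object's own core level). Absolute intensities do not transfer across a
tissue with regional staining variation — the very problem the workflow
exists for — and with 10–50 annotated objects a wide correlated feature
set lets spurious splits fit the annotations without generalizing. The
size axis matters because the point spread attenuates small nuclei more
than large ones, so the dose boundary is size-dependent: the brightest
large single-dose nuclei approach the dimmest small double-dose nuclei in
any pure intensity ratio, and the forest separates them jointly. The full
statistic set stays in the feature table and is selectable through
`feature_columns`.

The classifier is a 100-tree random forest with a fixed seed and all
features considered at every split (feature subsampling is
counterproductive at this feature count and training size), trained per
image on 10–50 annotated objects (both classes required, at least 10
objects), exactly the sparse-annotation regime the workflow targets;
cross-image model reuse is possible via serialization but experimental.
Predicted codes at or above 2 are homozygous; those objects are masked,
relabeled through the standard component/size-filter/remap pipeline, and
counted. Contrast normalization clips 0.05% per tail (the total-vs-per-tail
semantics of "0.1% saturated" being ambiguous, per-tail is chosen and
documented); ratio-type features are invariant under global multiplicative
rescaling, so the normalization mainly standardizes exports.

The unlabeled twin estimate is plain subtraction, total nuclear count
minus fluorescent count, with a consistency error when the difference
would be negative.

## Synthetic epithelium generator

The generator is the package's validation instrument: every workflow is
scored against its exact ground truth.

* **Geometry.** Ellipsoidal nuclei (default semi-axes 4.5×3×3 voxels,
  ±15% isotropic jitter, elongated along z as in a pseudostratified
  epithelium) are placed by random sequential adsorption inside a slab
  whose midplane folds sinusoidally. Overlap is tested in an
  anisotropy-normalized metric (coordinates divided by the base
  semi-axes, where every nucleus is a sphere), so a `min_gap` of 2 means
  at least 2 voxels of in-plane surface clearance — and at least that
  along z for z-elongated nuclei. Placement stops at the target count or
  after 50×n attempts; the achieved configuration is ground truth either
  way.
* **Clones.** Each clone grows from a founder by repeatedly absorbing the
  nearest unassigned nucleus. Presets additionally bound the link gap
  (clones are contiguous patches of adjacent daughters; an unconstrained
  nearest-neighbor rule can leave a member beyond image-merge reach) and
  keep founders apart, since the clone-recovery analysis conditions on
  separated clones. With `twin_pairs`, clones are generated as
  recombination pairs — the sister founded beside its twin, exactly one
  of each pair marked — which is both the twin-spot genetics being
  emulated and the reason marked clones never clump.
* **Rendering.** Nuclei are painted as flat-top ellipsoids (stained nuclei
  image as filled blobs; the watershed basins are created by the optics,
  not by intensity peaks), the twin channel is multiplied by the regional
  field (background included — staining and illumination scale all
  collected light), then Gaussian PSF blur (σ = 1 voxel), Poisson photon
  noise (0.55 photons per intensity unit, SNR ≈ 10 at the nominal nuclear
  intensity of 180) plus Gaussian read noise (σ = 2), and quantization to
  8 bits. The background offset (1.0) keeps the inverted tissue floor
  above the default watershed bound across the whole field range, the
  regime the default bound is designed for.
* **Regional field.** Smoothed uniform noise (Gaussian kernel at half the
  80 px correlation length), histogram-equalized onto the amplitude
  interval — a min/max rescale would concentrate values mid-range and
  leave a global threshold nearly sufficient, failing to emulate strong
  regional variation. The correlation length exceeds the classifier's
  50 px neighborhood so local contrast stays informative.
* **Presets.** `dense_disc`: ~800 nuclei in 60×300×300 voxels at 0.3 µm
  spacing, the density of a 100×100 µm epithelial patch holding ~800
  cells. `sparse_clones`: the same packing density with six
  well-separated marked clones of 3–12 cells (sub-5-cell clones included
  so the discard rule is exercised). `twin_spot_hard`: 25 recombination
  events (twin pairs of 5–9 cells, event founders kept ≥55 px apart,
  ~27% of visible objects homozygous) under a field spanning 0.5–1.5×.
  The event density balances two requirements: enough double-dose
  objects that no global threshold can sacrifice them cheaply (measured
  best-threshold accuracy ≈ 0.88), yet spread-out twin spots so that
  single-dose nuclei stay the local majority everywhere — clusters of
  marked clones beside their dark twins would create pockets where a dim
  homozygous region is indistinguishable from a bright heterozygous one
  at this field range, an ambiguity no local-intensity method can
  resolve.

**What the generator does not emulate:** peripodial membranes, tracheal
autofluorescence, optical aberrations, mitotic figures, chromatin texture
within nuclei, depth-dependent attenuation along z, or nucleus shape
irregularity. Passing these benchmarks therefore demonstrates the
correctness and self-consistency of the algorithms under the stated imaging
model, not performance on any particular real acquisition, where the blur
sigma and watershed bound may need the documented tuning.

## Numerical and testing choices

Validation runs use 10 scenes of each counting/clone preset and 5
twin-spot scenes, with 15 annotations per class; stochastic metrics
(count error, F1, classifier accuracy, homozygous-count error) are
reported as seed averages. Segmentation primitives are checked for exact
equality against independent brute-force oracles (breadth-first flood
fill, per-label tallies, exhaustive Huang minimization, Chebyshev
nearest-label scans) on small random instances, and end-to-end runs are
asserted bit-identical under fixed seeds. Label exports are 16-bit while
they fit (raising on request rather than wrapping) because the 65 536-label
ceiling is a file-format artifact, not an algorithmic one; internal labels
are at least 32-bit.

## Known limitations

* Clone recovery is exact only for image-separated clones; fused
  neighboring clones are counted as one, as the dilation-based definition
  implies.
* The neighborhood feature definition is centroid-based and in-plane; a
  per-pixel 3D neighborhood would weight context differently.
* The watershed bound default assumes the background regime described
  above; unusually high or structured background requires profiling.
* Very large basins in sparse regions dilute object mean intensities;
  classification robustness comes from the peak- and ratio-type features,
  not the means.
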