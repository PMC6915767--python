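# Methods

This note documents the models, defaults and numerical choices behind
`arraytomo`, and what the synthetic benchmark does and does not show.

## Imaging model and conventions

All volumes are `(section, row, col)` arrays with physical calibration
carried as metadata: lateral pixel size (default 0.1 µm/px, typical of a
63×/1.4 NA camera setup) and section thickness (default 0.07 µm, the
70 nm ultrathin sections used in array tomography). Voxels are therefore
strongly anisotropic; every distance, area, volume and density is
computed in physical units (µm, µm², µm³) from the calibration, and the
data is never resampled to isotropy. x runs along columns, y along rows,
z along sections; centroids use the voxel-centre convention (index
+ 0.5).

## Synthetic data generator

The generator stands in for the microscope and defines the conditions
under which the pipeline is validated.

* **Synaptic puncta.** Counts are Poisson with mean `density × volume`
  per channel; defaults are 1.0/µm³ for the postsynaptic (PSD95) and
  0.7/µm³ for the presynaptic (synaptophysin) channel, the order of
  magnitude measured for cortical neuropil. Each punctum is a 2D
  Gaussian blob (lateral radius ~N(0.12, 0.02) µm) repeated over a
  section range of `2 + Poisson(1)` sections (mean 3 ≈ 0.2 µm — small
  synaptic structures span a few 70 nm sections; nothing real is ever
  confined to one). Puncta of the same channel whose section ranges
  touch keep ≥ 0.6 µm lateral separation (hard-core placement):
  synaptic structures exclude each other physically, and the value is
  chosen so that two detection footprints cannot merge at default SNR.
* **Noise specks.** Single-section blobs at 0.2/µm³ per channel emulate
  staining debris and hot pixels — the artefact class the
  single-section filter exists to remove.
* **Markers.** Each synaptic punctum is independently tau-positive /
  Aβ-positive with configurable probabilities (default 5 % each, within
  the 0.4–10 % range such studies report); a positive label renders the
  same blob into the marker channel, so the volumetric overlap rule can
  recover the label.
* **Plaques.** Discs through the whole depth: the fibrillar core is
  bright in both the Thioflavin-S and pan-Aβ channels, the oligomeric
  halo (an annulus out to the halo radius, at 1/3 the core intensity)
  only in pan-Aβ. A plaque that does not fit the field is rejected.
* **Nuclei.** A DAPI channel contains 2+ nuclei (Gaussian envelope,
  radius ~1.5 µm) with granular chromatin texture, *constant across
  sections* — µm-scale nuclei traverse the entire ~1.4 µm ribbon, which
  is precisely why nuclear stains drive registration in practice.
* **Intensity model.** signal + camera offset (100) + Gaussian noise
  (SD 100); default punctum amplitude 1500, i.e. peak SNR 15. The
  "true footprint" of an object is defined as the voxels whose
  noiseless signal exceeds 3 noise SDs (the detectable extent); this is
  the oracle mask used by segmentation tests.
* **Misalignment.** Per-section translations ~N(0, 1.5 px), rounded to
  integers by default (subpixel optional), applied as circular rolls so
  that inverting the true shifts restores the pre-misalignment stack
  exactly. The truth object retains that aligned stack.

One RNG seeded from `SynthParams.seed` drives everything; identical
parameters give voxel-identical stacks.

What the generator does **not** emulate: optical PSF blurring across
sections, chromatic aberration, tissue compression/tearing, staining
gradients within a section, autofluorescence, or rotational
misalignment. Passing the benchmark therefore shows the algorithms are
correct under calibrated geometry and realistic counting statistics; it
does not certify performance on degraded real-world optics.

## Registration

Translation-only rigid model. The 70 nm ribbon geometry makes rotation
negligible between neighbouring sections; a rotation hook would be the
natural extension. Reference channel: DAPI when present, else the
presynaptic channel (dense, stain-independent structure).

The estimator is built in four stages, each addressing a failure mode
observed with sparse punctate content:

1. **Chain phase correlation.** Each section against its predecessor
   (upsampled cross-correlation, subpixel factor 50), composed to
   section 0. Sections are pre-smoothed (σ = 2 px, circular boundary)
   so camera noise does not perturb the correlation peak. If a pairwise
   shift exceeds a plausibility bound (¼ of the field), the peak search
   is redone on a ±bound window — sparse blob patterns occasionally
   produce a spurious distant correlation peak.
2. **Anchored refinement.** Chain composition accumulates random-walk
   drift, so each coarsely aligned section is re-registered directly
   against section 0 (valid because the nuclear structure persists
   through the ribbon); corrections > 1.5 px are rejected as
   content-driven.
3. **Integer snapping.** When a section's shift vector lies within
   0.35 px of a lattice point the misalignment is treated as integer
   (stage micro-steps) and applied as a lossless roll.
4. **Discrete verification.** Snapped shifts are hill-climbed over
   integer offsets maximising normalised correlation with the
   reference — a discrete decision independent of subpixel
   interpolation accuracy.

A registered stack carries a `valid_mask` marking the zero-filled
border strips; re-registration crops to the always-valid region so
those artificial edges cannot bias the estimate. Blank sections inherit
their predecessor's shift with a warning.

## Segmentation

Per-section binarisation as the union of automatic thresholds, default
Otsu (global bimodal; crisp on bright puncta) + Triangle (tail
sensitive; catches dim puncta). The union contract is the operative
requirement: adding a method can only add foreground. Each method's
threshold is floored at median + 2.5 × 1.4826 × MAD of the section — a
robust background estimate that prevents a method from collapsing into
the noise floor on sparse sections (Otsu does this when foreground is
≪ 1 % of pixels). Both the methods and the floor scale linearly with
intensity, so the mask is gain-invariant. 2D components smaller than 2
px are removed (single pixels are indistinguishable from shot noise);
this knob is configurable and documented as the only 2D size filter.
Thresholds are strictly per-section, which makes the result robust to
section-to-section staining variation and means section order commutes
with masking.

## 3D reconstruction

Within a section, 8-connectivity; across consecutive sections, two
footprints belong to one object iff they share ≥ 1 pixel at the same
xy — the weakest linkage consistent with removing single-section
objects, implemented as a 3D label structure with full in-plane and
centre-only out-of-plane connectivity. A `gap_tolerance` option (default
0, i.e. strict consecutiveness) bridges up to N blank sections per xy
column via binary closing along z, for users who want to tolerate a
missed detection. Objects with section span 1 are removed; span 2 is
the retained boundary case. Volumes are voxel counts × voxel volume;
centroids are unweighted voxel means (masks, not intensities, are the
unit of analysis). No maximum-size filter by default; a configurable
cap guards against plaque bleed-through when needed.

## Plaques, proximity, burden

Plaque detection reuses the union thresholding (the dim oligomeric halo
would not survive a single bimodal threshold), drops 2D components
below 20 µm² (puncta-scale debris; real plaque cross-sections are tens
to hundreds of µm²), and merges footprints across sections like
puncta. The edge-distance field is a Euclidean distance transform with
anisotropic sampling (0.07 µm in z, pixel size in xy), zero inside the
plaque and ∞ when the field has no plaque. Near/far uses the strict
rule: near iff distance < 20 µm; exactly 20 µm and ∞ are far. Distances
are measured from the fibrillar (ThioS) core edge, with pan-Aβ optional.
ROI proximity uses the ROI centre (configurable in spirit; the centre is
the implemented convention).

Burden metrics follow 2D histology practice: percent area, component
count and mean component area are computed per section and pooled; the
halo is pan ∧ ¬core. Region volume from sparsely sampled sections is
Σ(area × spacing) × hemisphere factor (defaults 1 mm spacing, factor 2).

## Colocalization

`overlap = |punctum ∩ marker| / |punctum|`; positive iff overlap ≥ 0.5
(the "minimum of 50 %" read as inclusive). Markers are scored
independently; the double-positive call is the conjunction of the
independent calls, matching how single-marker and rare double-positive
fractions are reported separately. Marker masks come from the same
union segmentation as synaptic channels (an option exists for raw
vs 3D-filtered marker masks; the filtered mask is the default in the
pipeline). Intensity-correlation colocalization (Pearson/Manders) is
deliberately out of scope — the rule is volumetric and object-based. A
stratum with no puncta reports its fraction as absent, never as zero.

## Behaviour

Arena: 40 × 40 cm square, inner zone the centred 20 × 20 cm square (the
standard open-field convention; placement is not otherwise specified).
Distance is the sum of Euclidean steps; each step and each inter-sample
interval is assigned to the zone of its *starting* sample, so inner +
outer reproduces the totals exactly (boundary-crossing steps are not
split — negligible at video frame rates). Samples outside the arena are
clipped with a warning. The generator provides forced regimes
(immobile, centre-only, wall-following) whose metrics have closed
forms; the wall-following fixture covers exactly 144 cm per lap at a
2 cm wall offset when the sampling interval divides the side length.

## Statistics

The experimental unit is the animal or case: all tests consume
per-animal means or medians, never per-synapse values. Mann-Whitney U
uses midranks; the p-value is exact (full permutation distribution) for
combined samples ≤ 12 without ties, else a normal approximation with
tie and continuity corrections — the branch taken is recorded in the
result. Two identical-constant groups return p = 1. Tests are two-sided
by default. No multiple-testing correction is applied by default (a
Benjamini-Hochberg helper exists, off by default). Chi-square goodness
of fit uses E = n·p and df = k−1. Parametric ANOVA-style models are out
of scope; a statistics package should be used for those.

The exact branch and the chi-square tail are implemented via scipy's
`mannwhitneyu(method="exact")` and `chi2.sf`; tests verify them against
independent oracles (exhaustive enumeration over all labelings, numeric
integration of the chi-square density).

## Pipeline and problem sizes

The pipeline is a pure function of (config, seed): per-animal sub-seeds
are derived deterministically, every stage writes its CSV, and the
manifest records the config hash, seed and package version; reruns are
byte-identical. Validation (calibration present and positive, known
generator parameters) happens before any compute.

Benchmarks in the test-suite and acceptance script use 10 × 10 µm
(occasionally up to 50 × 50 µm) fields of 4–20 sections — a few hundred
to a couple of thousand puncta per run. These sizes give the statistical
power the checks need (e.g. 3-SE binomial bounds over ≥ 2000 puncta)
while a full run of suite plus acceptance completes in ~1 minute on one
core; all recovery properties are size-independent.

## Known limitations

* Translation-only registration; rotation and elastic deformation are
  not modelled (nor generated).
* The union-threshold floor assumes the background dominates each
  section (median/MAD as background estimators); fields that are mostly
  foreground would need a different floor.
* Cross-section linking requires exact xy overlap after registration;
  sub-pixel residual misalignment larger than a blob radius would break
  linkage (not reachable at the accuracies measured here).
* The synapse pairing of pre- and postsynaptic puncta into synapses is
  out of scope; channels are quantified independently.
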