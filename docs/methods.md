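# Methods

`lesionscope` reimplements, on fully synthetic data with known ground
truth, three quantitative analyses used to evaluate rodent micro-CT scans
of lesioned and electrode-implanted brains: (1) lesion presence/extent via
masked slice-wise structural similarity (SSIM) and single-linkage
clustering, (2) electrode localization in a landmark-normalized 2D
anatomical frame, and (3) theta phase offsets between simultaneously
recorded LFP channels.  This note records the models, the parameters that
matter, and the numerical choices; everything quantitative stated here is
computed by the test suite or `scripts/acceptance.py`.

## Synthetic cohort model

Each subject is a 3D grayscale grid, axis order (AP, DV, ML), default
128 x 96 x 96 voxels with unit pitch — a desk-scale stand-in for
full-brain scans at micron-scale voxels.  A volume contains:

* an ellipsoidal **tissue** region (intensity 0.5) inside an optional
  **skull shell** (0.65) surrounded by air (0);
* two mirrored **hippocampal cell-layer sheets** (intensity 1.0): in each
  coronal section the sheet is a thin elliptic arc, parametrized by an
  angle running from the dorsal apex laterally and then ventrally.  The
  arc's radii grow along AP, and a gap around the lateral extreme splits
  the sheet into dorsal and ventral components anteriorly; the gap closes
  at 54 % of the layer's AP span — the **fusion point**, whose lateral
  extreme defines the (1,1) landmark of the normalized frame.  The
  anterior-most end of the dorsal component is the **tip** (origin)
  landmark.  An inner **dentate** sheet at 55 % of the arc radius provides
  the medial layer curve;
* i.i.d. Gaussian noise (sd 0.05, i.e. 10 % of the tissue level) and a
  small rigid **pose jitter** (up to 2 degrees per axis, 2 voxels per
  axis), applied by evaluating the analytic fields at inversely
  transformed coordinates, so masks stay crisp (no interpolation at
  generation time).

Landmark ground truth is derived from the *rasterized* layer mask by the
same geometric rule the detector uses, so detection can be validated
voxel-for-voxel.  Every random draw routes through
`numpy.random.SeedSequence(master_seed, spawn_key=(subject_index,))`;
identical configuration and seed reproduce volumes bit-for-bit.

**Lesions.** The 12 printed stereotaxic infusion rows (AP, +/-ML, DV, in
mm) are mirrored across the midline to 24 bilateral sites; the generator
maps them affinely into the layer's voxel frame and carves a cavity: the
layer mask dilated by 3 voxels, unioned with spherical foci at the mapped
sites, restricted to the lesioned AP interval (default fractions
[0.25, 0.65] of the layer span — dorsal plus dorsal-intermediate; the
ventral-most layer is untouched so the distal profile convergence is
reproducible), eroded/re-thresholded against a smooth noise field for a
ragged margin, and set to the cavity intensity (0.1) plus noise.  All
voxel changes are confined to the recorded lesion mask (asserted by
exhaustive diff in the tests).

**Electrodes.** Rods descend from the dorsal surface to a per-slot tip
depth on a rectangular 4 x 6 cannula grid (22 occupied slots, two empty;
the empty pair is asymmetric under a 180-degree flip so the pattern fixes
the grid orientation).  A rod's intensity profile is radially graded
(4.0 at the core to ~2x the layer intensity at the edge) so that any
threshold landing inside the rod band keeps a connected core column —
a flat profile would fragment at thresholds near its single value.  The
default tip depth (0.24 of the DV extent) leaves the rods just dorsal to
the cell layer, as in recordings where tetrodes are lowered toward the
layer; rods that intersected the layer would cut the arcs and corrupt the
component-count geometry below.

**LFP sessions.** Channel k carries `sin(2 pi f t + offset_k)` at
f = 8 Hz plus white noise; `snr` is the RMS signal-to-noise ratio
(default 10; `inf` disables noise).  The speed trace alternates 20 s of
running at 25 cm/s with 10 s still at 3 cm/s (25 Hz sampling), standing in
for foraging behavior.

## Rigid alignment

Volumes are registered by a closed-form landmark Kabsch fit (SVD of the
centered cross-covariance with the determinant sign fix; no scaling, no
reflection) and resampled trilinearly (`scipy.ndimage.map_coordinates`,
out-of-domain voxels take the fill value).  Two detectors supply
landmarks:

* **Layer landmarks** (tip and fusion, per hemisphere) from an
  intensity threshold built of order statistics restricted to the eroded
  brain interior (`median + 0.75 x (p98 - median)`), hence invariant to
  global affine intensity rescaling and robust to the much brighter but
  sparser electrode rods.  The fusion slice is the first where the
  hemisphere's outer-sheet components merge back to one after being split
  for at least 3 consecutive slices — the persistence requirement stops a
  single noise-fragmented slice from faking an early fusion.  Components
  reaching the dorsal surface (electrode shafts) and the inner dentate
  sheet (lateral extent below 85 % of the slice maximum) are excluded
  from the count.
* **Brain-outline landmarks** (centroid plus six axis poles of the
  largest Otsu-threshold component) register *whole* brains.  The lesion
  pipeline uses these, because lesioned subjects no longer possess
  internal layer landmarks — whole-brain registration must not depend on
  the very structure whose destruction is being measured.
  Pole correspondence under rotation is approximate (a pole of a rotated
  ellipsoid is not the rotated pole), contributing ~1 voxel of residual
  misalignment at 2-degree jitter — well inside the SSIM smoothing scale.

## Lesion similarity

For every AP slice in a generous hippocampal-region mask (the template's
layer mask dilated by 4 voxels, split by hemisphere) the SSIM between each
pair of co-registered brains is computed on the mask's per-slice bounding
box crops, left and right pooled with equal weight.  The SSIM map is

    ((2 mu_a mu_b + C1)(2 cov_ab + C2)) /
    ((mu_a^2 + mu_b^2 + C1)(sigma_a^2 + sigma_b^2 + C2)),

with Gaussian-weighted local moments (window truncated at 3.5 sigma,
reflective padding; all crop pixels count as valid), C1 = (0.01 L)^2,
C2 = (0.03 L)^2, and L the cohort-wide intensity range by default.  The
window sigma defaults to 50/1000 of the mask's overall ML span (~3.1 px
at the default grid): proportionally the same neighborhood as a 50 px
sigma on ~1000 px scans, and large enough to forgive ~1 voxel of residual
registration error.

Clustering uses the **dissimilarity 1 − S̄ averaged over the lesioned
(dorsal + dorsal-intermediate) AP interval** — the targeted portion —
with hand-rolled single linkage (merge heights provably nondecreasing;
deterministic smallest-index tie-break; verified against an MST oracle
and `scipy.cluster.hierarchy`).  Cutting the merge tree into k = 2 groups
(k exposed as a parameter; the group count is an analysis choice) assigns
every subject; with the default cohort the two groups coincide exactly
with the surgery labels across all tested seeds.

**Nearest-control profiles.**  For each subject and slice, the maximum
per-slice similarity to any control brain, *self excluded for controls*
(otherwise controls trivially score 1; the profiles would be
uninformative).  Group summaries are per-slice medians with interquartile
ranges, using the inclusive linear-interpolation quantile definition
(numpy's default).  Inside the lesioned interval the lesion-group median
sits below the control median on every slice; beyond it the medians
converge within the pooled IQR.  Two slices at each boundary are excluded
from the convergence check because trilinear resampling mixes adjacent
slices, smearing the cavity edge by one voxel.

## Electrode localization

The 2D frame maps the tip landmark to (0,0) and the fusion-point lateral
extent to (1,1) **per axis** (AP and ML scaled independently) — the only
map those two constraints fully determine.  DV is excluded: electrodes
are moved during recordings, so scan-time DV does not reflect recording
depth.  Frames are built per hemisphere and per subject; because the
frame anchors to anatomy, no intensity resampling is needed in this
pipeline — curves, landmarks and tips are extracted from raw volumes and
compared in normalized coordinates (pose translation is absorbed exactly,
the ≤2-degree rotations approximately).

Layer curves sample, per AP slice, the lateral-most pixel of the outer
sheet and the medial-most pixel of the dentate sheet (slices without a
sheet are recorded as gaps, never interpolated).  Electrode tips are
detected as 26-connected components above an intensity quantile (default
0.998 — calibrated to the ~0.3 % volume fraction of a 22-rod implant;
sparser implants need a higher quantile), kept at >= 10 voxels; the tip
is the centroid of the component's ventral-most voxel layer, and
components with a horizontal footprint over 3.5 voxels are flagged as
likely merged rods.  Cannula matching fits a similarity transform
(rotation, translation, uniform scale) seeded from the two mutually
farthest points of each set (both pairings tried, lower residual wins),
refines it by a least-squares similarity over a greedy nearest-neighbor
assignment, and flags surplus detections and unfilled slots.

## Theta phase offsets

The chain: (1) anti-alias low-pass below 400 Hz and polyphase resampling
to 1.5 kHz; (2) Parks–McClellan equiripple FIR band-pass, pass band
4–10 Hz, stop bands below 3 Hz and above 11 Hz, designed at single-pass
ripples delta_p = 0.0025 / delta_s = 0.01 (40 dB single-pass, 80 dB
combined stop band; combined pass-band gain at 8 Hz >= 0.99); the tap
count (3393 at 1.5 kHz) comes from the standard equiripple order
estimate and the realized response is verified, bumping the order up to
2x the estimate before declaring the spec unattainable; (3) zero-phase
application — reflect-pad by 3x the tap count, filter causally, reverse,
filter, reverse (overlap-add FFT convolution, so long sessions stay
cheap); (4) instantaneous phase as the angle of the Hilbert analytic
signal; (5) running periods: maximal intervals with speed strictly above
10 cm/s, resampled to LFP indices as half-open [start, end), dropped
under 1 s (10 cm/s is the standard running criterion in hippocampal
work; the 1 s minimum duration is this package's choice); (6) per pair, the instantaneous difference is the
angle of `exp(i phi_a) exp(-i phi_b)` using **unit phasors** (consistent
with "instantaneous phase differences"; amplitude weighting is available
as an option), averaged by the **two-stage** circular mean — over time
within each running period, then unweighted across periods.  The
two-stage and pooled definitions genuinely differ (a constructed session
with 10x unequal periods and a 40-degree offset switch separates them by
far more than 5 degrees); the unweighted two-stage form is the
implemented definition, with a duration-weighted variant off by default.
Degenerate circular means (resultant below 1e-9, e.g. antipodal angles)
raise an error carrying the resultant length.

With sessions of >= 300 s at SNR >= 5, true offsets are recovered within
2 degrees (typically < 0.1); artifacts confined to still epochs shift
estimates by < 0.5 degrees because only run samples enter the average
(filter-transient leakage is negligible a second away from a run
boundary).

## Problem sizes and runtimes

The default study-scale configuration (25 brains at 128 x 96 x 96) runs
the full lesion pipeline in ~10 s on one core; the separation acceptance
check repeats it over 20 master seeds (~4 min).  Unit tests use
96 x 72 x 72 grids and smaller cohorts, the smallest size at which the
voxel-thin ventral arc remains connected (below that, the generator
raises a sizing error).  Theta recovery uses 600 s sessions (10 seeds,
~1.5 s each).

## What the synthetic data does and does not show

The generator reproduces the *geometry* the analyses rely on — a bright
thin curved layer with a well-defined tip and fusion point, cavities that
remove it over a known AP interval, rods on a known grid, theta with
known offsets — with additive Gaussian noise and rigid pose error only.
It does not emulate reconstruction physics (phase contrast, ring or
streak artifacts, beam hardening), histology-scale texture, skull suture
geometry, deformable anatomical variability, or ventricular enlargement.
Passing tests therefore demonstrate that the statistics and their
implementations behave correctly under the stated noise model and that
the end-to-end pipelines separate the constructed effect sizes; they do
not certify performance on real scans, where registration error and
texture variation are richer.

## Known limitations

* Single-linkage clustering is chain-prone; separation is demonstrated
  for the default effect sizes, and k = 2 is an assumption exposed as a
  parameter.
* The electrode-tip quantile threshold assumes the rod volume fraction is
  known to within an order of magnitude.
* Outline-pole registration degrades with rotation; jitter beyond a few
  degrees would need the optional correlation refinement or more
  distinctive landmarks.
* The infusion-site mapping into the synthetic frame is affine and
  schematic; it anchors the cavity's span and laterality, not exact
  stereotaxic geometry.
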