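# Methods

This note records the conventions, defaults, and design choices behind
`mriqa`, and what the phantom-based tests do and do not demonstrate.

## Input model

A *Conventional* input is one directory of DICOM slices forming a 3D volume;
a *DCE* input is a directory of per-timepoint sub-directories forming a 4D
study whose first phase (timepoint 0) is pre-contrast and serves as the
full-reference comparison reference. Timepoints are ordered by DICOM
AcquisitionTime when every phase carries one, else by directory name. Slices
are ordered by the projection of ImagePositionPatient onto the slice normal
(computed from ImageOrientationPatient), falling back to SliceLocation, then
InstanceNumber — position-based ordering is the only geometry-safe
convention. Duplicate slice positions keep the highest InstanceNumber with a
warning; stray non-DICOM files in a series directory are skipped with a
warning rather than aborting, because clinical exports often contain them.
RescaleSlope/Intercept are applied exactly once at read time and pixels are
floating point from then on; all metrics are defined on intensities, not
stored integers. An `IQA` sub-directory (a previous run's output) is never
treated as input.

## Intensity normalisation

MRI intensities are arbitrary-unit, so a fixed normalisation is required for
cross-series comparability:

* NR metrics min-max normalise each slice — to [0, 1] for Total Variation,
  to 0–255 for BRISQUE, whose MSCN stabiliser `C = 1` presumes an 8-bit-like
  scale.
* FR metric pairs are normalised **jointly** by the shared min/max of target
  and reference (to unit range; ×255 for FSIM). Per-image normalisation
  would erase genuine intensity differences between contrast phases, which
  are exactly what PSNR is expected to see.

Because the normalisation is a convention, absolute NR values are not
comparable across tools; scores are meant for comparison across slices and
phases assessed under one convention.

## Metric conventions

* **Total Variation**: mean over pixels of the isotropic L2 norm of forward
  differences (zero past the last row/column). One caveat discovered during
  testing: if a small bright structure sets a slice's intensity range,
  blurring flattens that peak, shrinks the range, and the *normalised* TV
  can rise even though raw gradient content falls. Phase-level means are the
  robust comparison.
* **PSNR**: `10·log10(1/(MSE + 1e-8))` on unit range. The epsilon is chosen
  so that a self-comparison prints a finite 80.0 dB ceiling instead of an
  infinity; it is negligible for any non-identical pair.
* **SSIM**: 11×11 Gaussian window (σ 1.5), K1 = 0.01, K2 = 0.03 on data
  range L = 1; the score averages the local map over positions whose window
  lies fully inside the image (equivalent to a "valid" convolution), which
  keeps the implementation in exact agreement with a brute-force
  sliding-window oracle.
* **MS-SSIM**: five dyadic scales with 2×2 average-pool downsampling
  (floor semantics on odd dimensions), the standard weights, luminance only
  at the coarsest scale, and component means clamped at zero before
  exponentiation so the score stays real and in [0, 1] for non-negative
  images. With the 11-tap window this requires ≥ 176×176 in-plane; smaller
  inputs raise an error naming the minimum rather than silently dropping
  scales. The dynamic-study phantoms therefore default to 192×192.
* **FSIM**: phase congruency from a 4-scale × 4-orientation log-Gabor bank
  (minimum wavelength 6, scale multiplier 2, σ_on_f 0.55, angular σ
  π/4/1.2), energy-over-amplitude construction with a Rayleigh noise floor
  estimated from the smallest-scale amplitude median (k = 2 standard
  deviations); gradient magnitude from the Scharr operator; stabilisers
  T1 = 0.85 (PC similarity) and T2 = 160 (gradient similarity, 0–255
  scale); the similarity product is averaged weighted by the pointwise
  maximum phase congruency. For a structureless pair (zero PC everywhere)
  the unweighted mean similarity is returned, making two identical constant
  images score 1. FFT periodicity gives the image border a ridge of its own
  in the PC map; this cancels in the FSIM ratio for similar borders but is
  visible in raw PC maps.
* **BRISQUE**: MSCN field `(I−μ)/(σ+C)` with a 7×7 Gaussian window
  (σ = 7/6, replicate borders), AGGD moment-matching fits (shape recovered
  by Brent inversion of the moment ratio Γ(2/α)²/(Γ(1/α)Γ(3/α))); per
  scale, 2 features from the field (shape, root mean square) and 4 × 4 from
  the directional pairwise products (shape, mean offset η, left/right
  scales); scale 2 is a 2×2 block average. Note that the MSCN transform is
  not distribution-preserving: the field of pure Gaussian noise fits a
  shape near 3, not 2, because dividing by a locally estimated σ that
  includes the centre sample lightens the tails.

## The BRISQUE regressor

The published DMOS-trained support-vector regressor could not be bundled;
the shipped `data/brisque_svr_synthetic.txt` is a **synthetic stand-in**: an
RBF SVR (gamma 0.05, 137 support vectors) trained by
`scripts/make_brisque_model.py` on 242 phantom slices spanning blur kernels
3–11 and noise levels 2–20 % of range, with pseudo-quality labels increasing
in degradation severity. It preserves the operational contract — lower is
better, blur and noise raise the score, scoring is deterministic — but its
absolute scale is not a human-opinion scale, and scores should not be
compared against values produced by other BRISQUE implementations. The
plain-text model format (documented in `load_brisque_model`) accepts any
replacement with 36-dimensional features, e.g. a conversion of an
opinion-trained model.

## ROI statistics

SNR and CNR use the standard background-noise-referenced forms
`μ_tissue/σ_BG` and `|μ₁−μ₂|/σ_BG`; no formula is more natural given the
fixed `FG`/`BG` labelling. Relative SNR is the ratio of the two
background-referenced SNRs, which algebraically reduces to `μ₁/μ₂`; both
readings are reported so either interpretation is available. `FG` defaults
to the union `pos1 ∪ pos2` when no explicit foreground label is supplied
(the histogram initialiser constructs it that way); an independently drawn
FG mask takes precedence. No Rician correction is applied to σ_BG — for
magnitude MR background the Gaussian estimate is biased high by ~√(2/π)
relative to the underlying noise σ; a known limitation. Masks are integer
label grids (0 unlabeled, 1 pos1, 2 pos2, 3 FG, 4 BG) matching the image
grid, with a sphere rasteriser (`sphere_mask`) for centre+radius specs.

## Pipeline

NR metrics run on every slice of every timepoint; FR metrics on `k = 10`
equidistant slice locations (cell-midpoint rule `round((i+0.5)·n/k)`,
deduplicated; all slices when `n ≤ k`). A metric failure on one slice is
recorded as NaN and processing continues. Minima flagging scans the
quality direction (BRISQUE is negated): a coordinate is flagged when it is
a strict local minimum of the profile (profiles averaged over the
non-scanned coordinate first) *and* lies more than 2 robust deviations
(1.4826 × median absolute deviation) below the median; severity is that
multiple. The threshold is a package choice — the original workflow leaves
minima detection to the reader's eye — and is configurable
(`flag_threshold`). When more than half the profile is constant the MAD is
zero and any strict sub-median minimum is flagged with infinite severity.

Outputs are deterministic: CSVs are written with a fixed float format and
line terminator, so identical inputs give byte-identical tables. Plots are
a side product; nothing is asserted on rendered figures.

## The phantom

`default_breast_spec` emulates a multi-phase DCE breast study at desk
scale: 30 slices × 192×192, 2 mm × 0.8 mm × 0.8 mm voxels, 7 timepoints at
90 s temporal resolution (a typical protocol acquires 3–7 phases at about
this cadence). Three ellipsoidal compartments — a fat-dominated body
(baseline 220, ~5 % enhancement), a fibroglandular core (140, ~25 %), and a
small lesion (180, wash-in to 2.2× with a slow washout plateau) — are
modulated by a static multiplicative texture field (Gaussian-correlated,
12 % relative sd, 2-voxel correlation length) shared across timepoints, so
structure persists and FR comparisons respond to degradation rather than to
regenerated texture. Additive Gaussian noise (σ = 4, ~1 % of peak signal)
is drawn independently per timepoint. Degradations: in-plane Gaussian blur
(kernel k, σ = 0.3·((k−1)/2 − 1) + 0.8, the common computer-vision default,
applied before the noise) and through-plane slice shifts with edge
replication (applied volume-wise). Everything is deterministic for a fixed
seed. Intensities are quantised to 16 bits with per-slice
RescaleSlope/Intercept when written as DICOM, bounding round-trip error by
half a quantisation step.

What the phantom does **not** emulate: Rician magnitude statistics
(additive Gaussian noise is used; sufficient for metric-behaviour testing),
anatomical realism, coil-sensitivity shading, k-space-domain artifacts
(ghosting, spikes), and partial-volume boundaries. Passing tests therefore
demonstrate that the metrics and the flagging logic respond correctly to
controlled degradations of known location and strength — not that the
specific numeric values transfer to clinical data, where the texture
spectrum and artifact physics differ.

## Problem sizes

The feasibility experiments run at 30 slices × 192×192 × 7 phases (the
full-reference table is 10 locations × 7 phases); oracle cross-checks use
≤ 32×32 images for SSIM/TV and 64×64 slices for the brute-force BRISQUE
comparison; parameter-recovery tests draw 10⁵ samples per AGGD shape.
These sizes were chosen so the whole suite exercises every experiment in a
few minutes on a single CPU while keeping Monte-Carlo standard errors small
enough for 3-σ assertions.

## Known limitations

* DICOM only; no NIfTI/.mha readers, no multi-frame enhanced DICOM, no
  resampling or registration.
* Diffusion-weighted 4D series are out of scope (their quality profile —
  geometric distortion, b-value-dependent SNR drop — needs dedicated
  handling).
* The BRISQUE score scale is synthetic (see above).
* Background SNR is Rician-biased (see above).
* FR metrics assume co-registered phases; real inter-phase motion shows up
  as a quality drop, which is the intended behaviour, but it cannot be
  distinguished from other degradation sources without inspection.
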