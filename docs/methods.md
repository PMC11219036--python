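# Methods

This note documents the models, estimators and numerical choices behind
`fxmvol`, in the order data flows through the pipeline, together with what the
synthetic generator does and does not emulate.

## 1. The measurement model

Fluorescence-exclusion microscopy images a dye-filled chamber of height
h<sub>chamber</sub> (default 6 µm, configurable — chamber geometry is an input,
not an inference). At pixel (x, y) the raw signal is modeled as

    I_raw(x, y) = DF(x, y) + FF(x, y) · α_raw · d(x, y) + ε,

with DF the camera darkfield, FF the multiplicative illumination field,
α_raw the intensity per micron of dye column, d = h_chamber − h_cell the dye
column (0 over pillars), and ε additive Gaussian read noise. Every analysis
stage is the inverse of one factor of this model.

**Volume estimator.** After flatfield correction, the excluded volume over a
footprint A is V = (px²/α) Σ_A (I_max − I). Two distinct background
references share the symbol I_max in the field's usage; we keep them apart:

* `local_background` — the per-cell I_max: median corrected intensity in the
  annulus 2–10 px (≈1.3–6.5 µm at 0.65 µm/px) outside the cell's footprint,
  excluding all other labeled cells and pillars. At least 30 free annulus
  pixels are required ("locality occluded" otherwise); cells whose footprint
  touches the frame border are flagged and excluded rather than measured with
  a truncated annulus.
* `alpha_calibration` — the frame-level calibration α = (median background −
  median pillar) / h_chamber, recomputed per frame (drift-robust;
  configurable to once per run).

The printed form of the volume sum is dimensionless in area; we multiply by
px² so volumes come out in µm³. Negative per-pixel or per-cell values under
noise are deliberately not clamped — clamping would bias population medians
upward; the rolling median absorbs outliers instead.

**Normalization.** Each track's baseline is the median volume over the two
minutes preceding stimulation; normalized volume is V/baseline. The rolling
median uses a centered 7-frame window (≈1 min at the default 10 s interval),
shrinking at the series ends.

## 2. Segmentation

Cells appear dark on bright background, so the foreground is found
edge-first: Gaussian denoising (σ = 1 px; the denoiser is a pluggable,
deliberately simple stand-in — its identity is not load-bearing because the
volume equation integrates over the footprint), Scharr gradient magnitude,
and a threshold at exp(μ + k·σ) of the log-magnitudes over strictly positive
pixels (k = 1). The log domain is used because edge-strength distributions
are approximately log-normal; zero-magnitude pixels are excluded (log
undefined). Mean/SD are computed per frame. Thresholded edges are closed
(radius 1) to seal noise gaps, the background is flood-filled from the image
border, and its complement is the foreground.

Two topological/numerical details matter:

* the background flood is **4-connected** while foreground components are
  8-connected — Jordan-curve duality; an 8-connected flood leaks through
  diagonal runs of a one-pixel edge ring and deletes enclosed cells;
* the flood-filled region extends to the outer *tail* of the blurred
  gradient, not its ridge. For a Gaussian-blurred step of peak gradient g the
  suprathreshold band reaches s·sqrt(2·ln(g/θ)) beyond the physical boundary
  (s = blur scale of denoiser + Scharr support). `threshold_foreground`
  peels this predictable halo back (`halo_trim`, auto-estimated per frame)
  before applying the deliberate 1-px footprint dilation that captures
  scattered signal just outside the cell. Without the trim, footprints are
  biased ~3 px outward; volumes are nearly unaffected (the annulus background
  makes I_max − I ≈ 0 there) but footprint-area readouts would be inflated.

Instances are split by a watershed on the negative distance transform of the
foreground, seeded at nuclear-channel blob centroids (Gaussian smoothing,
Otsu threshold, area-filtered connected components — a classical detector;
nuclei are high-contrast blobs so a learned model would add dependency
weight without accuracy). Mask components containing no seed stay in the
foreground but unlabeled; they still occlude other cells' annuli.

## 3. Flatfield correction

Background pixels sample FF directly, so a smooth surface fit to
cell/pillar-free samples is the per-frame flatfield. Samples lie on a
sinusoidal path (200 points, 4 periods, 10 px margin) spanning the frame —
dense near the top and bottom edges. Points landing on the exclusion mask
(foreground ∪ pillars, each dilated 3 px) are moved ≤ 20 px or dropped; the
path's turning points cluster samples to 1–2 px spacing, so a minimum-spacing
filter (8 px) thins them — near-coincident noisy samples carry no information
but dominate the conditioning of the interpolation system. Sample values are
median-pooled over a 7×7 neighborhood restricted to non-excluded pixels, so
the surface fits illumination rather than pixel noise.

The surface is a multiquadric radial basis expansion
s(p) = Σ w_j sqrt(‖p − p_j‖² + ε²) **plus an affine tail** a₀ + a₁x + a₂y
with the standard orthogonality constraints. The multiquadric kernel is
conditionally positive definite of order 1, so the affine tail is the
mathematically complete interpolant; practically it makes constant and
linearly ramped fields reproduce exactly, which anchors the correction's
accuracy guarantees. ε defaults to the mean nearest-neighbor spacing; a
ridge of 1e−8·ε on the kernel diagonal absorbs near-duplicate points.
Correction divides darkfield-subtracted raw by the darkfield-subtracted
surface (fit to raw values; subtraction happens at evaluation), and any
non-positive denominator is a hard error. On noise-free synthetic frames with
a 20% illumination gradient the corrected whole-frame background CV is
≈0.4–0.7%.

## 4. Tracking

Detections (nuclear centroids, µm) are linked frame-to-frame. Default mode is
greedy nearest-pair matching with ties broken by smaller detection index;
`mode="exact"` solves the padded assignment problem (Hungarian algorithm)
that maximizes link count first and total distance second, and is invariant
to within-frame detection order (new-track ids are assigned in coordinate
order for the same reason). Defaults max_disp = 15 µm, memory = 2 frames:
neutrophil speeds ≲ 20 µm/min at 10 s frames give ≲ 3.3 µm/frame, so 15 µm
tolerates one or two missed detections without inviting swaps. Gap frames are
not interpolated; downstream series simply skip them.

## 5. Motility statistics

Velocity: ν_i = chord(i−τ, i+τ)/Δt in µm/min, τ = 3 frames; undefined at the
first/last τ frames. Angular alignment: for each position B, anchors A
(backward) and C (forward) are the first positions ≥ 10 µm of *cumulative
path* away; ∠ = atan2(|BA×BC|, BA·BC) ∈ [0, π] (cross product taken as the
z-component of the 2-D vectors). A bare division of ∠ by π maps to [0, 1]
and cannot express the documented endpoints (−1 reversal, +1 straight,
median ≈ 0 for Brownian motion); the affine map 2∠/π − 1 reproduces all
three and is what we implement. Population curves report, per timepoint, the
median across cells within each replicate, then mean ± SD (and a normal 95%
CI) across replicates; a single replicate reports SD 0 by convention.

## 6. Bulk assays

Density is linear in refractive index; a two-point calibration (e.g. RI
1.3419 → 1.045 g/mL, 1.3467 → 1.074 g/mL for the Percoll working solutions)
fixes the line, fit per tube. A population's median density is the
count-weighted median with linear interpolation inside the median fraction
(fractions are density intervals; interpolation is what lets discrete
fractions yield continuous medians), and the stimulation shift is the
difference of medians. Screen binning cuts fractions where the cumulative
count first crosses k/3 of the total, keeping bins contiguous and nonempty.
Coulter runs reduce to per-timepoint sample medians normalized by the mean of
the first three (pre-stimulus) medians.

Water-content arithmetic: a cell that is a fraction w water (≈0.65 for
neutrophils) and swells by a fraction s in volume gains s/w of its water
content if the added volume is water — s = 0.15, w = 0.65 gives ≈23%.

## 7. The synthetic generator

`simulate_experiment` renders the measurement model exactly, so ground truth
is exact by construction:

* **Cell shape** — a smooth dome h(r) = h_peak·(1 − (r/R)²)^1.5 clipped at
  the chamber height, with h_peak/R = 0.6 and R solved from the target volume
  by bracketed root finding (closed-form clipped-dome volume, tol 1e−8).
  Ground-truth volume is recorded *after* rasterization (px² × Σ height map),
  so recovery tests never conflate discretization with estimator error.
* **Volume program** — multiplicative factor: 1 pre-stimulation; a half-sine
  dip of depth 6% over 60 s at stimulation (spreading); then a saturating
  rise to +15% with τ = 240 s; a 2%-amplitude, 60 s-period sinusoid with
  per-cell phase rides throughout (motility-cycle fluctuations). Defaults
  mirror the biological magnitudes the assay is designed to resolve.
* **Motility** — persistent random walk, heading increments N(0, 0.3² rad)
  per 10 s step, speeds 0.5 µm/min before and 12 µm/min after stimulation.
  Cells live in an inner arena clear of pillars and borders; steps that would
  bring two centroids closer than one cell diameter are re-drawn (excluded
  volume), keeping footprints disjoint so per-cell truth stays exact.
* **Scene** — eight pillars (radius 6.5 µm) in a border band; illumination =
  off-center quadratic vignette + plane tilt with peak deviation 20% (the
  dominant structure of real widefield illumination); darkfield = 100 units
  with a 2% row gradient; additive Gaussian noise of 1% of the background
  amplitude; α_true = 100 units/µm.
* **Bulk generators** — normal density distributions histogrammed into
  fraction edges (out-of-range cells counted in end fractions, as in a real
  tube); lognormal Coulter volumes whose median follows the swell kinetics.

What it does **not** emulate: optics (PSF, scattered light, z-dependence),
photon-shot noise, cell divisions, shape irregularity or blebbing, adhesion
footprint dynamics decoupled from volume, chamber-height gradients, and flow.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated model, not robustness to every real-data
pathology; the halo-trim and annulus rules, in particular, inherit the
assumption that intensity outside a cell reaches background within ~2 px.

## 8. Problem sizes and determinism

The reference synthetic experiment is 50 cells, 120 frames at 500×500 px —
large enough that population medians are stable (MC error on the median of 50
cells ≈ 0.5% of the fluctuation amplitude) while a full end-to-end analysis
stays in the minutes range on one CPU. Identical configs (including seed)
produce bit-identical datasets and byte-identical result CSVs; the pipeline
itself draws no random numbers. All seeds derive from a single integer.

## Known limitations

* The greedy linker can swap identities when cells approach within max_disp;
  exact mode mitigates but true crossing trajectories are ambiguous without
  appearance models (out of scope).
* The multiquadric surface is fit per frame with no temporal smoothing; on
  very sparse backgrounds (>95% of the frame excluded) sampling fails hard
  rather than degrading.
* Instance splitting assumes one nuclear seed per cell; over/under-detection
  propagates directly to instance masks.
* `local_background` measures annulus distances from the (dilated) label
  mask rather than the pre-dilation footprint; at 1 px dilation the induced
  shift of the 2–10 px annulus is immaterial against a flat background.
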