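# Methods

`eprime` quantifies how precisely the degree of coronary stenosis can be
estimated from a cardiac CT angiography (CTA) image, given the patient's
anatomy and physiology and the scanner's acquisition and reconstruction
characteristics.  The figure of merit is the estimability index

    e' = 1 / SD(ŝ),

the reciprocal of the standard deviation of an ensemble of ideal
maximum-likelihood (ML) stenosis estimates `ŝ` computed over stochastic
realisations of image noise and cardiac motion.  Stenosis is fractional
diameter narrowing: a stenosed lumen of diameter `(1 − s)·d_ref` inside a
reference lumen of diameter `d_ref`.  An e' of 25.58 therefore corresponds to
a stenosis precision (SD) of 100/25.58 ≈ 3.91 percentage points, and a ±2 SD
(95%) uncertainty interval 15.6 points wide.

## Vessel and plaque model

A diseased cross-section is modelled as concentric disks on a hyper-resolution
grid (≥10× finer than the clinical pixel): contrast-enhanced stenosed lumen,
plaque annulus between the stenosed and reference lumen boundaries, 0.5 mm
vessel wall, and a uniform epicardial-fat-like background.  Defaults: plaque
attenuation by material class at 120 kV — noncalcified −40 HU, mixed 150 HU,
calcified 500 HU; wall 50 HU; background −90 HU (wall/background values are
package choices, configurable).  The reference diameter is a pure lookup by
sex and AHA coronary segment from a shipped, editable CSV spanning
1.5–5.0 mm (the published per-segment tables are not reproduced; the shipped
values are documented plausible defaults for a right-dominant tree).

Edges are rendered with a C¹ smoothstep over one hyper-pixel in the signed
distance to each disk boundary.  This keeps region interiors exactly at their
material HU, conserves disk areas to first order, and — crucially for the
estimator — makes the rendered image a smooth function of stenosis even for
sub-pixel radius changes, so template banks with 0.2-point stenosis spacing
have well-defined finite-difference gradients.  (Sub-sampled area-weighting
anti-aliasing was tried first; its area quantisation made the template
gradient jagged at the sub-pixel scale.)

Luminal enhancement is matched to the aortic contrast level and adjusted for
partial-volume averaging: when the stenosed lumen approaches one clinical
pixel, its modelled HU is the analytic area-weighted mixture of lumen contrast
and surrounding plaque within a clinical-pixel footprint centred on the axis.
The exact published adjustment rule is not printed; this area-fraction rule is
a documented stand-in with the required limits (no change for large lumens,
monotone decline with narrowing and with shrinking vessel calibre).

Plaque geometry is concentric by default.  Only the 2D in-plane cross-section
is modelled; slice thickness/interval are carried as metadata.

## Motion model

In-plane vessel velocity is an affine function of resting heart rate per sex
and segment (shipped CSV; 15–35 mm/s for heart rates 50–100 bpm, clipped to
10–50 mm/s outside), with speed and direction constant over the brief
half-scan window and the direction (and source start angle) uniformly random
per acquisition — the source rotation is not synchronised with the heart.

For each projection angle θ the motion component along the detector channel
direction `s(θ) = [sin θ, −cos θ]` creates data inconsistency; the motion PSF
instance is the weighted path of `(v·s(θ_t)) t s(θ_t)` over the reconstruction
span, splatted bilinearly onto the hyper grid and normalised.  Projection
weights are uniform by default with an optional raised-cosine
"smooth-transition" taper over the first/last 10% of the span.  Dual-source
and multisegment acquisition partition the span into `n_sources × n_segments`
contiguous angular subsets, each acquired in a proportionally shorter local
time window (local time restarts at zero per subset, anchoring every subset
path at the origin); heartbeat phase consistency across segments is assumed
perfect.  The effective temporal resolution is
`rotation_time × span/(2π) / (n_sources × n_segments)` — 165 ms for a
0.33 s single-source half-scan, 82.5 ms dual-source.

The default 1024–2048 midpoint angle samples reproduce a dense 10⁵-sample
accumulation to well under 1% L1 distance.

## Imaging operators

System blur is described by a task transfer function (TTF): a radial MTF
parameterised by its half-amplitude frequency f50, with a Gaussian shape by
default (`exp(−ln2 (f/f50)²)`, so `mtf(0)=1` and `mtf(f50)=0.5` exactly) and a
heavier-tailed `1/(1+(f/f50)⁴)` alternative; tabulated two-column CSV curves
can be supplied instead.  One TTF per case is selected for the dominant
contrast edge via a material→f50 map (defaults 0.36/0.40/0.44 mm⁻¹ for
noncalcified/mixed/calcified).  The PSF is obtained by sampling the radial
curve on the kernel's discrete frequency grid and inverse transforming; the DC
sample pins the kernel sum to one, and the kernel's discrete radial MTF
reproduces the curve by construction.

Noise texture follows a radial noise-power spectrum (NPS): a ramp-like
band-pass `f·exp(−f²/2f_p²)` with peak frequency f_p (default 0.25 mm⁻¹,
typical of filtered backprojection) or flat (white), normalised to unit 2D
integral.  Correlated fields are synthesized by filtering white Gaussian noise
with √NPS in frequency space, then recentring and rescaling every field so its
sample SD equals the case noise magnitude σ exactly — honouring per-case noise
matching and removing a nuisance source of Monte-Carlo variance.

Instance composition: hyper-resolution phantom → system PSF → one stochastic
motion PSF → block-average to the clinical grid → add one correlated-noise
field.  Convolutions are circular (FFT); the uniform background and centred
vessel make wrap-around benign at the default 12.8 mm field of view, which
accommodates the largest vessel plus the motion-blur extent for clinical
rotation times.  The deterministic part of the chain is linear and
shift-invariant, so blur order is immaterial.

## Ideal estimation and e'

Under Gaussian noise, the ideal (no-prewhitening) ML estimate is the stenosis
of the noise-free template minimising the pixel-wise squared difference with
the observed instance.  The template bank spans stenosis 0.15–0.85 in steps of
0.01 (71 templates) by default, runs the deterministic chain only, and fixes
nuisance parameters (diameter, contrast, material, velocity) to their case
values.  Residual ties within a 10⁻⁹ relative tolerance return the mean of
the tied stenosis values (the blur null space can make neighbouring templates
indistinguishable).  Estimates are clamped to the bank range and clamping is
flagged.

Templates include a *deterministic direction-averaged* motion blur at the case
velocity (12 evenly spaced directions, golden-ratio start angles).  This is a
deliberate design choice among the three implemented template policies
(motion-free / direction-averaged / full velocity-axis bank): the stochastic
asymmetric blur of an individual instance still cannot be prewhitened — its
direction is unknown — but the observer does know the expected radially
averaged blur at the case velocity.  With strictly motion-free templates,
case velocities above ≈20 mm/s drive every estimate to the bank edge (the
motion-blurred lumen is best matched by the tightest stenosis available),
collapsing the ensemble SD and destroying the monotone dependence of e' on
velocity; the direction-averaged policy restores small bias and the expected
qualitative behaviour while leaving the per-instance residuals non-white.

The ensemble uses 2300 instances per case by default (each with independent
uniform motion direction/start angle and noise field; per-instance RNG streams
spawned from the root seed, so results are order-independent).  `e' = 1/SD`
(sample SD, n−1) on the fractional scale; precision is reported in percent.
Cases with local plaque CNR ≤ 1 (CNR = |adjusted lumen HU − plaque HU|/σ) or
vessel velocity ≥ 40 mm/s are outside the index's informative regime and are
reported as nondiagnostic with e' = 0; a zero-variance ensemble reports an
infinite-e' sentinel with a flag.

An analytic cross-check for white noise linearises the template manifold
around the truth: `SD(ŝ) ≈ σ/‖∂T/∂s‖`, with the gradient from central finite
differences on the bank.  Monte-Carlo and closed form agree to a few percent
in the linear regime (σ = 10 HU for the reference 3 mm vessel, where the
gradient norm varies <2% over ±2 SD); at larger σ the curvature of the
template manifold inflates the Monte-Carlo SD relative to the linearised
formula, as expected.

## Cohort validation harness

The clinical benchmark that motivated the index split 132 CTA studies (88
high-quality, 44 low-quality, by expert quality score and reader concordance)
and asked whether per-case e' recovers the split.  The clinical images are not
available, so the harness draws *synthetic* cohorts from the published
class-conditional characteristics: heart rate 64±9 vs 69±11 bpm, contrast
578±154 vs 230±192 HU, noise σ 32±11 vs 41±16 HU, stenosis severity 33.6±16
vs 38.3±10.5%, plaque-material mix (calcified 1/88 vs 22/44), sex mix, and a
scanner catalogue patterned on the published manufacturer/model counts
(rotation times, dual-source/multisegment availability and usage fractions —
editorial choices, not published data).  Truncated-normal sampling bounds
(HR ≥ 30 bpm, contrast ≥ 0 HU, σ ≥ 1 HU, stenosis 15–85%) prevent
non-physical draws from the wide low-class contrast distribution.  Cases
reported without plaque are simulated as noncalcified, since a plaque is
required to pose the estimation task.  Quality labels are assigned by
construction (the generating class) — a synthetic stand-in for the
reader-based surrogate, which needs human reads.

Lesion selection (highest stenosis; reader-disagreement averaging; ties broken
by the larger reference-diameter segment) and best-series selection (highest
e', first index on ties) implement the benchmark's case-preparation rules.
ROC analysis uses the pairwise-concordance AUC (ties half); the operating
threshold minimises the distance to the ideal-classifier corner (0, 1) and is
reported as the midpoint of the decision gap below the selected point, which
splits the training data identically and generalises better to held-out
folds.  Uncertainty comes from within-class bootstrap (class sizes and ratio
preserved) and stratified fourfold cross-validation (round-robin dealing,
degrading gracefully to leave-one-out).

What passing cohort tests shows — and what it does not: the synthetic cohort
reproduces the *marginal* class-conditional distributions, not the joint
clinical covariance structure, reader behaviour, or image artefacts beyond
the modelled blur/noise/motion.  The end-to-end check therefore asserts
qualitative reproduction (class separation far above chance, bootstrap-stable
threshold), not the published AUC 0.985 / accuracy 0.977 / threshold 25.58,
which depend on the actual trial images.

## Protocol optimisation

A full-factorial design over patient factors (diameter 1.5–5 mm, stenosis
30–70%, velocity 15–35 mm/s, material, contrast 300–600 HU) and protocol
factors (pixel size 0.35–0.55 mm, σ 15–45 HU, rotation time 0.25–0.35 s,
dual-source on/off, f50 0.32–0.52 mm⁻¹) is swept with the engine (per-row
spawned seeds; degenerate rows flagged, not dropped) and the *precision*
(fractional SD = 1/e') is fit by OLS with intercept, linear, squared and
pairwise-interaction terms; categorical factors are dummy-coded against the
first observed level, and interaction names are canonicalised alphabetically.
The default candidate set is the full quadratic pruned by backward elimination
at p < 0.01 (perfect fits fall back to coefficient-magnitude pruning, since
p-values are undefined at zero residual); the retained-term count is reported,
not asserted.  Partial dependence is the plain per-level mean (balanced by the
factorial design); slice predictions carry 95% confidence bands from the
coefficient covariance.  Default sweep sizes (3 levels per continuous factor,
500 instances per row, optional row subsampling) are a fidelity/runtime trade
chosen for desk-scale studies; single-case runs default to 2300 instances.

## Numerical choices and problem sizes

- Hyper-resolution factor 10; field of view 12.8 mm (18 mm where the
  slowest-rotation kernels are exercised in isolation).
- Stenosis grid step 0.01 (0.002 in the closed-form oracle check, keeping
  quantisation variance ≪ ensemble variance).
- Monte-Carlo sizes: 2300 instances for single-case runs and the closed-form
  check; 500 for the monotonicity studies; 300 per case for the 132-case
  synthetic cohort; 500 bootstrap replicates.  These scaled-down sizes keep
  the sampling SE of SD (≈ 1/√(2n)) at the few-percent level.
- Seeds: every stochastic entry point takes a root seed; per-instance,
  per-case, and per-row streams are spawned deterministically from it.

## Known limitations

- Spectral physics (beam hardening, calcium blooming), through-plane
  (craniocaudal) motion, time-varying velocity within an acquisition, and
  nonlinear-reconstruction behaviour beyond the TTF/NPS description are not
  modelled.
- TTF/NPS curves, segment diameter/velocity tables and the scanner catalogue
  are parametric/editable stand-ins spanning published ranges, not measured
  scanner data.
- The estimator is "ideal" only up to the stated caveats: stochastic
  asymmetric motion makes residuals non-white, so e' is a representative — not
  strictly optimal — precision bound, with possible residual bias at high
  velocity.
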