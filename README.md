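# eprime — task-based estimability of coronary stenosis in cardiac CTA

Quantifying coronary stenosis from cardiac CT angiography is limited by image
noise, system blur and — uniquely in cardiac CT — stochastic motion artefacts
from the beating heart during half-scan acquisition.  `eprime` implements a
computational framework that turns these degradations into a single,
task-based figure of merit: the **estimability index**

```
e' = 1 / SD(ŝ)
```

the reciprocal of the standard deviation of an ensemble of ideal
maximum-likelihood stenosis estimates `ŝ` (fractional diameter narrowing,
`d_stenosed = (1 − s)·d_ref`).  An e' of 25.58 is equivalent to a stenosis
precision (SD) of 3.91 percentage points and a ±2σ (95%) interval 15.6 points
wide.  The index is intended for medical-imaging physicists and CTA
protocol designers who need to predict, compare, or optimise achievable
stenosis precision across patients, scanners and protocols.

The pipeline, end to end:

1. **phantom** — hyper-resolution (≥10× clinical sampling) cross-sections of a
   contrast-enhanced lumen narrowed by a plaque (noncalcified −40 HU, mixed
   150 HU, calcified 500 HU at 120 kV), with a 0.5 mm wall and fat-like
   background; reference diameters by sex and AHA segment; partial-volume
   adjustment of lumen enhancement for near-pixel lumens.
2. **motion** — stochastic 2D asymmetric motion PSFs: the vessel velocity
   (from heart rate, sex, segment) is projected on the rotating detector
   channel direction `s(θ) = [sin θ, −cos θ]` over the half-scan span; random
   motion direction and start angle per acquisition; dual-source/multisegment
   partitioning shortens the effective temporal window
   (`rotation × span/2π / (sources × segments)`).
3. **imaging** — task transfer function (TTF) blur, downsampling to the
   clinical grid, and correlated noise synthesized from a radial noise-power
   spectrum (NPS), rescaled so every field's SD equals the case noise σ.
4. **estimator** — squared-difference template matching (MLE without
   prewhitening) against a noise-free template bank (stenosis 15–85%, step 1
   point), 2300 stochastic instances per case, `e' = 1/SD`; cases with plaque
   CNR ≤ 1 or vessel speed ≥ 40 mm/s are flagged nondiagnostic (e' = 0).
5. **validation** — synthetic two-class (high/low image quality) cohorts from
   published class-conditional profiles, ROC/threshold analysis, within-class
   bootstrap, stratified k-fold cross-validation.
6. **protocol_opt** — full-factorial e' sweeps over patient/protocol factors
   with quadratic response-surface fitting, partial dependence and slice
   predictions.

See `docs/methods.md` for the model details, assumptions and design choices.

## Worked example

Compute e' for a typical case — a 50% mixed-plaque stenosis of the proximal
LAD in a female patient at 65 bpm, imaged at 450 HU luminal enhancement on a
0.33 s single-source scanner with 0.45 mm pixels and 30 HU noise:

```python
from eprime import CaseSpec, ScannerSpec, compute_case_eprime

case = CaseSpec(
    sex="F", heart_rate=65.0, aha_segment="proximal-LAD",
    stenosis_severity_pct=50.0, plaque_material="mixed",
    lumen_enhancement=450.0,
    scanner=ScannerSpec(rotation_time_s=0.33, pixel_size_mm=0.45, sigma_hu=30.0),
)
result = compute_case_eprime(case, n_instances=2300, seed=17)
print(result.to_dict())
```

```
{'e_prime': 10.421946489844917,
 'precision_pct': 9.595136580046674,
 'mean': 0.5283217391304347,
 'bias': 0.028321739130434676,
 'n_instances': 2300,
 'flags': {'degenerate_cnr': False, 'degenerate_velocity': False,
           'zero_variance': False, 'edge_clipping': True}}
```

Reading: across 2300 stochastic noise-and-motion realisations the ideal
estimator recovers the stenosis with a standard deviation of 9.6 percentage
points (e' ≈ 10.4, inside the practical 3–120 band), with a small positive
bias of 2.8 points caused by the unprewhitenable asymmetric motion blur at
the case's 18 mm/s vessel speed; a handful of estimates reached the template
bank edge (`edge_clipping`).  Halving the noise or imaging on a dual-source
geometry raises e'; a calcified plaque or a faster vessel lowers it.

The same computation from the shell:

```bash
eprime compute --case case.json --n 2300 --seed 17 --out result.json
eprime cohort --n-high 88 --n-low 44 --seed 7 --score --out cohort.csv
eprime roc --table cohort.csv --boot 1000 --cv 4 --out roc.json
eprime sweep --config sweep.yaml --out sweep.csv && eprime fit --table sweep.csv --out model.json
```

Every command writes a `.manifest.json` (config hash, seed, version) next to
its output, so any artifact is reproducible from its manifest alone.

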