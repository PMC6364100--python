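# Methods

This note documents the models, conventions and numerical choices behind
phenoscreen, in the spirit of a package reference: what is computed, under
which assumptions, and what a passing test does and does not establish.

## 1. Instrument model (synthetic data)

The simulator emulates a UPLC coupled to a miniature single-quadrupole
mass detector acquiring alternating positive and negative full scans over
50–400 Da plus selected-ion-monitoring (SIM) traces.

**Mass axis.**  Unit resolution: all m/z values are integer-centred 1-Da
bins and all adduct arithmetic is nominal — [M+H]⁺ = M+1, [M+Na]⁺ = M+23,
[M−H]⁻ = M−1.  No isotope patterns.

**Elution.**  Each analyte elutes as a Gaussian centred at its library
retention time with σ = 0.05 min (default).  Retention times are library
constants; no gradient model.  Both polarities are sampled at the same
nominal RT within a cycle, every 0.05 min (default).  With the default
σ = cycle period, a peak spans ~2.4 samples at half height — deliberately
coarse, as a low-end detector would deliver; trapezoidal integration of a
Gaussian is nonetheless essentially exact at this sampling (the
Euler–Maclaurin error is e^(−2π²σ²/Δt²) ≈ 3·10⁻⁹ of the area).

**Response.**  The integrated SIM area of a compound follows the affine
model `area = response_factor × concentration + area_intercept` with
concentration in µg/mL of the injected extract.  By default the intercept
is zero (then area is exactly proportional to concentration) and each
compound's response factor is the published calibration slope of its
quantifying standard — the same equal-response assumption that underlies
surrogate quantification, stated here as a simulator default rather than
hidden.  Dry-sample content maps to concentration through the
matrix-solid-phase-dispersion constants, `conc = content × recovery ×
sample_mass / elution_volume` (defaults 0.5 g into 10 mL: content = 20 ×
conc).  Full-scan ion intensities divide the elution profile according to
the fingerprint's relative abundances.

**Noise.**  Baseline noise is i.i.d. Gaussian, mean zero, SD
`noise_level`, added per point and clipped at zero (intensities are
non-negative).  `noise_level` is a scalar (applied to full scans and all
SIM traces) or a per-compound map (applied to SIM traces only; a shared
channel receives the largest of its members' values).  Clipping matters:
it puts a ~0.4 σ positive floor under dark baselines and deflates the
observed SD of a blank to ~0.58 σ — see §4.

**Negative-mode signal.**  Bibenzyls with free hydroxyls show a negative
signal whose m/z the published fingerprints do not list; the simulator
emits [M−H]⁻ at 30% relative abundance (classification only tests the
*presence* of the signal, so this value is uncritical).  Flavones are
simulated negative-only: their positive response is described as much
weaker and is below the detection threshold of this model.
Chrysotobibenzyl, lacking a hydroxyl, gives no negative signal.

**Spiked batches.**  A fortified replicate's content is
`endogenous + recovery_true × spike`: the recovery applies to the spike,
while the endogenous term is the already-measured (post-extraction)
level.  Paired unspiked blanks are always generated.

**What the generator does not emulate.**  Retention-time drift, matrix
interferences beyond a flat noise floor, detector saturation, isotope
envelopes, heteroscedastic (signal-dependent) noise, carry-over.  A green
end-to-end test therefore establishes the correctness of the *computa-
tional chain*, not robustness against those physical effects.

## 2. Signal processing

Detection runs on a centred moving-average smoothed trace; heights and
areas are measured on the raw trace.

* **Smoothing window: 3 points.**  A 5-point window at the default
  sampling spans five elution sigmas and demonstrably merges the
  erianin/chrysotoxin pair, which share the 341⁺ SIM channel 0.28 min
  apart; 3 points is the widest window that resolves every pair the
  method must separate.
* **Maxima** come from prominence-thresholded local maxima of the
  smoothed trace (threshold: max of 3× the noise estimate and 1% of the
  trace's dynamic range — offset-invariant by construction).
* **Boundaries** walk outward to the nearest point where the smoothed
  trace returns to the local base + 1% of height, or to the local
  minimum, whichever comes first; the descent tolerates upticks below
  3× the noise estimate so fine-sampled noisy flanks do not stop it
  prematurely.  Neighbouring peaks whose boundaries (nearly) touch share
  a boundary at the raw-trace valley between their apexes.
* **Cluster baseline (perpendicular drop).**  Peaks separated only by a
  valley form a cluster; every member's linear baseline runs between the
  cluster's *outer* boundaries, so a small peak is not sliced off by a
  big neighbour's flank.  Baseline anchor values average up to five
  points strictly outward of each anchor (noise robustness).
* **Integration span** is clamped to apex ± 4 σ̂, σ̂ estimated from the
  smoothed full width at half maximum; the (systematic) tail loss
  cancels through calibration, while the noise integral stays short.
* **S/N** = baseline-subtracted height / noise SD, with the noise SD of
  a blank window defined as its sample standard deviation (the
  peak-to-peak alternative is noted as an open choice; SD was chosen for
  testability).
* Trace-internal noise for detection thresholds uses the MAD-scaled
  smoothing residual; it is only a detection heuristic, not the LOD
  noise (§4).

## 3. Screening rules

Fingerprints take the base peak from the positive spectrum, falling back
to the negative one only when positive is empty; relative abundances are
% of base, ions below 10% are dropped (base always kept).  Family rules,
in order:

1. **Bibenzyl** — a positive ion pair spaced 22 Da.  When the sodium
   adduct is the base peak, the [M+H]⁺ partner must fall in [20%, 80%]
   (observed values span 35–52%; a window is required and none is
   published).  When the protonated ion is the base (chrysotoxin: Na at
   83%), a sodium partner ≥ 20% suffices.  MW = m/z(Na) − 23.  No
   negative-mode requirement (chrysotobibenzyl has none).
2. **Flavone** — negative signal strictly stronger than positive;
   MW = m/z(neg base) + 1.
3. **Phenanthrene** — positive-only, two ions spaced 28 or 32 Da
   (neutral CO/CH₃OH-type losses); MW = base − 1.  A positive-only
   single ion is **coumarin-like**, MW = base − 1.  Anything else is
   unknown.

Identification against the nine-standard library requires both RT
(±0.1 min) and base-ion (±0.5 Da) agreement; otherwise a classified peak
is newly elucidated with the family surrogate (bibenzyl → erianin, or
gigantol iff inferred MW = 274 — the nearest-mass family standard;
flavone → naringenin; phenanthrene → moscatin; coumarin-like → coumarin,
an extension of the published mapping to a case it never needed).  SIM
ion selection prefers the sodium adduct for bibenzyls even off-base-peak.
Naming new compounds (literature search) is out of computational scope.

## 4. Calibration, LOD/LOQ, quantification

Ordinary least squares (unweighted, matching the published line form);
R² = 1 − SSres/SStot.  A zero slope raises a degenerate-calibration
error.  LOD and LOQ are the concentrations whose predicted peak *height*
(slope × conc × height_per_area, intercept excluded — the signal is the
response above baseline) equals 3× and 10× the baseline noise SD;
LOQ/LOD = 10/3 exactly, and zero noise degenerates both to zero with a
warning.  `height_per_area = 1/(σ√2π)` is the Gaussian shape constant.

The pipeline measures channel noise on a simulated *blank injection*
using the median-to-84th-percentile spread rather than the plain SD:
for Gaussian noise the two coincide, but zero-clipping deflates the SD
of a dark baseline by ~40% while leaving the upper quantile spread — the
side that produces false peaks — intact.  Quantification additionally
requires a measured peak S/N ≥ 10, which is the LOQ definition applied
to the peak itself; contents below LOQ are reported missing.

Known bias: at detection-limit S/N (~20) the clipped noise floor
inflates the baseline anchors but not the peak core, biasing raw areas a
few percent low.  The bias is systematic, cancels through calibration
(standards and samples share it), and is characterised in the test suite
(mean within 5%, every seed within 10% at S/N = 20).

## 5. Validation statistics

Recovery = 100 × (mean spiked − endogenous)/added; endogenous is the
blank mean with below-LOQ blanks as zero.  RSD uses the sample (n−1) SD —
the analytical-chemistry convention.  Two intrinsic limits, quantified in
the acceptance tests rather than hidden: (a) compounds sharing a SIM
channel (gigantol/DDB on 297⁺, erianin/chrysotoxin on 341⁺) exchange a
small amount of area through perpendicular-drop allocation, bounding
noise-free recovery within ~3 percentage points there; (b) the published
design spikes 50 mg/kg onto endogenous levels up to 345 mg/kg, so
recovery amplifies content noise by endogenous/spike (up to ~7×) — with
1% peak-height noise the honest Monte-Carlo bound at that level is tens
of percentage points, which is a property of the design, not the code.

## 6. Reporting conventions

The content table carries one row per sample plus an Average row: the
arithmetic mean over non-missing samples, missing iff all samples are
missing.  Display values truncate toward zero at three significant
digits ("—" for missing; empty cells in CSV); truncation is the unique
simple rule consistent with the published table's cells (425.5→425,
20.875→20.8, 13.65→13.6, 9.7475→9.74), of which exactly one printed cell
(confusarin, 246.5) keeps a fourth digit; internal values keep full
precision.  Pipelines are deterministic: the same configuration and seed
produce byte-identical tables.

## 7. Serialization

Runs round-trip exactly through a plain CSV long format (one row per
recorded point) and through a minimal self-contained mzML 1.1 subset
(centroided spectra with polarity and scan start time; SIM traces as
chromatograms; uncompressed 64-bit little-endian arrays).  The mzML
reader is limited to that subset.  Scenario configurations use flat YAML;
all report tables are CSV.

## 8. Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| peak σ | 0.05 | min | no published widths; plausible UPLC peak |
| cycle period | 0.05 | min | matches the coarse scan-rate class of the detector |
| sample mass / elution volume | 0.5 / 10 | g / mL | published preparation |
| calibration levels | 2,5,10,20,50,100 (1,2,10,20,50,100 below) | µg/mL | six points over the published ranges |
| calibration replicates | 3 | — | published triplicate injection |
| smoothing window | 3 | points | §2 |
| boundary threshold | 1% of height | — | return-to-baseline criterion |
| RT match tolerance (screening / SIM assignment) | 0.1 / 0.2 | min | unit-resolution practice |
| m/z tolerance | 0.5 | Da | unit resolution |
| [M+H]⁺ window (bibenzyl rule) | 20–80 | % | brackets the observed 35–52% |
| min. relative abundance | 10 | % | fingerprint ion retention |
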