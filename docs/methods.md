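# Methods

## The measurement being modeled

A cryogenic ion trap sits between the ion-mobility region and the TOF
pusher of an IM-MS instrument. Each trap cycle has three phases: ions
accumulate and thermalize for 50 ms while a N₂/He gas pulse (led by 2 ms)
enables messenger tagging; the packet is released; the laser fires at
50.092 ms while the pusher runs at 18 kHz inside a 50.045–50.099 ms
window. Cycles alternate laser-on/laser-off at 20 Hz, so one 100 ms
acquisition cycle yields one paired (off, on) transient set; a scan steps
the laser over a wavenumber grid (default 990–1810 cm⁻¹ in 2 cm⁻¹ steps,
411 points) and averages a user-defined number of pairs (default 75) per
step. Upstream, the exit lens of the mobility cell can gate a chosen
arrival-time window so only one mobility feature reaches the trap.

`ciris` implements (a) the inverse problem — from raw paired transients to
a relative absorption cross-section spectrum — and (b) a forward simulator
with the same statistical structure, so the inverse chain can be verified
against known ground truth. Hardware control, and the measured band
positions of real analytes, are explicitly out of scope: the latter are
properties of the molecules, not of the data processing, and cannot be
reproduced without the physical instrument.

## Retrieval model

Per wavenumber ν̃, with window-integrated intensities summed over cycle
pairs:

* depleted fraction `F = (I_on − I_off) / I_off`. Referencing against the
  interleaved laser-off signal cancels drifts in total ion current and in
  tagging efficiency. F may be negative (noise) and is not clipped, so
  null experiments stay symmetric about zero.
* saturation linearization `S = −ln(1 − min(F, cap))`, `cap = 0.999`.
  If i of N tagged ions have already lost their tag, only N − i remain
  observable in the same cycle; the logarithm undoes this compounding.
  Points with F ≥ cap are flagged `saturated`, never dropped silently.
* photon-flux normalization `σ_rel = S / (E(ν̃)·ν̃)`. The number of photons
  per pulse is E/E_photon ∝ E·λ; with a near-diffraction-limited focus
  (area ∝ λ²) the flux is ∝ E/λ ∝ E·ν̃. The internal spectral axis is
  wavenumber; the wavelength form −λ·ln(1−F)/E differs only by a fixed
  unit constant absorbed into the relative scale.

**Reference-mode duality.** `untagged_off` (default) monitors the *gain*
of the untagged ion relative to its own laser-off level — the formula
above verbatim. `tagged_off` monitors the *loss* of the summed tag series
(windows at base + n·28.006/|z|, n = 1..max_tags) relative to its
laser-off level. For an ensemble in which every tagged ion carries exactly
one tag, the tagged-reference linearized signal is exactly proportional to
the absorption cross-section at any depletion; with a Poisson tag-number
distribution both conventions are linear only to first order in the
absorbed dose (see "Fidelity and its limits"). Both modes are exposed and
tested.

**Averaging.** Pairs are combined as a ratio of sums, not a mean of
per-pair ratios — the ratio estimator's bias falls as 1/(n·counts) whereas
per-pair ratios at low counts are noisy and skewed. The per-point standard
error is a leave-one-pair-out jackknife on the full F → S → σ chain; on
homogeneous synthetic data it scales as 1/√n_pairs (tested).

## Forward model

* **Ion numbers.** Each trap cycle receives Poisson-distributed ion
  numbers (mean `source_rate`, default 3000, split by relative abundance),
  drawn independently for on and off cycles — electrospray fluctuation
  that the off-reference cannot cancel, only average down.
* **Tagging.** Tag counts are Poisson with species mean `mean_tags`.
  The study systems report only mean tag counts; Poisson is the minimal
  model for independent rare attachment events. A degenerate
  (`tag_distribution="fixed"`) alternative is provided, both for injection
  of other models and because it makes the linearization exact.
* **Detagging.** One absorbed photon removes one tag; each tag is lost
  independently with `p = 1 − exp(−fluence_scale·σ(ν̃)·E(ν̃)·ν̃)`.
  `fluence_scale` is the single calibration constant converting σ·E·ν̃
  into an exponent; presets set it with `set_peak_depletion(sc, 0.95,
  mode="tagged")` so the strongest band reaches 95% expected tag depletion,
  the top of the instrument's stated 90–95% operating range. Retagging
  after release is not modeled (irradiation after release suppresses it on
  the instrument).
* **Arrival times.** Gaussian per species (mean, FWHM); the exit-lens gate
  is a sharp half-open window applied to events (the real gate's edge
  transfer function is unknown; a sharp gate is assumed).
* **TOF synthesis.** Each (species, n tags) population adds a Gaussian
  peak (σ = `peak_width`, default 0.01 µs) at t = t0 + k·√(m/z) on a
  uniform axis (dt = 0.002 µs), plus a constant baseline (default 2
  counts/sample) and Poisson counting noise. The per-ion response is
  normalized so each ion contributes equal *m/z-domain* peak area: the
  √(m/z) flight-time Jacobian is folded into the detector response at
  synthesis, because the analysis side deliberately performs no Jacobian
  rescaling when mapping traces to spectra. Without this convention,
  window integrals across the 28 Da tag ladder would differ by ~2.5% per
  tag for identical ion numbers, biasing tag fractions and mean tag
  counts.
* **Noiseless mode** (`stochastic=False`) propagates expected values
  (expected tag histograms, binomial-thinning expectations, no counting
  noise) — the limit used for round-trip verification.

All randomness in a scan flows from one integer seed through a single
generator; identical (scenario, seed) reproduce the dataset bit-exactly.

### Preset study systems

* `leu_enk`: protonated leucine enkephalin, m/z 556.28, mean 1 N₂ tag
  (tagging yield 1 − e⁻¹ ≈ 63%), synthetic amide-like band pattern with
  its strongest band at 1688 cm⁻¹. Its arrival-time parameters (6.10 ms,
  FWHM 0.5 ms) are a plausible choice, not a reported value; nothing
  quantitative depends on them.
* `trisaccharide_mixture`: isobaric sodiated melezitose + cellotriose,
  both m/z 527.16 (the instrument-nominal 526.4 is kept as `label_mz`),
  arrival apexes 4.75 / 5.35 ms, FWHM 0.4 ms, relative abundance 0.85 : 1
  (slightly less melezitose in the gas phase), mean tags 1.0 / 2.85 so the
  mixture averages 2 tags while the sliced early component averages 1.
  The two species carry distinct synthetic band patterns concentrated in
  the C–O deformation region below 1200 cm⁻¹.
* `melezitose_sliced`: the early mixture component alone.

The synthetic laser profile rises smoothly from 1.5 mJ near 1000 cm⁻¹ to
~3.2 mJ at 1810 cm⁻¹, mimicking an OPO/OPA chain; profiles are linearly
interpolated in ν̃ and never extrapolated.

## Fidelity and its limits

For single-tag ions in `tagged_off` mode the retrieval inverts the forward
model exactly: F = p, so S = −ln(1−p) = fluence·σ·E·ν̃ and σ_rel ∝ σ at any
depletion (tested to < 0.5% RMS at the 95% operating point). For Poisson
tag numbers, ions with k ≥ 2 tags make the ensemble's depletion a mixture
of exponentials, and no single logarithm linearizes a mixture: at the
90–95% operating point the tagged-reference shape error reaches ~10%, and
the untagged-gain reference saturates outright on strong bands (expected
F ≈ e^{μp} − 1 > 1 at μ = 1, p = 0.95 — flagged, not hidden). The
quantitative fidelity check therefore runs in a quasi-linear probe regime
(~6% peak tag depletion), where the noiseless round trip matches the true
cross-section to ≲1% relative RMS after one global scale factor.
Linearization still pays at high depletion: at 90% peak depletion the
linearized retrieval's shape error is strictly smaller than the
unlinearized one (~10% vs ~20% RMS).

## Numerical choices

* Baseline: rolling quantile (default 10th percentile, 501-sample window),
  evaluated on a stride of window/8 and interpolated. The pipeline default
  uses the median instead: for discrete low-count baselines the 10th
  percentile is integer-quantized toward zero and under-subtracts. Any
  residual constant offset enters I_on and I_off identically and cancels
  in the numerator of F.
* Window integration: trapezoid with interpolated endpoints, exactly
  additive over adjacent windows; half-open [lo, hi) convention. Tag
  windows default to ±0.35 Th (z = 1), far narrower than the 28 Da
  spacing, and the extractor refuses half-widths that would overlap.
* Negative intensities after baseline subtraction are retained in spectra
  (unbiased integrals) but clipped in the mean-tag-count estimator.
* Peak detection: scipy prominences (threshold as a fraction of the
  maximum, default 5%), three-point parabolic apex refinement, FWHM by
  linear interpolation at half height; on partially resolved peaks the
  flank walk stops at the enclosing valley and the value is flagged
  `shoulder_limited`. Mobilograms are parameterized by bin width (default
  0.11 ms); the instrument actually fixes the bin *count* per cycle and
  varies the width with the m/z range (~0.11 vs ~0.22 ms), which the
  bin-width parameterization reproduces one cycle at a time.
* Calibration is the two-parameter model only; higher-order TOF
  corrections are out of scope. Parameter standard errors come from the
  residual variance and (XᵀX)⁻¹.
* Container: little-endian, f64 axes, f32 intensities, fixed-size records
  (streamable); magic/version checked on read, truncation reported with
  the byte offset.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: tagging
spectra at 1–2×10⁵ ions, mobilograms at 10⁵ events, scans on 10–300 cm⁻¹
step grids with 1–75 pairs per point, and the zero-fluence null at 103
grid points × 75 pairs. The full tests finish in well under a minute
except the null-spectrum suite (~15 s) and the end-to-end 411-point
pipeline run (~10 s).

## Known limitations

* Trap physics (RF confinement, gas dynamics, temperature/pressure
  dependence of tagging) is not modeled; trap temperature is metadata.
* The tag-number model is Poisson by assumption; real tagging may be
  over- or under-dispersed, which would change the high-depletion shape
  residual discussed above.
* Arrival-time distributions are Gaussian; real mobility peaks can be
  skewed, which would bias FWHM estimates near shoulders.
* Negative-polarity sign conventions are carried (charge sign) but no
  anion-specific tagging chemistry is modeled.
* No mzML export; interoperability is via the documented CSV formats.
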