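# Methods

This note documents the models, numerical choices and limitations of
`qusdr`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`, not asserted from
elsewhere.

## The RF simulation model

The generator is a 1-D per-scan-line convolution model. Each scatterer at
depth `z` and lateral position `x` is assigned to its nearest scan line
and contributes an echo at `t = 2z/c` whose spectrum is

```
A(f) = a · √C · P(f) · (f/f_c)² · exp(−0.827 k² a_eff² / 2) · 10^(−α f 2z / 20)
```

where `a` is the scatterer reflectivity, `C` the acoustic concentration,
`P(f)` a Gaussian pulse spectrum (centre 8 MHz, fractional −6 dB amplitude
bandwidth 0.6 by default), `(f/f_c)²` the Rayleigh small-scatterer
response, the exponential the spherical Gaussian form-factor amplitude
(`k = 2πf/c`, `a_eff` the effective radius) and the last factor two-way
attenuation (`α` in dB/MHz/cm, `f` in MHz, `z` in cm). The Rayleigh term
makes the simulated backscatter coefficient follow the Insana–Hall
`f⁴·exp(−0.827k²a²)` law that the size/concentration estimator inverts; a
`rayleigh=False` switch produces the bare point-scatterer model used in a
few analytic tests.

Attenuation is applied **exactly per echo** in the frequency domain. On
the sample grid this damped Fourier sum is a chirp-z transform
(`scipy.signal.czt` with ratio `exp(−(σ + 2πi)/N)`, where `σ` encodes α),
so a full 256-line frame costs one CZT per line. Sub-sample delays are
deposited by linear interpolation of the impulse train; the resulting
high-frequency droop is identical in expectation for sample and reference
frames and cancels in normalization. A slow `method="direct"` path sums
echo spectra at continuous delays and is bit-compared against the CZT path
on on-grid scatterers in the tests.

Scatterer fields come in two modes: `random` (homogeneous planar Poisson
positions, standard-normal amplitudes — fully developed speckle) and
`quasi_periodic` (vertical columns of axially regular scatterers with
lattice constant `mean_spacing` and Gaussian jitter, unit amplitudes),
the ground truth for spacing estimation. Additive white Gaussian noise
sits 30 dB below the mean echo power by default.

### Default conditions

Acquisition mirrors the clinical system: 40 MHz sampling, 256 lines over
3.8 cm, 5 cm depth, ~8 MHz centre frequency, c = 1540 m/s. The reference
phantom has attenuation 0.576 dB/MHz/cm, c = 1540 m/s, and glass-bead
scatterers (17.5 µm effective diameter, Gaussian backscatter law).
Scatterer density defaults to 20 000/cm² (several scatterers per
resolution cell, giving Rayleigh speckle statistics).

Cohort frames are simulated on a node-centred subframe (2 cm depth,
128 lines at the clinical line pitch): metastatic neck nodes are
superficial, the analysis is ROI-restricted, and the subframe is
physically equivalent for every estimator while keeping a 36-patient ×
4-time-point cohort lightweight. The full sector remains the default
`AcquisitionGeometry` and is used in the estimator-recovery runs.

### Planted cohort effects

`EffectSpec` defines per-group tissue trajectories over baseline / 24 h /
week 1 / week 4. Defaults encode treatment-induced microstructural change —
rising acoustic concentration and scatterer size with growing spatial
disorganization and attenuation — stronger and faster in complete
responders, with log-normal between-patient (8%) and scan-to-scan (4%)
variability. These are *illustrative* study conditions chosen once to give
group separation that grows over the first weeks of treatment; they are
not fitted to any clinical dataset, and classifier accuracies obtained on
them characterize the pipeline, not patients. `SurvivalSpec` draws
exponential recurrence times reproducing 3-year recurrence-free survival
of 84% (CR) vs 72% (PR) with uniform 12–57 month censoring; at n = 36
with ~25% event fraction the log-rank test is frequently non-significant,
which the acceptance script reports as-is.

## Spectral estimation

* **Windows.** 2 × 2 mm, 94% overlap in both axes. Millimetres are
  converted to samples via c/2fs (minimum 16 samples) and to lines via the
  line pitch (minimum 2); with the default pitch (0.148 mm) the lateral
  step rounds to one line. Per-line periodograms (Hann taper, NFFT = 4×
  window length) are computed once per axial row and averaged into window
  spectra by cumulative sums over the line axis.
* **Noise handling.** The additive-noise periodogram level is estimated
  from frequencies above twice the centre frequency (where the pulse
  carries no energy) and subtracted from sample and reference spectra
  (clipped at 5% of the noise level); windows whose in-band power is
  within 3 dB of the noise floor are masked out of the maps and of all
  means. Without this step, deep windows bias the attenuation slope toward
  zero.
* **Analysis bands.** The fitting band is the −6 dB band of the reference
  mean spectrum; the spacing estimator uses the −20 dB band to see more
  ripple periods. Both are configurable.
* **ACE.** For each band frequency, the mean NPS over in-ROI windows is
  regressed on window depth; the per-frequency slopes are combined by
  least squares through the origin against `f`, weighted by each bin's
  mean signal power (spectral valleys of structured media are
  noise-limited). The NPS depth trend under the simulator's amplitude
  convention is −2(α_s − α_r)·f·z dB, so ACE = α_ref − slope/2, clamped to
  [0, 3] dB/MHz/cm. ACE is a frame-level value (its map is constant): only
  its mean enters the feature set and a constant map carries no texture.
* **Compensation.** Each window's NPS gains +2(ACE − α_ref)·f·z dB at its
  centre depth (point compensation).
* **ASD/AAC.** `ln BSC − 4 ln f` is regressed on `k²`; slope = −0.827 a²
  (a in metres), ASD = 2a in µm; a non-negative slope is reported as
  ASD = 0 with a warning. AAC (dB) is the intercept with the a⁶ size
  dependence removed; its additive constant (units, bead constants) is
  arbitrary and cancels in delta features, which is all the downstream
  analysis uses.
* **SAS.** The compensated dB spectrum on the SAS band is linearly
  detrended and fitted with a Burg AR model (batch recursion vectorized
  across windows; `statsmodels`' per-series Burg is the test oracle). The
  AR spectrum is evaluated on a dense grid of ripple frequencies
  restricted to the physical spacing range 0.1–1.5 mm and the dominant
  peak gives SAS = c·q/2. The default order is 14 — the smallest order
  that resolves the 0.30 mm lattice ripple at the default geometry
  (order 10 misses the 10% band; the estimate stabilizes from ~14 up).
  An estimate whose AR peak-to-median contrast falls below 5 is flagged
  unreliable.

### What recovery the defaults achieve

With defaults (median over all in-ROI windows; values from the acceptance
run at seed 1): planted attenuation 1.0 dB/MHz/cm is recovered at ~1%
error on a diffuse medium; a 0.30 mm zero-jitter lattice at ~5%; a 30 µm
diameter at ~2% when windows are pooled over four frames. Diameter
estimation is the compensation-sensitive quantity: a 0.05 dB/MHz/cm ACE
error at 2.5 cm depth shifts the apparent `k²` slope by as much as the
whole form-factor signal of a 30 µm scatterer, so the diameter-recovery
condition uses attenuation matched to the phantom (the standard phantom
validation setting) and pools windows across frames so the per-frame
compensation error averages out. On quasi-periodic (lattice) media the
comb spectrum degrades the smooth form-factor fit; ASD/AAC values on such
media are meaningful only as relative (delta) quantities.

## Texture

Maps are min–max quantized inside the ROI into 16 levels per scan (so
delta features remain self-contained per scan). GLCMs are accumulated by
explicit pair counting so the both-pixels-in-ROI rule is exact
(`skimage.feature.graycomatrix` has no mask support and is the
cross-check oracle on full masks); diagonal offsets move `d` pixels in
both axes (chessboard convention). The 16 (distance, angle) feature
values are combined by unweighted mean. Correlation of a zero-variance
marginal is defined as 0. Note that `skimage`'s "energy" is √ASM and its
homogeneity weights pairs by 1/(1+(i−j)²); this package uses the Haralick
definitions ENE = Σp² and HOM = Σp/(1+|i−j|).

## Features and statistics

Each scan yields 31 features: 7 spectral means + 24 texture values (no
texture for the constant ACE map). Delta features subtract the baseline
scan; Δ(baseline) ≡ 0 exactly. Group comparison requires Shapiro–Wilk
non-rejection (α = 0.05) in *both* groups before using a Welch
(unequal-variance) t-test — appropriate for 14-vs-22 group sizes —
otherwise the two-sided Mann–Whitney U-test; group summaries are
mean ± SEM (SD/√n). No multiple-testing correction is applied across the
31 features; the reported p-values are raw, which is a deliberate
limitation of the reporting format. Survival uses the Kaplan–Meier
product-limit estimator and the two-group log-rank test via `lifelines`,
verified against hand product-limit and observed-minus-expected oracles.

## Classification

K-NN (k = 3 by default; the value is a package choice, configurable) and
Gaussian naive Bayes (empirical priors, per-feature class-conditional
Gaussians with a 10⁻⁹-of-feature-variance floor) are implemented directly
because the pipeline pins conventions sklearn's estimators do not expose:
K-NN vote ties resolve to the class of the single nearest neighbour, the
ROC score is the fraction of neighbours voting for the positive class, and
features are z-scored with training-fold statistics only inside each
leave-one-out fold. `sklearn`'s KNeighborsClassifier and GaussianNB serve
as cross-check oracles in the tests. The positive class is CR and is
configurable.

Sequential forward selection runs inside the wrapper: at each step the
feature maximizing LOO accuracy joins the subset (ties broken by feature
order — deterministic), up to ⌊n/10⌋ features by default. Reported
metrics come from the same LOO predictions the wrapper optimized, so the
single-feature accuracy is optimistically biased by selection; the test
suite measures this inflation on null cohorts (best-of-31 selection on
pure noise scores ~7–15 points above the 61% majority rate) and bounds
it, and the calibration tests verify that a fixed feature on null data
scores at the majority rate while a planted 2-SD effect yields ≥80%
median single-feature NB accuracy over 100 seeds. An unbiased estimate
would need an outer CV loop around the selection; that mode is a
straightforward extension but is not the default because the headline
report format reports wrapper-internal LOO.

## What the synthetic data do and do not show

The generator reproduces the spectral physics the estimators invert —
attenuation, form-factor decay, spacing ripple, concentration scaling —
with per-line 1-D propagation. It does not model diffraction, elevational
beam width, phase aberration, multi-plane (3-D) node coverage, TGC, or
biological heterogeneity beyond the planted parameter trajectories.
Passing tests therefore demonstrate that the pipeline correctly measures
what it claims to measure on media satisfying its model assumptions, and
that the statistical/classification layer behaves correctly under known
effects and under the null; they do not validate clinical performance on
patient data.

## Problem sizes used

Unit tests run on small frames (48 lines × 1.5 cm). Estimator-recovery
tests use one full-geometry frame per scenario (≈16 000 in-ROI windows;
four frames pooled for diameter). The end-to-end pipeline test uses a
6-patient cohort; the acceptance script runs the full 36-patient × 4-scan
study on the node-centred subframe and the recovery scenarios at full
geometry, completing in a few minutes on one CPU. Calibration suites use
100 seeds of 36 × 31 feature matrices.
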