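# qusdr — quantitative-ultrasound delta-radiomics

`qusdr` implements an end-to-end quantitative ultrasound (QUS) delta-radiomics
pipeline for monitoring tumour response during radiotherapy, aimed at
researchers in ultrasound tissue characterization and radiomics. Clinical
studies of head-and-neck lymph nodes scan patients before treatment and at
24 h, week 1 and week 4, extract spectral tissue parameters and texture
features from the raw radiofrequency (RF) echo data, and use the *changes
from baseline* (delta features) to predict, within days of starting
treatment, who will be a complete responder (CR) at 3 months. Because such
patient RF data are not publicly deposited, the package includes a
first-class synthetic RF generator with known ground truth, so every
estimator — and the classification layer on top — is testable end to end.

## What it computes

From each RF frame (axial samples × scan lines) and a reference-phantom
frame acquired at identical settings:

1. **Normalized power spectra.** Per 2 × 2 mm sliding window (94% overlap
   both axes), the mean per-line periodogram is divided by the phantom
   spectrum: `NPS(f) = 10 log₁₀(S_sample / S_ref)` dB, cancelling the
   system transfer function.
2. **Attenuation (ACE).** The NPS depth trend is −2(α_s − α_r)·f·z dB
   (f in MHz, z in cm, two-way path); a pooled depth regression over all
   in-ROI windows gives the frame-level attenuation coefficient estimate,
   used to point-compensate every window.
3. **Linear spectral fit.** On the analysis band, `NPS = SI + SS·f`; the
   mid-band fit is `MBF = SI + SS·f_c` (an exact identity, asserted in
   tests).
4. **Scatterer size and concentration (ASD, AAC).** The backscatter
   coefficient `BSC(f) = BSC_ref(f)·10^(NPS/10)` is fitted with the
   spherical Gaussian form factor: `ln BSC − 4 ln f` is linear in `k²`
   with slope `−0.827 a_eff²` (Insana–Hall), giving ASD = 2·a_eff and the
   concentration term AAC in dB.
5. **Scatterer spacing (SAS).** The spectral ripple of quasi-periodic
   scatterer populations has period Δf = c/(2·SAS); a Burg autoregressive
   model of the spectrum-as-sequence locates the ripple frequency.
6. **Texture.** Each of the six non-constant parametric maps (MBF, SS, SI,
   SAS, ASD, AAC) is quantized in-ROI and summarized by 16 grey-level
   co-occurrence matrices (distances 1–4 px × angles 0/45/90/135°),
   yielding Haralick contrast, correlation, energy and homogeneity —
   24 texture features plus the 7 spectral means = **31 features per
   scan**; delta features subtract the baseline scan.
7. **Statistics and classification.** CR-vs-PR group tests (Shapiro–Wilk
   routed Welch-t / Mann–Whitney), Kaplan–Meier + log-rank survival, and
   K-NN / Gaussian naive-Bayes classifiers with sequential forward
   selection in a leave-one-out wrapper, capped at ⌊n/10⌋ features
   (3 at n = 36), reporting sensitivity, specificity, accuracy and ROC AUC.

## Worked example

```python
import numpy as np
from qusdr import (AcquisitionGeometry, ReferencePhantom, ellipse_roi,
                   make_scatterer_field, simulate_reference_frame,
                   simulate_rf_frame, build_parametric_maps, assemble_features)

geom = AcquisitionGeometry()                 # 40 MHz, 256 lines, 5 cm depth
phantom = ReferencePhantom()                 # 0.576 dB/MHz/cm, 1540 m/s
ref = simulate_reference_frame(phantom, geom, seed=100)

field = make_scatterer_field("quasi_periodic", 20000, geometry=geom,
                             mean_spacing=0.30, jitter=0.0, diameter=30.0,
                             seed=1)
frame = simulate_rf_frame(field, geom, attenuation=0.7, seed=1)
roi = ellipse_roi(geom, center_z=1.7, center_x=1.9, semi_z=0.8, semi_x=1.2)

maps = build_parametric_maps(frame, ref, roi)
for name in ("ACE", "SAS"):
    m = maps.maps[name]
    print(name, round(float(np.median(m[maps.roi_mask & np.isfinite(m)])), 3))
```

prints (planted truth: attenuation 0.7 dB/MHz/cm, spacing 0.30 mm):

```
ACE 0.706
SAS 0.314
```

i.e. the attenuation and the lattice spacing are recovered within ~1% and
~5%. Scatterer-diameter recovery is demonstrated on diffuse (fully
developed speckle) media by the acceptance script — size estimation
assumes the diffuse-scattering model and is the most
compensation-sensitive of the seven parameters (see `docs/methods.md`).

The full study runs from the shell:

```bash
qusdr run-all --out run/ --seed 1         # simulate -> extract -> classify
qusdr simulate-cohort --out cohort/ --seed 1
qusdr survival --labels cohort/manifest.csv --out surv.json
```

`run/report.json` holds the group-test tables per time point, the
classifier reports for 1–3 features × {K-NN, naive Bayes} × 3 time points,
and the Kaplan–Meier summary; the report hash is a pure function of
(config, seed).

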