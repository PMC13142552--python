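# filmspec

Processing pipeline for **fluorescence-detected mid-infrared photothermal
(FILM) hyperspectral microscopy** — an imaging modality that reads out
vibrational (mid-IR) absorption of the molecules around a fluorescent
reporter through the thermal quenching of its fluorescence, yielding a
fingerprint-region (1000–1800 cm⁻¹) absorption spectrum for every pixel of
a fluorescence image. Its flagship application is metabolic profiling of
individual organelles (lysosomes, lipid droplets, mitochondria) in living
cells and organisms.

The package is aimed at microscopists and image analysts working with such
data (or building methods for it). It covers the full data path:

1. **Forward simulation** (`filmspec.synthetic`) — renders hyperspectral
   stacks from the multiplicative signal model
   `S(p, ω) = DC(p) · I_IR(ω) · σ_IR(p, ω)` with an IR power dip near
   1450 cm⁻¹, frame-wise photobleaching, linear thermal quenching
   (12 % per 10 K dye class) and spatially correlated noise, with exact
   ground truth for testing.
2. **Spectral calibration** (`filmspec.calibration`) — baseline,
   photobleach and IR-power correction, neighbouring-average smoothing,
   exclusion of the 1380–1480 cm⁻¹ artifact band, and area-under-curve
   normalization, recovering σ_IR.
3. **SPEND denoising** (`filmspec.denoise`) — self-supervised
   Noise2Noise: the stack is permuted into odd/even spectral frames that
   serve as input–target pairs for a compact 3-D convolutional
   encoder-decoder (NumPy, explicit backprop); the trained model denoises
   the original stack. Includes noise-correlation diagnostics and SNR
   metrics.
4. **Segmentation** (`filmspec.segmentation`) — DC-intensity thresholding,
   spectral phasor analysis (first-harmonic DFT, polygon gating in the
   (g, s) plane) and connected-component labelling, producing
   per-organelle spectrum tables.
5. **MCR-LASSO unmixing** (`filmspec.unmixing`) — augmented MCR-ALS
   refinement of an eight-component reference library (protein, amino
   acids, FFA, TAG, ceramide, glycogen, DNA, cholesterol ester) followed
   by non-negative LASSO decomposition
   (min ½‖y − Sᵀc‖² + λ‖c‖₁, c ≥ 0) with cosine/Euclidean fit metrics.
6. **Profiling** (`filmspec.profiling`) — hydrolytic-activity band ratios
   (1587/1649 cm⁻¹ proteolytic, 1711/1741 cm⁻¹ lipolytic), three-group
   classification, z-score spectra, t-SNE cluster distances, abundance
   correlation chords (|r| > 0.5) and Welch t-tests with star annotation.

`docs/methods.md` documents every model, default and numerical choice.

## Worked example

Simulate a field of view, calibrate, segment, unmix and classify:

```python
import numpy as np
import filmspec as fs
from filmspec.synthetic import (AcquisitionSpec, build_reference_library,
                                ir_power_profile, photobleach_curve,
                                random_scene, render_stack)
from filmspec.calibration import CalibrationConfig, calibrate, normalize_auc
from filmspec.segmentation import extract_table, label_organelles, threshold_dc
from filmspec.unmixing import McrConfig, mcr_lasso
from filmspec.profiling import (LIPOLYTIC_RATIO, PROTEOLYTIC_RATIO,
                                band_ratio, classify_groups)

# 1. simulate a small acquisition with known ground truth
axis = fs.make_axis(1000, 1800, 126)
refs = build_reference_library("default8", axis)
scene = random_scene(shape=(48, 48), n_organelles=8, seed=3)
acq = AcquisitionSpec(axis=axis, ir_power=ir_power_profile(axis, dip_depth=0.3),
                      bleach_rate=0.005, noise_sigma=0.02,
                      noise_corr_len_px=3, noise_axis="row", seed=3)
stack, truth = render_stack(scene, refs, acq)

# 2. calibrate per pixel (bleach and power divided out, 1380-1480 masked)
config = CalibrationConfig(ir_power=acq.effective_power(),
                           bleach_curve=photobleach_curve(126, acq.bleach_rate),
                           normalize="none")
calibrated = calibrate(stack, config)

# 3. segment on the DC channel and pool per-organelle spectra
labels = label_organelles(threshold_dc(stack.dc), min_size_px=4)
table = extract_table(calibrated, labels)
table = fs.SpectrumTable.from_spectra(
    table.ids, [normalize_auc(table.row(i)) for i in range(len(table))],
    table.size_px, table.dc_mean)
print(f"segmented {labels.n_regions} organelles")

# 4. unmix against the eight-component library (augmented MCR + LASSO)
conc = mcr_lasso(table, refs, McrConfig(max_iter=30), lam="auto")
print(f"mean reconstruction cosine similarity: {conc.cosine_sim.mean():.3f}")
matched = [truth.masks[labels.labels == i + 1].max() for i in range(len(table))]
err = np.abs(conc.fractions - truth.composition_table[np.array(matched) - 1]).mean()
print(f"mean |abundance fraction - ground truth|: {err:.3f}")

# 5. hydrolytic-activity ratios and classification
groups = classify_groups(band_ratio(table, PROTEOLYTIC_RATIO),
                         band_ratio(table, LIPOLYTIC_RATIO))
for oid, g, p, l in zip(table.ids, groups.group,
                        groups.proteolytic_ratio, groups.lipolytic_ratio):
    print(f"{oid}: 1587/1649 = {p:5.2f}  1711/1741 = {l:5.2f}  -> {g}")
```

Output:

```
segmented 8 organelles
mean reconstruction cosine similarity: 0.999
mean |abundance fraction - ground truth|: 0.041
organelle_001: 1587/1649 =  0.03  1711/1741 =  0.99  -> high_lipolytic
organelle_002: 1587/1649 =  0.04  1711/1741 =  0.05  -> low_both
organelle_003: 1587/1649 = 13.55  1711/1741 =  5.23  -> high_both
organelle_004: 1587/1649 = 17.37  1711/1741 =  0.04  -> high_proteolytic
organelle_005: 1587/1649 =  0.68  1711/1741 = -1.45  -> high_proteolytic
organelle_006: 1587/1649 = 11.05  1711/1741 = 29.84  -> high_both
organelle_007: 1587/1649 =  0.04  1711/1741 =  0.49  -> low_both
organelle_008: 1587/1649 =  0.02  1711/1741 = 21.63  -> high_lipolytic
```

All eight organelles are found, the unmixed abundance fractions track the
ground-truth compositions to 0.04 on average, and the two ratios sort the
organelles into the hydrolytic-activity groups. Organelle 5 shows what a
noise-dominated ratio looks like: its ester (1741 cm⁻¹) band is essentially
zero, so its lipolytic ratio is meaningless (here negative) — with real
data such organelles should be filtered on the denominator intensity.

The same pipeline runs from the shell:

```bash
filmspec run --config pipeline.yaml   # simulate→calibrate→denoise→segment→unmix→profile
filmspec simulate --out stack.h5 --shape 48 48 --frames 126 --seed 3
filmspec spend train --in stack.h5 --model model.npz
filmspec spend apply --model model.npz --in stack.h5 --out denoised.h5
filmspec segment --in denoised.h5 --table spectra.csv
filmspec unmix --table spectra.csv --out concentrations.csv
filmspec profile --table spectra.csv --out profile.json
```

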