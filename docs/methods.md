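# Methods

## Signal model

Fluorescence-detected mid-infrared photothermal (FILM) microscopy reads out
vibrational absorption through the thermal quenching of a fluorescent
reporter. A pulsed mid-IR pump heats the focal volume in proportion to the
local absorption cross section σ_IR(ω); the temperature rise ΔT lowers the
reporter's quantum yield, and the demodulated intensity change is

    S(p, ω) = DC(p) · I_IR(ω) · σ_IR(p, ω) · q,      q = c_q · k_T

where DC is the unmodulated fluorescence image, I_IR the per-wavenumber IR
power, c_q the dye's thermal sensitivity (fractional fluorescence loss per
kelvin) and k_T the temperature rise per unit absorbed power. The quench
model is linear in ΔT; the generator default c_q = 0.012 K⁻¹ corresponds to
the LysoSensor DND-189 class of thermosensitive dyes (12 % loss per 10 K).
Linearity is the minimal model consistent with a single two-point
sensitivity measurement; `quench_response` raises once c_q·ΔT would reach
1. k_T (`temp_rise_scale`) defaults to 1 in arbitrary units — absolute
thermometry is out of scope, and every downstream quantity is invariant to
it because spectra are area-normalized.

## Synthetic data generator (`filmspec.synthetic`)

The generator renders disk-shaped organelles (default linear edge feather
of 1 px; organelle shape is otherwise unconstrained by the application) on
a weak uniform background, each with a non-negative composition over a
reference library, and emits

    emitted(p, t) = q · DC(p) · I_IR(t) · bleach(t) · σ(p, t) + baseline + noise.

Instrument features emulated:

* **IR power profile** — smooth with a Gaussian dip near 1450 cm⁻¹
  (quantum-cascade laser chip switch); depth and width configurable.
* **Photobleaching** — geometric per frame, `(1 − r)^t`; the curve form is
  a modelling choice, mono-exponential being the standard first-order
  photochemistry model.
* **Baseline** — a constant detection offset, measurable through designated
  IR-off frames (power forced to zero there).
* **Noise** — additive Gaussian, optionally correlated along one array axis
  by a length-L uniform moving average (wrap boundary, rescaled to the
  requested standard deviation). This is the simplest stationary process
  with a controllable correlation length; `noise_sigma` is relative to the
  peak noiseless modulated signal. Detector shot-noise statistics, optical
  PSF and thermal diffusion are *not* modelled, so passing benchmarks shows
  correctness of the processing chain, not instrument-level realism.

All stochastic outputs are reproducible from `(seed, spec)`.

The **default eight-component library** (protein, amino acids, FFA, TAG,
ceramide, glycogen, DNA, cholesterol ester) is a synthetic stand-in built
from the application's anchor bands — 1587 (amino acid), 1649 (Amide I),
1711 (free fatty acid C=O), 1741 (ester C=O), 1095/1240 (phosphate), 1294
— plus literature-typical secondary bands, each component max-normalized.
Band positions and widths (FWHM 24–50 cm⁻¹) are typical of condensed-phase
fingerprint spectra but are not measured standards; quantitative component
assignments on real data require a measured library (`ReferenceLibrary.from_csv`).

`perturbed_library` jitters band centres (σ = 3 cm⁻¹) and rescales
widths/amplitudes by ±10 %. Unmixing benchmarks generate data from the
perturbed library while handing the unperturbed one to the unmixer: this
emulates the in-situ deviation of organelle constituents from pure
standards that motivates reference refinement, and makes the
MCR-vs-plain-LASSO comparison a meaningful contrast rather than a tie.

## Calibration (`filmspec.calibration`)

The correction chain runs in fixed order — baseline → photobleach → power →
smoothing → band exclusion → AUC normalization — matching the order in
which the corrections compose physically (the chain is order-sensitive and
regression-tested as such). Choices:

* Baseline is a constant estimated from IR-off frames, or, when none were
  recorded, from the w = 3 lowest-IR-power frames ("power-dip proxy"). In
  IR-off mode those frames are masked afterwards (they carry no absorption
  signal and would otherwise be divided by zero power).
* Smoothing is a centred neighbouring average, window 3 by default
  (5 optional, 1 disables); masked bins are excluded from every window and
  edges use shrunken windows. Smoothing contracts total variation.
* The 1380–1480 cm⁻¹ band (around the power dip) is excluded by default:
  bins are *masked*, not dropped — values are retained but omitted from all
  norms, areas, fits and phasor sums downstream.
* AUC normalization divides by the trapezoidal area over unmasked bins;
  sub-intervals touching a masked bin are omitted (gaps are not bridged).
  Normalization is idempotent to 1e-12 and fails on non-positive area.

On any noiseless simulated scene the chain inverts the forward model
exactly (the acceptance suite checks 1e-6; in practice it is at machine
precision), because every corruption the simulator applies is either
divided out or removed by the area normalization.

Whole-stack calibration applies the same chain per pixel but (in the
pipeline) defers area normalization until after per-organelle spectra are
pooled, since per-pixel areas in dye-free background regions are near zero
and would amplify noise.

## SPEND denoising (`filmspec.denoise`)

Self-permutation Noise2Noise: the stack is split along the spectral axis
into even-index (input) and odd-index (target) frames, both kept in
ascending order; a network trained to map one half onto the other
converges toward the clean conditional mean because the halves carry
independent noise. The orientation (even → input) is a convention; both
orientations are used during training. The one-frame wavenumber offset
between halves is deliberately ignored (adjacent frames treated as repeat
measurements of the same field of view) — see Limitations.

Pairing stays valid under spatially correlated noise because the split is
perpendicular to the spatial correlation axis. `diagnose_noise_correlation`
verifies this assumption: for each axis it removes smooth content by
subtracting a 3×3 box mean over the *other two* axes only (so the high-pass
introduces no correlation along the tested axis; white noise reports ~0)
and reports lag-1 autocorrelations plus the dominant axis.

**Backbone.** A compact 3-D convolutional encoder-decoder written in NumPy
with explicit backpropagation: two resolution levels (3×3×3 convolutions +
ReLU, average-pool down, nearest-neighbour up, skip concatenation), 8 base
channels, a global residual connection, Adam on an MSE objective,
gradient-checked against finite differences. Default training: 70 epochs ×
12 steps × batch 2 on random 32×32×16 patches of the standardized halves,
learning rate 2e-3 halved at 60 % and quartered at 85 % of training.
These sizes train a 64×64×64 stack in ~8 minutes on one CPU core; they are
the package's desk-scale defaults, and all of depth, channels, epochs and
patch size scale up through `DenoiserConfig` for larger acquisitions.
Training is bit-deterministic for a fixed seed.

**Inference** feeds the original (non-permuted) stack through the network
with tiled, linearly blended patches, and by default averages the
predictions over the four spatial flip orientations (row/col): flips leave
both the scene statistics and the row/col-correlated noise model
invariant, so averaging reduces the stochastic residual at 4× inference
cost. Negative outputs are clipped with a count recorded in provenance.

**SNR metrics** (definitions are package choices, recorded in each
report): image SNR = mean over signal pixels at the peak frame / standard
deviation over background pixels at that frame; spectral SNR =
(peak − off-resonance mean) / standard deviation of the linearly detrended
off-resonance region (lowest-intensity quartile of frames).

## Phasor segmentation (`filmspec.segmentation`)

Per pixel, g + i·s is the first-harmonic DFT coefficient of the spectrum
normalized by total intensity, with the +sin (counter-clockwise)
convention. Properties used by the tests: non-negative spectra map into the
unit disk, convex mixtures map onto chords, and the map is invariant to
global intensity rescaling. Excluded bins are omitted from the DFT with the
remaining frames renumbered 0..n−1 (zero-filling available via
`renumber=False`); zero-total pixels are flagged invalid rather than
raising. Gates are polygons in the (g, s) plane, boundary-inclusive.
Default segmentation is an Otsu threshold on the DC channel, optionally
intersected with a phasor gate; connected components (8-connectivity
default) are labelled in raster-scan order of their first pixel, with a
minimum-size filter.

## MCR-LASSO unmixing (`filmspec.unmixing`)

Augmented MCR-ALS refines the K = 8 reference spectra on the measured
spectra matrix D (M × N, unmasked bins only): D′ = [D; w · S₀] is
factorized as C·S under non-negativity on both factors, initialized at
S = S₀, with w (`augmentation_weight`, default 1) replications of the
reference rows anchoring the refined components. Both alternating steps are
exact non-negative least-squares solves (scipy NNLS per row/column), so the
Frobenius residual is non-increasing by construction — asserted on every
run. Convergence: relative residual change < 1e-6 or 50 iterations;
non-convergence or a final relative residual above 0.05 flags the result
(the latter indicates model misspecification, e.g. a constituent absent
from the library). An optional ridge anchor toward S₀ is exposed (off by
default) for small noisy datasets where ALS could over-adjust the
references. Refined rows are re-normalized to unit area.

Per-spectrum decomposition minimizes ½‖y − Sᵀc‖² + λ‖c‖₁ with c ≥ 0 by
cyclic coordinate descent with soft thresholding (coordinate tolerance
1e-8). Non-negativity is imposed because abundances are physical.
λ = "auto" minimizes generalized cross-validation, GCV(λ) =
RSS / (n(1 − df/n)²) with df = number of active coordinates, over 20
log-spaced points on [10⁻⁴, 1] × λ_max, where λ_max = max(S·y) is the full
shrinkage threshold (a relative grid keeps the selection scale-invariant).
Abundances are reported raw and as fractions of their sum; with
area-normalized references the fractions are relative contributions to
spectral area. Fit quality per spectrum: cosine similarity and Euclidean
distance between data and reconstruction on unmasked bins.

One global MCR refinement is run per dataset (not per condition); a dye
spectrum can be added as an extra library component via the CSV interface
but is not included by default.

## Profiling (`filmspec.profiling`)

* Hydrolysis proxies: 1587/1649 cm⁻¹ (amino acid / Amide I) for
  proteolytic and 1711/1741 cm⁻¹ (free fatty acid / lipid ester) for
  lipolytic activity. Nearest-bin lookup without interpolation, ties toward
  the lower wavenumber; denominators below 1e-12 flag the pixel invalid.
* Classification thresholds default to per-dataset medians (no absolute
  cut is defined by the application); a value exactly at its threshold
  falls on the low side. Four cells are kept internally
  (high-proteolytic / high-lipolytic / high-both / low-both); reports may
  collapse the fourth.
* Z-scores are per wavenumber relative to the pooled mean:
  z_g(ω) = (mean_g − mean_all)/sd_all with sample (ddof = 1) standard
  deviation; zero-variance bins give z = 0 with a warning. The
  group-size-weighted mean of z over groups is identically 0.
* Embeddings use seeded t-SNE with exact gradients (robust to duplicate
  spectra; cheap at per-dataset organelle counts) and PCA initialization;
  perplexity defaults to min(30, (n−1)/3). Intra/inter-group mean pairwise
  Euclidean distances are reported in both spectral and embedding space —
  spectral-space distances are the quantitative ones, the embedding is for
  display.
* Abundance correlations: Pearson r per unordered component pair, retained
  at |r| > 0.5 with sign; zero-variance components are skipped with a flag.
* Group comparisons: Welch (unequal-variance) two-sided t-tests with the
  conventional star bins (* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001,
  ns otherwise). Raw p-values are reported; a Benjamini–Hochberg option is
  deliberately not applied by default.

## Pipeline

`filmspec run --config pipeline.yaml` executes
simulate → calibrate → denoise → segment → unmix → profile with per-stage
toggles, a single global seed propagated to every stochastic stage, and a
JSON run report (package version, seeds, parameters, stage timings, config
hash). A failed stage aborts with its name; the partial report is kept with
a `.partial` suffix. Exit codes: 0 ok, 2 config error, 3 stage failure.

## Benchmark problem sizes

* Denoising: 64×64 px × 64 frames (1000–1800 cm⁻¹), 12 organelles,
  additive noise at 0.5× the peak signal, correlation length 5 px along
  rows, seed 42 — a deliberately low-SNR, desk-scale stand-in for
  short-dwell in vivo acquisition.
* Unmixing: 40 spectra × 126 frames, sparse 2–4-component mixtures of the
  perturbed library, spectral SNR 20, the 1380–1480 cm⁻¹ band masked.
* Classification: four designed subpopulations of 50 organelles with ±0.30
  composition shifts between high and low activity and 2 % multiplicative
  spectral noise.

## Known limitations

* At coarse spectral sampling (the 64-frame benchmark steps 12.7 cm⁻¹ with
  band FWHMs down to ~24 cm⁻¹), the odd/even pairing makes adjacent frames
  imperfect mutual targets: the trained network attenuates sharp spectral
  peaks (it approximates an interpolator between neighbouring frames).
  This is inherent to ignoring the one-frame wavenumber offset and shrinks
  as the frame count grows; at the 126-frame acquisition grid the effect
  is roughly four times smaller in the exponent.
* The NumPy backbone is single-threaded and deliberately small; it is not
  a replacement for GPU-scale training on multi-field-of-view data.
* MCR-LASSO is reference-guided: abundances are interpretable only
  relative to the supplied library, and a constituent missing from the
  library surfaces as a flagged residual, not as a new component.
* The simulator's noise is additive Gaussian; real photothermal data mixes
  shot noise, dye photophysics and scan artifacts. Benchmarks therefore
  validate the algorithms, not detector physics.
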