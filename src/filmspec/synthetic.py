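"""Forward simulator for FILM hyperspectral acquisitions.

Fluorescence-detected mid-infrared photothermal (FILM) imaging reads out IR
absorption through the thermal quenching of a fluorescent reporter: each IR
pulse heats the focal volume in proportion to the local absorption cross
section sigma_IR(omega), and the temperature rise lowers the reporter's
quantum yield. The demodulated signal is therefore multiplicative,

    signal(p, t) = DC(p) * I_IR(t) * sigma_IR(p, t),

scaled by the (linear) thermal sensitivity of the dye. This module renders
that model over a synthetic scene of disk-shaped organelles with known
composition, adding the instrument features that the calibration and
denoising stages must undo:

* a smooth IR power profile with a dip near 1450 cm^-1 (laser-chip switch),
* frame-wise mono-exponential photobleaching,
* a constant detection baseline, optionally measurable via IR-off frames,
* additive Gaussian noise correlated along one chosen array axis.

Every stochastic output is reproducible from (seed, spec) alone; the
returned :class:`GroundTruth` carries the clean stack, per-pixel absorption
spectra, the organelle label raster and the composition table so that
downstream stages can be tested against an exact oracle.

The eight-component default reference library is a synthetic stand-in: peak
positions follow the anchor bands of the biological application (1587 amino
acid, 1649 Amide I, 1711 free fatty acid, 1741 triglyceride ester,
1095/1240 phosphate, ...) plus literature-typical secondary bands, not a
measured standard library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .datatypes import HyperStack, ReferenceLibrary, WavenumberAxis, make_axis
from .errors import SaturationError

__all__ = [
    "ComponentPeakSpec",
    "OrganelleSpec",
    "SceneSpec",
    "AcquisitionSpec",
    "GroundTruth",
    "DEFAULT_QUENCH_COEFF",
    "build_reference_library",
    "ir_power_profile",
    "quench_response",
    "photobleach_curve",
    "correlated_noise",
    "render_stack",
    "pulse_duration",
    "detection_frequency",
    "random_scene",
    "spend_benchmark",
    "perturbed_library",
    "unmixing_benchmark",
]

#: LysoSensor DND-189 class thermal sensitivity: 12 % fluorescence loss per 10 K.
DEFAULT_QUENCH_COEFF = 0.012  # K^-1

_NOISE_AXES = {"row": 0, "col": 1, "frame": 2}


# --------------------------------------------------------------------------
# acquisition timing helpers

def pulse_duration(duty_cycle: float, frequency_hz: float) -> float:
    """Excitation pulse length (s) from duty cycle and modulation frequency.

    A 30 % duty cycle at the 400 kHz visible modulation gives 750 ns.
    """
    if not 0 < duty_cycle <= 1:
        raise ValueError("duty cycle must lie in (0, 1]")
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return duty_cycle / frequency_hz


def detection_frequency(ir_rep_rate_hz: float, harmonic: int = 2) -> float:
    """Visible modulation placed at a harmonic of the IR repetition rate
    (2f scheme: 200 kHz IR -> 400 kHz visible)."""
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    return float(harmonic) * ir_rep_rate_hz


# --------------------------------------------------------------------------
# component spectra

@dataclass(frozen=True)
class ComponentPeakSpec:
    """Named component rendered as a sum of Gaussian/Lorentzian bands.

    Peaks are (center_cm-1, fwhm_cm-1, relative amplitude).
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"component {self.name!r} has no peaks")
        for center, fwhm, amplitude in self.peaks:
            if fwhm <= 0:
                raise ValueError("peak fwhm must be positive")
            if amplitude < 0:
                raise ValueError("peak amplitudes must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def render(self, axis: WavenumberAxis) -> np.ndarray:
        """Sum of band profiles on `axis`, max-normalized to 1."""
        omega = axis.values
        profile = np.zeros_like(omega)
        for center, fwhm, amplitude in self.peaks:
            if not (axis.start <= center <= axis.stop):
                warnings.warn(
                    f"peak at {center} cm^-1 of {self.name!r} lies outside the "
                    f"axis span [{axis.start}, {axis.stop}]; tail truncated",
                    stacklevel=2,
                )
            if self.shape == "gaussian":
                profile = profile + amplitude * np.exp(
                    -4.0 * np.log(2.0) * ((omega - center) / fwhm) ** 2
                )
            else:
                profile = profile + amplitude / (1.0 + (2.0 * (omega - center) / fwhm) ** 2)
        peak = profile.max()
        if peak <= 0:
            raise ValueError(f"component {self.name!r} renders to zero on this axis")
        return profile / peak


# Synthetic stand-in band tables for the eight standards (see module docstring).
DEFAULT8_SPECS: tuple[ComponentPeakSpec, ...] = (
    ComponentPeakSpec("protein", ((1649, 36, 1.0), (1545, 42, 0.65), (1240, 50, 0.18))),
    ComponentPeakSpec("amino_acids", ((1587, 30, 1.0), (1515, 28, 0.25), (1410, 36, 0.45))),
    ComponentPeakSpec("ffa", ((1711, 26, 1.0), (1412, 30, 0.30), (1285, 32, 0.25))),
    ComponentPeakSpec("tag", ((1741, 24, 1.0), (1240, 30, 0.20), (1160, 38, 0.50))),
    ComponentPeakSpec("ceramide", ((1635, 32, 0.90), (1545, 34, 0.45), (1066, 40, 0.50))),
    ComponentPeakSpec("glycogen", ((1150, 40, 0.55), (1080, 46, 0.90), (1030, 46, 1.0))),
    ComponentPeakSpec("dna", ((1715, 30, 0.20), (1294, 30, 0.35), (1240, 44, 0.80), (1095, 44, 1.0))),
    ComponentPeakSpec("cholesterol_ester", ((1730, 26, 1.0), (1178, 36, 0.55), (1010, 30, 0.35))),
)


def build_reference_library(
    specs: Sequence[ComponentPeakSpec] | Literal["default8"],
    axis: WavenumberAxis,
) -> ReferenceLibrary:
    """Render component peak specs into a :class:`ReferenceLibrary`.

    ``"default8"`` yields the eight-component stand-in library (protein,
    amino acids, FFA, TAG, ceramide, glycogen, DNA, cholesterol ester), each
    spectrum max-normalized to 1.
    """
    if isinstance(specs, str):
        if specs != "default8":
            raise ValueError(f"unknown library preset {specs!r}")
        specs = DEFAULT8_SPECS
    specs = list(specs)
    if not specs:
        raise ValueError("empty component spec list")
    return ReferenceLibrary(
        names=[s.name for s in specs],
        spectra=np.vstack([s.render(axis) for s in specs]),
        axis=axis,
    )


# --------------------------------------------------------------------------
# instrument response pieces

def ir_power_profile(
    axis: WavenumberAxis,
    dip_center: float = 1450.0,
    dip_depth: float = 0.3,
    dip_fwhm: float = 80.0,
) -> np.ndarray:
    """Smooth per-frame IR power with a Gaussian dip at `dip_center`.

    The dip emulates the power drop where the quantum-cascade laser switches
    chips; ``dip_depth`` is the fractional loss at the dip minimum.
    """
    if not 0 <= dip_depth < 1:
        raise ValueError("dip_depth must lie in [0, 1) so power stays positive")
    omega = axis.values
    return 1.0 - dip_depth * np.exp(-4.0 * np.log(2.0) * ((omega - dip_center) / dip_fwhm) ** 2)


def quench_response(delta_t: float, quench_coeff: float = DEFAULT_QUENCH_COEFF) -> float:
    """Fractional fluorescence decrease for a temperature rise `delta_t` (K).

    Linear model: decrease = quench_coeff * delta_t. With the default
    LysoSensor DND-189 class sensitivity (0.012 K^-1) a 10 K rise quenches
    12 % of the fluorescence.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be non-negative")
    if quench_coeff < 0:
        raise ValueError("quench_coeff must be non-negative")
    decrease = quench_coeff * delta_t
    if decrease >= 1.0:
        raise SaturationError(
            f"quench of {decrease:.3f} would exceed total fluorescence"
        )
    return decrease


def photobleach_curve(
    n_frames: int, bleach_rate: float, model: Literal["exponential"] = "exponential"
) -> np.ndarray:
    """Per-frame fluorescence multiplier (1 - rate)**t; frame 0 is unbleached."""
    if model != "exponential":
        raise ValueError(f"unknown bleach model {model!r}")
    if not 0 <= bleach_rate < 1:
        raise ValueError("bleach_rate must lie in [0, 1)")
    return (1.0 - bleach_rate) ** np.arange(n_frames, dtype=float)


def correlated_noise(
    shape: tuple[int, ...],
    sigma: float,
    corr_len_px: int = 0,
    axis: Literal["row", "col", "frame"] = "row",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean Gaussian field with a moving-average correlation along one axis.

    White Gaussian noise is smoothed by a length-``corr_len_px`` uniform
    moving average along the chosen axis (wrap boundary, so the field is
    stationary) and rescaled to sample standard deviation ``sigma``. The
    other axes stay independent. ``corr_len_px`` of 0 or 1 leaves the noise
    white.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if corr_len_px < 0:
        raise ValueError("corr_len_px must be non-negative")
    if sigma == 0:
        return np.zeros(shape)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    if corr_len_px >= 2:
        ax = _NOISE_AXES[axis] if isinstance(axis, str) else int(axis)
        if ax >= len(shape):
            raise ValueError(f"axis {axis!r} out of range for shape {shape}")
        noise = uniform_filter1d(noise, size=int(corr_len_px), axis=ax, mode="wrap")
    noise = noise - noise.mean()
    return noise * (sigma / noise.std())


# --------------------------------------------------------------------------
# scenes

@dataclass(frozen=True)
class OrganelleSpec:
    """One disk-shaped organelle: spatial footprint, composition, dye load."""

    center_px: tuple[float, float]
    radius_px: float
    composition: np.ndarray
    dye_level: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "composition", np.asarray(self.composition, dtype=float))
        if self.radius_px < 1:
            raise ValueError("organelle radius must be >= 1 px")
        if np.any(self.composition < 0):
            raise ValueError("composition weights must be non-negative")
        if abs(self.composition.sum() - 1.0) > 1e-9:
            raise ValueError("composition weights must sum to 1 within 1e-9")
        if self.dye_level < 0:
            raise ValueError("dye_level must be non-negative")


@dataclass(frozen=True)
class SceneSpec:
    """Spatial layout of a synthetic field of view."""

    shape: tuple[int, int]
    organelles: tuple[OrganelleSpec, ...]
    background_dye: float = 0.0
    background_composition: np.ndarray | None = None
    feather_px: float = 1.0  # linear edge ramp width in px; 0 = hard disks

    def __post_init__(self) -> None:
        if self.background_composition is not None:
            comp = np.asarray(self.background_composition, dtype=float)
            object.__setattr__(self, "background_composition", comp)
            if np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
                raise ValueError("background composition must be non-negative and sum to 1")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Instrument settings for one simulated acquisition.

    ``noise_sigma`` is relative: the additive noise standard deviation is
    ``noise_sigma`` times the peak noiseless modulated signal in the stack.
    ``temp_rise_scale`` converts absorption x power into kelvin (arbitrary
    units by default; absolute thermometry is out of scope).
    """

    axis: WavenumberAxis
    ir_power: np.ndarray | None = None  # None -> flat unit power
    bleach_rate: float = 0.0
    quench_coeff: float = DEFAULT_QUENCH_COEFF
    temp_rise_scale: float = 1.0
    baseline_offset: float = 0.0
    ir_off_frames: tuple[int, ...] = ()
    noise_sigma: float = 0.0
    noise_corr_len_px: int = 0
    noise_axis: Literal["row", "col", "frame"] = "row"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ir_power is not None:
            power = np.asarray(self.ir_power, dtype=float)
            object.__setattr__(self, "ir_power", power)
            if power.shape != (self.axis.n_frames,):
                raise ValueError("ir_power length must match the axis")
        if not 0 <= self.bleach_rate < 1:
            raise ValueError("bleach_rate must lie in [0, 1)")
        if self.quench_coeff < 0:
            raise ValueError("quench_coeff must be non-negative")
        object.__setattr__(self, "ir_off_frames", tuple(int(i) for i in self.ir_off_frames))
        for i in self.ir_off_frames:
            if not 0 <= i < self.axis.n_frames:
                raise ValueError(f"IR-off frame index {i} outside axis")

    def effective_power(self) -> np.ndarray:
        """Per-frame power with IR-off frames forced to zero."""
        power = (
            np.ones(self.axis.n_frames)
            if self.ir_power is None
            else np.asarray(self.ir_power, dtype=float).copy()
        )
        off = np.zeros(self.axis.n_frames, dtype=bool)
        if self.ir_off_frames:
            off[list(self.ir_off_frames)] = True
        power[off] = 0.0
        if np.any(power[~off] <= 0):
            raise ValueError("ir_power must be positive on IR-on frames")
        return power


@dataclass
class GroundTruth:
    """Simulator-side oracle emitted alongside a noisy stack."""

    clean_stack: HyperStack  # dc * sigma: noise-, bleach-, power- and baseline-free
    noiseless_stack: HyperStack  # full forward model minus the noise term
    sigma_map: np.ndarray  # (rows, cols, n_frames) true absorption spectra
    masks: np.ndarray  # labeled raster, 0 = background, 1..n organelles
    composition_table: np.ndarray  # (n_organelles, K) weights
    component_names: list[str]
    dc: np.ndarray


def _membership_maps(scene: SceneSpec) -> np.ndarray:
    rows, cols = scene.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    alphas = np.zeros((len(scene.organelles), rows, cols))
    feather = max(scene.feather_px, 0.0)
    for i, org in enumerate(scene.organelles):
        dist = np.hypot(rr - org.center_px[0], cc - org.center_px[1])
        if feather > 0:
            alphas[i] = np.clip((org.radius_px + 0.5 - dist) / feather, 0.0, 1.0)
        else:
            alphas[i] = (dist <= org.radius_px).astype(float)
    return alphas


def render_stack(
    scene: SceneSpec, refs: ReferenceLibrary, acq: AcquisitionSpec
) -> tuple[HyperStack, GroundTruth]:
    """Run the forward model over a scene.

    Per pixel p and frame t (q = quench_coeff * temp_rise_scale):

        sigma(p, t)    = sum_k composition_k(p) * ref_k(t)
        clean(p, t)    = dc(p) * sigma(p, t)
        emitted(p, t)  = q * dc(p) * ir_power(t) * bleach(t) * sigma(p, t)
                         + baseline + noise(p, t)

    The DC fluorescence image is emitted alongside, and the ground truth
    carries the clean stack, the exact noiseless stack, per-pixel sigma,
    the organelle label raster and the composition table.
    """
    if refs.axis != acq.axis:
        raise ValueError("reference library and acquisition axes differ")
    n_k = refs.n_components
    for org in scene.organelles:
        if org.composition.shape != (n_k,):
            raise ValueError(
                f"organelle composition has {org.composition.shape[0]} weights, "
                f"library has {n_k} components"
            )
    bg_comp = (
        np.zeros(n_k)
        if scene.background_composition is None
        else scene.background_composition
    )
    if bg_comp.shape != (n_k,):
        raise ValueError("background composition length must match the library")

    alphas = _membership_maps(scene)  # (n_org, rows, cols)
    total_alpha = alphas.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        overlap_scale = np.where(total_alpha > 1.0, 1.0 / np.maximum(total_alpha, 1e-300), 1.0)
    alphas = alphas * overlap_scale
    bg_weight = np.clip(1.0 - alphas.sum(axis=0), 0.0, 1.0)

    # per-pixel composition: (rows, cols, K)
    comp_map = np.tensordot(alphas, np.stack([o.composition for o in scene.organelles]), axes=(0, 0)) if scene.organelles else np.zeros(scene.shape + (n_k,))
    comp_map = comp_map + bg_weight[..., None] * bg_comp[None, None, :]

    dye = bg_weight * scene.background_dye
    for i, org in enumerate(scene.organelles):
        dye = dye + alphas[i] * org.dye_level

    sigma_map = comp_map @ refs.spectra  # (rows, cols, n_frames)
    clean = dye[..., None] * sigma_map

    power = acq.effective_power()
    bleach = photobleach_curve(acq.axis.n_frames, acq.bleach_rate)
    qamp = acq.quench_coeff * acq.temp_rise_scale
    noiseless = qamp * clean * (power * bleach)[None, None, :] + acq.baseline_offset

    modulated_peak = float((qamp * clean * (power * bleach)[None, None, :]).max())
    noise_scale = acq.noise_sigma * modulated_peak if modulated_peak > 0 else acq.noise_sigma
    noise = correlated_noise(
        noiseless.shape,
        noise_scale,
        acq.noise_corr_len_px,
        acq.noise_axis,
        np.random.default_rng(acq.seed),
    )
    emitted = noiseless + noise

    labels = np.zeros(scene.shape, dtype=np.int32)
    for i in range(len(scene.organelles) - 1, -1, -1):
        labels[alphas[i] > 0.5] = i + 1

    meta = {"simulator": "filmspec.synthetic", "seed": acq.seed}
    stack = HyperStack(emitted, acq.axis, dc=dye.copy(), meta=meta)
    truth = GroundTruth(
        clean_stack=HyperStack(clean, acq.axis, dc=dye.copy(), meta=dict(meta)),
        noiseless_stack=HyperStack(noiseless, acq.axis, dc=dye.copy(), meta=dict(meta)),
        sigma_map=sigma_map,
        masks=labels,
        composition_table=np.stack([o.composition for o in scene.organelles])
        if scene.organelles
        else np.zeros((0, n_k)),
        component_names=list(refs.names),
        dc=dye,
    )
    return stack, truth


# --------------------------------------------------------------------------
# canonical benchmark scenes

def random_scene(
    shape: tuple[int, int] = (64, 64),
    n_organelles: int = 12,
    n_components: int = 8,
    seed: int = 0,
    radius_range: tuple[float, float] = (2.5, 4.5),
    dye_range: tuple[float, float] = (0.7, 1.3),
    background_dye: float = 0.08,
    sparsity: int = 3,
) -> SceneSpec:
    """Non-overlapping random disks with sparse Dirichlet compositions.

    Each organelle mixes at most ``sparsity`` library components (lysosome
    spectra are dominated by a few constituents); dye loading varies ~+-30 %
    around unity, and a weak uniform background emulates out-of-organelle
    autofluorescence.
    """
    rng = np.random.default_rng(seed)
    organelles: list[OrganelleSpec] = []
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(organelles) < n_organelles and attempts < 10000:
        attempts += 1
        radius = rng.uniform(*radius_range)
        margin = radius + 2.0
        center = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        if any(
            np.hypot(center[0] - r0, center[1] - c0) < radius + r + 3.0
            for r0, c0, r in placed
        ):
            continue
        active = rng.choice(n_components, size=rng.integers(2, sparsity + 1), replace=False)
        comp = np.zeros(n_components)
        comp[active] = rng.dirichlet(np.ones(active.size))
        organelles.append(
            OrganelleSpec(
                center_px=center,
                radius_px=radius,
                composition=comp,
                dye_level=rng.uniform(*dye_range),
            )
        )
        placed.append((center[0], center[1], radius))
    if len(organelles) < n_organelles:
        raise RuntimeError("could not place the requested organelles without overlap")
    bg_comp = np.zeros(n_components)
    bg_comp[0] = 1.0  # weak protein-like background
    return SceneSpec(
        shape=shape,
        organelles=tuple(organelles),
        background_dye=background_dye,
        background_composition=bg_comp,
    )


def spend_benchmark(
    seed: int = 42,
    shape: tuple[int, int] = (64, 64),
    n_frames: int = 64,
    noise_sigma: float = 0.5,
    noise_corr_len_px: int = 5,
) -> tuple[HyperStack, GroundTruth]:
    """Canonical 64 x 64 x 64 denoising benchmark.

    Row-correlated noise at half the peak signal amplitude emulates the
    low-SNR regime of short-dwell FILM acquisition; flat power and no bleach
    keep the noiseless stack proportional to the clean one so denoising is
    scored in isolation.
    """
    axis = make_axis(1000, 1800, n_frames)
    refs = build_reference_library("default8", axis)
    scene = random_scene(shape=shape, seed=seed)
    acq = AcquisitionSpec(
        axis=axis,
        noise_sigma=noise_sigma,
        noise_corr_len_px=noise_corr_len_px,
        noise_axis="row",
        seed=seed,
    )
    return render_stack(scene, refs, acq)


def perturbed_library(
    specs: Sequence[ComponentPeakSpec] | Literal["default8"],
    axis: WavenumberAxis,
    seed: int = 0,
    center_jitter_cm: float = 3.0,
    width_scale: float = 0.1,
    amplitude_scale: float = 0.1,
) -> ReferenceLibrary:
    """Library rendered from randomly perturbed band tables.

    Emulates the in-situ deviation of organelle constituents from
    pure-standard references (matrix effects, environment-dependent peak
    shifts): each band centre is jittered by N(0, center_jitter_cm) and
    widths/secondary amplitudes are rescaled by ~10 %. Used as the
    data-generating truth in unmixing benchmarks while the unperturbed
    library is handed to the unmixer.
    """
    if isinstance(specs, str):
        specs = DEFAULT8_SPECS
    rng = np.random.default_rng(seed)
    perturbed = []
    for spec in specs:
        peaks = tuple(
            (
                center + rng.normal(0.0, center_jitter_cm),
                fwhm * (1.0 + rng.uniform(-width_scale, width_scale)),
                amplitude * (1.0 + rng.uniform(-amplitude_scale, amplitude_scale)),
            )
            for center, fwhm, amplitude in spec.peaks
        )
        perturbed.append(ComponentPeakSpec(spec.name, peaks, spec.shape))
    return build_reference_library(perturbed, axis)


def unmixing_benchmark(
    seed: int = 7,
    n_organelles: int = 40,
    n_frames: int = 126,
    spectral_snr: float = 20.0,
    sparsity: int = 4,
):
    """Eight-component decomposition benchmark at a given spectral SNR.

    Spectra are sparse mixtures of a *perturbed* eight-component library
    (the in-situ truth) plus white spectral noise with standard deviation
    peak/spectral_snr, AUC-normalized and carrying the 1380-1480 cm^-1
    exclusion mask; the unmixer receives the unperturbed library. Returns
    ``(table, true_fractions, library)`` where ``true_fractions`` are the
    per-organelle area fractions of each component.
    """
    from .calibration import exclude_band, normalize_auc
    from .datatypes import Spectrum, SpectrumTable

    axis = make_axis(1000, 1800, n_frames)
    library = build_reference_library("default8", axis)
    truth_lib = perturbed_library("default8", axis, seed=seed)
    # AUC-normalize the truth so composition weights are area fractions
    areas = np.trapezoid(truth_lib.spectra, axis.values, axis=1)
    truth_spectra = truth_lib.spectra / areas[:, None]

    rng = np.random.default_rng(seed)
    k = library.n_components
    fractions = np.zeros((n_organelles, k))
    for i in range(n_organelles):
        active = rng.choice(k, size=int(rng.integers(2, sparsity + 1)), replace=False)
        fractions[i, active] = rng.dirichlet(np.ones(active.size))
    clean = fractions @ truth_spectra
    noise = rng.normal(0.0, clean.max(axis=1, keepdims=True) / spectral_snr, clean.shape)
    noisy = clean + noise

    spectra = []
    for i in range(n_organelles):
        spectrum = Spectrum(noisy[i], axis)
        spectrum = exclude_band(spectrum, 1380.0, 1480.0)
        spectra.append(normalize_auc(spectrum))
    table = SpectrumTable.from_spectra(
        [f"organelle_{i:03d}" for i in range(n_organelles)],
        spectra,
        size_px=np.full(n_organelles, 12),
        dc_mean=np.ones(n_organelles),
    )
    return table, fractions, library
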