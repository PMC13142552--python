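"""Spectral calibration: raw FILM signal -> absorption spectra sigma_IR.

The demodulated photothermal signal is proportional to the product of DC
fluorescence, IR power and the molecular absorption cross section. The
correction chain therefore runs, in fixed order:

1. baseline subtraction (mean intensity of IR-off frames, or of the lowest
   IR-power frames as a proxy when no IR-off frames were recorded),
2. division by the photobleaching curve (given, or fitted mono-exponentially
   to a per-frame DC trace),
3. division by the IR power profile,
4. optional 3- or 5-point neighbouring average,
5. exclusion of artifact bands (default 1380-1480 cm^-1, around the
   laser-chip power dip),
6. area-under-curve normalization over the remaining bins.

Masked (excluded) bins keep their values but are omitted from smoothing
averages and from the trapezoidal area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .datatypes import HyperStack, Spectrum, SpectrumTable
from .errors import ConfigError, NormalizationError

__all__ = [
    "CalibrationConfig",
    "correct_baseline",
    "correct_photobleach",
    "fit_bleach_curve",
    "normalize_power",
    "smooth_spectrum",
    "exclude_band",
    "normalize_auc",
    "masked_auc",
    "calibrate",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Settings for the correction chain.

    ``ir_off_frames`` lists frame indices acquired with the IR beam blocked;
    after baseline subtraction these frames are masked (they carry no
    absorption signal). ``smooth_window`` of 1 disables smoothing.
    """

    ir_power: np.ndarray | None = None
    bleach_curve: np.ndarray | Literal["fit-exponential"] | None = None
    dc_trace: np.ndarray | None = None
    baseline_mode: Literal["ir_off_frames", "power_dip_proxy", "none"] = "none"
    ir_off_frames: tuple[int, ...] = ()
    dip_window: int = 3
    smooth_window: int = 3
    exclude_bands: tuple[tuple[float, float], ...] = ((1380.0, 1480.0),)
    normalize: Literal["auc", "none"] = "auc"

    def __post_init__(self) -> None:
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError(f"smooth_window must be odd and >= 1, got {self.smooth_window}")
        if self.dip_window < 1:
            raise ConfigError("dip_window must be >= 1")
        if self.ir_power is not None:
            object.__setattr__(self, "ir_power", np.asarray(self.ir_power, dtype=float))
        if isinstance(self.bleach_curve, np.ndarray) or (
            self.bleach_curve is not None and not isinstance(self.bleach_curve, str)
        ):
            object.__setattr__(self, "bleach_curve", np.asarray(self.bleach_curve, dtype=float))
        if self.dc_trace is not None:
            object.__setattr__(self, "dc_trace", np.asarray(self.dc_trace, dtype=float))
        object.__setattr__(self, "ir_off_frames", tuple(int(i) for i in self.ir_off_frames))
        for lo, hi in self.exclude_bands:
            if not lo < hi:
                raise ConfigError(f"exclusion band ({lo}, {hi}) must have lo < hi")


# --------------------------------------------------------------------------
# elementary steps (Spectrum level)

def _baseline_bins(spectrum: Spectrum, config: CalibrationConfig) -> np.ndarray:
    if config.baseline_mode == "ir_off_frames":
        if not config.ir_off_frames:
            raise ConfigError("baseline_mode 'ir_off_frames' requires ir_off_frames indices")
        return np.asarray(config.ir_off_frames, dtype=int)
    if config.baseline_mode == "power_dip_proxy":
        if config.ir_power is None:
            raise ConfigError("baseline_mode 'power_dip_proxy' requires an ir_power profile")
        w = min(config.dip_window, config.ir_power.size)
        return np.argsort(config.ir_power, kind="stable")[:w]
    raise ConfigError(f"no baseline bins for mode {config.baseline_mode!r}")


def correct_baseline(spectrum: Spectrum, config: CalibrationConfig) -> Spectrum:
    """Subtract a constant baseline estimated from IR-off (or lowest-power)
    frames; in ``ir_off_frames`` mode those frames are masked afterwards."""
    bins = _baseline_bins(spectrum, config)
    baseline = float(spectrum.intensities[bins].mean())
    out = spectrum.with_intensities(spectrum.intensities - baseline)
    if config.baseline_mode == "ir_off_frames":
        mask = out.mask.copy()
        mask[bins] = True
        out = out.with_mask(mask)
    return out


def fit_bleach_curve(dc_trace: np.ndarray) -> np.ndarray:
    """Mono-exponential fit to a per-frame DC fluorescence trace, returned as
    a multiplier curve normalized to 1 at frame 0."""
    trace = np.asarray(dc_trace, dtype=float)
    if trace.ndim != 1 or trace.size < 2:
        raise ValueError("dc_trace must be a 1-D array with >= 2 frames")
    if np.any(trace <= 0):
        raise ValueError("dc_trace must be positive for an exponential fit")
    t = np.arange(trace.size)
    slope, intercept = np.polyfit(t, np.log(trace), 1)
    curve = np.exp(slope * t)
    return curve / curve[0]


def correct_photobleach(
    spectrum: Spectrum,
    bleach_curve: np.ndarray | None = None,
    dc_trace: np.ndarray | None = None,
) -> Spectrum:
    """Divide by the per-frame photobleaching multiplier (or fit one from a
    DC trace first)."""
    if bleach_curve is None:
        if dc_trace is None:
            raise ConfigError("provide a bleach_curve or a dc_trace to fit one from")
        bleach_curve = fit_bleach_curve(dc_trace)
    curve = np.asarray(bleach_curve, dtype=float)
    if curve.shape != spectrum.intensities.shape:
        raise ValueError("bleach curve length must match the spectrum")
    if np.any(curve[spectrum.unmasked] <= 0):
        raise ZeroDivisionError("bleach multiplier must be positive on unmasked bins")
    out = spectrum.intensities.copy()
    ok = curve > 0
    out[ok] = out[ok] / curve[ok]
    return spectrum.with_intensities(out)


def normalize_power(spectrum: Spectrum, ir_power: np.ndarray) -> Spectrum:
    """Element-wise division by the IR power profile."""
    power = np.asarray(ir_power, dtype=float)
    if power.shape != spectrum.intensities.shape:
        raise ValueError("ir_power length must match the spectrum")
    if np.any(power[spectrum.unmasked] <= 0):
        raise ZeroDivisionError("ir_power must be positive on unmasked bins")
    out = spectrum.intensities.copy()
    ok = power > 0
    out[ok] = out[ok] / power[ok]
    return spectrum.with_intensities(out)


def _masked_moving_average(values: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis; invalid bins are left out
    of each window and edges use shrunken windows."""
    from scipy.ndimage import convolve1d

    kernel = np.ones(window)
    weights = convolve1d(valid.astype(float), kernel, axis=-1, mode="constant", cval=0.0)
    sums = convolve1d(values * valid, kernel, axis=-1, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        averaged = sums / weights
    out = np.where(valid, averaged, values)
    return out


def smooth_spectrum(spectrum: Spectrum, window: int = 3) -> Spectrum:
    """Neighbouring average over ``window`` bins (odd); masked bins are
    excluded from every average and keep their stored values."""
    if window % 2 == 0:
        raise ConfigError(f"smooth window must be odd, got {window}")
    if window > spectrum.intensities.size:
        raise ConfigError("smooth window exceeds spectrum length")
    if window == 1:
        return spectrum.copy()
    smoothed = _masked_moving_average(
        spectrum.intensities[None, :], spectrum.unmasked, window
    )[0]
    return spectrum.with_intensities(smoothed)


def exclude_band(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Mark every bin with lo <= wavenumber <= hi as excluded."""
    if not lo < hi:
        raise ValueError("band must have lo < hi")
    in_band = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if not in_band.any():
        warnings.warn(
            f"exclusion band ({lo}, {hi}) cm^-1 contains no bins of this axis; no-op",
            stacklevel=2,
        )
        return spectrum.copy()
    mask = spectrum.mask | in_band
    return spectrum.with_mask(mask)


def masked_auc(spectrum: Spectrum) -> float:
    """Trapezoidal area over unmasked bins; sub-intervals touching a masked
    bin are omitted (gaps are not bridged)."""
    valid = spectrum.unmasked
    wn = spectrum.wavenumbers
    y = spectrum.intensities
    pair_ok = valid[:-1] & valid[1:]
    segments = 0.5 * (y[:-1] + y[1:]) * np.diff(wn)
    return float(segments[pair_ok].sum())


def normalize_auc(spectrum: Spectrum) -> Spectrum:
    """Scale so the area under the unmasked curve equals 1."""
    area = masked_auc(spectrum)
    if not area > 0:
        raise NormalizationError(f"non-positive unmasked area {area}")
    return spectrum.with_intensities(spectrum.intensities / area)


# --------------------------------------------------------------------------
# full chain

def _chain_spectrum(spectrum: Spectrum, config: CalibrationConfig) -> tuple[Spectrum, list[dict]]:
    steps: list[dict] = []
    out = spectrum.copy()
    if config.baseline_mode != "none":
        out = correct_baseline(out, config)
        steps.append({"step": "baseline", "mode": config.baseline_mode})
    if config.bleach_curve is not None or config.dc_trace is not None:
        if isinstance(config.bleach_curve, str):
            if config.dc_trace is None:
                raise ConfigError("bleach_curve 'fit-exponential' requires a dc_trace")
            out = correct_photobleach(out, dc_trace=config.dc_trace)
            steps.append({"step": "photobleach", "mode": "fit-exponential"})
        else:
            out = correct_photobleach(out, bleach_curve=config.bleach_curve, dc_trace=config.dc_trace)
            mode = "curve" if config.bleach_curve is not None else "fit-exponential"
            steps.append({"step": "photobleach", "mode": mode})
    if config.ir_power is not None:
        out = normalize_power(out, config.ir_power)
        steps.append({"step": "power"})
    if config.smooth_window > 1:
        out = smooth_spectrum(out, config.smooth_window)
        steps.append({"step": "smooth", "window": config.smooth_window})
    for lo, hi in config.exclude_bands:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = exclude_band(out, lo, hi)
    if config.exclude_bands:
        steps.append({"step": "exclude", "bands": list(config.exclude_bands)})
    if config.normalize == "auc":
        out = normalize_auc(out)
        steps.append({"step": "normalize", "mode": "auc"})
    return out, steps


def calibrate(
    obj: Spectrum | SpectrumTable | HyperStack, config: CalibrationConfig
) -> Spectrum | SpectrumTable | HyperStack:
    """Apply the full correction chain to a spectrum, a spectrum table or a
    whole stack (per pixel). The applied steps are recorded on the result: as
    a ``provenance`` attribute for spectra/tables and under
    ``meta['calibration']`` for stacks.
    """
    if isinstance(obj, Spectrum):
        out, steps = _chain_spectrum(obj, config)
        out.provenance = steps  # type: ignore[attr-defined]
        return out
    if isinstance(obj, SpectrumTable):
        spectra = []
        for i in range(len(obj)):
            cal, steps = _chain_spectrum(obj.row(i), config)
            spectra.append(cal)
        table = SpectrumTable.from_spectra(
            obj.ids, spectra, obj.size_px, obj.dc_mean, obj.group_label
        )
        table.provenance = steps  # type: ignore[attr-defined]
        return table
    if isinstance(obj, HyperStack):
        return _calibrate_stack(obj, config)
    raise TypeError(f"cannot calibrate object of type {type(obj).__name__}")


def _calibrate_stack(stack: HyperStack, config: CalibrationConfig) -> HyperStack:
    rows, cols, n = stack.data.shape
    flat = np.asarray(stack.data, dtype=float).reshape(-1, n)
    mask = np.zeros(n, dtype=bool)
    steps: list[dict] = []

    if config.baseline_mode != "none":
        if config.baseline_mode == "ir_off_frames" and not config.ir_off_frames:
            raise ConfigError("baseline_mode 'ir_off_frames' requires ir_off_frames indices")
        probe = Spectrum(flat[0], stack.axis)
        bins = _baseline_bins(probe, config)
        flat = flat - flat[:, bins].mean(axis=1, keepdims=True)
        if config.baseline_mode == "ir_off_frames":
            mask[bins] = True
        steps.append({"step": "baseline", "mode": config.baseline_mode})

    if isinstance(config.bleach_curve, str):
        if config.dc_trace is None:
            raise ConfigError("bleach_curve 'fit-exponential' requires a dc_trace")
        curve = fit_bleach_curve(config.dc_trace)
        steps.append({"step": "photobleach", "mode": "fit-exponential"})
    elif config.bleach_curve is not None:
        curve = np.asarray(config.bleach_curve, dtype=float)
        steps.append({"step": "photobleach", "mode": "curve"})
    elif config.dc_trace is not None:
        curve = fit_bleach_curve(config.dc_trace)
        steps.append({"step": "photobleach", "mode": "fit-exponential"})
    else:
        curve = None
    if curve is not None:
        if np.any(curve[~mask] <= 0):
            raise ZeroDivisionError("bleach multiplier must be positive on unmasked frames")
        ok = curve > 0
        flat[:, ok] = flat[:, ok] / curve[ok]

    if config.ir_power is not None:
        power = config.ir_power
        if np.any(power[~mask] <= 0):
            raise ZeroDivisionError("ir_power must be positive on unmasked frames")
        ok = power > 0
        flat[:, ok] = flat[:, ok] / power[ok]
        steps.append({"step": "power"})

    if config.smooth_window > 1:
        if config.smooth_window % 2 == 0:
            raise ConfigError("smooth window must be odd")
        flat = _masked_moving_average(flat, ~mask, config.smooth_window)
        steps.append({"step": "smooth", "window": config.smooth_window})

    wn = stack.axis.values
    for lo, hi in config.exclude_bands:
        in_band = (wn >= lo) & (wn <= hi)
        if not in_band.any():
            warnings.warn(
                f"exclusion band ({lo}, {hi}) cm^-1 contains no bins of this axis; no-op",
                stacklevel=2,
            )
        mask |= in_band
    if config.exclude_bands:
        steps.append({"step": "exclude", "bands": list(config.exclude_bands)})

    n_invalid = 0
    if config.normalize == "auc":
        valid = ~mask
        pair_ok = valid[:-1] & valid[1:]
        seg = 0.5 * (flat[:, :-1] + flat[:, 1:]) * np.diff(wn)[None, :]
        areas = seg[:, pair_ok].sum(axis=1)
        bad = areas <= 0
        n_invalid = int(bad.sum())
        areas[bad] = np.nan
        flat = flat / areas[:, None]
        steps.append({"step": "normalize", "mode": "auc"})

    meta = dict(stack.meta)
    meta["calibration"] = steps
    meta["excluded_frames"] = mask.tolist()
    if n_invalid:
        meta["masked"] = True
        meta["n_invalid_pixels"] = n_invalid
    return HyperStack(flat.reshape(rows, cols, n), stack.axis, dc=stack.dc, meta=meta)
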