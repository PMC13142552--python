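"""Organelle localization: DC thresholding, spectral phasor gating, labeling.

The spectral phasor maps each pixel's spectrum onto the first-harmonic
discrete Fourier coefficient, normalized by total intensity:

    g = sum_t I_t cos(2 pi h t / N) / sum_t I_t
    s = sum_t I_t sin(2 pi h t / N) / sum_t I_t         (h = harmonic, default 1)

For non-negative spectra (g, s) lies in the unit disk, and the phasor of a
convex mixture of two spectra lies on the segment joining their phasors, so
chemically distinct populations form separable clusters that can be gated
with a polygon. The sign convention uses +sin (counter-clockwise angles).

Frames excluded by calibration are omitted from the DFT sums with the
remaining frames renumbered 0..n-1 (set ``renumber=False`` to zero-fill the
excluded bins instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label, regionprops

from .datatypes import HyperStack, SpectrumTable, extract_spectrum
from .errors import EmptySelectionError

__all__ = [
    "PhasorMap",
    "LabelMap",
    "spectral_phasor",
    "phasor_coordinates",
    "gate_phasor",
    "threshold_dc",
    "label_organelles",
    "extract_table",
]


@dataclass
class PhasorMap:
    """Per-pixel first-harmonic phasor coordinates."""

    g: np.ndarray
    s: np.ndarray
    harmonic: int = 1
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.g.shape, dtype=bool)


def phasor_coordinates(
    intensities: np.ndarray, harmonic: int = 1, frame_mask: np.ndarray | None = None,
    renumber: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phasor (g, s) of spectra along the last axis.

    ``frame_mask`` marks excluded frames (True = excluded). Returns
    (g, s, valid); pixels with non-positive total intensity are invalid
    (g = s = 0 there).
    """
    x = np.asarray(intensities, dtype=float)
    if frame_mask is not None:
        frame_mask = np.asarray(frame_mask, dtype=bool)
        if renumber:
            x = x[..., ~frame_mask]
        else:
            x = np.where(frame_mask, 0.0, x)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("phasor needs at least 2 usable frames")
    t = np.arange(n)
    angle = 2.0 * np.pi * harmonic * t / n
    total = x.sum(axis=-1)
    valid = total > 0
    safe = np.where(valid, total, 1.0)
    g = (x * np.cos(angle)).sum(axis=-1) / safe
    s = (x * np.sin(angle)).sum(axis=-1) / safe
    g = np.where(valid, g, 0.0)
    s = np.where(valid, s, 0.0)
    return g, s, valid


def spectral_phasor(stack: HyperStack, harmonic: int = 1, renumber: bool = True) -> PhasorMap:
    """First-harmonic phasor map of a stack.

    Uses the calibration frame exclusion recorded in
    ``stack.meta['excluded_frames']`` when present.
    """
    frame_mask = None
    if "excluded_frames" in stack.meta:
        frame_mask = np.asarray(stack.meta["excluded_frames"], dtype=bool)
    data = np.nan_to_num(np.asarray(stack.data, dtype=float), nan=0.0)
    g, s, valid = phasor_coordinates(data, harmonic, frame_mask, renumber)
    return PhasorMap(g=g, s=s, harmonic=harmonic, valid=valid)


def gate_phasor(phasor: PhasorMap, gate: np.ndarray) -> np.ndarray:
    """Pixels whose valid (g, s) falls inside (or on the boundary of) the
    gate polygon, given as an (n >= 3, 2) vertex list in the (g, s) plane."""
    vertices = np.asarray(gate, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("gate must be an (n>=3, 2) vertex array")
    polygon = Polygon(vertices)
    if not polygon.is_valid or polygon.area == 0:
        raise ValueError("degenerate gate polygon")
    points = shapely.points(phasor.g.ravel(), phasor.s.ravel())
    inside = shapely.covers(polygon, points).reshape(phasor.g.shape)
    return inside & phasor.valid


def threshold_dc(
    dc: np.ndarray, method: str = "otsu", value: float | None = None
) -> np.ndarray:
    """Boolean mask of above-threshold DC fluorescence pixels."""
    dc = np.asarray(dc, dtype=float)
    if method == "otsu":
        if np.ptp(dc) == 0:
            raise ValueError("otsu thresholding needs a non-constant image")
        threshold = threshold_otsu(dc)
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        threshold = float(value)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return dc > threshold


@dataclass
class LabelMap:
    """Connected-component raster: 0 = background, labels 1..n_regions in
    raster-scan order of each region's first pixel."""

    labels: np.ndarray
    n_regions: int
    size_px: np.ndarray
    centroids: np.ndarray


def label_organelles(
    mask: np.ndarray, min_size_px: int = 1, connectivity: int = 8
) -> LabelMap:
    """Label connected components of a boolean mask, dropping regions below
    ``min_size_px``."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    raw = _cc_label(mask, connectivity=1 if connectivity == 4 else 2)
    sizes = np.bincount(raw.ravel())
    keep = np.flatnonzero(sizes >= min_size_px)
    keep = keep[keep != 0]
    # relabel surviving regions by raster-scan order of their first pixel
    keep_set = set(int(k) for k in keep)
    flat = raw.ravel()
    first_seen: dict[int, int] = {}
    for pos, lab in enumerate(flat):
        lab = int(lab)
        if lab != 0 and lab in keep_set and lab not in first_seen:
            first_seen[lab] = pos
    order = sorted(first_seen, key=first_seen.get)
    labels = np.zeros_like(raw, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        labels[raw == old] = new
    props = regionprops(labels)
    return LabelMap(
        labels=labels,
        n_regions=len(order),
        size_px=np.array([p.area for p in props], dtype=int),
        centroids=np.array([p.centroid for p in props]) if props else np.zeros((0, 2)),
    )


def extract_table(stack: HyperStack, labels: LabelMap) -> SpectrumTable:
    """Mean spectrum, size and DC intensity per labeled organelle."""
    if labels.labels.shape != stack.spatial_shape:
        raise ValueError("label map shape does not match the stack")
    if labels.n_regions == 0:
        import warnings

        warnings.warn("empty label map: returning empty table", stacklevel=2)
        return SpectrumTable(
            axis=stack.axis,
            intensities=np.zeros((0, stack.n_frames)),
            ids=[],
            size_px=np.zeros(0, dtype=int),
            dc_mean=np.zeros(0),
        )
    frame_mask = None
    if "excluded_frames" in stack.meta:
        frame_mask = np.asarray(stack.meta["excluded_frames"], dtype=bool)
    spectra, sizes, dc_means, ids = [], [], [], []
    for region in range(1, labels.n_regions + 1):
        region_mask = labels.labels == region
        if not region_mask.any():
            raise EmptySelectionError(f"label {region} has no pixels")
        spectrum = extract_spectrum(stack, region_mask)
        spectra.append(spectrum.intensities)
        sizes.append(int(region_mask.sum()))
        dc_means.append(
            float(stack.dc[region_mask].mean()) if stack.dc is not None else np.nan
        )
        ids.append(f"organelle_{region:03d}")
    return SpectrumTable(
        axis=stack.axis,
        intensities=np.vstack(spectra),
        ids=ids,
        size_px=np.array(sizes),
        dc_mean=np.array(dc_means),
        mask=frame_mask,
    )
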