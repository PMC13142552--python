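"""Core in-memory containers for FILM hyperspectral data.

A hyperspectral acquisition is a 3-D intensity array indexed (row, col,
frame) whose frame axis maps onto a wavenumber axis in cm^-1, optionally
accompanied by a DC fluorescence image of the same spatial shape. Spectra
carry an exclusion mask so that instrument-artifact bands (e.g. the
1380-1480 cm^-1 region around the laser-chip power dip) can be dropped from
every downstream norm without losing the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, InvalidAxisError

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "HyperStack",
    "SpectrumTable",
    "ReferenceLibrary",
    "make_axis",
    "extract_spectrum",
]

_EVEN_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing, evenly spaced wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise InvalidAxisError("axis needs at least 2 wavenumber values")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise InvalidAxisError("wavenumbers must be strictly increasing")
        step = (values[-1] - values[0]) / (values.size - 1)
        if not np.allclose(steps, step, rtol=_EVEN_SPACING_RTOL, atol=abs(step) * _EVEN_SPACING_RTOL):
            raise InvalidAxisError("wavenumbers must be evenly spaced")

    @classmethod
    def linspace(cls, start: float, stop: float, n_frames: int) -> "WavenumberAxis":
        if n_frames < 2:
            raise InvalidAxisError(f"n_frames must be >= 2, got {n_frames}")
        if not stop > start:
            raise InvalidAxisError(f"stop ({stop}) must exceed start ({start})")
        return cls(np.linspace(start, stop, int(n_frames)))

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.n_frames - 1)

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the bin closest to `wavenumber`; ties break toward the
        lower wavenumber."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=1e-12, atol=1e-9
        )

    def __len__(self) -> int:
        return self.n_frames


def make_axis(start: float, stop: float, n_frames: int) -> WavenumberAxis:
    """Evenly spaced axis inclusive of both endpoints.

    ``make_axis(1000, 1800, 126)`` reproduces the organelle acquisition grid;
    ``make_axis(980, 1780, 160)`` the bacterial one.
    """
    return WavenumberAxis.linspace(start, stop, n_frames)


def _as_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError(f"mask shape {mask.shape} != ({n},)")
    return mask


@dataclass
class Spectrum:
    """1-D intensity trace aligned to a wavenumber axis.

    ``mask`` marks excluded bins (True = excluded, numpy.ma convention);
    excluded bins keep their stored value but are omitted from every norm,
    area and fit computed downstream.
    """

    intensities: np.ndarray
    axis: WavenumberAxis
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.axis.n_frames,):
            raise ValueError(
                f"intensities length {self.intensities.shape} != axis frames {self.axis.n_frames}"
            )
        self.mask = _as_mask(self.mask, self.axis.n_frames)

    @property
    def unmasked(self) -> np.ndarray:
        """Boolean selector of included bins."""
        return ~self.mask

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.axis.values

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(np.asarray(intensities, dtype=float), self.axis, self.mask.copy())

    def with_mask(self, mask: np.ndarray) -> "Spectrum":
        return Spectrum(self.intensities.copy(), self.axis, mask)

    def copy(self) -> "Spectrum":
        return Spectrum(self.intensities.copy(), self.axis, self.mask.copy())


@dataclass
class HyperStack:
    """3-D hyperspectral intensity array indexed (row, col, frame)."""

    data: np.ndarray
    axis: WavenumberAxis
    dc: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3-D (row, col, frame), got ndim={self.data.ndim}")
        if self.data.shape[2] != self.axis.n_frames:
            raise ValueError(
                f"frame count {self.data.shape[2]} != axis frames {self.axis.n_frames}"
            )
        if self.dc is not None:
            self.dc = np.asarray(self.dc)
            if self.dc.shape != self.data.shape[:2]:
                raise ValueError(
                    f"dc shape {self.dc.shape} != spatial shape {self.data.shape[:2]}"
                )
        if not self.meta.get("masked", False) and np.isnan(
            np.asarray(self.data, dtype=float)
        ).any():
            raise ValueError("stack contains NaN but is not flagged masked")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "HyperStack":
        return HyperStack(
            self.data.copy(),
            self.axis,
            None if self.dc is None else self.dc.copy(),
            dict(self.meta),
        )


def extract_spectrum(stack: HyperStack, mask: np.ndarray) -> Spectrum:
    """Per-frame mean over the pixels selected by a boolean raster."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != stack spatial shape {stack.spatial_shape}")
    if not mask.any():
        raise EmptySelectionError("mask selects no pixels")
    return Spectrum(stack.data[mask].mean(axis=0).astype(float), stack.axis)


@dataclass
class SpectrumTable:
    """Per-organelle spectra with size/intensity metadata.

    Rows share one axis and one exclusion mask; `intensities` is the
    (n_rows, n_frames) matrix whose rows are individual spectra.
    """

    axis: WavenumberAxis
    intensities: np.ndarray
    ids: list[str]
    size_px: np.ndarray
    dc_mean: np.ndarray
    group_label: list[str | None] = field(default=None)  # type: ignore[assignment]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        n_rows = self.intensities.shape[0]
        if self.intensities.shape[1] != self.axis.n_frames:
            raise ValueError("spectra length does not match axis")
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != n_rows:
            raise ValueError("ids length mismatch")
        if len(set(self.ids)) != n_rows:
            raise ValueError("organelle ids must be unique")
        self.size_px = np.asarray(self.size_px, dtype=int)
        self.dc_mean = np.asarray(self.dc_mean, dtype=float)
        if self.size_px.shape != (n_rows,) or self.dc_mean.shape != (n_rows,):
            raise ValueError("metadata length mismatch")
        if self.group_label is None:
            self.group_label = [None] * n_rows
        if len(self.group_label) != n_rows:
            raise ValueError("group_label length mismatch")
        self.mask = _as_mask(self.mask, self.axis.n_frames)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.intensities[i].copy(), self.axis, self.mask.copy())

    @classmethod
    def from_spectra(
        cls,
        ids: Sequence[str],
        spectra: Iterable[Spectrum],
        size_px: Sequence[int] | None = None,
        dc_mean: Sequence[float] | None = None,
        group_label: Sequence[str | None] | None = None,
    ) -> "SpectrumTable":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra:
            if s.axis != axis:
                raise ValueError("all spectra must share one axis")
        mask = spectra[0].mask
        ids = list(ids)
        n = len(spectra)
        return cls(
            axis=axis,
            intensities=np.vstack([s.intensities for s in spectra]),
            ids=ids,
            size_px=np.zeros(n, dtype=int) if size_px is None else np.asarray(size_px),
            dc_mean=np.full(n, np.nan) if dc_mean is None else np.asarray(dc_mean, dtype=float),
            group_label=None if group_label is None else list(group_label),
            mask=mask,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide CSV layout: first column the wavenumber, one column per id."""
        data = {"wavenumber_cm-1": self.axis.values}
        for i, oid in enumerate(self.ids):
            data[oid] = self.intensities[i]
        return pd.DataFrame(data)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "organelle_id": self.ids,
                "size_px": self.size_px,
                "dc_mean": self.dc_mean,
                "group_label": self.group_label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectrumTable":
        frame = pd.read_csv(path)
        if frame.columns[0] != "wavenumber_cm-1":
            raise ValueError("first column must be 'wavenumber_cm-1'")
        axis = WavenumberAxis(frame.iloc[:, 0].to_numpy())
        ids = list(frame.columns[1:])
        intensities = frame.iloc[:, 1:].to_numpy().T
        return cls(
            axis=axis,
            intensities=intensities,
            ids=ids,
            size_px=np.zeros(len(ids), dtype=int),
            dc_mean=np.full(len(ids), np.nan),
        )


@dataclass
class ReferenceLibrary:
    """K named, non-negative component spectra on one shared axis."""

    names: list[str]
    spectra: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if len(self.names) < 1:
            raise ValueError("library needs at least one component")
        if len(set(self.names)) != len(self.names):
            raise ValueError("component names must be unique")
        if self.spectra.shape != (len(self.names), self.axis.n_frames):
            raise ValueError("spectra shape does not match names/axis")
        if np.any(self.spectra < 0):
            raise ValueError("reference spectra must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.names)

    def spectrum(self, name: str) -> Spectrum:
        return Spectrum(self.spectra[self.names.index(name)].copy(), self.axis)

    def to_frame(self) -> pd.DataFrame:
        data = {"wavenumber_cm-1": self.axis.values}
        for i, name in enumerate(self.names):
            data[name] = self.spectra[i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceLibrary":
        frame = pd.read_csv(path)
        axis = WavenumberAxis(frame.iloc[:, 0].to_numpy())
        names = list(frame.columns[1:])
        return cls(names=names, spectra=frame.iloc[:, 1:].to_numpy().T, axis=axis)
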