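"""Readers and writers for hyperspectral stacks.

Two on-disk layouts are supported:

* multi-page TIFF — one page per wavenumber frame in ascending wavenumber
  order, with a JSON sidecar ``<stem>.json`` holding
  ``{"start", "stop", "n_frames", "units": "cm-1"}`` plus provenance; the DC
  fluorescence image, when present, is stored as ``<stem>_dc.tif``;
* HDF5 — datasets ``/film``, ``/dc`` (optional) and ``/wavenumbers``, with
  axis endpoints and provenance stored as root attributes.

Integer data round-trips bit-exactly; floats are stored at their native
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .datatypes import HyperStack, WavenumberAxis
from .errors import FormatError, MetadataError

__all__ = ["read_stack", "write_stack"]

_FORMATS = {"tiff", "hdf5"}
_SUFFIX_FORMAT = {".tif": "tiff", ".tiff": "tiff", ".h5": "hdf5", ".hdf5": "hdf5"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {fmt!r}")
        return fmt
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer format from suffix {path.suffix!r}") from None


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _dc_path(path: Path) -> Path:
    return path.with_name(path.stem + "_dc.tif")


def write_stack(stack: HyperStack, path, format: str | None = None, overwrite: bool = False) -> None:
    """Write a stack to disk; refuses to clobber unless ``overwrite``."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if fmt == "tiff":
        _write_tiff(stack, path)
    else:
        _write_hdf5(stack, path)


def read_stack(path, format: str | None = None) -> HyperStack:
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    return _read_tiff(path) if fmt == "tiff" else _read_hdf5(path)


def _write_tiff(stack: HyperStack, path: Path) -> None:
    # pages are frame-major: page t is the image at wavenumber axis.values[t]
    tifffile.imwrite(path, np.moveaxis(stack.data, 2, 0))
    sidecar = {
        "start": stack.axis.start,
        "stop": stack.axis.stop,
        "n_frames": stack.axis.n_frames,
        "units": "cm-1",
        "dc_file": None,
        "meta": stack.meta,
    }
    if stack.dc is not None:
        dc_path = _dc_path(path)
        tifffile.imwrite(dc_path, stack.dc)
        sidecar["dc_file"] = dc_path.name
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, default=str))


def _read_tiff(path: Path) -> HyperStack:
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise MetadataError(f"missing wavenumber sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("start", "stop", "n_frames"):
        if key not in sidecar:
            raise MetadataError(f"sidecar lacks {key!r}")
    axis = WavenumberAxis.linspace(sidecar["start"], sidecar["stop"], sidecar["n_frames"])
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != axis.n_frames:
        raise FormatError(
            f"TIFF has {pages.shape[0]} pages but axis metadata says {axis.n_frames} frames"
        )
    dc = None
    if sidecar.get("dc_file"):
        dc = tifffile.imread(path.with_name(sidecar["dc_file"]))
    return HyperStack(np.moveaxis(pages, 0, 2), axis, dc=dc, meta=sidecar.get("meta", {}))


def _write_hdf5(stack: HyperStack, path: Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("film", data=stack.data)
        fh.create_dataset("wavenumbers", data=stack.axis.values.astype(np.float64))
        if stack.dc is not None:
            fh.create_dataset("dc", data=stack.dc)
        fh.attrs["start"] = stack.axis.start
        fh.attrs["stop"] = stack.axis.stop
        fh.attrs["n_frames"] = stack.axis.n_frames
        fh.attrs["units"] = "cm-1"
        fh.attrs["meta_json"] = json.dumps(stack.meta, default=str)


def _read_hdf5(path: Path) -> HyperStack:
    with h5py.File(path, "r") as fh:
        if "wavenumbers" not in fh:
            raise MetadataError("HDF5 file lacks /wavenumbers")
        if "film" not in fh:
            raise FormatError("HDF5 file lacks /film")
        axis = WavenumberAxis(fh["wavenumbers"][()])
        data = fh["film"][()]
        if data.ndim != 3 or data.shape[2] != axis.n_frames:
            raise FormatError(
                f"/film shape {data.shape} inconsistent with {axis.n_frames}-frame axis"
            )
        dc = fh["dc"][()] if "dc" in fh else None
        meta = json.loads(fh.attrs.get("meta_json", "{}"))
    return HyperStack(data, axis, dc=dc, meta=meta)
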