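"""End-to-end orchestration: simulate -> calibrate -> denoise -> segment ->
unmix -> profile, driven by a single YAML config with per-stage sections.

Every stochastic stage derives its seed from the global seed, all artifacts
are written under ``output_dir`` and a JSON run report records versions,
seeds, parameters, stage timings and the config hash, so a rerun with the
same config reproduces the deterministic artifacts bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .calibration import CalibrationConfig, calibrate
from .datatypes import HyperStack
from .denoise import DenoiserConfig, denoise, make_permutation_pair, train_denoiser
from .errors import ConfigError, FilmspecError
from .io import read_stack, write_stack
from .profiling import (
    LIPOLYTIC_RATIO,
    PROTEOLYTIC_RATIO,
    band_ratio,
    classify_groups,
    correlation_chords,
    zscore_profile,
)
from .segmentation import extract_table, gate_phasor, label_organelles, spectral_phasor, threshold_dc
from .synthetic import (
    AcquisitionSpec,
    build_reference_library,
    make_axis,
    random_scene,
    render_stack,
)
from .unmixing import McrConfig, mcr_lasso

__all__ = ["PipelineConfig", "PipelineStageError", "validate_config", "run_pipeline"]

STAGES = ("simulate", "calibrate", "denoise", "segment", "unmix", "profile")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {
        "shape": [48, 48],
        "n_frames": 48,
        "start_cm": 1000.0,
        "stop_cm": 1800.0,
        "n_organelles": 8,
        "noise_sigma": 0.3,
        "noise_corr_len_px": 3,
        "noise_axis": "row",
    },
    "calibrate": {
        "smooth_window": 3,
        "exclude_bands": [[1380.0, 1480.0]],
        "baseline_mode": "none",
        "normalize": "auc",
    },
    "denoise": {
        "depth": 2,
        "base_channels": 4,
        "epochs": 4,
        "steps_per_epoch": 8,
        "patch_shape": [24, 24, 12],
        "learning_rate": 2e-3,
        "batch_size": 2,
    },
    "segment": {"min_size_px": 4, "connectivity": 8, "gate": None},
    "unmix": {"lambda": "auto", "max_iter": 30, "augmentation_weight": 1, "refs_csv": None},
    "profile": {"ratio_thresholds": "median", "chord_threshold": 0.5},
}


class PipelineStageError(FilmspecError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("filmspec_run")
    input_path: Path | None = None
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    log_level: str = "INFO"

    def stage_params(self, stage: str) -> dict[str, Any]:
        merged = dict(_DEFAULTS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "input_path": None if self.input_path is None else str(self.input_path),
            "stages": dict(self.stages),
            "params": {s: self.stage_params(s) for s in STAGES},
            "log_level": self.log_level,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(path_or_dict) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a pipeline config; returns (config, violations).

    All violations are collected and returned together, not just the first.
    """
    if isinstance(path_or_dict, (str, Path)):
        try:
            raw = yaml.safe_load(Path(path_or_dict).read_text())
        except FileNotFoundError:
            return None, [f"config file not found: {path_or_dict}"]
        except yaml.YAMLError as exc:
            return None, [f"unparseable config: {exc}"]
    else:
        raw = dict(path_or_dict)
    if raw is None:
        raw = {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config root must be a mapping"]

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed must be an integer, got {seed!r}")
        seed = 0
    stages = {s: True for s in STAGES}
    for name, enabled in (raw.get("stages") or {}).items():
        if name not in STAGES:
            errors.append(f"unknown stage {name!r}")
        elif not isinstance(enabled, bool):
            errors.append(f"stage toggle {name} must be boolean")
        else:
            stages[name] = enabled

    params = {s: dict(raw.get(s) or {}) for s in STAGES}
    for stage, values in params.items():
        known = _DEFAULTS.get(stage, {})
        for key in values:
            if key not in known:
                errors.append(f"unknown parameter {stage}.{key}")

    sw = params["calibrate"].get("smooth_window", _DEFAULTS["calibrate"]["smooth_window"])
    if not isinstance(sw, int) or sw < 1 or sw % 2 == 0:
        errors.append(f"calibrate.smooth_window must be an odd integer >= 1, got {sw!r}")
    ns = params["simulate"].get("noise_sigma", _DEFAULTS["simulate"]["noise_sigma"])
    if not isinstance(ns, (int, float)) or ns < 0:
        errors.append(f"simulate.noise_sigma must be >= 0, got {ns!r}")
    lam = params["unmix"].get("lambda", _DEFAULTS["unmix"]["lambda"])
    if lam != "auto" and (not isinstance(lam, (int, float)) or lam < 0):
        errors.append(f"unmix.lambda must be 'auto' or a non-negative number, got {lam!r}")
    refs_csv = params["unmix"].get("refs_csv")
    if refs_csv is not None and not Path(refs_csv).exists():
        errors.append(f"unmix.refs_csv does not exist: {refs_csv}")
    input_path = raw.get("input_path")
    if not stages["simulate"] and input_path is None:
        errors.append("input_path is required when the simulate stage is disabled")
    if input_path is not None and not Path(input_path).exists():
        errors.append(f"input_path does not exist: {input_path}")

    if errors:
        return None, errors
    return (
        PipelineConfig(
            seed=seed,
            output_dir=Path(raw.get("output_dir", "filmspec_run")),
            input_path=None if input_path is None else Path(input_path),
            stages=stages,
            params=params,
            log_level=str(raw.get("log_level", "INFO")),
        ),
        [],
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in fixed order and write a run report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "filmspec_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": {s: config.stage_params(s) for s in STAGES},
        "stages": [],
        "skipped": [s for s in STAGES if not config.stages.get(s, True)],
        "artifacts": {},
    }

    state: dict[str, Any] = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](config, state, out, report)
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            partial = out / "report.partial.json"
            partial.write_text(json.dumps(report, indent=1, default=str))
            raise PipelineStageError(stage, exc) from exc
        report["stages"].append(
            {"name": stage, "seconds": round(time.perf_counter() - t0, 3)}
        )

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, default=str))
    report["artifacts"]["report"] = str(report_path)
    return report


# --------------------------------------------------------------------------
# stage implementations

def _stage_simulate(config, state, out, report):
    p = config.stage_params("simulate")
    axis = make_axis(p["start_cm"], p["stop_cm"], p["n_frames"])
    refs = build_reference_library("default8", axis)
    scene = random_scene(
        shape=tuple(p["shape"]), n_organelles=p["n_organelles"], seed=config.seed
    )
    acq = AcquisitionSpec(
        axis=axis,
        noise_sigma=p["noise_sigma"],
        noise_corr_len_px=p["noise_corr_len_px"],
        noise_axis=p["noise_axis"],
        seed=config.seed,
    )
    stack, truth = render_stack(scene, refs, acq)
    state["stack"], state["truth"], state["refs"] = stack, truth, refs
    path = out / "stack.h5"
    write_stack(stack, path, overwrite=True)
    report["artifacts"]["stack"] = str(path)


def _stage_load_input(config, state):
    if "stack" not in state:
        state["stack"] = read_stack(config.input_path)


def _stage_calibrate(config, state, out, report):
    _stage_load_input(config, state)
    p = config.stage_params("calibrate")
    cal_config = CalibrationConfig(
        smooth_window=p["smooth_window"],
        exclude_bands=tuple(tuple(b) for b in p["exclude_bands"]),
        baseline_mode=p["baseline_mode"],
        normalize="none",  # per-pixel AUC happens after spectra are pooled
    )
    state["calibrated"] = calibrate(state["stack"], cal_config)
    state["table_normalize"] = p["normalize"]
    path = out / "calibrated.h5"
    write_stack(state["calibrated"], path, overwrite=True)
    report["artifacts"]["calibrated"] = str(path)


def _stage_denoise(config, state, out, report):
    source: HyperStack = state.get("calibrated", state.get("stack"))
    if source is None:
        _stage_load_input(config, state)
        source = state["stack"]
    p = config.stage_params("denoise")
    pair, swapped = make_permutation_pair(source, with_swapped=True)
    dn_config = DenoiserConfig(
        depth=p["depth"],
        base_channels=p["base_channels"],
        epochs=p["epochs"],
        steps_per_epoch=p["steps_per_epoch"],
        patch_shape=tuple(p["patch_shape"]),
        learning_rate=p["learning_rate"],
        batch_size=p["batch_size"],
        seed=config.seed,
    )
    model = train_denoiser([pair], dn_config)
    state["denoised"] = denoise(model, source)
    model_path = out / "denoiser.npz"
    model.save(model_path)
    path = out / "denoised.h5"
    write_stack(state["denoised"], path, overwrite=True)
    report["artifacts"]["denoised"] = str(path)
    report["artifacts"]["denoiser"] = str(model_path)


def _analysis_stack(state) -> HyperStack:
    for key in ("denoised", "calibrated", "stack"):
        if key in state:
            return state[key]
    raise ConfigError("no stack available for analysis")


def _stage_segment(config, state, out, report):
    stack = _analysis_stack(state)
    p = config.stage_params("segment")
    if stack.dc is None:
        raise ConfigError("segmentation needs a DC fluorescence image")
    mask = threshold_dc(stack.dc, method="otsu")
    if p["gate"]:
        phasor = spectral_phasor(stack)
        mask &= gate_phasor(phasor, np.asarray(p["gate"], dtype=float))
    labels = label_organelles(mask, min_size_px=p["min_size_px"], connectivity=p["connectivity"])
    table = extract_table(stack, labels)
    if state.get("table_normalize", "auc") == "auc":
        from .calibration import normalize_auc

        spectra = [normalize_auc(table.row(i)) for i in range(len(table))]
        from .datatypes import SpectrumTable

        table = SpectrumTable.from_spectra(
            table.ids, spectra, table.size_px, table.dc_mean, table.group_label
        )
    state["labels"], state["table"] = labels, table
    path = out / "spectra.csv"
    table.to_csv(path)
    report["artifacts"]["spectra"] = str(path)
    report["n_organelles"] = labels.n_regions


def _stage_unmix(config, state, out, report):
    p = config.stage_params("unmix")
    table = state.get("table")
    if table is None:
        raise ConfigError("unmix stage needs the segmentation table")
    if p["refs_csv"]:
        from .datatypes import ReferenceLibrary

        refs = ReferenceLibrary.from_csv(p["refs_csv"])
    else:
        refs = state.get("refs") or build_reference_library("default8", table.axis)
    mcr_config = McrConfig(
        max_iter=p["max_iter"], augmentation_weight=p["augmentation_weight"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conc = mcr_lasso(table, refs, mcr_config, lam=p["lambda"])
    state["concentrations"] = conc
    path = out / "concentrations.csv"
    conc.to_csv(path)
    report["artifacts"]["concentrations"] = str(path)


def _stage_profile(config, state, out, report):
    p = config.stage_params("profile")
    table = state.get("table")
    if table is None:
        raise ConfigError("profile stage needs the segmentation table")
    proteo = band_ratio(table, PROTEOLYTIC_RATIO)
    lipo = band_ratio(table, LIPOLYTIC_RATIO)
    thresholds = p["ratio_thresholds"]
    if thresholds != "median":
        thresholds = tuple(thresholds)
    assignment = classify_groups(proteo, lipo, thresholds)
    profile: dict[str, Any] = {
        "organelle_id": list(table.ids),
        "proteolytic_ratio": assignment.proteolytic_ratio.tolist(),
        "lipolytic_ratio": assignment.lipolytic_ratio.tolist(),
        "group": assignment.group,
        "thresholds": {
            "proteolytic": assignment.proteolytic_threshold,
            "lipolytic": assignment.lipolytic_threshold,
        },
    }
    groups = sorted(set(assignment.group))
    if len(table) >= 2 and len(groups) >= 1:
        by_group = {
            g: table.intensities[[i for i, lab in enumerate(assignment.group) if lab == g]]
            for g in groups
        }
        by_group = {g: m for g, m in by_group.items() if m.shape[0] >= 1}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zscores = zscore_profile(by_group)
        profile["zscore_groups"] = {g: z.tolist() for g, z in zscores.items()}
    conc = state.get("concentrations")
    if conc is not None and len(conc.ids) >= 3 and conc.fractions.shape[1] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chords = correlation_chords(conc, threshold=p["chord_threshold"])
        profile["chords"] = [
            {"a": a, "b": b, "r": round(r, 4)} for a, b, r in chords
        ]
    path = out / "profile.json"
    path.write_text(json.dumps(profile, indent=1))
    report["artifacts"]["profile"] = str(path)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "denoise": _stage_denoise,
    "segment": _stage_segment,
    "unmix": _stage_unmix,
    "profile": _stage_profile,
}
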