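"""End-to-end experiment orchestration from a YAML config.

One experiment = a data source (synthetic phantom cohort, or a
directory of NIfTI cases) x a set of sequences x a set of preprocessing
variants x one segmentation backend.  For every (case, sequence,
variant) the pipeline resamples to an isotropic grid, preprocesses,
segments, and scores against the reference; it then writes a report
directory:

* ``records.csv``    — one row per (case, sequence, variant, class) DSC
* ``summary.csv``    — mean DSC + 95% bootstrap CI per (sequence, variant)
* ``summary_wide.csv`` — mean DSC, rows = sequence, columns = variant
* ``stats.csv``      — pairwise Wilcoxon comparisons, BH-adjusted jointly
* ``tumor_analysis.json`` — localization counts + volume stratification
* ``manifest.json``  — config, seeds, package version, config hash
* ``run.log``        — per-case progress lines

Runs are reproducible: re-running with the manifest's config and seeds
reproduces all CSVs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backends import default_windows, external_segment, load_windows, make_window_backend
from .evaluation import (ClassMapping, EvalTable, classify_localization,
                         evaluate_case, stratify_by_volume, summarize)
from .inversion import PreprocessVariant, VARIANT_NAMES, preprocess
from .phantom import PhantomSpec, generate_cohort
from .stats import bh_adjust, compare_variants, comparisons_frame
from .volume_io import read_labelmap, read_volume, resample_isotropic

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "PipelineError"]

SEQUENCES = ("CT", "T1w", "T2wfs")
SEQUENCE_FILES = {"CT": "ct.nii.gz", "T1w": "t1.nii.gz", "T2wfs": "t2fs.nii.gz"}

_TOP_KEYS = {"output_dir", "data", "sequences", "variants", "backend", "mapping",
             "resample_mm", "clip", "background_percentile", "bootstrap",
             "tumor_class", "tumor_analysis"}
_PHANTOM_KEYS = {"n", "master_seed", "tumor_volume_range_cm3", "side_fractions",
                 "grid_shape", "spacing_mm", "noise_sd", "bias_amplitude",
                 "psf_sigma_mm"}
_BACKEND_KEYS = {"kind", "windows", "command", "class_map"}


class PipelineError(RuntimeError):
    """Configuration or execution failure of an experiment run."""


@dataclass
class ExperimentConfig:
    """Validated, defaults-filled experiment description."""

    output_dir: Path
    sequences: tuple[str, ...]
    variants: tuple[str, ...]
    phantom: dict | None = None
    data_dir: Path | None = None
    backend_kind: str = "windows"
    windows_path: Path | None = None
    command: str | None = None
    class_map_path: Path | None = None
    mapping_path: Path | None = None
    resample_mm: float = 1.0
    clip: tuple[float, float] = (0.0, 3000.0)
    background_percentile: float = 1.0
    n_boot: int = 2000
    bootstrap_seed: int = 0
    tumor_class: str = "tumor"
    tumor_sequence: str = "T1w"
    tumor_variant: str = "inverted_black"
    raw: dict = field(default_factory=dict)


def _fail(errors: list[str]):
    if errors:
        raise PipelineError("invalid experiment config:\n- " + "\n- ".join(errors))


def validate_config(path) -> ExperimentConfig:
    """Parse and strictly validate a YAML experiment config."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise PipelineError(f"{path}: config must be a YAML mapping")
    return config_from_dict(raw, base_dir=path.parent)


def config_from_dict(raw: dict, base_dir: Path | None = None) -> ExperimentConfig:
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)} (allowed: {sorted(_TOP_KEYS)})")

    def resolve(p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else base_dir / p

    if "output_dir" not in raw:
        errors.append("missing required key: output_dir")
    sequences = tuple(raw.get("sequences", ()))
    if not sequences:
        errors.append("at least one sequence is required")
    bad = [s for s in sequences if s not in SEQUENCES]
    if bad:
        errors.append(f"unknown sequences {bad}; allowed: {list(SEQUENCES)}")
    variants = tuple(raw.get("variants", ()))
    if not variants:
        errors.append("at least one variant is required")
    bad = [v for v in variants if v not in VARIANT_NAMES]
    if bad:
        errors.append(f"unknown variants {bad}; allowed: {list(VARIANT_NAMES)}")

    data = raw.get("data") or {}
    phantom_cfg = data.get("phantom")
    data_dir = data.get("directory")
    if (phantom_cfg is None) == (data_dir is None):
        errors.append("data must specify exactly one of 'phantom' or 'directory'")
    if phantom_cfg is not None:
        unknown = set(phantom_cfg) - _PHANTOM_KEYS
        if unknown:
            errors.append(f"unknown phantom keys: {sorted(unknown)}")
        if int(phantom_cfg.get("n", 0)) < 1:
            errors.append("phantom.n must be >= 1")
    if data_dir is not None:
        data_dir = resolve(data_dir)
        if not data_dir.is_dir():
            errors.append(f"data directory does not exist: {data_dir}")

    backend = raw.get("backend") or {"kind": "windows"}
    unknown = set(backend) - _BACKEND_KEYS
    if unknown:
        errors.append(f"unknown backend keys: {sorted(unknown)}")
    kind = backend.get("kind", "windows")
    if kind not in ("windows", "external"):
        errors.append(f"backend.kind must be 'windows' or 'external', got {kind!r}")
    if kind == "external" and not backend.get("command"):
        errors.append("external backend requires backend.command")
    windows_path = backend.get("windows")
    if windows_path is not None:
        windows_path = resolve(windows_path)
        if not windows_path.exists():
            errors.append(f"window table not found: {windows_path}")
    class_map_path = backend.get("class_map")
    if class_map_path is not None:
        class_map_path = resolve(class_map_path)
        if not class_map_path.exists():
            errors.append(f"class map not found: {class_map_path}")
    mapping_path = raw.get("mapping")
    if mapping_path is not None:
        mapping_path = resolve(mapping_path)
        if not mapping_path.exists():
            errors.append(f"mapping file not found: {mapping_path}")

    clip = tuple(raw.get("clip", (0.0, 3000.0)))
    if len(clip) != 2 or not clip[0] < clip[1]:
        errors.append(f"clip must be (lo, hi) with lo < hi, got {clip}")
    pct = float(raw.get("background_percentile", 1.0))
    if not 0 < pct < 100:
        errors.append(f"background_percentile must lie in (0, 100), got {pct}")
    resample_mm = float(raw.get("resample_mm", 1.0))
    if resample_mm <= 0:
        errors.append("resample_mm must be positive")

    bootstrap = raw.get("bootstrap") or {}
    tumor_cfg = raw.get("tumor_analysis") or {}
    _fail(errors)

    return ExperimentConfig(
        output_dir=resolve(raw["output_dir"]),
        sequences=sequences,
        variants=variants,
        phantom=dict(phantom_cfg) if phantom_cfg is not None else None,
        data_dir=data_dir,
        backend_kind=kind,
        windows_path=windows_path,
        command=backend.get("command"),
        class_map_path=class_map_path,
        mapping_path=mapping_path,
        resample_mm=resample_mm,
        clip=(float(clip[0]), float(clip[1])),
        background_percentile=pct,
        n_boot=int(bootstrap.get("n_boot", 2000)),
        bootstrap_seed=int(bootstrap.get("seed", 0)),
        tumor_class=str(raw.get("tumor_class", "tumor")),
        tumor_sequence=str(tumor_cfg.get("sequence", "T1w")),
        tumor_variant=str(tumor_cfg.get("variant", "inverted_black")),
        raw=dict(raw),
    )


def _load_cases(config: ExperimentConfig):
    """Yield (case_id, {sequence: Volume}, truth LabelMap)."""
    if config.phantom is not None:
        p = config.phantom
        spec = PhantomSpec(
            grid_shape=tuple(p.get("grid_shape", (96, 96, 96))),
            spacing_mm=tuple(p.get("spacing_mm", (2.0, 2.0, 2.0))),
            noise_sd=float(p.get("noise_sd", 8.0)),
            bias_amplitude=float(p.get("bias_amplitude", 0.015)),
            psf_sigma_mm=float(p.get("psf_sigma_mm", 1.0)),
        )
        cases = generate_cohort(
            n=int(p["n"]),
            master_seed=int(p.get("master_seed", 0)),
            tumor_volume_range_cm3=tuple(p.get("tumor_volume_range_cm3", (1.0, 200.0))),
            side_fractions=tuple(p.get("side_fractions", (0.45, 0.55))),
            base_spec=spec,
        )
        for case in cases:
            volumes = {s: case.volume(s) for s in config.sequences}
            yield case.case_id, volumes, case.truth
    else:
        case_dirs = sorted(d for d in config.data_dir.iterdir() if d.is_dir())
        if not case_dirs:
            raise PipelineError(f"no case subdirectories in {config.data_dir}")
        for d in case_dirs:
            volumes = {}
            for s in config.sequences:
                f = d / SEQUENCE_FILES[s]
                if not f.exists():
                    raise PipelineError(f"missing {SEQUENCE_FILES[s]} in case {d.name}")
                volumes[s] = read_volume(f, modality_tag=s)
            yield d.name, volumes, read_labelmap(d / "truth.nii.gz")


def _make_backend(config: ExperimentConfig):
    if config.backend_kind == "windows":
        windows = (load_windows(config.windows_path) if config.windows_path
                   else default_windows())
        return make_window_backend(windows)
    class_map = None
    if config.class_map_path:
        class_map = {str(k): int(v)
                     for k, v in json.loads(config.class_map_path.read_text()).items()}
    workroot = config.output_dir / "external_work"

    def backend(v):
        return external_segment(config.command, v, workroot, class_map=class_map)

    return backend


def _config_hash(raw: dict) -> str:
    return hashlib.sha256(json.dumps(raw, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full experiment grid; returns the report directory.

    Backend failures are recorded per case and the run continues; if
    more than half of all cases fail, a :class:`PipelineError` is raised
    after the report is written.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    backend = _make_backend(config)
    variants = {name: PreprocessVariant(name=name, clip_lo=config.clip[0],
                                        clip_hi=config.clip[1],
                                        background_percentile=config.background_percentile)
                for name in config.variants}

    table = EvalTable(provenance={"config_hash": _config_hash(config.raw),
                                  "package_version": __version__})
    mapping = None
    if config.mapping_path:
        mapping = ClassMapping.from_dict(json.loads(config.mapping_path.read_text()))
    localization: dict[str, str] = {}
    failures: list[str] = []
    n_cases = 0

    for case_id, volumes, truth in _load_cases(config):
        n_cases += 1
        t0 = time.perf_counter()
        try:
            truth_iso = resample_isotropic(truth, config.resample_mm)
            case_mapping = mapping or ClassMapping.identity(truth_iso.vocabulary.values())
            for sequence, volume in volumes.items():
                vol_iso = resample_isotropic(volume, config.resample_mm)
                for vname, variant in variants.items():
                    pred = backend(preprocess(vol_iso, variant))
                    table.extend(evaluate_case(
                        pred, truth_iso, case_mapping, case_id=case_id,
                        sequence=sequence, variant=vname))
                    if sequence == config.tumor_sequence and vname == config.tumor_variant:
                        try:
                            ref_mask = truth_iso.mask(truth_iso.id_of(config.tumor_class))
                            pred_mask = pred.mask(pred.id_of(config.tumor_class))
                            if ref_mask.any():
                                localization[case_id] = classify_localization(pred_mask, ref_mask)
                        except KeyError:
                            pass
            log_lines.append(f"{case_id}\tok\t{time.perf_counter() - t0:.2f}s")
        except Exception as exc:  # noqa: BLE001 — per-case isolation is the contract
            failures.append(case_id)
            log_lines.append(f"{case_id}\tFAILED\t{exc}")

    frame = table.to_frame()
    frame.to_csv(out / "records.csv", index=False, float_format="%.10g")

    if not frame.empty:
        summary = summarize(table, n_boot=config.n_boot, seed=config.bootstrap_seed)
        summary.to_csv(out / "summary.csv", index=False, float_format="%.10g")
        wide = summary.pivot(index="sequence", columns="variant", values="mean_dsc")
        wide = wide.reindex(index=[s for s in SEQUENCES if s in wide.index],
                            columns=[v for v in VARIANT_NAMES if v in wide.columns])
        wide.to_csv(out / "summary_wide.csv", float_format="%.10g")
        _write_stats(config, table, out)
        _write_tumor_analysis(config, frame, localization, out)

    manifest = {
        "config": config.raw,
        "config_hash": _config_hash(config.raw),
        "package_version": __version__,
        "n_cases": n_cases,
        "n_failed": len(failures),
        "failed_cases": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    if n_cases and len(failures) > n_cases / 2:
        raise PipelineError(
            f"{len(failures)}/{n_cases} cases failed; see {out / 'run.log'}"
        )
    return out


def _variant_pairs(variants: Sequence[str]) -> list[tuple[str, str]]:
    return [(a, b) for i, a in enumerate(variants) for b in variants[i + 1:]]


def _write_stats(config: ExperimentConfig, table: EvalTable, out: Path) -> None:
    pairs = _variant_pairs(list(config.variants))
    if not pairs:
        pd.DataFrame(columns=["label", "sequence", "level"]).to_csv(
            out / "stats.csv", index=False)
        return
    comparisons = []
    levels = []
    for level in ("mean_per_case", "tumor"):
        rows = compare_variants(table, pairs, level=level,
                                tumor_class=config.tumor_class)
        comparisons.extend(rows)
        levels.extend([level] * len(rows))
    if comparisons:
        # one BH family across both comparison levels, per the report contract
        adjusted = bh_adjust([c.p_raw for c in comparisons])
        for c, adj in zip(comparisons, adjusted):
            c.p_adjusted = float(adj)
    stats_frame = comparisons_frame(comparisons)
    stats_frame.insert(2, "level", levels)
    stats_frame.to_csv(out / "stats.csv", index=False, float_format="%.10g")


def _write_tumor_analysis(config: ExperimentConfig, frame: pd.DataFrame,
                          localization: dict[str, str], out: Path) -> None:
    tumor = frame[(frame["sequence"] == config.tumor_sequence)
                  & (frame["variant"] == config.tumor_variant)
                  & (frame["class_name"] == config.tumor_class)
                  & (frame["ref_volume_cm3"] > 0)]
    payload: dict = {
        "sequence": config.tumor_sequence,
        "variant": config.tumor_variant,
        "localization_counts": {
            outcome: sum(1 for v in localization.values() if v == outcome)
            for outcome in ("correct", "incorrect", "not_detected")
        },
        "localization_by_case": dict(sorted(localization.items())),
    }
    if len(tumor) >= 2:
        payload["volume_stratification"] = stratify_by_volume(tumor)
    (out / "tumor_analysis.json").write_text(json.dumps(payload, indent=1))
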