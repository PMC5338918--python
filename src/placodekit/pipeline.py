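"""End-to-end orchestration: simulate -> segment -> measure.

A :class:`RunConfig` (plain-text YAML on disk) drives the stages; every
output directory receives the effective config echoed verbatim plus a
provenance record (config hash, package version, seed), and deterministic
stages are bit-identical across reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .areas import area_distribution, compare_distributions
from .dispersion import (clustering_permutation_test, dispersion_stats,
                         lower_quantile_cells, pit_relative_coordinates)
from .intensity import measure_scene_partitions
from .pulses import detect_peaks, interval_statistics
from .segmentation import SegmentationParams, segment_cells
from .synthetic import (PulsationConfig, SceneConfig, export_ground_truth,
                        generate_pulse_traces, generate_scene,
                        render_channels, scene_cell_table)

__all__ = ["RunConfig", "run_pipeline", "validate_tables",
           "CELL_TABLE_SCHEMA"]

log = logging.getLogger("placodekit")

#: documented CellTable column schema (name -> kind for validation)
CELL_TABLE_SCHEMA = {
    "cell_id": "integer",
    "area": "numeric",
    "centroid_x": "numeric",
    "centroid_y": "numeric",
    "depth": "numeric",
    "boundary_cell": "boolean",
    "placode_id": "any",
}


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``junction_path`` (TIFF; with optional ``mask_path``) points at
    real data, or ``simulate`` is true and two synthetic scenes (clustered
    and random area fields) are generated and analysed end to end.
    """

    out_dir: str = "placodekit_run"
    seed: int = 0
    pixel_size: float = 0.2
    simulate: bool = True
    junction_path: str | None = None
    myosin_path: str | None = None
    mask_path: str | None = None
    pit_center: tuple[float, float] | None = None
    scene: dict = dc_field(default_factory=dict)
    segmentation: dict = dc_field(default_factory=dict)
    pulsation: dict = dc_field(default_factory=dict)
    lower_quantile: float = 0.30
    n_perm: int = 999
    bin_width: float = 4.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_provenance(out: Path, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    (out / "provenance.json").write_text(json.dumps({
        "config_hash": config.config_hash,
        "version": __version__,
        "seed": config.seed,
    }, indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages; returns a result bundle of key outputs."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    _write_provenance(out, config)
    log.info("effective config:\n%s", config.to_yaml())
    try:
        if config.simulate:
            return _run_synthetic_demo(config, out)
        return _run_real_data(config, out)
    except Exception as exc:  # re-raise with the failing stage named
        stage = getattr(exc, "_stage", "pipeline")
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                exc._stage = name
                raise
        return wrapper
    return deco


@_stage("simulate")
def _make_scene(config: RunConfig, mode: str):
    scfg = SceneConfig(field_mode=mode, seed=config.seed,
                       pixel_size=config.pixel_size, **config.scene)
    scene = render_channels(generate_scene(scfg))
    return scene


@_stage("segment")
def _segment(scene, config: RunConfig):
    params = SegmentationParams(**config.segmentation)
    return segment_cells(scene.junction_image, scene.label_image > 0,
                         config.pixel_size, params)


def _run_synthetic_demo(config: RunConfig, out: Path) -> dict:
    bundle: dict = {}
    disp = {}
    for mode in ("clustered", "random"):
        mdir = out / mode
        _write_provenance(mdir, config)
        scene = _make_scene(config, mode)
        export_ground_truth(scene, mdir / "ground_truth")
        lab, table = _segment(scene, config)
        tifffile.imwrite(mdir / "segmentation_labels.tif",
                         lab.astype(np.uint16))
        _write_cell_table(table, mdir / "cells.csv")

        dist = area_distribution(table["area"], bin_width=config.bin_width,
                                 label=mode)
        dist.as_frame().to_csv(mdir / "area_distribution.csv", index=False)

        sub = lower_quantile_cells(table, config.lower_quantile)
        frame = pit_relative_coordinates(sub, scene.pit_center)
        stats = dispersion_stats(frame)
        stats["clustering_p"] = clustering_permutation_test(
            table, q=config.lower_quantile, n_perm=config.n_perm,
            seed=config.seed)
        disp[mode] = stats

        part = measure_scene_partitions(scene)
        part.to_csv(mdir / "intensity_partitions.csv", index=False)
        bundle[mode] = {"cells": table, "dispersion": stats,
                        "intensity": part, "scene": scene}

    comparison = {
        "sd_DV_clustered": disp["clustered"]["sd_DV"],
        "sd_DV_random": disp["random"]["sd_DV"],
        "clustered_more_compact":
            disp["clustered"]["sd_DV"] < disp["random"]["sd_DV"],
        "clustering_p": {m: disp[m]["clustering_p"]
                         for m in ("clustered", "random")},
    }
    (out / "dispersion_comparison.json").write_text(
        json.dumps(comparison, indent=2))
    bundle["dispersion_comparison"] = comparison

    pcfg = PulsationConfig(**config.pulsation)
    traces = generate_pulse_traces(pcfg, n_cells=14, seed=config.seed)
    for tr in traces:
        detect_peaks(tr)
    stats = interval_statistics(traces)
    stats_out = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in stats.items()}
    (out / "pulse_intervals.json").write_text(json.dumps(stats_out, indent=2))
    bundle["pulse_intervals"] = stats

    ab = compare_distributions(bundle["clustered"]["cells"]["area"],
                               bundle["random"]["cells"]["area"])
    (out / "area_comparison.json").write_text(json.dumps(ab, indent=2))
    bundle["area_comparison"] = ab
    return bundle


def _run_real_data(config: RunConfig, out: Path) -> dict:
    if not config.junction_path:
        raise FileNotFoundError("junction_path is required when simulate "
                                "is false")
    jpath = Path(config.junction_path)
    if not jpath.exists():
        raise FileNotFoundError(f"junction channel not found: {jpath}")
    junction = tifffile.imread(jpath).astype(float)
    if junction.ndim == 3:
        junction = junction.max(axis=0)
    if config.mask_path:
        mpath = Path(config.mask_path)
        if not mpath.exists():
            raise FileNotFoundError(f"mask not found: {mpath}")
        mask = tifffile.imread(mpath) > 0
    else:
        mask = np.ones(junction.shape, dtype=bool)
    params = SegmentationParams(**config.segmentation)
    lab, table = segment_cells(junction, mask, config.pixel_size, params)
    tifffile.imwrite(out / "segmentation_labels.tif", lab.astype(np.uint16))
    _write_cell_table(table, out / "cells.csv")
    dist = area_distribution(table["area"], bin_width=config.bin_width)
    dist.as_frame().to_csv(out / "area_distribution.csv", index=False)
    bundle = {"cells": table, "labels": lab, "area_distribution": dist}
    if config.pit_center is not None:
        sub = lower_quantile_cells(table, config.lower_quantile)
        frame = pit_relative_coordinates(sub, config.pit_center)
        bundle["dispersion"] = dispersion_stats(frame)
        (out / "dispersion.json").write_text(
            json.dumps(bundle["dispersion"], indent=2))
    return bundle


def _write_cell_table(table: pd.DataFrame, path: Path) -> None:
    import shapely
    out = table.copy()
    if "polygon" in out.columns:
        out["polygon"] = [
            shapely.Polygon(np.asarray(p)).wkt if len(p) >= 3 else ""
            for p in out["polygon"]]
    out.to_csv(path, index=False)


def validate_tables(paths: list[str | Path],
                    schema: dict | None = None) -> dict:
    """Check CSV tables against the documented CellTable schema.

    Returns a report per file: missing columns are violations, extra
    columns a warning, unparsable types violations naming the column.
    """
    schema = schema or CELL_TABLE_SCHEMA
    report: dict = {}
    for p in paths:
        p = Path(p)
        entry = {"ok": True, "violations": [], "warnings": []}
        try:
            df = pd.read_csv(p)
        except Exception as exc:
            report[str(p)] = {"ok": False,
                              "violations": [f"unreadable: {exc}"],
                              "warnings": []}
            continue
        for col, kind in schema.items():
            if col not in df.columns:
                entry["violations"].append(f"missing column: {col}")
                continue
            s = df[col]
            if kind == "integer" and not pd.api.types.is_integer_dtype(s):
                entry["violations"].append(f"column {col} not integer")
            elif kind == "numeric" and not pd.api.types.is_numeric_dtype(s):
                entry["violations"].append(f"column {col} not numeric")
            elif kind == "boolean" and not (
                    pd.api.types.is_bool_dtype(s)
                    or set(s.dropna().unique()) <= {True, False, 0, 1,
                                                    "True", "False"}):
                entry["violations"].append(f"column {col} not boolean")
        extra = set(df.columns) - set(schema) - {"polygon"}
        if extra:
            entry["warnings"].append(f"extra columns: {sorted(extra)}")
        entry["ok"] = not entry["violations"]
        report[str(p)] = entry
    return report
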