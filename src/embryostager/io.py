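"""Configuration, readers/writers, run manifests and pipeline drivers.

The configuration defaults encode the published analysis constants (3x3
mean filter, 2x2 Gaussian, 150x150 and 15/10 local-threshold windows, LoG
scale ranges (5, 15) / (1, 10), per-dataset rotation angles).  Every run
writes a manifest with the tool version, a reproducible configuration
hash and input checksums, so results can be traced back to their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, synth
from .errors import ConfigurationError
from .length import LengthConfig, aggregate_curves, length_timeseries, tip_kinematics
from .nuclei import (
    DATASET_ROTATION_ANGLES,
    NucleiConfig,
    PoleCellConfig,
    count_pole_cells_3d,
    nuclei_stats,
    segment_nuclei_2d,
    summarize_counts,
)
from .staging import aggregate_staging, read_staging_tables, stage_durations
from .types import ImageFrame, ImageStack

PIPELINES = ("synth", "length", "tip", "nuclei", "polecells", "staging")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable parameters of the pipelines, with published defaults."""

    pixel_size: float | None = None              # micrometres / pixel
    voxel_size: tuple[float, float, float] | None = None
    posterior_end: str = "max_y"
    posterior_offset: int = 150
    posterior_size: int = 150
    length: LengthConfig = field(default_factory=LengthConfig)
    nuclei: NucleiConfig = field(default_factory=NucleiConfig)
    polecells: PoleCellConfig = field(default_factory=PoleCellConfig)
    rotation_angles: dict = field(default_factory=lambda: dict(DATASET_ROTATION_ANGLES))

    def validate(self) -> None:
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        if self.voxel_size is not None and any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be positive")
        if self.posterior_end not in ("max_y", "min_y"):
            raise ConfigurationError("posterior_end must be 'max_y' or 'min_y'")
        if self.length.mean_range <= 0 or self.length.mean_range % 2 == 0:
            raise ConfigurationError("length.mean_range must be odd and positive")
        for name, window in (
            ("length.threshold_window", self.length.threshold_window),
            ("nuclei.local_range", self.nuclei.local_range),
            ("polecells.local_range", self.polecells.local_range),
            ("posterior_offset", self.posterior_offset),
            ("posterior_size", self.posterior_size),
        ):
            if int(window) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name, (lo, hi) in (
            ("nuclei.log_scales", self.nuclei.log_scales),
            ("polecells.log_scales", self.polecells.log_scales),
        ):
            if not 0 < lo <= hi:
                raise ConfigurationError(f"{name} must satisfy 0 < min <= max")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, payload: dict):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - names
            if unknown:
                raise ConfigurationError(
                    f"unknown config keys for {dc_type.__name__}: {sorted(unknown)}"
                )
            return dc_type(**payload)

        data = dict(data)
        sub = {}
        for key, dc_type in (("length", LengthConfig), ("nuclei", NucleiConfig),
                             ("polecells", PoleCellConfig)):
            if key in data:
                payload = data.pop(key) or {}
                for k, v in payload.items():
                    if isinstance(v, list):
                        payload[k] = tuple(v)
                sub[key] = build(dc_type, payload)
        for k, v in data.items():
            if isinstance(v, list):
                data[k] = tuple(v)
        cfg = build(cls, {**data, **sub})
        cfg.validate()
        return cfg


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# image I/O
# --------------------------------------------------------------------------

def read_image(
    path,
    pixel_size: float | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    dataset_id: str | None = None,
    timepoint_id: str | None = None,
):
    """Read a TIFF as an :class:`ImageFrame` (single page) or
    :class:`ImageStack` (multi-page, pages = z planes)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image not found: {path}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt / unsupported
        raise IOError(f"could not read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        return ImageFrame(data=data, pixel_size=pixel_size)
    if data.ndim == 3:
        return ImageStack(data=data, voxel_size=voxel_size,
                          dataset_id=dataset_id, timepoint_id=timepoint_id)
    raise IOError(f"unsupported TIFF dimensionality {data.ndim} in {path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    pipeline: str
    tool_version: str
    config_hash: str
    seed: int | None
    inputs: dict
    outputs: list
    warnings: list
    created: str = ""

    def write(self, path) -> None:
        payload = asdict(self)
        payload["created"] = payload["created"] or datetime.now(timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------------
# pipeline drivers
# --------------------------------------------------------------------------

def run_pipeline(
    name: str,
    config: PipelineConfig,
    out_dir,
    inputs: list | None = None,
    seed: int = 0,
) -> RunManifest:
    """Run one named pipeline end to end and write outputs plus manifest.

    All validation happens before any computation starts; warnings raised
    during the run are captured into the manifest.
    """
    if name not in PIPELINES:
        raise ConfigurationError(f"unknown pipeline {name!r}; choose from {PIPELINES}")
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = [Path(p) for p in (inputs or [])]
    for p in inputs:
        if not p.exists():
            raise IOError(f"input not found: {p}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        outputs = _DISPATCH[name](config, inputs, out_dir, seed)

    manifest = RunManifest(
        pipeline=name,
        tool_version=__version__,
        config_hash=config.config_hash(),
        seed=seed,
        inputs={str(p): _sha256(p) for p in inputs},
        outputs=[str(p) for p in outputs],
        warnings=[str(w.message) for w in caught],
    )
    manifest.write(out_dir / f"{name}_manifest.json")
    return manifest


def _run_synth(config: PipelineConfig, inputs, out_dir: Path, seed: int) -> list:
    spec = synth.SyntheticEmbryoSpec(rng_seed=seed)
    frames, truth = synth.generate_embryo_movie(spec)
    synth.write_movie(out_dir / "movie.tif", frames)
    synth.write_ground_truth_lengths(out_dir / "movie_truth.csv", truth)
    synth.write_spec(out_dir / "movie_spec.yaml", spec)

    window, wtruth = synth.generate_nuclei_window(25, sigma=3.0, seed=seed + 1)
    synth.write_movie(out_dir / "nuclei_window.tif", window[np.newaxis])
    pd.DataFrame(wtruth.centers, columns=["row", "col"]).to_csv(
        out_dir / "nuclei_window_truth.csv", index=False
    )

    stack, struth = synth.generate_pole_cell_stack(27, tilt_angle=-40.0, seed=seed + 2)
    synth.write_movie(out_dir / "pole_cells.tif", stack)

    tables, _ = synth.generate_stage_table(5, seed=seed + 3)
    from .staging import write_staging_tables

    write_staging_tables(tables, out_dir / "stage_tables.csv")
    return [out_dir / n for n in (
        "movie.tif", "movie_truth.csv", "movie_spec.yaml",
        "nuclei_window.tif", "nuclei_window_truth.csv",
        "pole_cells.tif", "stage_tables.csv",
    )]


def _run_length(config: PipelineConfig, inputs, out_dir: Path, seed: int) -> list:
    if not inputs:
        raise ConfigurationError("length pipeline needs a movie TIFF input")
    outputs = []
    series = []
    for path in inputs:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            raise ConfigurationError("length pipeline needs a multi-page TIFF movie")
        times_csv = path.with_suffix(".times.csv")
        times = pd.read_csv(times_csv)["time_h"].to_numpy() if times_csv.exists() else None
        s = length_timeseries(frames, times_h=times, cfg=config.length,
                              dataset_id=path.stem, pixel_size=config.pixel_size)
        series.append(s)
        out = out_dir / f"{path.stem}_lengths.csv"
        s.to_frame().to_csv(out, index=False)
        outputs.append(out)
    if len(series) >= 2:
        agg = aggregate_curves(series)
        out = out_dir / "length_aggregate.csv"
        agg.to_frame().to_csv(out, index=False)
        outputs.append(out)
    return outputs


def _run_tip(config: PipelineConfig, inputs, out_dir: Path, seed: int) -> list:
    if not inputs:
        raise ConfigurationError("tip pipeline needs an annotations CSV input")
    if config.pixel_size is None:
        raise ConfigurationError("tip pipeline needs pixel_size in the config")
    outputs = []
    for path in inputs:
        kin = tip_kinematics(pd.read_csv(path), config.pixel_size)
        out = out_dir / f"{path.stem}_kinematics.csv"
        kin.to_csv(out, index=False)
        outputs.append(out)
    return outputs


def _run_nuclei(config: PipelineConfig, inputs, out_dir: Path, seed: int) -> list:
    if not inputs:
        raise ConfigurationError("nuclei pipeline needs window TIFF inputs")
    objects, summaries = [], []
    for path in inputs:
        window = np.squeeze(tifffile.imread(path))
        labels = segment_nuclei_2d(window, config.nuclei, pixel_size=config.pixel_size)
        stats = nuclei_stats(labels, pixel_size=config.pixel_size, timepoint_id=path.stem)
        table = labels.table()
        table.insert(0, "window", path.stem)
        objects.append(table)
        summaries.append(
            {
                "window": path.stem,
                "count": stats.count,
                "mean_area_px": stats.mean_area_px,
                "density_per_px2": stats.density_per_px2,
            }
        )
    obj_out = out_dir / "nuclei_objects.csv"
    sum_out = out_dir / "nuclei_summary.csv"
    pd.concat(objects, ignore_index=True).to_csv(obj_out, index=False) if objects else None
    pd.DataFrame(summaries).to_csv(sum_out, index=False)
    return [obj_out, sum_out]


def _dataset_of(path: Path) -> str | None:
    m = re.search(r"(DS\d{4})", path.stem)
    return m.group(1) if m else None


def _run_polecells(config: PipelineConfig, inputs, out_dir: Path, seed: int) -> list:
    if not inputs:
        raise ConfigurationError("polecells pipeline needs stack TIFF inputs")
    counts = []
    for path in inputs:
        stack = tifffile.imread(path)
        ds = _dataset_of(path) or path.stem
        angle = config.rotation_angles.get(ds, 0.0)
        counts.append(count_pole_cells_3d(stack, angle, config.polecells,
                                          dataset_id=ds, timepoint_id=path.stem))
    df = pd.DataFrame(
        [
            {"dataset": c.dataset_id, "timepoint": c.timepoint_id,
             "rotation_deg": c.rotation_angle, "count": c.count}
            for c in counts
        ]
    )
    out = out_dir / "pole_cell_counts.csv"
    df.to_csv(out, index=False)
    outputs = [out]
    if len(counts) >= 2:
        mean, sd = summarize_counts(counts)
        out2 = out_dir / "pole_cell_summary.csv"
        pd.DataFrame([{"n_stacks": len(counts), "mean": mean, "sd": sd}]).to_csv(out2, index=False)
        outputs.append(out2)
    return outputs


def _run_staging(config: PipelineConfig, inputs, out_dir: Path, seed: int) -> list:
    if not inputs:
        raise ConfigurationError("staging pipeline needs a stage-table CSV input")
    tables = []
    for path in inputs:
        tables.extend(read_staging_tables(path))
    rows = []
    for t in tables:
        d_abs = stage_durations(t)
        d_norm = stage_durations(t, normalized=True)
        for s in range(len(d_abs)):
            rows.append({"dataset": t.dataset_id, "stage": s + 1,
                         "duration_h": d_abs[s], "duration_norm": d_norm[s]})
    dur_out = out_dir / "stage_durations.csv"
    pd.DataFrame(rows).to_csv(dur_out, index=False)
    outputs = [dur_out]
    if len(tables) >= 2:
        agg = aggregate_staging(tables)
        for key, frame in agg.items():
            out = out_dir / f"staging_aggregate_{key}.csv"
            frame.to_csv(out, index=False)
            outputs.append(out)
    return outputs


_DISPATCH = {
    "synth": _run_synth,
    "length": _run_length,
    "tip": _run_tip,
    "nuclei": _run_nuclei,
    "polecells": _run_polecells,
    "staging": _run_staging,
}
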