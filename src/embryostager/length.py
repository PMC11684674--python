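"""Embryo length dynamics and germband-tip kinematics.

The embryo length of a frame is the largest extension along y of the
convex hull of the largest bright object, obtained with the five-step
recipe: crop to the region of interest, 3x3 mean smoothing, local-mean
thresholding in a 150x150 window, retention of the largest connected
component, convex hull.  Frames must be pre-aligned so the
anterior-posterior axis runs along y (rows).

Cross-dataset curves are compared on a normalized time axis (fraction of
embryonic development) with per-gridpoint mean and sample standard
deviation; peaks of the SD channel flag developmental transitions with
elevated inter-individual variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import ops
from .errors import ConfigurationError, EmbryoNotFoundError, EmptyMaskError
from .staging import StagingTable, classify_time
from .types import as_array

__all__ = [
    "LengthConfig",
    "LengthSeries",
    "AggregateCurve",
    "measure_embryo_length",
    "length_timeseries",
    "aggregate_curves",
    "tip_kinematics",
    "detect_sd_peaks",
]


@dataclass
class LengthConfig:
    """Parameters of the length pipeline (defaults reproduce the recipe)."""

    crop: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)
    mean_range: int = 3
    threshold_window: int = 150


@dataclass
class LengthSeries:
    """Per-timepoint embryo extent for one dataset."""

    dataset_id: str
    time_h: np.ndarray
    length_px: np.ndarray       # NaN where a frame failed
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.length_px = np.asarray(self.length_px, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        valid = self.length_px[np.isfinite(self.length_px)]
        if valid.size == 0:
            raise EmbryoNotFoundError("no frame yielded a length")
        if np.any(valid <= 0):
            raise ConfigurationError("lengths must be positive")

    @property
    def length_um(self) -> np.ndarray:
        if self.pixel_size is None:
            raise ConfigurationError("pixel_size unknown")
        return self.length_px * self.pixel_size

    @property
    def normalized_length(self) -> np.ndarray:
        """Length as a fraction of the first measured frame."""
        first = self.length_px[np.isfinite(self.length_px)][0]
        return self.length_px / first

    @property
    def normalized_time(self) -> np.ndarray:
        """Elapsed time as a fraction of the recorded span."""
        t = self.time_h
        return (t - t[0]) / (t[-1] - t[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "dataset": self.dataset_id,
                "time_h": self.time_h,
                "length_px": self.length_px,
                "norm_time": self.normalized_time,
                "norm_length": self.normalized_length,
            }
        )
        if self.pixel_size is not None:
            df["length_um"] = self.length_um
        return df


@dataclass
class AggregateCurve:
    """Pointwise mean and sample SD of normalized curves on a common grid."""

    grid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"norm_time": self.grid, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


def measure_embryo_length(frame, cfg: LengthConfig | None = None) -> int:
    """Embryo extent along y in pixels for a single aligned frame."""
    cfg = cfg or LengthConfig()
    img = np.asarray(as_array(frame), dtype=float)
    if cfg.crop is not None:
        r0, r1, c0, c1 = cfg.crop
        img = img[r0:r1, c0:c1]
    smooth = ops.mean_filter(img, cfg.mean_range)
    mask = ops.local_mean_threshold(smooth, cfg.threshold_window)
    try:
        blob = ops.largest_component(mask)
        _, extent = ops.convex_hull_extent(blob)
    except EmptyMaskError as exc:
        raise EmbryoNotFoundError("embryo not found in frame") from exc
    return extent


def length_timeseries(
    frames,
    times_h=None,
    cfg: LengthConfig | None = None,
    dataset_id: str = "DS",
    pixel_size: float | None = None,
) -> LengthSeries:
    """Measure every frame of a movie; failures are recorded, not fatal.

    ``frames`` is a (T, rows, cols) array or a sequence of frames;
    ``times_h`` defaults to the frame index.  A frame in which no embryo
    is found contributes NaN and a warning.
    """
    arr = [np.asarray(as_array(f), dtype=float) for f in frames]
    if len(arr) < 2:
        raise ConfigurationError("need at least two frames for a time series")
    t = np.arange(len(arr), dtype=float) if times_h is None else np.asarray(times_h, dtype=float)
    if t.shape != (len(arr),):
        raise ConfigurationError("times_h length must match frame count")
    lengths = np.full(len(arr), np.nan)
    for i, frame in enumerate(arr):
        try:
            lengths[i] = measure_embryo_length(frame, cfg)
        except EmbryoNotFoundError:
            warnings.warn(f"frame {i}: embryo not found; recorded as missing", stacklevel=2)
    return LengthSeries(dataset_id=dataset_id, time_h=t, length_px=lengths, pixel_size=pixel_size)


def aggregate_curves(series_list: list[LengthSeries], n_grid: int = 1000) -> AggregateCurve:
    """Mean and sample SD of normalized length over normalized time.

    Each series is linearly interpolated onto ``n_grid`` evenly spaced
    normalized timepoints; missing frames are bridged by the same linear
    interpolation.  Pixel size cancels in the normalization, so mixed
    calibrations aggregate cleanly.
    """
    if len(series_list) < 2:
        raise ConfigurationError("need at least two series to aggregate")
    grid = np.linspace(0.0, 1.0, n_grid)
    stack = []
    for s in series_list:
        tt = s.normalized_time
        ll = s.normalized_length
        ok = np.isfinite(ll)
        if ok.sum() < 2:
            raise ConfigurationError(f"series {s.dataset_id} has fewer than two valid frames")
        stack.append(np.interp(grid, tt[ok], ll[ok]))
    stack = np.stack(stack)
    return AggregateCurve(
        grid=grid,
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        n=len(series_list),
    )


def tip_kinematics(annotations: pd.DataFrame, pixel_size: float) -> pd.DataFrame:
    """Cumulative germband-tip migration distance and per-interval speed.

    ``annotations`` columns: ``time_h``, ``row``, ``col`` (manual tip
    positions in the z-maximum projection).  Distance is the running sum
    of straight Euclidean steps between successive annotations times
    ``pixel_size``; speed is step length over step duration.  The first
    row carries speed NaN (no preceding interval).
    """
    if len(annotations) < 2:
        raise ConfigurationError("need at least two annotated timepoints")
    df = annotations.sort_values("time_h").reset_index(drop=True)
    t = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(t) == 0):
        raise ConfigurationError("duplicate timestamps in tip annotations")
    pos = df[["row", "col"]].to_numpy(dtype=float)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) * pixel_size
    dt = np.diff(t)
    out = pd.DataFrame(
        {
            "time_h": t,
            "cumulative_distance_um": np.concatenate([[0.0], np.cumsum(steps)]),
            "speed_um_per_h": np.concatenate([[np.nan], steps / dt]),
        }
    )
    return out


def detect_sd_peaks(
    curve: AggregateCurve,
    min_prominence: float,
    staging_table: StagingTable | None = None,
) -> pd.DataFrame:
    """Local maxima of the SD channel exceeding a prominence threshold.

    Returns a frame with the peak positions in normalized time and SD
    height; if a staging table is supplied each peak is also mapped to its
    stage and event.
    """
    idx, props = find_peaks(curve.sd, prominence=min_prominence)
    out = pd.DataFrame(
        {
            "norm_time": curve.grid[idx],
            "sd": curve.sd[idx],
            "prominence": props.get("prominences", np.zeros(len(idx))),
        }
    )
    if staging_table is not None and len(out):
        assigned = [classify_time(t, staging_table, normalized=True) for t in out["norm_time"]]
        out["stage"] = [a.stage for a in assigned]
        out["event"] = [a.event for a in assigned]
    return out
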