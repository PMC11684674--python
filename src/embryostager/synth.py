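"""Synthetic recordings with exact ground truth.

The generators emulate the statistical structure of nuclear-labelled
light-sheet recordings of a fly embryo so that every downstream stage of
the quantification pipelines can be exercised without any real data:

* an elongated ellipsoidal embryo (z-maximum projection) whose
  anterior–posterior extent follows a prescribed relative-length
  trajectory, with Gaussian-spot surface nuclei along the rim;
* square analysis windows filled with non-overlapping Gaussian-spot
  nuclei at controllable count and radius;
* an anisotropy-aware 3D stack holding a tightly clustered group of
  pole-cell nuclei, optionally tilted about the rotation axis so the
  counting pipeline's de-rotation step is exercised.

Every generator is a pure function of its spec and seed: fixed seeds give
bit-identical output, and ground truth is exact by construction.  Noise is
shot (Poisson) followed by additive Gaussian read noise; both optional,
default on.  Nuclei are isotropic Gaussian spots — real nuclei are
irregular, but spots suffice to exercise every operator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError
from .staging import N_STAGES, StagingTable

__all__ = [
    "SyntheticEmbryoSpec",
    "EmbryoGroundTruth",
    "NucleiGroundTruth",
    "PoleCellGroundTruth",
    "generate_embryo_movie",
    "generate_nuclei_window",
    "generate_pole_cell_stack",
    "generate_stage_table",
    "DEFAULT_STAGE_DURATIONS_H",
    "default_mean_boundaries",
    "write_movie",
    "write_ground_truth_lengths",
    "write_spec",
]

# Synthetic emulation defaults for a ~62.5 h embryogenesis, anchored on the
# qualitative timeline (long quiescent stage 5, ~7.5 h germband retraction,
# fast-then-slow germband elongation across stages 8-11).  These are
# invented, plausible values, not measured ones.
DEFAULT_STAGE_DURATIONS_H: tuple[float, ...] = (
    1.0, 1.5, 1.0, 1.5, 4.5,       # I   blastoderm formation
    1.0, 1.5,                      # II  early gastrulation
    2.0, 2.5, 3.0, 2.5,            # III germband elongation
    7.5,                           # IV  germband retraction
    5.0, 5.0, 6.0,                 # V   dorsal closure
    8.0, 9.0,                      # VI  muscular movement
)


def default_mean_boundaries(start_h: float = 0.0) -> np.ndarray:
    """The 18 default stage boundaries implied by the default durations."""
    return start_h + np.concatenate([[0.0], np.cumsum(DEFAULT_STAGE_DURATIONS_H)])


def _apply_noise(img: np.ndarray, rng: np.random.Generator,
                 poisson: bool, read_noise_sd: float) -> np.ndarray:
    out = np.asarray(img, dtype=float)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if read_noise_sd > 0:
        out = out + rng.normal(0.0, read_noise_sd, size=out.shape)
    return np.clip(out, 0, None)


def _add_gaussian_spot(img: np.ndarray, centre: Sequence[float],
                       sigma_px: Sequence[float], amplitude: float,
                       core_radius: float = 0.0) -> None:
    """Accumulate a nucleus spot in place, on a local patch.

    With ``core_radius = 0`` the spot is an (an)isotropic Gaussian.  A
    positive ``core_radius`` gives a flat-topped disc of that radius (in
    sigma-scaled units, i.e. isotropic in the scaled coordinates) whose
    edge rolls off as a Gaussian of width ``sigma_px`` — closer to the
    filled, sharp-edged appearance of real interphase nuclei.
    """
    slices, grids = [], []
    reach = core_radius + 4.0
    for ax, (c, s) in enumerate(zip(centre, sigma_px)):
        lo = max(0, int(np.floor(c - reach * s)))
        hi = min(img.shape[ax], int(np.ceil(c + reach * s)) + 1)
        if hi <= lo:
            return
        slices.append(slice(lo, hi))
        grids.append((np.arange(lo, hi) - c) / s)
    mesh = np.meshgrid(*grids, indexing="ij")
    r = np.sqrt(sum(g ** 2 for g in mesh))
    excess = np.clip(r - core_radius, 0.0, None)
    img[tuple(slices)] += amplitude * np.exp(-0.5 * excess ** 2)


# --------------------------------------------------------------------------
# embryo movie
# --------------------------------------------------------------------------

@dataclass
class SyntheticEmbryoSpec:
    """Recipe for a synthetic embryo movie (z-maximum projection series).

    ``embryo_semi_axes`` is ``(a, b)`` in pixels with ``a`` along y (the
    anterior–posterior axis) and ``b`` along x.  ``length_trajectory``
    maps time in hours to relative length (1.0 = initial); the embryo's
    y semi-axis is scaled by it frame by frame.  Surface nuclei sit on the
    ellipse rim, inset by three nucleus sigmas so their tails stay inside
    the true outline.
    """

    rng_seed: int
    frame_shape: tuple[int, int] = (512, 256)
    embryo_semi_axes: tuple[float, float] = (200.0, 80.0)
    length_trajectory: Callable[[float], float] | None = None
    n_frames: int = 30
    frame_interval: float = 0.5            # hours
    n_surface_nuclei: int = 120
    nucleus_sigma: float = 3.0             # pixels
    intensity_embryo: float = 300.0
    intensity_nucleus: float = 600.0
    background_level: float = 50.0
    poisson: bool = True
    read_noise_sd: float = 3.0
    pixel_size: float = 1.0                # micrometres / pixel

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def trajectory(self, t: float) -> float:
        return 1.0 if self.length_trajectory is None else float(self.length_trajectory(t))

    def validate(self) -> None:
        rows, cols = self.frame_shape
        a, b = self.embryo_semi_axes
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.nucleus_sigma <= 0:
            raise ConfigurationError("nucleus_sigma must be positive")
        if self.n_surface_nuclei < 0:
            raise ConfigurationError("counts must be >= 0")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
        svals = np.array([self.trajectory(t) for t in self.times()])
        if np.any(svals <= 0) or np.any(svals > 1.2):
            raise ConfigurationError("length_trajectory values must lie in (0, 1.2]")
        if 2 * a * svals.max() >= rows:
            raise ConfigurationError(
                f"embryo does not fit inside frame: 2*a*max_trajectory = "
                f"{2 * a * svals.max():.1f} >= {rows} rows"
            )
        if 2 * b >= cols:
            raise ConfigurationError("embryo wider than frame along x")


@dataclass
class EmbryoGroundTruth:
    """Exact per-frame truth for a synthetic embryo movie."""

    times_h: np.ndarray
    lengths_px: np.ndarray           # 2 * a * trajectory(t), exact
    lengths_um: np.ndarray
    nucleus_centers: list[np.ndarray]  # per frame, (n, 2) row/col
    n_nuclei: int


def generate_embryo_movie(spec: SyntheticEmbryoSpec) -> tuple[np.ndarray, EmbryoGroundTruth]:
    """Render the movie described by ``spec`` and return it with its truth."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    rows, cols = spec.frame_shape
    a, b = spec.embryo_semi_axes
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.mgrid[:rows, :cols]
    theta = rng.uniform(0.0, 2 * np.pi, size=spec.n_surface_nuclei)

    times = spec.times()
    frames = np.empty((spec.n_frames, rows, cols), dtype=float)
    centers_per_frame: list[np.ndarray] = []
    lengths = np.empty(spec.n_frames)
    inset = 3.0 * spec.nucleus_sigma
    for i, t in enumerate(times):
        s = spec.trajectory(t)
        lengths[i] = 2.0 * a * s
        frame = np.full((rows, cols), spec.background_level, dtype=float)
        inside = ((yy - cy) / (a * s)) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        frame[inside] += spec.intensity_embryo
        cy_n = cy + (a * s - inset) * np.cos(theta)
        cx_n = cx + (b - inset) * np.sin(theta)
        centers = np.column_stack([cy_n, cx_n])
        centers_per_frame.append(centers)
        for c in centers:
            _add_gaussian_spot(frame, c, (spec.nucleus_sigma,) * 2, spec.intensity_nucleus)
        frames[i] = _apply_noise(frame, rng, spec.poisson, spec.read_noise_sd)
    truth = EmbryoGroundTruth(
        times_h=times,
        lengths_px=lengths,
        lengths_um=lengths * spec.pixel_size,
        nucleus_centers=centers_per_frame,
        n_nuclei=spec.n_surface_nuclei,
    )
    return frames, truth


# --------------------------------------------------------------------------
# nuclei windows
# --------------------------------------------------------------------------

@dataclass
class NucleiGroundTruth:
    """Exact truth for a synthetic nuclei window."""

    centers: np.ndarray        # (n, 2) row/col
    count: int
    halfmax_areas_px: np.ndarray  # pixels above half the spot maximum

    @property
    def mean_halfmax_area(self) -> float:
        return float(self.halfmax_areas_px.mean()) if self.count else 0.0


def _halfmax_area(centre: Sequence[float], sigma: float, shape: tuple[int, int],
                  core_radius: float = 0.0) -> int:
    """Pixels whose centre lies where the spot exceeds half its maximum."""
    r_half = core_radius + sigma * np.sqrt(2.0 * np.log(2.0))
    cy, cx = centre
    reach = r_half + 2 * sigma
    lo_y, hi_y = int(np.floor(cy - reach)), int(np.ceil(cy + reach)) + 1
    lo_x, hi_x = int(np.floor(cx - reach)), int(np.ceil(cx + reach)) + 1
    yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
    return int(np.sum((yy - cy) ** 2 + (xx - cx) ** 2 < r_half ** 2))


def _place_points(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    min_sep: float,
    max_tries: int,
) -> np.ndarray:
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise ConfigurationError(
                f"placement infeasible after {max_tries} attempts: "
                f"reduce the count or the spot size"
            )
        tries += 1
        cand = rng.uniform(low, high)
        if all(np.sum((cand - p) ** 2) >= min_sep ** 2 for p in pts):
            pts.append(cand)
    return np.array(pts).reshape(n, len(low))


def generate_nuclei_window(
    n: int,
    sigma: float = 3.0,
    window: int = 150,
    amplitude: float = 500.0,
    background: float = 100.0,
    poisson: bool = True,
    read_noise_sd: float = 3.0,
    seed: int = 0,
    core_radius: float = 0.0,
    min_sep: float | None = None,
    margin: float | None = None,
    max_tries_per_point: int = 2000,
) -> tuple[np.ndarray, NucleiGroundTruth]:
    """A square window holding exactly ``n`` non-overlapping nucleus spots.

    With ``core_radius = 0`` (default) nuclei are plain Gaussian spots of
    width ``sigma``; a positive ``core_radius`` (pixels) gives flat-topped
    discs with a Gaussian edge of width ``sigma``, whose thresholded area
    tracks the squared radius the way real, sharp-edged nuclei do.
    Centres are rejection-sampled with minimum separation
    ``4 * sigma + 2 * core_radius`` (default) and kept that far from the
    window border so border removal cannot eat true objects.  ``n = 0``
    yields a pure-noise window.
    """
    if n < 0:
        raise ConfigurationError("count must be >= 0")
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    if core_radius < 0:
        raise ConfigurationError("core_radius must be >= 0")
    rng = np.random.default_rng(seed)
    min_sep = 4.0 * sigma + 2.0 * core_radius if min_sep is None else min_sep
    margin = 4.0 * sigma + core_radius if margin is None else margin
    img = np.full((window, window), background, dtype=float)
    if n > 0:
        lo = np.array([margin, margin])
        hi = np.array([window - 1 - margin, window - 1 - margin])
        if np.any(hi <= lo):
            raise ConfigurationError("window too small for the requested margin")
        centers = _place_points(rng, n, lo, hi, min_sep, n * max_tries_per_point)
        for c in centers:
            _add_gaussian_spot(img, c, (sigma, sigma), amplitude,
                               core_radius=core_radius / sigma)
        areas = np.array([_halfmax_area(c, sigma, img.shape, core_radius) for c in centers])
    else:
        centers = np.zeros((0, 2))
        areas = np.zeros(0, dtype=int)
    img = _apply_noise(img, rng, poisson, read_noise_sd)
    return img, NucleiGroundTruth(centers=centers, count=n, halfmax_areas_px=areas)


# --------------------------------------------------------------------------
# pole-cell stacks
# --------------------------------------------------------------------------

@dataclass
class PoleCellGroundTruth:
    """Exact truth for a synthetic pole-cell stack."""

    centers_index: np.ndarray      # (n, 3) z/y/x index coordinates as rendered
    centers_untilted: np.ndarray   # same cluster before the tilt was applied
    count: int
    tilt_angle: float


def generate_pole_cell_stack(
    n: int,
    cluster_radius: float = 16.0,
    shape: tuple[int, int, int] = (48, 64, 48),
    blob_sigma: float = 2.0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    tilt_angle: float = 0.0,
    amplitude: float = 800.0,
    background: float = 50.0,
    poisson: bool = True,
    read_noise_sd: float = 3.0,
    seed: int = 0,
    min_sep: float | None = None,
    max_tries_per_point: int = 4000,
) -> tuple[np.ndarray, PoleCellGroundTruth]:
    """A 3D stack holding ``n`` clustered nucleus blobs, tilted about y.

    Blob centres are sampled in physical coordinates inside a ball of
    ``cluster_radius`` around the stack centre, with minimum separation
    ``4 * blob_sigma`` (default).  A positive ``tilt_angle`` rotates the
    cluster in the ``(z, x)`` plane with the same convention as
    :func:`embryostager.ops.rotate_about_y`, so de-rotating the stack by
    ``-tilt_angle`` restores an axis-aligned cluster.  Anisotropic voxels
    squash the rendered blobs accordingly.
    """
    if n < 0:
        raise ConfigurationError("count must be >= 0")
    vs = np.asarray(voxel_size, dtype=float)
    if np.any(vs <= 0):
        raise ConfigurationError("voxel sizes must be positive")
    rng = np.random.default_rng(seed)
    min_sep = 4.0 * blob_sigma if min_sep is None else min_sep
    centre_phys = (np.array(shape) - 1) / 2.0 * vs

    if n > 0:
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n:
            if tries >= n * max_tries_per_point:
                raise ConfigurationError(
                    "placement infeasible: reduce the count, the separation "
                    "or enlarge cluster_radius"
                )
            tries += 1
            cand = rng.uniform(-cluster_radius, cluster_radius, size=3)
            if np.sum(cand ** 2) > cluster_radius ** 2:
                continue
            if all(np.sum((cand - p) ** 2) >= min_sep ** 2 for p in pts):
                pts.append(cand)
        offsets = np.array(pts)
    else:
        offsets = np.zeros((0, 3))

    theta = np.deg2rad(tilt_angle)
    rot = offsets.copy()
    # matches scipy.ndimage.rotate(axes=(0, 2)): (z, x) -> (z c - x s, z s + x c)
    rot[:, 0] = offsets[:, 0] * np.cos(theta) - offsets[:, 2] * np.sin(theta)
    rot[:, 2] = offsets[:, 0] * np.sin(theta) + offsets[:, 2] * np.cos(theta)

    centers_idx = (centre_phys + rot) / vs
    centers_untilted_idx = (centre_phys + offsets) / vs
    pad = 4.0 * blob_sigma / vs
    if n > 0 and (np.any(centers_idx - pad < 0)
                  or np.any(centers_idx + pad > np.array(shape) - 1)):
        raise ConfigurationError("cluster too large for stack")

    img = np.full(shape, background, dtype=float)
    sigma_idx = blob_sigma / vs
    for c in centers_idx:
        _add_gaussian_spot(img, c, sigma_idx, amplitude)
    img = _apply_noise(img, rng, poisson, read_noise_sd)
    truth = PoleCellGroundTruth(
        centers_index=centers_idx,
        centers_untilted=centers_untilted_idx,
        count=n,
        tilt_angle=tilt_angle,
    )
    return img, truth


# --------------------------------------------------------------------------
# staging tables
# --------------------------------------------------------------------------

def generate_stage_table(
    n_datasets: int,
    mean_boundaries: np.ndarray | None = None,
    boundary_sd: float | np.ndarray = 0.5,
    seed: int = 0,
) -> tuple[list[StagingTable], dict]:
    """Jittered per-dataset staging tables around a mean boundary set.

    Each dataset's 18 boundaries are the mean boundaries plus independent
    Gaussian jitter (per-boundary SD), re-sorted so they remain monotone.
    Returns the tables and the ground-truth means/SDs used.
    """
    if n_datasets < 1:
        raise ConfigurationError("need at least one dataset")
    means = default_mean_boundaries() if mean_boundaries is None else np.asarray(mean_boundaries, dtype=float)
    if means.shape != (N_STAGES + 1,):
        raise ConfigurationError(f"need {N_STAGES + 1} mean boundaries (17 stages)")
    if np.any(np.diff(means) <= 0):
        raise ConfigurationError("mean boundaries must be strictly increasing")
    sds = np.broadcast_to(np.asarray(boundary_sd, dtype=float), means.shape).copy()
    if np.any(sds < 0):
        raise ConfigurationError("boundary_sd must be non-negative")
    rng = np.random.default_rng(seed)
    tables = [
        StagingTable(f"SYN{i + 1:04d}", np.sort(means + rng.normal(0.0, sds)))
        for i in range(n_datasets)
    ]
    truth = {
        "mean_boundaries": means,
        "boundary_sd": sds,
        "mean_durations": np.diff(means),
    }
    return tables, truth


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_movie(path, frames: np.ndarray) -> None:
    """Write a frame series or stack as a multi-page 32-bit TIFF."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32), photometric="minisblack")


def write_ground_truth_lengths(path, truth: EmbryoGroundTruth) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(truth.times_h)),
            "time_h": truth.times_h,
            "length_px": truth.lengths_px,
            "length_um": truth.lengths_um,
        }
    ).to_csv(path, index=False)


def write_spec(path, spec: SyntheticEmbryoSpec) -> None:
    """Serialize a spec as YAML (the trajectory callable is noted, not stored)."""
    d = asdict(spec)
    d["length_trajectory"] = (
        "constant 1.0" if spec.length_trajectory is None else "<callable, not serialized>"
    )
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
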