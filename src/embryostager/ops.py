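"""Reusable image operators for the embryo quantification pipelines.

Every operator is deterministic: re-running on identical input yields a
bit-identical result.  All operators accept plain numpy arrays (2D frames
or 3D stacks); the calibrated container types wrap them at the pipeline
level.  Window sums are accumulated exactly for integer-valued images, so
threshold decisions are reproducible down to the last bit.

Connectivity defaults to the maximal neighbourhood (8 in 2D, 26 in 3D),
which avoids spuriously split nuclei; pass ``connectivity=1`` for the
minimal (4/6) neighbourhood.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.feature import blob_log

from .errors import (
    ConfigurationError,
    DegenerateHistogramError,
    EmptyMaskError,
    NoMarkersError,
)
from .types import SeedSet, as_array

__all__ = [
    "mean_filter",
    "gaussian_smooth",
    "local_mean_threshold",
    "otsu_threshold",
    "fill_holes",
    "largest_component",
    "convex_hull_extent",
    "log_seeds",
    "seeded_watershed",
    "apply_mask",
    "remove_border_objects",
    "resample_isotropic",
    "rotate_about_y",
]


def _check_window(window: int, name: str = "range") -> int:
    if not isinstance(window, (int, np.integer)) or window <= 0:
        raise ConfigurationError(f"{name} must be a positive integer, got {window!r}")
    return int(window)


def mean_filter(img, size: int = 3) -> np.ndarray:
    """Box mean with an odd ``size x size`` window and edge replication.

    ``size=3`` reproduces the smoothing used before the embryo-length
    threshold.  Borders are handled by edge replication, so a constant
    image is unchanged (exactly so for integer-valued data).
    """
    size = _check_window(size)
    if size % 2 == 0:
        raise ConfigurationError(f"mean filter range must be odd, got {size}")
    a = np.asarray(as_array(img), dtype=float)
    kernel = np.ones((size,) * a.ndim)
    return ndi.correlate(a, kernel, mode="nearest") / size ** a.ndim


def gaussian_smooth(img, sigma: float = 2.0) -> np.ndarray:
    """Gaussian smoothing with standard deviation ``sigma`` in pixels.

    The published pipelines call this a "pixel range"; here the range is
    read as the Gaussian standard deviation (the conventional parameter).
    Borders use edge replication, so sums are preserved up to border
    effects.
    """
    if sigma <= 0:
        raise ConfigurationError(f"gaussian range must be positive, got {sigma}")
    return ndi.gaussian_filter(np.asarray(as_array(img), dtype=float), sigma, mode="nearest")


def local_mean_threshold(img, window: int = 150) -> np.ndarray:
    """Binarize by strict comparison against the windowed local mean.

    A pixel is foreground iff its value strictly exceeds the mean intensity
    in the ``window``-sized box centred on it (edge replicated).  For even
    windows the box spans ``[i - window//2, i + (window-1)//2]`` along each
    axis.  If the window covers the whole image along every axis the
    comparison degenerates to the global mean.
    """
    window = _check_window(window, "window")
    a = np.asarray(as_array(img), dtype=float)
    if all(window >= s for s in a.shape):
        return a > a.mean()
    sums = a.copy()
    weights = np.ones(window)
    for axis in range(a.ndim):
        sums = ndi.correlate1d(sums, weights, axis=axis, mode="nearest")
    return a > sums / window ** a.ndim


def otsu_threshold(img) -> np.ndarray:
    """Binarize at the threshold maximizing between-class variance.

    The threshold is searched over the distinct intensity values (no
    binning); ties pick the smallest threshold.  The mask is ``img > t``.
    A constant image has no two classes and raises
    :class:`DegenerateHistogramError`.
    """
    a = np.asarray(as_array(img))
    vals, counts = np.unique(a, return_counts=True)
    if vals.size < 2:
        raise DegenerateHistogramError("degenerate histogram: image is constant")
    probs = counts / counts.sum()
    means = vals * probs
    w0 = np.cumsum(probs)[:-1]
    w1 = 1.0 - w0
    mu0 = np.cumsum(means)[:-1] / w0
    mu1 = (means.sum() - np.cumsum(means)[:-1]) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    t = vals[int(np.argmax(between))]  # argmax takes the first (smallest) tie
    return a > t


def fill_holes(mask) -> np.ndarray:
    """Fill background regions not connected to the image border.

    Background connectivity is the minimal neighbourhood (4 in 2D, 6 in
    3D), the usual complement of maximally-connected foreground.
    Idempotent; foreground pixels are never removed.
    """
    return ndi.binary_fill_holes(np.asarray(as_array(mask), dtype=bool))


def largest_component(mask, connectivity: int | None = None) -> np.ndarray:
    """Keep only the connected component with the most pixels.

    Ties are broken in favour of the component whose first pixel comes
    earliest in row-major order (that component receives the smallest
    label during the raster-scan labelling).
    """
    m = np.asarray(as_array(mask), dtype=bool)
    if not m.any():
        raise EmptyMaskError("no object in mask")
    structure = ndi.generate_binary_structure(m.ndim, connectivity or m.ndim)
    lab, n = ndi.label(m, structure=structure)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def convex_hull_extent(mask) -> tuple[np.ndarray, int]:
    """Convex hull of the foreground pixel centres and its extent along y.

    Returns ``(vertices, extent)`` where ``vertices`` are hull vertex
    coordinates (row, col[, ...]) and ``extent`` is the inclusive pixel
    count ``max_row - min_row + 1``.  The axis-aligned extent of a convex
    hull equals the extent of the underlying point set, so the value is
    exact regardless of hull degeneracies.
    """
    m = np.asarray(as_array(mask), dtype=bool)
    coords = np.argwhere(m)
    if coords.size == 0:
        raise EmptyMaskError("no foreground pixel")
    extent = int(coords[:, 0].max() - coords[:, 0].min() + 1)
    try:
        hull = ConvexHull(coords.astype(float))
        vertices = coords[hull.vertices]
    except QhullError:  # collinear or single-point foreground
        vertices = np.unique(coords, axis=0)
    return vertices, extent


def log_seeds(
    img,
    scale_min: float,
    scale_max: float,
    n_scales: int = 10,
    threshold_rel: float = 0.1,
    overlap: float = 0.5,
) -> SeedSet:
    """Multi-scale Laplacian-of-Gaussian blob seeds.

    Local maxima of the scale-normalized −LoG response over ``n_scales``
    logarithmically spaced sigmas in ``[scale_min, scale_max]`` are kept if
    they exceed ``threshold_rel`` of the strongest response; overlapping
    detections are suppressed so no two seeds are closer than their
    detection scale allows.
    """
    if not 0 < scale_min <= scale_max:
        raise ConfigurationError("need 0 < scale_min <= scale_max")
    a = np.asarray(as_array(img), dtype=float)
    lo, hi = a.min(), a.max()
    if hi <= lo:
        return SeedSet(np.zeros((0, a.ndim), dtype=int), np.zeros(0))
    norm = (a - lo) / (hi - lo)
    blobs = blob_log(
        norm,
        min_sigma=scale_min,
        max_sigma=scale_max,
        num_sigma=n_scales,
        threshold=None,
        threshold_rel=threshold_rel,
        overlap=overlap,
        log_scale=True,
    )
    if blobs.size == 0:
        return SeedSet(np.zeros((0, a.ndim), dtype=int), np.zeros(0))
    coords = np.rint(blobs[:, : a.ndim]).astype(int)
    scales = blobs[:, a.ndim]
    # drop duplicate coordinates, keep deterministic row-major ordering
    order = np.lexsort(coords.T[::-1])
    coords, scales = coords[order], scales[order]
    keep = np.ones(len(coords), dtype=bool)
    keep[1:] = np.any(coords[1:] != coords[:-1], axis=1)
    return SeedSet(coords[keep], scales[keep])


def seeded_watershed(
    relief,
    seeds: SeedSet | np.ndarray,
    mask=None,
    connectivity: int | None = None,
) -> np.ndarray:
    """Seeded immersion watershed over a relief image.

    Flooding starts from the seed locations (labelled ``1..K`` in seed
    order) and proceeds in order of increasing relief value; lower values
    flood first.  Ties are broken by ``(relief value, insertion order,
    row-major coordinate)``, which makes plateau assignment fully
    deterministic.  Seeds outside the mask are dropped with a warning;
    flooding never leaves the mask.
    """
    a = np.asarray(as_array(relief), dtype=float)
    m = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(as_array(mask), dtype=bool)
    if m.shape != a.shape:
        raise ConfigurationError("mask shape does not match relief shape")
    coords = seeds.coords if isinstance(seeds, SeedSet) else np.atleast_2d(np.asarray(seeds, dtype=int))
    kept: list[tuple[int, ...]] = []
    for c in coords:
        c = tuple(int(v) for v in c)
        if any(v < 0 or v >= s for v, s in zip(c, a.shape)):
            raise ConfigurationError(f"seed {c} outside image of shape {a.shape}")
        if not m[c]:
            warnings.warn(f"seed {c} outside mask; dropped", stacklevel=2)
            continue
        kept.append(c)
    if not kept:
        raise NoMarkersError("no markers inside the mask")

    # pad by one so flat neighbour offsets never wrap across rows
    pad = tuple((1, 1) for _ in a.shape)
    ap = np.pad(a, pad, mode="edge").ravel()
    mp = np.pad(m, pad, mode="constant", constant_values=False)
    pshape = mp.shape
    mp = mp.ravel()
    labels = np.zeros(mp.shape, dtype=np.int32)

    structure = ndi.generate_binary_structure(a.ndim, connectivity or a.ndim)
    strides = np.array([int(np.prod(pshape[i + 1:])) for i in range(len(pshape))])
    offsets = []
    for idx in np.argwhere(structure):
        delta = idx - 1
        if not np.any(delta):
            continue
        offsets.append(int(np.dot(delta, strides)))

    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for lab, c in enumerate(kept, start=1):
        flat = int(np.dot(np.array(c) + 1, strides))
        heapq.heappush(heap, (float(ap[flat]), counter, flat, lab))
        counter += 1
    while heap:
        _, _, flat, lab = heapq.heappop(heap)
        if labels[flat]:
            continue
        labels[flat] = lab
        for off in offsets:
            nb = flat + off
            if mp[nb] and not labels[nb]:
                heapq.heappush(heap, (float(ap[nb]), counter, nb, lab))
                counter += 1
    labels = labels.reshape(pshape)[tuple(slice(1, -1) for _ in a.shape)]
    return np.ascontiguousarray(labels)


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive 1..K preserving ascending label order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size and labels.max() > 0 else 1, dtype=labels.dtype)
    lut[present] = np.arange(1, present.size + 1, dtype=labels.dtype)
    return lut[labels]


def apply_mask(labels, mask) -> np.ndarray:
    """Zero labels outside the mask and re-compact to consecutive 1..K."""
    lab = np.asarray(as_array(labels))
    m = np.asarray(as_array(mask), dtype=bool)
    if lab.shape != m.shape:
        raise ConfigurationError("labels and mask shapes differ")
    return _compact_labels(np.where(m, lab, 0))


def remove_border_objects(labels) -> np.ndarray:
    """Discard objects with any pixel on any image face; re-compact labels."""
    lab = np.asarray(as_array(labels)).copy()
    doomed: set[int] = set()
    for axis in range(lab.ndim):
        for sl in (0, -1):
            doomed.update(np.unique(np.take(lab, sl, axis=axis)).tolist())
    doomed.discard(0)
    if doomed:
        lab[np.isin(lab, list(doomed))] = 0
    return _compact_labels(lab)


def resample_isotropic(stack, voxel_size: tuple[float, float, float], order: int = 1) -> np.ndarray:
    """Resample an anisotropic stack to cubic voxels at the finest spacing."""
    a = np.asarray(as_array(stack), dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    if np.any(vs <= 0):
        raise ConfigurationError("voxel sizes must be positive")
    if np.allclose(vs, vs[0]):
        return a
    return ndi.zoom(a, vs / vs.min(), order=order, mode="nearest")


def rotate_about_y(
    stack,
    angle: float,
    voxel_size: tuple[float, float, float] | None = None,
    order: int = 1,
) -> np.ndarray:
    """Rigid rotation of a ``(z, y, x)`` stack about the y (rotation) axis.

    Anisotropic stacks are first resampled to isotropic voxels (linear
    interpolation).  The rotation acts on the ``(z, x)`` planes with the
    output canvas enlarged to contain the rotated volume; ``angle=0`` is an
    exact identity.  De-rotation uses the opposite sign.
    """
    a = np.asarray(as_array(stack), dtype=float)
    if a.ndim != 3:
        raise ConfigurationError("rotate_about_y expects a 3D stack (z, y, x)")
    if voxel_size is not None:
        a = resample_isotropic(a, voxel_size, order=order)
    if angle % 360 == 0:
        return a.copy()
    return ndi.rotate(a, angle, axes=(0, 2), reshape=True, order=order, mode="constant", cval=0.0)
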