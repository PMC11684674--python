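"""Independent brute-force reference implementations.

Deliberately naive (double loops, linear scans, BFS) so they share no code
path with the package.  Used to pin down the exact semantics of every
low-level operator: edge replication, strict thresholds, tie-breaking and
flooding order.
"""

from __future__ import annotations

import numpy as np


def _clamp(i: int, n: int) -> int:
    return min(max(i, 0), n - 1)


def _window_bounds(i: int, w: int) -> range:
    # window spans [i - w//2, i + (w-1)//2] along each axis
    return range(i - w // 2, i + (w - 1) // 2 + 1)


def mean_filter_oracle(img: np.ndarray, size: int) -> np.ndarray:
    rows, cols = img.shape
    out = np.empty_like(img, dtype=float)
    for r in range(rows):
        for c in range(cols):
            vals = [
                img[_clamp(rr, rows), _clamp(cc, cols)]
                for rr in _window_bounds(r, size)
                for cc in _window_bounds(c, size)
            ]
            out[r, c] = np.mean(vals)
    return out


def local_mean_threshold_oracle(img: np.ndarray, window: int) -> np.ndarray:
    rows, cols = img.shape
    if window >= rows and window >= cols:
        return img > img.mean()
    out = np.empty((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            vals = [
                img[_clamp(rr, rows), _clamp(cc, cols)]
                for rr in _window_bounds(r, window)
                for cc in _window_bounds(c, window)
            ]
            out[r, c] = img[r, c] > np.mean(vals)
    return out


def otsu_oracle(img: np.ndarray) -> np.ndarray:
    """Minimize total within-class weighted variance (an equivalent
    objective computed with a different formula); smallest threshold wins
    ties."""
    flat = img.ravel().astype(float)
    candidates = np.unique(flat)[:-1]
    best_t, best_score = None, np.inf
    for t in candidates:
        lo, hi = flat[flat <= t], flat[flat > t]
        score = 0.0
        if lo.size:
            score += lo.size * np.var(lo)
        if hi.size:
            score += hi.size * np.var(hi)
        if score < best_score - 1e-12:
            best_score, best_t = score, t
    return img > best_t


def _neighbours(r: int, c: int, rows: int, cols: int, conn8: bool):
    if conn8:
        deltas = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        deltas = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    for dr, dc in deltas:
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            yield rr, cc


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Complement flood fill: background reachable from the border (4-conn)
    stays background; everything else becomes foreground."""
    rows, cols = mask.shape
    reachable = np.zeros_like(mask, dtype=bool)
    stack = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if (r in (0, rows - 1) or c in (0, cols - 1)) and not mask[r, c]
    ]
    for r, c in stack:
        reachable[r, c] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in _neighbours(r, c, rows, cols, conn8=False):
            if not mask[rr, cc] and not reachable[rr, cc]:
                reachable[rr, cc] = True
                stack.append((rr, cc))
    return mask | ~reachable


def label_components_oracle(mask: np.ndarray, conn8: bool = True) -> list[list[tuple[int, int]]]:
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                comp, stack = [], [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for yy, xx in _neighbours(y, x, rows, cols, conn8):
                        if mask[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            stack.append((yy, xx))
                comps.append(comp)
    return comps


def largest_component_oracle(mask: np.ndarray) -> np.ndarray:
    comps = label_components_oracle(mask)
    # max size; ties -> earliest first pixel in row-major order (components
    # are discovered in raster order, so the first maximal one wins)
    best = max(comps, key=len)
    out = np.zeros_like(mask, dtype=bool)
    for r, c in best:
        out[r, c] = True
    return out


def hull_extent_oracle(mask: np.ndarray) -> int:
    rows = [r for r in range(mask.shape[0]) if mask[r].any()]
    return max(rows) - min(rows) + 1


def apply_mask_oracle(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = labels * mask.astype(labels.dtype)
    mapping = {}
    for lab in sorted(set(out.ravel().tolist()) - {0}):
        mapping[lab] = len(mapping) + 1
    res = np.zeros_like(out)
    for lab, new in mapping.items():
        res[out == lab] = new
    return res


def remove_border_objects_oracle(labels: np.ndarray) -> np.ndarray:
    rows, cols = labels.shape
    doomed = set()
    for r in range(rows):
        for c in range(cols):
            if (r in (0, rows - 1) or c in (0, cols - 1)) and labels[r, c]:
                doomed.add(int(labels[r, c]))
    kept = labels.copy()
    for lab in doomed:
        kept[kept == lab] = 0
    return apply_mask_oracle(kept, np.ones_like(kept, dtype=bool))


def watershed_oracle(relief: np.ndarray, seeds: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Priority flood with a linear-scan frontier instead of a heap.

    Same contract as the package watershed: seeds labelled 1..K in order,
    flooding by (relief value, insertion order); already-labelled entries
    are skipped when selected.
    """
    rows, cols = relief.shape
    m = np.ones_like(relief, dtype=bool) if mask is None else mask
    labels = np.zeros((rows, cols), dtype=int)
    frontier: list[tuple[float, int, int, int, int]] = []
    counter = 0
    for lab, (r, c) in enumerate(seeds, start=1):
        if not m[r, c]:
            continue
        frontier.append((float(relief[r, c]), counter, int(r), int(c), lab))
        counter += 1
    while frontier:
        best = min(range(len(frontier)), key=lambda i: (frontier[i][0], frontier[i][1]))
        _, _, r, c, lab = frontier.pop(best)
        if labels[r, c]:
            continue
        labels[r, c] = lab
        for rr, cc in _neighbours(r, c, rows, cols, conn8=True):
            if m[rr, cc] and not labels[rr, cc]:
                frontier.append((float(relief[rr, cc]), counter, rr, cc, lab))
                counter += 1
    return labels
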