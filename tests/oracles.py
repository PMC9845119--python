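"""Independent brute-force references for the crown-separation stages.

Everything here is written as plainly as possible — all-pairs scans and
BFS floods with no library shortcuts — so it can serve as an oracle for
the optimised pipeline on small grids.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.draw import line as bresenham_line


def brute_distance_transform(mask: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance to background, border counted as background."""
    nrow, ncol = mask.shape
    # background positions, including a one-pixel virtual ring outside the image
    bg = [
        (r, c)
        for r in range(-1, nrow + 1)
        for c in range(-1, ncol + 1)
        if r < 0 or c < 0 or r >= nrow or c >= ncol or mask[r, c] == 0
    ]
    out = np.zeros(mask.shape, dtype=float)
    for r in range(nrow):
        for c in range(ncol):
            if mask[r, c]:
                out[r, c] = math.sqrt(min((r - br) ** 2 + (c - bc) ** 2 for br, bc in bg))
    return out


def brute_detect_centres(dt: np.ndarray, m: int) -> list[tuple[int, int]]:
    """Window-max scan plus BFS plateau merge, smallest row-major pixel kept."""
    nrow, ncol = dt.shape
    half = m // 2
    candidates = set()
    for r in range(nrow):
        for c in range(ncol):
            if dt[r, c] <= 0:
                continue
            window_max = 0.0
            for rr in range(max(0, r - half), min(nrow, r + half + 1)):
                for cc in range(max(0, c - half), min(ncol, c + half + 1)):
                    window_max = max(window_max, dt[rr, cc])
            if dt[r, c] == window_max:
                candidates.add((r, c))
    centres = []
    seen: set[tuple[int, int]] = set()
    for start in sorted(candidates):
        if start in seen:
            continue
        component = []
        stack = [start]
        seen.add(start)
        while stack:
            node = stack.pop()
            component.append(node)
            r, c = node
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in candidates and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
        centres.append(min(component))
    return sorted(centres)


def brute_relabel(
    mask: np.ndarray, centres: list[tuple[int, int]], penalty: float
) -> np.ndarray:
    """Evaluate the penalised distance for every pixel-centre pair, no pruning."""
    labels = np.zeros(mask.shape, dtype=np.int32)
    fg = mask.astype(bool)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not fg[r, c]:
                continue
            best = None
            for k, (cr, cc) in enumerate(centres):
                d = math.sqrt((r - cr) ** 2 + (c - cc) ** 2)
                if penalty > 0:
                    rr, ll = bresenham_line(cr, cc, r, c)
                    n_bg = sum(1 for pr, pc in zip(rr[1:-1], ll[1:-1]) if not fg[pr, pc])
                    d += penalty * n_bg
                if best is None or d < best[0]:
                    best = (d, k)
            labels[r, c] = best[1] + 1
    return labels


def brute_fill_holes(labels: np.ndarray) -> np.ndarray:
    """Flood background components; fill those enclosed by a single label."""
    nrow, ncol = labels.shape
    out = labels.copy()
    visited = np.zeros(labels.shape, dtype=bool)
    for r0 in range(nrow):
        for c0 in range(ncol):
            if labels[r0, c0] != 0 or visited[r0, c0]:
                continue
            component = []
            stack = [(r0, c0)]
            visited[r0, c0] = True
            touches_border = False
            while stack:
                r, c = stack.pop()
                component.append((r, c))
                if r in (0, nrow - 1) or c in (0, ncol - 1):
                    touches_border = True
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):  # 4-connectivity
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrow and 0 <= cc < ncol and labels[rr, cc] == 0 and not visited[rr, cc]:
                        visited[rr, cc] = True
                        stack.append((rr, cc))
            if touches_border:
                continue
            border_labels = set()
            for r, c in component:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrow and 0 <= cc < ncol and labels[rr, cc] > 0:
                            border_labels.add(int(labels[rr, cc]))
            if len(border_labels) == 1:
                lab = border_labels.pop()
                for r, c in component:
                    out[r, c] = lab
    return out


def brute_dcr(mask: np.ndarray, m: int, penalty: float | None = None) -> np.ndarray:
    if penalty is None:
        penalty = math.hypot(*mask.shape)
    dt = brute_distance_transform(mask)
    centres = brute_detect_centres(dt, m)
    if not centres:
        return np.zeros(mask.shape, dtype=np.int32)
    labels = brute_relabel(mask, centres, penalty)
    return brute_fill_holes(labels)
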