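"""Independent brute-force reference implementations used only by tests.

Everything here is written from first principles (explicit loops, textbook
formulas) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Shape features
# ---------------------------------------------------------------------------

# Marching-squares case table on a 2x2 cell with corners
# (top-left, top-right, bottom-left, bottom-right) in row/col coordinates.
# Each segment connects midpoints of cell edges; coordinates are offsets
# (row, col) from the top-left corner of the cell.
_TOP = (0.0, 0.5)
_BOTTOM = (1.0, 0.5)
_LEFT = (0.5, 0.0)
_RIGHT = (0.5, 1.0)


def _cell_segments(tl, tr, bl, br):
    case = (tl > 0.5) * 8 + (tr > 0.5) * 4 + (br > 0.5) * 2 + (bl > 0.5) * 1
    table = {
        0: [],
        1: [(_BOTTOM, _LEFT)],
        2: [(_RIGHT, _BOTTOM)],
        3: [(_RIGHT, _LEFT)],
        4: [(_TOP, _RIGHT)],
        6: [(_TOP, _BOTTOM)],
        7: [(_TOP, _LEFT)],
        8: [(_LEFT, _TOP)],
        9: [(_BOTTOM, _TOP)],
        11: [(_RIGHT, _TOP)],
        12: [(_LEFT, _RIGHT)],
        13: [(_BOTTOM, _RIGHT)],
        14: [(_LEFT, _BOTTOM)],
        15: [],
    }
    if case == 5:  # saddle: resolve by cell mean (binary input -> mean rule)
        if (tl + tr + bl + br) / 4 > 0.5:
            return [(_TOP, _RIGHT), (_BOTTOM, _LEFT)]
        return [(_TOP, _LEFT), (_BOTTOM, _RIGHT)]
    if case == 10:
        if (tl + tr + bl + br) / 4 > 0.5:
            return [(_LEFT, _TOP), (_RIGHT, _BOTTOM)]
        return [(_RIGHT, _TOP), (_LEFT, _BOTTOM)]
    return table[case]


def marching_squares_loops(mask: np.ndarray) -> list[np.ndarray]:
    """Closed 0.5-level contours of a padded binary mask, as vertex arrays."""
    grid = np.pad(mask.astype(float), 1)
    edges = {}
    for r in range(grid.shape[0] - 1):
        for c in range(grid.shape[1] - 1):
            segs = _cell_segments(grid[r, c], grid[r, c + 1], grid[r + 1, c], grid[r + 1, c + 1])
            for a, b in segs:
                pa = (r + a[0], c + a[1])
                pb = (r + b[0], c + b[1])
                edges.setdefault(pa, []).append(pb)
                edges.setdefault(pb, []).append(pa)
    loops = []
    visited = set()
    for start in sorted(edges):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxts = [p for p in edges[cur] if p != prev]
            nxt = nxts[0]
            if nxt == start:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        loops.append(np.array(loop, dtype=float))
    return loops


def perimeter_oracle(mask: np.ndarray, window: int = 5) -> float:
    """Smoothed boundary-polygon length via hand-rolled marching squares."""
    total = 0.0
    for loop in marching_squares_loops(mask):
        n = len(loop)
        if n >= window:
            half = window // 2
            sm = np.empty_like(loop)
            for i in range(n):
                idx = [(i + j - half) % n for j in range(window)]
                sm[i] = loop[idx].mean(axis=0)
        else:
            sm = loop
        closed = np.vstack([sm, sm[:1]])
        total += float(np.sum(np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1]))))
    return total


def convex_hull_area_oracle(mask: np.ndarray) -> float:
    """Monotone-chain hull over pixel corner points, shoelace area."""
    rows, cols = np.nonzero(mask)
    pts = set()
    for r, c in zip(rows, cols):
        for dr in (-0.5, 0.5):
            for dc in (-0.5, 0.5):
                pts.add((r + dr, c + dc))
    pts = sorted(pts)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper = []
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    area = 0.0
    for i in range(len(hull)):
        x1, y1 = hull[i]
        x2, y2 = hull[(i + 1) % len(hull)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def median_radius_oracle(mask: np.ndarray) -> float:
    """Median distance of object pixels to the nearest background pixel."""
    fg = np.argwhere(mask)
    padded = np.pad(mask, 1)  # frame counts as background
    bg = np.argwhere(~padded) - 1
    d = np.sqrt(((fg[:, None, :] - bg[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    return float(np.median(d))


def shape_features_oracle(mask: np.ndarray) -> dict[str, float]:
    area = float(mask.sum())
    perim = perimeter_oracle(mask)
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    mean_sq = float(np.mean((rows - cy) ** 2 + (cols - cx) ** 2))
    return {
        "area": area,
        "perimeter": perim,
        "form_factor": 4 * np.pi * area / perim**2,
        "compactness": 2 * np.pi * mean_sq / area,
        "solidity": area / convex_hull_area_oracle(mask),
        "median_radius": median_radius_oracle(mask),
    }


# ---------------------------------------------------------------------------
# Granulometry
# ---------------------------------------------------------------------------

def _disk_offsets(radius: int):
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def _erode(img: np.ndarray, offs) -> np.ndarray:
    out = np.empty_like(img)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            m = np.inf
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    v = img[yy, xx]
                    if v < m:
                        m = v
            out[y, x] = m
    return out


def _dilate(img: np.ndarray, offs) -> np.ndarray:
    out = np.empty_like(img)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            m = -np.inf
            for dy, dx in offs:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w:
                    v = img[yy, xx]
                    if v > m:
                        m = v
            out[y, x] = m
    return out


def granulometry_oracle(image: np.ndarray, mask: np.ndarray, n_scales: int) -> np.ndarray:
    """Percent of masked signal removed per successive opening scale."""
    work = np.where(mask, image.astype(float), 0.0)
    total = work[mask].sum()
    prev = total
    values = np.empty(n_scales)
    for k in range(1, n_scales + 1):
        offs = _disk_offsets(k)
        opened = _dilate(_erode(work, offs), offs)
        s = opened[mask].sum()
        values[k - 1] = max(prev - s, 0.0) * 100.0 / total
        prev = s
    return values


# ---------------------------------------------------------------------------
# PCA feature weights
# ---------------------------------------------------------------------------

def pca_weights_oracle(X: np.ndarray, threshold: float = 0.90, standardize: bool = True):
    """Weights by full eigendecomposition of the covariance matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Xc = Xc / sd
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    a = evals / evals.sum()
    k = 1
    while a[:k].sum() < threshold - 1e-12 and k < len(a):
        k += 1
    raw = np.zeros(X.shape[1])
    for i in range(k):
        raw += a[i] * np.abs(evecs[:, i])
    return raw / raw.sum(), k, a


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_oracle(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def _ranks(v) -> np.ndarray:
    v = np.asarray(v, float)
    order = np.argsort(v)
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    return pearson_oracle(_ranks(x), _ranks(y))
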