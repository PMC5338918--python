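"""Polygon and power-diagram primitives used by the synthetic generator.

All coordinates are continuous, in micrometres, with x along the
anterior-posterior (A/P) axis and y along the dorsal-ventral (D/V) axis.
The raster convention used elsewhere in the package places pixel centres at
``(i + 0.5) * pixel_size``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "shoelace_area",
    "polygon_perimeter",
    "polygon_centroid",
    "regular_polygon",
    "clip_halfplane",
    "power_cells",
    "power_area_jacobian",
]


def shoelace_area(poly: np.ndarray) -> float:
    """Signed-magnitude area of a simple polygon given as an (n, 2) array."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(poly: np.ndarray) -> float:
    """Total edge length of a closed polygon (closure edge included)."""
    p = np.asarray(poly, dtype=float)
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:  # degenerate: fall back to vertex mean
        return p.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def regular_polygon(center, radius: float, n: int = 256) -> np.ndarray:
    """Regular n-gon approximating a circle, counter-clockwise."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def clip_halfplane(poly: np.ndarray, normal, offset: float) -> np.ndarray:
    """Clip a polygon to the half-plane {x : normal . x <= offset}.

    Sutherland-Hodgman step.  Returns an (m, 2) array, possibly empty.
    """
    if len(poly) == 0:
        return poly
    d = poly @ np.asarray(normal, dtype=float) - offset
    if d.max() <= 0.0:  # no vertex cut off
        return poly
    out: list[np.ndarray] = []
    m = len(poly)
    for i in range(m):
        j = (i + 1) % m
        di, dj = d[i], d[j]
        if di <= 0.0:
            out.append(poly[i])
        if (di <= 0.0) != (dj <= 0.0):
            t = di / (di - dj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    if not out:
        return np.empty((0, 2))
    return np.asarray(out)


def power_cells(
    seeds: np.ndarray,
    weights: np.ndarray,
    region: np.ndarray,
    k_neighbors: int = 14,
) -> list[np.ndarray]:
    """Power-diagram (Laguerre-Voronoi) cells clipped to a convex region.

    Cell i is {x : |x - s_i|^2 - w_i <= |x - s_j|^2 - w_j for all j},
    obtained by clipping ``region`` with the radical-axis half-plane against
    each of the ``k_neighbors`` nearest seeds.  The region polygon must be
    convex (the generator uses a fine regular polygon).
    """
    seeds = np.asarray(seeds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = len(seeds)
    k = min(k_neighbors + 1, n)
    tree = cKDTree(seeds)
    _, nbrs = tree.query(seeds, k=k)
    if n == 1:
        return [region.copy()]
    norms = (seeds ** 2).sum(axis=1)
    cells: list[np.ndarray] = []
    for i in range(n):
        cell = region
        for j in nbrs[i][1:]:
            # |x-si|^2 - wi <= |x-sj|^2 - wj  =>  2(sj-si).x <= |sj|^2-|si|^2 + wi - wj
            a = 2.0 * (seeds[j] - seeds[i])
            c = norms[j] - norms[i] + weights[i] - weights[j]
            cell = clip_halfplane(cell, a, c)
            if len(cell) < 3:
                break
        cells.append(cell if len(cell) >= 3 else np.empty((0, 2)))
    return cells


def power_area_jacobian(seeds, weights, cells, k_neighbors: int = 14):
    """Sparse Jacobian dA_i/dw_j of power-cell areas w.r.t. weights.

    Raising w_i moves each shared radical-axis edge of length L_ij away
    from seed i at rate 1 / (2 |s_i - s_j|), so
    dA_i/dw_i = sum_j L_ij / (2 d_ij) and dA_i/dw_j = -L_ij / (2 d_ij):
    a weighted graph Laplacian over the adjacency of the diagram.  Edges on
    the clip region boundary do not move with the weights and contribute
    nothing.
    """
    from scipy import sparse

    n = len(seeds)
    tree = cKDTree(seeds)
    _, nbrs = tree.query(seeds, k=min(k_neighbors + 1, n))
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for i in range(n):
        poly = cells[i]
        if len(poly) < 3:
            continue
        mids = (poly + np.roll(poly, -1, axis=0)) / 2.0
        lens = np.hypot(*(np.roll(poly, -1, axis=0) - poly).T)
        pw_i = ((mids - seeds[i]) ** 2).sum(axis=1) - weights[i]
        for j in nbrs[i][1:]:
            pw_j = ((mids - seeds[j]) ** 2).sum(axis=1) - weights[j]
            on_edge = np.abs(pw_i - pw_j) < 1e-6 * (1.0 + np.abs(pw_i))
            if not on_edge.any():
                continue
            L = float(lens[on_edge].sum())
            d = float(np.hypot(*(seeds[j] - seeds[i])))
            g = L / (2.0 * d)
            diag[i] += g
            rows.append(i)
            cols.append(int(j))
            vals.append(-g)
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
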