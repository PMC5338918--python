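"""Placode-boundary tracing and isoperimetric circularity.

Circularity C = 4*pi*area / perimeter^2 equals 1 for a perfect circle and
falls below 1 as a contour roughens, so it serves as a smoothness / tension
proxy for the tissue boundary where the supracellular actomyosin cable
runs.  The placode boundary can be compared with boundaries shifted one
cell layer outward (placode plus edge-adjacent neighbours) or inward
(placode minus its boundary cells).  The ventral midline of the embryo
closes the contour as a straight chord wherever the placode touches it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.measure import approximate_polygon, find_contours

from .geometry import polygon_perimeter, shoelace_area

__all__ = ["BoundaryTrace", "trace_placode_boundary", "shift_boundary",
           "circularity", "circularity_comparison", "label_adjacency"]


@dataclass(frozen=True)
class BoundaryTrace:
    """A closed tissue contour with its scalar shape summary."""

    contour: np.ndarray  # (k, 2) µm, closed implicitly
    perimeter: float
    area: float
    circularity: float
    which: str = "placode"  # placode | outer | inner
    midline_chord: bool = False


def circularity(trace_or_contour) -> float:
    """Isoperimetric circularity C = 4*pi*area / perimeter^2 of a contour."""
    if isinstance(trace_or_contour, BoundaryTrace):
        a, p = trace_or_contour.area, trace_or_contour.perimeter
    else:
        poly = np.asarray(trace_or_contour, dtype=float)
        a, p = shoelace_area(poly), polygon_perimeter(poly)
    if p <= 0:
        raise ValueError("degenerate contour: zero perimeter")
    return float(4.0 * np.pi * a / p ** 2)


def _trace_mask(mask: np.ndarray, pixel_size: float, which: str,
                midline_y: float | None,
                include_chord_in_perimeter: bool = True,
                simplify_tol_px: float = 1.0) -> BoundaryTrace:
    """Marching-squares contour of a binary mask, simplified, in µm.

    The contour is traced at sub-pixel precision and simplified with a
    one-pixel tolerance; a raw pixel-edge perimeter would overestimate
    length and break the isoperimetric bound.  If a ventral midline is
    given, the mask is cut there and the straight chord closes the contour.
    """
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("empty region: nothing to trace")
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        main = int(sizes.argmax()) + 1
        # stray rasterization specks are dropped; real fragmentation is an
        # error the caller must resolve
        if sizes.sum() - sizes.max() > 0.01 * sizes.sum():
            raise ValueError(
                f"region has {n} connected components (sizes in px: "
                f"{sizes.astype(int).tolist()}); cells must be contiguous")
        mask = lab == main

    work = mask
    chord = False
    if midline_y is not None:
        rows_um = (np.arange(mask.shape[0]) + 0.5) * pixel_size
        below = rows_um > midline_y
        if mask[below].any():
            chord = True
            work = mask & ~below[:, None]
            if not work.any():
                raise ValueError("region lies entirely beyond the midline")

    padded = np.pad(work.astype(float), 1)
    contours = find_contours(padded, 0.5)
    contour = max(contours, key=lambda c: len(c))
    contour = approximate_polygon(contour, tolerance=simplify_tol_px)
    y = (contour[:, 0] - 1 + 0.5) * pixel_size
    x = (contour[:, 1] - 1 + 0.5) * pixel_size
    poly = np.column_stack([x, y])
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    if chord:
        # snap near-midline vertices exactly onto the chord
        poly[np.abs(poly[:, 1] - midline_y) <= pixel_size, 1] = midline_y

    area = shoelace_area(poly)
    perim = polygon_perimeter(poly)
    if chord and not include_chord_in_perimeter:
        on_mid = np.abs(poly[:, 1] - midline_y) < 1e-9
        nxt = np.roll(on_mid, -1)
        seg = np.abs(np.roll(poly[:, 0], -1) - poly[:, 0])
        perim -= float(seg[on_mid & nxt].sum())
    return BoundaryTrace(contour=poly, perimeter=perim, area=area,
                         circularity=float(4.0 * np.pi * area / perim ** 2),
                         which=which, midline_chord=chord)


def trace_placode_boundary(
    label_image: np.ndarray,
    placode_ids,
    pixel_size: float,
    midline_y: float | None = None,
    include_chord_in_perimeter: bool = True,
) -> BoundaryTrace:
    """Trace the outer contour of the union of the placode cells."""
    mask = np.isin(label_image, np.asarray(placode_ids))
    return _trace_mask(mask, pixel_size, "placode", midline_y,
                       include_chord_in_perimeter)


def label_adjacency(label_image: np.ndarray) -> dict[int, set[int]]:
    """Edge-adjacency between labels (4-connectivity; 0 = background).

    Vertex-only contact does not count as adjacency.
    """
    lab = np.asarray(label_image)
    adj: dict[int, set[int]] = {}
    for ax in (0, 1):
        a = np.take(lab, np.arange(lab.shape[ax] - 1), axis=ax).ravel()
        b = np.take(lab, np.arange(1, lab.shape[ax]), axis=ax).ravel()
        diff = a != b
        for u, v in zip(a[diff], b[diff]):
            adj.setdefault(int(u), set()).add(int(v))
            adj.setdefault(int(v), set()).add(int(u))
    return adj


def shift_boundary(
    label_image: np.ndarray,
    placode_ids,
    direction: str,
    pixel_size: float,
    midline_y: float | None = None,
    include_chord_in_perimeter: bool = True,
) -> BoundaryTrace:
    """Boundary shifted one cell layer outward or inward.

    ``outer``: placode cells plus every non-placode cell sharing an edge
    with a placode boundary cell.  ``inner``: placode minus its boundary
    cells (those adjacent to a non-placode cell or to the background).
    """
    if direction not in ("outer", "inner"):
        raise ValueError("direction must be 'outer' or 'inner'")
    pids = set(int(i) for i in np.asarray(placode_ids).ravel())
    adj = label_adjacency(label_image)
    boundary_cells = {i for i in pids
                      if (adj.get(i, set()) - pids)}  # touches outside or bg
    if direction == "outer":
        extra = set()
        for i in boundary_cells:
            extra |= {j for j in adj.get(i, set()) if j != 0 and j not in pids}
        ids = pids | extra
    else:
        ids = pids - boundary_cells
        if not ids:
            raise ValueError("inner boundary is empty: the placode is only "
                             "one cell layer thick")
    mask = np.isin(label_image, sorted(ids))
    return _trace_mask(mask, pixel_size, direction, midline_y,
                       include_chord_in_perimeter)


def circularity_comparison(
    placode: list[float],
    outer: list[float] | None = None,
    inner: list[float] | None = None,
) -> dict:
    """Group means +/- SEM and unpaired two-tailed t-tests versus placode.

    Missing groups are allowed (some genotypes permit only placode and
    inner measurements).
    """
    def summary(vals):
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError("need at least two placodes per group")
        return {"mean": float(v.mean()),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)),
                "n": int(v.size)}

    report: dict = {"placode": summary(placode)}
    for name, vals in (("outer", outer), ("inner", inner)):
        if vals is None:
            continue
        report[name] = summary(vals)
        t = stats.ttest_ind(np.asarray(placode, dtype=float),
                            np.asarray(vals, dtype=float))
        report[f"placode_vs_{name}"] = {"t": float(t.statistic),
                                        "p": float(t.pvalue)}
    return report
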