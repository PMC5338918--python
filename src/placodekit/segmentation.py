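"""Per-cell apical segmentation from a junctional marker and stage calling.

Cell outlines are recovered by seeded watershed on the smoothed junction
channel: junctional signal (E-Cad) forms ridges between cells, so cells are
the watershed basins.  Seeds are the maxima of the distance transform of the
low-junction-signal interior.  Invagination stage is called from the
apical-surface internalization depth of the deepest cells (read from
focal-plane offsets, supplied as a column, not inferred from a single 2D
projection) plus a spatial-clustering test on the most constricted cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, regionprops
from skimage.segmentation import watershed

from .geometry import shoelace_area

__all__ = ["SegmentationParams", "StageCall", "max_project", "segment_cells",
           "classify_stage"]

#: four invagination stages, in temporal order
STAGES = ("before_invagination", "clustered_constriction",
          "beginning_invagination", "deep_invagination")

#: internalization depth (µm) beyond which a placode is in deep invagination
DEEP_DEPTH_UM = 2.0


@dataclass(frozen=True)
class SegmentationParams:
    """Watershed parameters.

    ``smooth_sigma_px`` — Gaussian pre-smoothing of the junction channel;
    ``min_seed_distance_um`` — minimum spacing between watershed seeds,
    of the order of the smallest expected cell radius;
    ``min_cell_area_um2`` — labels smaller than this are dissolved into the
    neighbouring basin (spurious fragments);
    ``exclude_boundary_cells`` — drop cells touching the mask edge from the
    returned table (whole placodes are analysed by default, so off).
    """

    smooth_sigma_px: float = 1.0
    min_seed_distance_um: float = 2.0
    min_cell_area_um2: float = 4.0
    exclude_boundary_cells: bool = False


@dataclass(frozen=True)
class StageCall:
    """Invagination stage with the evidence used to call it."""

    stage: str
    max_depth: float
    clustering_p: float | None = None


def max_project(stack: np.ndarray, plane_indices=None) -> np.ndarray:
    """Maximum-intensity projection over selected planes of a z-stack.

    A 2D image is returned unchanged.  ``plane_indices`` defaults to all
    planes; typically two or three apical planes are projected.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3:
        raise ValueError("stack must be 2D or 3D (planes, y, x)")
    if plane_indices is None:
        planes = stack
    else:
        plane_indices = np.asarray(plane_indices, dtype=int)
        if plane_indices.size == 0:
            raise ValueError("at least one plane index required")
        if plane_indices.min() < 0 or plane_indices.max() >= stack.shape[0]:
            raise IndexError("plane index out of range")
        planes = stack[plane_indices]
    return planes.max(axis=0)


def segment_cells(
    junction_image: np.ndarray,
    placode_mask: np.ndarray,
    pixel_size: float,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment apical cell outlines along junctional ridges.

    Returns the label image (0 = background/watershed lines outside mask)
    and a CellTable with per-cell polygon, area (pixel count x pixel
    area), centroid and boundary flag.  Areas and coordinates are in µm.
    """
    params = params or SegmentationParams()
    img = np.asarray(junction_image, dtype=float)
    mask = np.asarray(placode_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask must have the same shape")
    if not mask.any():
        raise ValueError("placode mask is empty: no cells to segment")

    smooth = gaussian(img, params.smooth_sigma_px, preserve_range=True)
    vals = smooth[mask]
    if np.ptp(vals) < 1e-12:
        # featureless input: a single region covering the mask
        lab = mask.astype(np.int32)
        table = _label_table(lab, mask, pixel_size, params)
        return lab, table

    thresh = threshold_otsu(vals)
    interior = mask & (smooth < thresh)
    dist = ndimage.distance_transform_edt(interior)
    min_dist_px = max(int(round(params.min_seed_distance_um / pixel_size)), 1)
    coords = peak_local_max(dist, min_distance=min_dist_px, labels=mask,
                            exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    # raster order of the seed list keeps flooding deterministic
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    for k, (r, c) in enumerate(coords[order], start=1):
        markers[r, c] = k
    if markers.max() == 0:
        raise ValueError("no watershed seeds found inside the mask")

    lab = watershed(smooth, markers, mask=mask, watershed_line=False)
    lab = _dissolve_small(lab, smooth,
                          params.min_cell_area_um2 / pixel_size ** 2)
    table = _label_table(lab, mask, pixel_size, params)
    return lab, table


def _dissolve_small(lab: np.ndarray, elevation: np.ndarray,
                    min_px: float) -> np.ndarray:
    """Merge labels below the minimum area into the surrounding basin."""
    counts = np.bincount(lab.ravel())
    small = np.flatnonzero(counts < min_px)
    small = small[small > 0]
    if small.size == 0:
        return _relabel(lab)
    lab = lab.copy()
    for s in small:
        region = lab == s
        ring = ndimage.binary_dilation(region) & ~region
        neigh = lab[ring]
        neigh = neigh[neigh > 0]
        lab[region] = np.bincount(neigh).argmax() if neigh.size else 0
    return _relabel(lab)


def _relabel(lab: np.ndarray) -> np.ndarray:
    ids = np.unique(lab)
    ids = ids[ids > 0]
    remap = np.zeros(lab.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[lab]


def _label_table(lab, mask, pixel_size, params) -> pd.DataFrame:
    """Region properties, polygons from marching squares, in µm."""
    rows = []
    edge = np.zeros(mask.shape, dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    mask_edge = edge | (ndimage.binary_dilation(mask) & ~mask)
    for rp in regionprops(lab):
        poly = _region_polygon(lab, rp, pixel_size)
        touches = bool((mask_edge[rp.slice] &
                        (lab[rp.slice] == rp.label)).any()) or \
            bool((ndimage.binary_dilation(lab[rp.slice] == rp.label) &
                  ~mask[rp.slice]).any())
        rows.append({
            "cell_id": rp.label,
            "area": rp.area * pixel_size ** 2,
            "centroid_x": (rp.centroid[1] + 0.5) * pixel_size,
            "centroid_y": (rp.centroid[0] + 0.5) * pixel_size,
            "depth": 0.0,
            "boundary_cell": touches,
            "placode_id": "placode",
            "polygon": poly,
        })
    table = pd.DataFrame(rows)
    if params.exclude_boundary_cells and len(table):
        table = table[~table["boundary_cell"]].reset_index(drop=True)
    return table


def _region_polygon(lab, rp, pixel_size) -> np.ndarray:
    """Sub-pixel contour of one label, traced on its padded bounding box."""
    sl = rp.slice
    crop = np.pad((lab[sl] == rp.label).astype(float), 1)
    contours = find_contours(crop, 0.5)
    if not contours:
        return np.empty((0, 2))
    contour = max(contours, key=len)
    # (row, col) crop frame -> (x, y) µm; pad offset of 1, pixel centres +0.5
    y = (contour[:, 0] - 1 + sl[0].start + 0.5) * pixel_size
    x = (contour[:, 1] - 1 + sl[1].start + 0.5) * pixel_size
    return np.column_stack([x, y])


def classify_stage(
    cells: pd.DataFrame,
    clustering_alpha: float = 0.05,
    q: float = 0.30,
    n_perm: int = 999,
    seed: int = 0,
) -> StageCall:
    """Call the invagination stage from cell depths and spatial clustering.

    Deepest cells internalized > 2 µm mean deep invagination; any nonzero
    depth up to 2 µm means invagination has begun.  With all cells at the
    surface, the placode is in clustered apical constriction if the most
    constricted cells (lower ``q`` by area) cluster spatially at level
    ``clustering_alpha`` under a permutation null, and before invagination
    otherwise.  The clustering criterion is this package's own
    operationalization of a qualitative distinction; the p-value is
    returned so callers can see the evidence.
    """
    if "depth" not in cells.columns or cells["depth"].isna().any():
        raise ValueError("stage classification requires a populated depth "
                         "column (from focal-plane metadata)")
    max_depth = float(cells["depth"].max())
    if max_depth > DEEP_DEPTH_UM:
        return StageCall("deep_invagination", max_depth)
    if max_depth > 0.0:
        return StageCall("beginning_invagination", max_depth)
    from .dispersion import clustering_permutation_test
    p = clustering_permutation_test(cells, q=q, n_perm=n_perm, seed=seed)
    stage = "clustered_constriction" if p < clustering_alpha \
        else "before_invagination"
    return StageCall(stage, 0.0, clustering_p=p)


def polygon_pixel_area_consistency(table: pd.DataFrame) -> pd.Series:
    """Relative gap between polygon (shoelace) and pixel-count areas."""
    poly_area = table["polygon"].map(
        lambda p: shoelace_area(p) if len(p) else np.nan)
    return (poly_area - table["area"]).abs() / table["area"]
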