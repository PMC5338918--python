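"""Synthetic placode scenes with known ground truth.

The generator emulates the apical surface of an embryonic epithelial placode
(such as the fly salivary-gland primordium) as seen in a junctional-marker /
myosin-reporter two-channel confocal image:

* a contiguous patch of ~100-200 polygonal cells tiling a disk,
* a spatial apical-area field — constriction clustered around an
  invagination pit, the same area multiset spatially shuffled, a uniform
  field, or expansion around the pit,
* a junctional channel with intensity concentrated in ridges on cell edges,
* a myosin channel combining the junctional ridge pool with a per-cell
  central (apicomedial) blob of configurable integrated density,
* optional PSF blur and Poisson shot noise,
* pulsatile apicomedial intensity traces with normally distributed
  inter-pulse intervals.

Every scene carries its full ground truth (polygons, areas, per-cell
intensity pools, pulse event times), so downstream measurements can be
validated against what was actually generated.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy import ndimage

from scipy.sparse import eye as sparse_eye

from .geometry import (
    polygon_centroid,
    power_area_jacobian,
    power_cells,
    regular_polygon,
    shoelace_area,
)

__all__ = [
    "SceneConfig",
    "PulsationConfig",
    "PlacodeScene",
    "PulseTrace",
    "generate_scene",
    "render_channels",
    "generate_pulse_traces",
    "export_ground_truth",
    "scene_cell_table",
    "preset_area_samples",
]

FIELD_MODES = ("clustered", "random", "uniform", "expanded")
NOISE_MODELS = ("none", "poisson")


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic placode.

    Geometric parameters are in micrometres; intensities in arbitrary
    units interpreted as expected photon counts when Poisson noise is on.
    ``pit_center`` and ``constriction_sigma`` default to a pit offset
    posteriorly from the tissue centre and a constriction length scale of
    0.35 placode radii, mirroring the posterior pit position in vivo.
    """

    n_cells: int = 150
    field_mode: str = "clustered"
    pit_center: tuple[float, float] | None = None
    constriction_depth: float = 0.5
    constriction_sigma: float | None = None
    base_area: float = 35.0
    junction_width: float = 0.5
    psf_sigma: float = 0.25
    noise_model: str = "poisson"
    pixel_size: float = 0.2
    seed: int = 0
    # intensity model
    junction_amplitude: float = 150.0
    baseline: float = 10.0
    ja_ratio: float = 2.0
    medial_sigma: float | None = None  # µm; default scales with cell size
    # tissue context
    surround_layers: int = 0
    smooth_boundary: bool = False
    margin: float = 4.0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("n_cells must be >= 3")
        if not (0.0 <= self.constriction_depth < 1.0):
            raise ValueError("constriction_depth must be in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.base_area <= 0:
            raise ValueError("base_area must be positive")
        if self.field_mode not in FIELD_MODES:
            raise ValueError(f"field_mode must be one of {FIELD_MODES}")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if np.sqrt(self.base_area) / self.pixel_size < 4.0:
            raise ValueError(
                "cells would span fewer than ~4 pixels across; decrease "
                "pixel_size or increase base_area"
            )

    @property
    def placode_radius(self) -> float:
        return float(np.sqrt(self.n_cells * self.base_area / np.pi))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass(frozen=True)
class PulsationConfig:
    """Pulsatile apicomedial-myosin trace parameters.

    Defaults follow live-imaging conditions for the salivary-gland placode:
    inter-pulse intervals normally distributed with mean 131.7 s and SD
    42.8 s, sampled every 5 s.  ``pulse_width`` is the FWHM of each
    Gaussian-in-time pulse; intervals are truncated to exceed it so that
    successive pulses stay resolvable.
    """

    mean_interval: float = 131.7
    sd_interval: float = 42.8
    pulse_width: float = 20.0
    frame_interval: float = 5.0
    n_frames: int = 360
    baseline: float = 100.0
    amplitude: float = 300.0
    noise_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.mean_interval <= 0:
            raise ValueError("mean_interval must be positive")
        if self.sd_interval < 0:
            raise ValueError("sd_interval must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pulse_width >= self.mean_interval:
            raise ValueError("pulse_width must be smaller than mean_interval")


@dataclass
class PulseTrace:
    """One cell's apicomedial intensity time series.

    ``peak_indices`` and ``intervals`` are filled in by peak detection
    (:mod:`placodekit.pulses`); the generator leaves them empty and records
    the true pulse event times instead.
    """

    times: np.ndarray
    intensities: np.ndarray
    cell_id: int = 0
    true_event_times: np.ndarray | None = None
    peak_indices: np.ndarray | None = None
    intervals: np.ndarray | None = None


@dataclass
class PlacodeScene:
    """A generated placode with full ground truth.

    ``polygons`` are (k, 2) vertex arrays in µm that tile the tissue region
    without overlap; ``areas`` are their shoelace areas.  ``is_placode``
    distinguishes placode cells from optional surrounding epithelial cells.
    The channel images are filled by :func:`render_channels`.
    """

    config: SceneConfig
    cell_ids: np.ndarray
    polygons: list[np.ndarray]
    areas: np.ndarray
    target_areas: np.ndarray
    centroids: np.ndarray
    seeds: np.ndarray
    weights: np.ndarray
    is_placode: np.ndarray
    pit_center: np.ndarray
    region: np.ndarray
    placode_region: np.ndarray
    canvas_um: tuple[float, float]
    junction_image: np.ndarray | None = None
    myosin_image: np.ndarray | None = None
    true_junctional: np.ndarray | None = None
    true_medial: np.ndarray | None = None
    _label_image: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return int(self.is_placode.sum())

    @property
    def placode_areas(self) -> np.ndarray:
        return self.areas[self.is_placode]

    @property
    def placode_ids(self) -> np.ndarray:
        return self.cell_ids[self.is_placode]

    @property
    def true_ratio(self) -> np.ndarray | None:
        if self.true_junctional is None or self.true_medial is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.true_junctional / self.true_medial

    @property
    def shape_px(self) -> tuple[int, int]:
        px = self.config.pixel_size
        return (int(round(self.canvas_um[1] / px)),
                int(round(self.canvas_um[0] / px)))

    @property
    def label_image(self) -> np.ndarray:
        """Integer label raster (0 = background), consistent with polygons."""
        if self._label_image is None:
            self._label_image = _rasterize_labels(self)
        return self._label_image


def _area_factor(mode: str, d: np.ndarray, depth: float, sigma: float) -> np.ndarray:
    bump = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    if mode in ("clustered", "random"):
        return 1.0 - depth * bump
    if mode == "expanded":
        return 1.0 + depth * bump
    return np.ones_like(d)


def _assign_power(points: np.ndarray, seeds: np.ndarray, weights: np.ndarray,
                  chunk: int = 65536) -> np.ndarray:
    """Index of the power-nearest seed for each point, chunked for memory."""
    s = seeds.astype(np.float32)
    w = weights.astype(np.float32)
    offs = (s ** 2).sum(axis=1) - w  # |s|^2 - w, constant per seed
    out = np.empty(len(points), dtype=np.int32)
    pts = points.astype(np.float32)
    for lo in range(0, len(points), chunk):
        p = pts[lo:lo + chunk]
        # argmin over |p|^2 - 2 p.s + |s|^2 - w; |p|^2 is seed-independent
        d2 = offs[None, :] - 2.0 * (p @ s.T)
        out[lo:lo + chunk] = np.argmin(d2, axis=1)
    return out


def _raster_lloyd(seeds, weights, targets, region_r, center, inner_r, n_placode,
                  grid_h, n_iter, lr, move_seeds, rng):
    """Weighted-Lloyd relaxation on a coarse raster.

    Returns updated (seeds, weights).  Placode seeds are kept inside the
    inner radius and surround seeds outside it so the two groups stay
    spatially coherent.
    """
    lim = region_r + grid_h
    ax = np.arange(center[0] - lim, center[0] + lim, grid_h) + grid_h / 2
    ay = np.arange(center[1] - lim, center[1] + lim, grid_h) + grid_h / 2
    gx, gy = np.meshgrid(ax, ay)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = ((pts - center) ** 2).sum(axis=1) <= region_r ** 2
    pts = pts[inside]
    cell_px_area = grid_h ** 2
    n = len(seeds)
    for _ in range(n_iter):
        lab = _assign_power(pts, seeds, weights)
        counts = np.bincount(lab, minlength=n).astype(float)
        areas = counts * cell_px_area
        if move_seeds:
            sx = np.bincount(lab, weights=pts[:, 0], minlength=n)
            sy = np.bincount(lab, weights=pts[:, 1], minlength=n)
            ok = counts > 0
            seeds = seeds.copy()
            seeds[ok, 0] = sx[ok] / counts[ok]
            seeds[ok, 1] = sy[ok] / counts[ok]
            # dead cells: respawn at a random interior point
            for i in np.flatnonzero(~ok):
                t = rng.uniform(0, 2 * np.pi)
                r = region_r * np.sqrt(rng.uniform())
                seeds[i] = center + r * np.array([np.cos(t), np.sin(t)])
            seeds = _constrain_groups(seeds, center, inner_r, n_placode)
        if targets is not None:
            weights = weights + lr * (targets - areas)
            weights[counts == 0] += targets[counts == 0]
            weights -= weights.mean()
    return seeds, weights


def _constrain_groups(seeds, center, inner_r, n_placode):
    """Clamp placode seeds inside the placode disk and surround seeds outside."""
    if n_placode >= len(seeds):
        return seeds
    v = seeds - center
    r = np.hypot(v[:, 0], v[:, 1])
    r = np.where(r < 1e-9, 1e-9, r)
    rp = r[:n_placode]
    bad = rp > inner_r * 0.98
    if bad.any():
        scale = inner_r * 0.98 / rp[bad]
        seeds[:n_placode][bad] = center + v[:n_placode][bad] * scale[:, None]
    rs = r[n_placode:]
    bad = rs < inner_r * 1.02
    if bad.any():
        scale = inner_r * 1.02 / rs[bad]
        seeds[n_placode:][bad] = center + v[n_placode:][bad] * scale[:, None]
    return seeds


def generate_scene(config: SceneConfig) -> PlacodeScene:
    """Generate the placode geometry and ground-truth area field.

    Cells are realized as power-diagram (additively weighted Voronoi) cells
    relaxed by Lloyd iteration toward per-cell target areas.  In clustered
    mode the target area at pit distance d follows
    ``base_area * (1 - depth * exp(-d^2 / 2 sigma^2))`` up to one global
    normalization that makes the targets tile the tissue region exactly; in
    random mode the identical target multiset is spatially permuted; uniform
    and expanded modes follow their names.  Channel images are left empty
    (see :func:`render_channels`).
    """
    rng = np.random.default_rng(config.seed)
    R = config.placode_radius
    sigma = config.constriction_sigma if config.constriction_sigma is not None \
        else 0.35 * R

    ring_w = config.surround_layers * np.sqrt(config.base_area)
    R_out = R + ring_w
    half = R_out + config.margin
    center = np.array([half, half])
    canvas = (2.0 * half, 2.0 * half)
    if config.pit_center is not None:
        pit = np.asarray(config.pit_center, dtype=float)
    else:
        pit = center + np.array([0.55 * R, 0.0])

    n_sur = 0
    if config.surround_layers > 0:
        n_sur = max(int(round(np.pi * (R_out ** 2 - R ** 2) / config.base_area)), 1)
    n_total = config.n_cells + n_sur

    # initial seeds: uniform in disk / annulus
    t = rng.uniform(0, 2 * np.pi, config.n_cells)
    r = R * np.sqrt(rng.uniform(size=config.n_cells))
    seeds_p = center + np.column_stack([r * np.cos(t), r * np.sin(t)])
    if n_sur:
        t = rng.uniform(0, 2 * np.pi, n_sur)
        r = np.sqrt(rng.uniform(R ** 2, R_out ** 2, n_sur))
        seeds_s = center + np.column_stack([r * np.cos(t), r * np.sin(t)])
        seeds = np.vstack([seeds_p, seeds_s])
    else:
        seeds = seeds_p
    weights = np.zeros(n_total)

    grid_h = max(np.sqrt(config.base_area) / 6.0, config.pixel_size)
    # phase 1: unweighted CVT -> spatially uniform, well-shaped cells
    seeds, weights = _raster_lloyd(
        seeds, weights, None, R_out, center, R, config.n_cells,
        grid_h, n_iter=15, lr=0.0, move_seeds=True, rng=rng)

    # targets from the relaxed (mode-independent) positions
    d = np.hypot(*(seeds[:config.n_cells] - pit).T)
    raw = _area_factor(config.field_mode, d, config.constriction_depth, sigma)
    if config.field_mode == "random":
        raw = rng.permutation(raw)
    targets_p = raw * (np.pi * R ** 2 / raw.sum())
    if n_sur:
        targets_s = np.full(n_sur, np.pi * (R_out ** 2 - R ** 2) / n_sur)
        targets = np.concatenate([targets_p, targets_s])
    else:
        targets = targets_p

    # phase 2: weighted Lloyd toward the targets
    seeds, weights = _raster_lloyd(
        seeds, weights, targets, R_out, center, R, config.n_cells,
        grid_h, n_iter=8, lr=0.4, move_seeds=True, rng=rng)
    seeds, weights = _raster_lloyd(
        seeds, weights, targets, R_out, center, R, config.n_cells,
        grid_h, n_iter=15, lr=0.4, move_seeds=False, rng=rng)

    # phase 3: exact polygon cells, Newton polish on exact areas
    # (the area/weight Jacobian is a graph Laplacian over shared edges)
    region = regular_polygon(center, R_out, 256)
    from scipy.sparse.linalg import spsolve
    for _ in range(5):
        cells = power_cells(seeds, weights, region)
        areas = np.array([shoelace_area(c) if len(c) else 0.0 for c in cells])
        if (areas == 0).any():
            weights[areas == 0] += targets[areas == 0]
            continue
        err = float((np.abs(areas - targets) /
                     np.maximum(targets, 1e-12)).max())
        if err < 0.02:
            break
        jac = power_area_jacobian(seeds, weights, cells)
        ridge = 1e-6 * jac.diagonal().mean()
        jac = jac + ridge * sparse_eye(len(seeds))
        weights = weights + spsolve(jac.tocsc(), targets - areas)
    else:
        cells = power_cells(seeds, weights, region)
        areas = np.array([shoelace_area(c) if len(c) else 0.0 for c in cells])

    if config.smooth_boundary and n_sur:
        cells = _group_tessellation(seeds, weights, center, R, region,
                                    config.n_cells)
        areas = np.array([shoelace_area(c) if len(c) else 0.0 for c in cells])

    if (areas <= 0).any():
        raise RuntimeError("tessellation produced an empty cell; "
                           "n_cells may be too large for the canvas")

    centroids = np.array([polygon_centroid(c) for c in cells])
    is_placode = np.zeros(n_total, dtype=bool)
    is_placode[:config.n_cells] = True
    return PlacodeScene(
        config=config,
        cell_ids=np.arange(1, n_total + 1),
        polygons=cells,
        areas=areas,
        target_areas=targets,
        centroids=centroids,
        seeds=seeds,
        weights=weights,
        is_placode=is_placode,
        pit_center=pit,
        region=region,
        placode_region=regular_polygon(center, R, 256),
        canvas_um=canvas,
    )


def _group_tessellation(seeds, weights, center, R, region, n_placode):
    """Tessellate placode and surround cells within their own regions.

    Emulates the smooth tissue boundary produced in vivo by the
    supracellular actomyosin cable: placode cells tile the disk of radius
    R exactly (their rim edges follow the circle), surrounding cells tile
    the annulus outside it.
    """
    disk = regular_polygon(center, R, 256)
    cells_p = power_cells(seeds[:n_placode], weights[:n_placode], disk)
    cells_s_full = power_cells(seeds[n_placode:], weights[n_placode:], region)
    disk_poly = shapely.Polygon(disk)
    cells_s = []
    for c in cells_s_full:
        if len(c) == 0:
            cells_s.append(c)
            continue
        clipped = shapely.Polygon(c).difference(disk_poly)
        if clipped.is_empty:
            cells_s.append(np.empty((0, 2)))
            continue
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        cells_s.append(np.asarray(clipped.exterior.coords[:-1]))
    return cells_p + cells_s


def _rasterize_labels(scene: PlacodeScene) -> np.ndarray:
    """Label raster from the power assignment of pixel centres.

    Pixels outside the tissue region are 0.  With a smooth placode
    boundary, pixels are assigned within their own group (placode versus
    surround) so the raster honours the circular clip.
    """
    cfg = scene.config
    h, w = scene.shape_px
    px = cfg.pixel_size
    ys = (np.arange(h) + 0.5) * px
    xs = (np.arange(w) + 0.5) * px
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    center = np.array(scene.canvas_um) / 2.0
    r2 = ((pts - center) ** 2).sum(axis=1)
    R_out = cfg.placode_radius + cfg.surround_layers * np.sqrt(cfg.base_area)
    inside = r2 <= R_out ** 2
    lab = np.zeros(len(pts), dtype=np.int32)
    n_p = cfg.n_cells
    if cfg.smooth_boundary and cfg.surround_layers > 0:
        in_disk = inside & (r2 <= cfg.placode_radius ** 2)
        in_ring = inside & ~in_disk
        lab[in_disk] = 1 + _assign_power(
            pts[in_disk], scene.seeds[:n_p], scene.weights[:n_p])
        lab[in_ring] = 1 + n_p + _assign_power(
            pts[in_ring], scene.seeds[n_p:], scene.weights[n_p:])
    else:
        lab[inside] = 1 + _assign_power(pts[inside], scene.seeds, scene.weights)
    return lab.reshape(h, w)


def render_channels(
    scene: PlacodeScene,
    medial_densities: np.ndarray | None = None,
    ja_ratios: np.ndarray | None = None,
) -> PlacodeScene:
    """Render the junction and myosin channels into the scene (in place).

    The junction channel is a ridge of width ``junction_width`` on every
    cell edge at ``junction_amplitude``.  The myosin channel adds, per cell,
    a centred Gaussian apicomedial blob whose integrated density is the
    cell's junctional integrated density divided by its configured
    junctional:apicomedial ratio (``ja_ratios`` or ``config.ja_ratio``), or
    ``medial_densities[i]`` if given explicitly.  Both channels are then PSF
    blurred and, under the Poisson noise model, offset by ``baseline`` and
    shot-noise sampled.  With ``noise_model="none"`` and ``psf_sigma=0`` the
    junction channel is exactly the ridge mask times the amplitude.
    """
    cfg = scene.config
    lab = scene.label_image
    px = cfg.pixel_size
    n = len(scene.cell_ids)

    edge = np.zeros(lab.shape, dtype=bool)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        rolled = np.roll(lab, sh, axis=ax)
        edge |= (lab != rolled)
    edge &= lab > 0

    half_w = cfg.junction_width / 2.0
    if half_w > px:
        dist = ndimage.distance_transform_edt(~edge) * px
        ridge = edge | (dist <= half_w - px / 2.0)
        ridge &= lab > 0
    else:
        ridge = edge

    junction = np.where(ridge, cfg.junction_amplitude, 0.0)

    ridge_counts = np.bincount(lab[ridge].ravel(), minlength=n + 1)[1:]
    true_j = cfg.junction_amplitude * ridge_counts.astype(float)
    if medial_densities is not None:
        true_m = np.asarray(medial_densities, dtype=float)
    else:
        ratios = np.asarray(ja_ratios, dtype=float) if ja_ratios is not None \
            else np.full(n, cfg.ja_ratio)
        true_m = true_j / ratios

    myosin = junction.copy()
    obj = ndimage.find_objects(lab)
    ys_all = (np.arange(lab.shape[0]) + 0.5) * px
    xs_all = (np.arange(lab.shape[1]) + 0.5) * px
    for i in range(n):
        if true_m[i] <= 0 or obj[i] is None:
            continue
        sl = obj[i]
        mask = lab[sl] == i + 1
        cy, cx = scene.centroids[i][1], scene.centroids[i][0]
        gy = ys_all[sl[0]][:, None] - cy
        gx = xs_all[sl[1]][None, :] - cx
        # blob width tracks the apical domain so constricted cells keep
        # their medial pool central rather than pressed into the junctions
        sig_m = cfg.medial_sigma if cfg.medial_sigma is not None \
            else 0.11 * np.sqrt(scene.areas[i])
        g = np.exp(-(gx ** 2 + gy ** 2) / (2.0 * sig_m ** 2))
        g = np.where(mask, g, 0.0)
        tot = g.sum()
        if tot > 0:
            myosin[sl] += true_m[i] * g / tot

    if cfg.psf_sigma > 0:
        s = cfg.psf_sigma / px
        junction = ndimage.gaussian_filter(junction, s)
        myosin = ndimage.gaussian_filter(myosin, s)

    if cfg.noise_model == "poisson":
        rng = np.random.default_rng([cfg.seed, 7])
        junction = rng.poisson(junction + cfg.baseline).astype(float)
        myosin = rng.poisson(myosin + cfg.baseline).astype(float)

    scene.junction_image = junction
    scene.myosin_image = myosin
    scene.true_junctional = true_j
    scene.true_medial = true_m
    return scene


def generate_pulse_traces(
    pcfg: PulsationConfig, n_cells: int, seed: int = 0
) -> list[PulseTrace]:
    """Generate asynchronous pulsatile apicomedial intensity traces.

    Each trace is ``baseline`` plus a sum of Gaussian-in-time pulses whose
    successive event-time differences are drawn from
    Normal(mean_interval, sd_interval) truncated to exceed ``pulse_width``
    (resampled on violation); the phase of the first event is independent
    per cell, so pulses are asynchronous across cells.
    """
    duration = pcfg.n_frames * pcfg.frame_interval
    if duration < 2.0 * pcfg.mean_interval:
        warnings.warn(
            "trace shorter than two mean intervals; interval statistics "
            "will be unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    sig = pcfg.pulse_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sd
    times = np.arange(pcfg.n_frames) * pcfg.frame_interval
    traces = []
    for c in range(n_cells):
        t = -rng.uniform(0.0, pcfg.mean_interval)
        events = []
        while t < duration + 3.0 * sig:
            if t > -3.0 * sig:
                events.append(t)
            gap = rng.normal(pcfg.mean_interval, pcfg.sd_interval)
            while gap <= pcfg.pulse_width:
                gap = rng.normal(pcfg.mean_interval, pcfg.sd_interval)
            t += gap
        events = np.asarray(events)
        y = np.full(pcfg.n_frames, pcfg.baseline, dtype=float)
        if pcfg.amplitude != 0:
            for ev in events:
                y += pcfg.amplitude * np.exp(-((times - ev) ** 2) / (2 * sig ** 2))
        if pcfg.noise_sd > 0:
            y += rng.normal(0.0, pcfg.noise_sd, size=y.shape)
        in_window = events[(events >= 0) & (events <= duration)]
        traces.append(PulseTrace(times=times, intensities=y, cell_id=c + 1,
                                 true_event_times=in_window))
    return traces


def scene_cell_table(scene: PlacodeScene, placode_only: bool = True) -> pd.DataFrame:
    """Ground-truth CellTable for a scene (schema shared with segmentation)."""
    idx = np.flatnonzero(scene.is_placode) if placode_only \
        else np.arange(len(scene.cell_ids))
    boundary = _boundary_cell_flags(scene)
    return pd.DataFrame({
        "cell_id": scene.cell_ids[idx],
        "area": scene.areas[idx],
        "centroid_x": scene.centroids[idx, 0],
        "centroid_y": scene.centroids[idx, 1],
        "depth": 0.0,
        "boundary_cell": boundary[idx],
        "placode_id": "synthetic",
        "polygon": [scene.polygons[i] for i in idx],
    })


def _boundary_cell_flags(scene: PlacodeScene) -> np.ndarray:
    """Placode cells touching the placode rim (or tissue rim if no surround)."""
    center = np.array(scene.canvas_um) / 2.0
    R = scene.config.placode_radius
    flags = np.zeros(len(scene.cell_ids), dtype=bool)
    for i, poly in enumerate(scene.polygons):
        if len(poly) == 0 or not scene.is_placode[i]:
            continue
        rmax = np.hypot(*(poly - center).T).max()
        flags[i] = rmax >= R * 0.995
    return flags


def export_ground_truth(scene: PlacodeScene, out_dir: str | Path) -> dict[str, Path]:
    """Write label/channel TIFFs, the CellTable CSV, and the config JSON.

    Polygons are serialized as WKT in the CSV.  Files round-trip: reading
    them back yields the in-memory arrays exactly (channel images as
    float32).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    lab = scene.label_image.astype(np.uint16)
    paths["labels"] = out / "labels.tif"
    tifffile.imwrite(paths["labels"], lab)
    for name in ("junction", "myosin"):
        img = getattr(scene, f"{name}_image")
        if img is not None:
            paths[name] = out / f"{name}.tif"
            tifffile.imwrite(paths[name], img.astype(np.float32))
    table = scene_cell_table(scene, placode_only=False)
    table = table.assign(
        polygon=[shapely.Polygon(p).wkt for p in table["polygon"]])
    paths["cells"] = out / "cells.csv"
    table.to_csv(paths["cells"], index=False)
    paths["config"] = out / "scene_config.json"
    paths["config"].write_text(scene.config.to_json())
    return paths


def preset_area_samples(n: int = 300, seed: int = 0) -> dict[str, np.ndarray]:
    """Paired apical-area samples for the median-scaling workflow.

    Returns a reference sample emulating a wild-type placode before
    invagination and a smaller-area mutant-like sample rescaled so that the
    reference:mutant median ratio is exactly 1.2, the normalization factor
    applied to fkh-mutant glands.  Both are lognormal with realistic spread.
    """
    rng = np.random.default_rng(seed)
    reference = np.exp(rng.normal(np.log(30.0), 0.35, size=n))
    mutant = np.exp(rng.normal(np.log(25.0), 0.35, size=n))
    mutant = mutant * (np.median(reference) / 1.2) / np.median(mutant)
    return {"reference": reference, "mutant": mutant}
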