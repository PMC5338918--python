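"""Apical-area distribution statistics and heat maps.

Binned frequency / cumulative-frequency distributions (bin width 4 µm² by
convention), two-sample comparisons (Mann-Whitney U and two-sample
Kolmogorov-Smirnov), median-scaling normalization between genotypes, and
per-cell area heat maps on the segmented polygons.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AreaDistribution", "area_distribution", "compare_distributions",
           "median_scale", "render_area_heatmap", "area_color_values"]


@dataclass(frozen=True)
class AreaDistribution:
    """Percentage and cumulative percentage of cells per apical-area bin."""

    bin_edges: np.ndarray  # uniform, starting at 0, µm²
    percentage: np.ndarray
    cumulative: np.ndarray
    n_cells: int
    label: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "percentage": self.percentage,
            "cumulative_percentage": self.cumulative,
        })


def area_distribution(areas, bin_width: float = 4.0,
                      label: str = "") -> AreaDistribution:
    """Histogram of apical areas in half-open bins [k·w, (k+1)·w) from 0."""
    a = np.asarray(areas, dtype=float)
    if a.size == 0:
        raise ValueError("no areas given")
    if (a <= 0).any():
        raise ValueError("areas must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(a.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum((a / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    pct = 100.0 * counts / a.size
    return AreaDistribution(bin_edges=edges, percentage=pct,
                            cumulative=np.cumsum(pct), n_cells=a.size,
                            label=label)


def compare_distributions(a, b) -> dict:
    """Two-sample comparison of area distributions.

    Reports the Mann-Whitney U statistic and p-value together with the
    two-sample Kolmogorov-Smirnov D statistic (max gap between empirical
    CDFs) and p-value, the tests used for percentage and cumulative area
    distributions respectively.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    ks = stats.ks_2samp(a, b)
    return {
        "mannwhitney_u": float(u.statistic),
        "mannwhitney_p": float(u.pvalue),
        "ks_d": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


def median_scale(target, reference) -> tuple[np.ndarray, float]:
    """Scale ``target`` areas so their median matches the reference median.

    Every area is multiplied by ``median(reference) / median(target)``;
    the returned factor is that multiplier (1.2 for the fkh-mutant
    normalization).  Applying the operation twice with the same reference
    is a no-op after the first application.
    """
    t = np.asarray(target, dtype=float)
    r = np.asarray(reference, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("empty sample")
    mt, mr = np.median(t), np.median(r)
    if mt <= 0 or mr <= 0:
        raise ValueError("medians must be positive")
    factor = mr / mt
    return t * factor, float(factor)


def area_color_values(areas, vmin: float, vmax: float) -> np.ndarray:
    """Areas mapped onto the fixed [0, 1] colour scale shared across panels."""
    if vmax <= vmin:
        raise ValueError("vmax must exceed vmin")
    return np.clip((np.asarray(areas, dtype=float) - vmin) / (vmax - vmin),
                   0.0, 1.0)


def render_area_heatmap(cells: pd.DataFrame, vmin: float, vmax: float,
                        cmap: str = "viridis", ax=None):
    """Fill each cell polygon with a colour mapped from its apical area.

    The colour scale (vmin, vmax, in µm²) is fixed so that panels compared
    side by side share it.  Returns the matplotlib Axes.
    """
    from matplotlib import pyplot as plt
    from matplotlib.collections import PolyCollection

    polys = [np.asarray(p) for p in cells["polygon"] if len(p) >= 3]
    vals = area_color_values(cells["area"].to_numpy(), vmin, vmax)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cm = matplotlib.colormaps[cmap]
    pc = PolyCollection(polys, facecolors=cm(vals), edgecolors="k",
                        linewidths=0.3)
    ax.add_collection(pc)
    allv = np.vstack([p for p in polys])
    ax.set_xlim(allv[:, 0].min(), allv[:, 0].max())
    ax.set_ylim(allv[:, 1].max(), allv[:, 1].min())  # image convention
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm, A/P)")
    ax.set_ylabel("y (µm, D/V)")
    return ax
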