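# placodekit

Quantitative image analysis of **apical constriction** during epithelial
placode invagination — the process by which a flat patch of epithelial
precursor cells (for example the *Drosophila* salivary-gland primordium)
bends inward at an invagination pit to form a tube. Apical constriction is
driven by pulsatile apicomedial actomyosin and coordinated in space: the
most constricted cells cluster near the pit, and a supracellular myosin
cable keeps the tissue boundary smooth and under tension.

`placodekit` turns the measurements used to characterise this process into
a tested, reusable library:

- **Segmentation** — per-cell apical outlines and areas from a junctional
  marker (E-Cad) image by seeded watershed, plus four-stage invagination
  calling from internalization depth (> 2 µm ⇒ deep invagination) and
  spatial clustering of constricted cells.
- **Area statistics** — binned frequency / cumulative distributions
  (bin width 4 µm²), Mann–Whitney U and two-sample Kolmogorov–Smirnov
  comparisons, median-scaling normalization between genotypes, and
  per-cell area heat maps.
- **Spatial dispersion** — pit-relative (A/P, D/V) coordinates, standard
  deviations of the lower-area quantile, and a permutation test for
  whether constricted cells cluster at all.
- **Myosin intensity** — junctional vs apicomedial integrated densities
  (background-corrected) from a band around each cell contour, their
  ratio, 0–100 rescaling, and the Pearson area–intensity correlation.
- **Boundary circularity** — placode boundary tracing (with a ventral
  midline chord), one-cell-layer outer/inner shifts, and the
  isoperimetric circularity `C = 4π·area / perimeter²` (1 for a circle).
- **Pulsation** — peak detection on apicomedial intensity traces and
  pooled inter-pulse interval statistics.
- **Synthetic placodes** — a generator producing two-channel images of
  100–200 polygonal cells (power-diagram tessellation with Lloyd/Newton
  area control) with clustered, random, uniform or expanded area fields,
  known intensity pools, PSF blur, Poisson noise, and pulsatile traces
  with normally distributed intervals — ground truth for every
  measurement above.

## A worked example

```python
import numpy as np
from placodekit import (SceneConfig, generate_scene, render_channels,
                        segment_cells, lower_quantile_cells,
                        pit_relative_coordinates, dispersion_stats,
                        clustering_permutation_test, scene_cell_table)

cfg = SceneConfig(n_cells=150, field_mode="clustered", seed=0)
scene = render_channels(generate_scene(cfg))

labels, cells = segment_cells(scene.junction_image,
                              scene.label_image > 0, cfg.pixel_size)
print(len(cells))                       # 150  (all cells recovered)

sub = lower_quantile_cells(cells, 0.30)  # most constricted 30%
frame = pit_relative_coordinates(sub, scene.pit_center)
print(dispersion_stats(frame))
# {'sd_AP': 9.0, 'sd_DV': 10.5, 'n': 45}  -- tight around the pit
print(clustering_permutation_test(cells, q=0.30, seed=0))
# 0.001  -- constricted cells are significantly clustered
```

With `field_mode="random"` the same area multiset is spread over the
tissue: the D/V standard deviation roughly doubles (≈ 21 µm) and the
clustering p-value becomes non-significant — the quantitative signature
separating coordinated constriction from its spatially uncoordinated
(mutant-like) counterpart.

The `examples/` directory holds one short script per capability
(synthetic scenes, segmentation and area distributions, dispersion,
myosin partitioning, circularity, pulses); each prints the numbers it
computes and says what they mean. A thin CLI mirrors the library:

```sh
placodekit simulate --mode clustered --n-cells 150 --seed 0 --out-dir sim
placodekit segment sim/junction.tif --out-dir seg
placodekit run-all --out-dir demo --seed 0
```

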