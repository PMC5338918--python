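# Methods

This note documents the models, defaults and numerical choices behind
`placodekit`, and what the synthetic ground truth does and does not
emulate.

## Coordinate and unit conventions

All geometry is in continuous micrometres: x runs along the
anterior–posterior (A/P) axis, y along the dorsal–ventral (D/V) axis.
Rasters use 0-based indices with pixel centres at `(i + 0.5) · pixel_size`;
images are indexed `[y, x]`. Intensities are arbitrary units, interpreted
as expected photon counts when Poisson noise is enabled.

## Synthetic placode generator

**Tessellation.** A placode of `n_cells` (default 150) tiles a disk whose
area is `n_cells · base_area` (default base area 35 µm², a mid-range
apical area for columnar epithelial precursors). Cells are power-diagram
(additively weighted Voronoi) cells. Per-cell target areas are realized in
three phases: (1) unweighted Lloyd relaxation on a coarse raster to obtain
a spatially uniform, well-shaped tessellation; (2) weighted Lloyd with a
proportional weight update toward the targets; (3) a Newton polish on the
exact polygon cells, using the fact that the Jacobian of cell areas with
respect to weights is a weighted graph Laplacian over shared edges
(`dA_i/dw_i = Σ_j L_ij / 2d_ij`). Realized areas typically match targets
to ~1% (the package guarantees 15%); the sum of cell areas equals the
region polygon's shoelace area to machine precision by construction.

**Area fields.** At pit distance `d` the target area is
`base_area · (1 − depth · exp(−d²/2σ²))` (clustered), its spatial
permutation (random — same multiset, shuffled positions), a constant
(uniform), or `base_area · (1 + depth·exp(·))` (expanded). One global
factor rescales the multiset so the targets tile the fixed region exactly;
conservation of tissue area is preferred over the absolute area scale,
and the monotone dependence on pit distance — what downstream statistics
consume — is unaffected. Defaults: constriction depth 0.5, σ = 0.35
placode radii, pit offset 0.55 radii posterior of the tissue centre
(invagination starts near the posterior edge in vivo).

**Channels.** The junction channel is a ridge of width `junction_width`
(default 0.5 µm) on every cell edge at a constant amplitude (150 counts).
The myosin channel adds, per cell, a centred Gaussian apicomedial blob
whose width scales with the apical domain (σ = 0.11·√area, so constricted
cells keep their medial pool central) and whose integrated density is the
cell's junctional integrated density divided by the configured
junctional:apicomedial ratio; an explicit per-cell density array can
override this (used, for example, to build myosin ∝ 1/area scenes for the
correlation analysis). Both channels are blurred with a Gaussian PSF
(default σ 0.25 µm at 0.2 µm/px) and, under the Poisson model, offset by
a 10-count baseline and shot-noise sampled. With noise off and zero PSF
the junction channel is exactly the ridge mask times the amplitude, which
anchors the rendering tests.

**Tissue context.** Optional surrounding epithelial layers
(`surround_layers`) add cells in an annulus. With `smooth_boundary`,
placode cells are tessellated within the disk and surround cells within
the annulus, so the placode rim follows the circle exactly — emulating
the smooth, taut boundary imposed in vivo by the supracellular actomyosin
cable, and giving the circularity comparison a ground truth in which the
placode boundary is smooth while one-cell-shifted boundaries are jagged.

**Pulses.** Each cell's apicomedial trace is a baseline (100) plus
Gaussian-in-time pulses (FWHM 20 s, amplitude 300) at event times whose
gaps are Normal(131.7 s, 42.8 s) — the measured salivary-gland rhythm —
truncated to exceed the pulse width by resampling, so pulses never merge
completely and peak detection stays well-posed. Traces are sampled every
5 s (the live-imaging acquisition interval) for 360 frames (30 min) with
Gaussian read noise (σ 15, SNR 20). Phases are independent across cells
(pulses are asynchronous in vivo).

**What the generator does not emulate.** Cell rearrangement and tracking
through time, 3D tissue curvature, supracellular cable dynamics,
anisotropic cell shapes under tension, uneven illumination, and
junctional intensity variation between edges. Tests passing on these
scenes demonstrate the correctness of the measurement operations, not
robustness to every artefact of real micrographs.

## Segmentation

Cells are watershed basins of the smoothed junction channel (Gaussian
σ 1 px). Seeds are maxima of the distance transform of the
below-Otsu-threshold interior, separated by at least
`min_seed_distance_um` (default 2 µm, roughly the smallest expected cell
radius); seeds are planted in raster order so flooding is deterministic.
Labels smaller than 4 µm² are dissolved into the neighbouring basin.
Areas are pixel counts times pixel area; polygons are marching-squares
contours, and polygon (shoelace) area agrees with pixel-count area within
5% on every cell, which is asserted on synthetic scenes.

Internalization depth cannot be inferred from a single 2D projection, so
`depth` is an input column (populated from focal-plane metadata on real
data; zero in synthetic scenes). Stage calling: max depth > 2 µm ⇒ deep
invagination; 0 < depth ≤ 2 µm ⇒ beginning of invagination; all cells at
the surface ⇒ clustered apical constriction if the lower-30%-area cells
cluster spatially at α = 0.05 under the permutation null, else before
invagination. The clustering criterion operationalizes a distinction that
is otherwise qualitative; the p-value is reported in the stage call so
users can see the evidence. Boundary cells (touching the mask edge) are
flagged but kept by default, since whole placodes are analysed.

## Area statistics

Histograms use half-open bins `[k·w, (k+1)·w)` from 0 µm² with w = 4 µm²
by default. Percentages use the pooled-cell denominator. Two-sample
comparisons report the Mann–Whitney U and two-sample KS statistics with
their p-values; the KS D is verified against a brute-force
empirical-CDF-gap oracle in the tests, while p-values are delegated to
scipy. Median scaling multiplies every area in the target sample by
`median(reference)/median(target)`; the bundled genotype-like presets are
constructed so that this factor is exactly 1.2, the normalization used
for non-invaginating mutant glands. The operation is idempotent after the
first application.

## Spatial dispersion

Pit-relative coordinates are centroid minus pit centre, axis-aligned.
Dispersion is summarised by sample (n−1) standard deviations along A/P
and D/V — small placodes argue for the unbiased denominator. On real
data the pit centre defaults to the centroid of cells deeper than 2 µm
when present, otherwise it must be supplied. The clustering permutation
test uses the mean pairwise distance among the lower-q cells as the
statistic and random equal-size subsets as the null, with the add-one
correction `p = (1 + #{null ≤ obs})/(n_perm + 1)`; ties in area are
broken by cell id so the subset is deterministic. Under random-mode
scenes the p-values are uniform (verified over 200 generator seeds).

## Myosin intensity

The junctional compartment of a cell is the band of half-width
`band_width/2` around its contour clipped to the cell; the apicomedial
compartment is the eroded remainder, so the two partition the cell and
shared edges are split at the contour midline between neighbours
(nothing is double-counted). The hand-drawn regions this replaces were a
manual convention, as was averaging three repeated tracings; the derived
regions are deterministic, so a single measurement is taken. The default
band is 0.5 µm; when measuring rendered scenes the band defaults to
`junction_width + 4·psf_sigma` so the blurred ridge falls inside it —
a measurement matched to known optics. Integrated density is the sum of
background-corrected intensities with negative residuals clipped to zero;
the background level defaults to the mean intensity outside the labelled
tissue. Ratio recovery on noisy scenes is within a few percent for
configured ratios 0.5–4 on interior cells; rim cells lose part of their
outer-edge signal to the background and are excluded from recovery
statistics (measurements in vivo likewise used placode-interior cells).
Cells whose band consumes the whole interior are flagged
(`medial_empty`) and their ratio is NaN, not infinity.

## Circularity

`C = 4π·area/perimeter²`; 1 for a circle by the isoperimetric
inequality, and ≤ 1.02 for every traced contour (the 2% allowance covers
rasterization). Contours are marching-squares traces simplified with a
1-px tolerance — a raw pixel-edge perimeter would overestimate length and
break the bound badly. "One cell layer" is defined by edge adjacency on
the label raster (corner contact does not count): the outer boundary adds
edge-adjacent non-placode cells, the inner boundary removes cells
adjacent to non-placode labels or background. The ventral midline closes
the contour as a straight chord where the placode touches it; the chord
is counted in the perimeter by default, with a flag to exclude it.
Isolated specks below 1% of a region's pixels are ignored during
tracing; larger fragmentation is an error. Group comparisons report
means ± SEM and unpaired two-tailed t-tests, and tolerate missing groups
(some genotypes only permit placode and inner measurements).

## Pulse analysis

Peaks are local maxima with prominence ≥ 2× the trace's median absolute
deviation (a scale-free threshold tied to noise) and separation ≥ 30 s,
after Gaussian smoothing by one frame — well under a pulse width — so
single-frame noise excursions do not register. Peak time is the apex
sample, keeping the quantization error within one frame interval;
parabolic sub-frame interpolation is available behind a flag. Interval
statistics pool all inter-peak intervals across cells (the pooled
convention), with per-cell means reported alongside. On default
generator traces detection sensitivity and precision both exceed 0.9 and
the pooled mean recovers the generating 131.7 s interval to well within
5%; the residual upward bias from occasional merged pulses is ~1%
because gaps shorter than the 30 s separation occur with probability
under 1%.

## Problem sizes

Default analyses use 150-cell placodes at 0.2 µm/px (≈ 450² px canvases),
50–60 pulse traces of 360 frames, 999 permutations for single tests and
199 where many seeds are aggregated, 100 seed pairs for the
clustered-vs-random dispersion comparison and 200 seeds for the
permutation-null calibration — sizes at which every statistic above is
stable while a full run remains a desk-scale computation.

## Known limitations

- Area control in the tessellation is numerical, not exact; the 15%
  guarantee is loose relative to typical ~1% behaviour.
- The smooth-boundary option changes rim-cell areas relative to their
  targets (the circular clip takes precedence there).
- Watershed segmentation assumes closed junctional ridges; gaps in the
  junctional signal merge cells, which the generator does not emulate.
- Stage calling depends on a user-supplied depth column for real data.
- The intensity partition assigns the full band inside each cell to that
  cell; with very wide bands relative to cell size the apicomedial
  compartment vanishes and the ratio is undefined rather than
  extrapolated.
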