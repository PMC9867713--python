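# Methods

`epiquant` quantifies how nuclear marker expression relates to local
disruption of an epithelial monolayer's tight-junction (TJ) network, plus
the two companion measurements used in such studies: radial fate-domain
profiles of circular micropattern colonies and comparative-Ct RT-qPCR.
This note describes the models, the defaults and the numerical choices, and
what the synthetic validation does and does not establish.

## The spatial statistic

The central quantity is the percentage of marker-positive cells as a
function of distance from "disrupted areas" — regions where the junction
network (ZO1-type staining) is fragmented into foci or absent. The
computation is:

1. **Disrupted mask.** Either supplied manually (any binary image) or
   detected automatically (below). The reported area fraction is exactly
   `100 · true_pixels / total_pixels`.
2. **Distance bands.** An exact Euclidean distance transform of the
   non-disrupted pixels, in µm, binned into half-open bands
   `[0, 30), [30, 60), [60, 90), [90, ∞)`; the disrupted pixels themselves
   form a fifth "0 µm" class. The five masks are pairwise disjoint and tile
   the image — this is asserted pixel-wise in tests, and the band
   assignment is checked against an independent nearest-pixel search. The
   EDT is used rather than iterated ring dilation because dilation with a
   discrete structuring element approximates a chamfer metric, while the
   band definition is genuinely Euclidean ("µm away from" the mask).
3. **Binning cells.** Each nucleus goes to the band containing its centroid
   (rounded to the nearest pixel). Centroid assignment, rather than
   any-overlap, makes the per-cell count unambiguous. Empty bands report
   `NaN`, never `0` — a band with no cells carries no information.
4. **Slope.** Ordinary least squares of percentage against band position.
   The default x is the band index 0..4 (the slope unit is then percentage
   points per band); `x_convention="bin_center_um"` uses representative
   distances (0, 15, 45, 75, 105 µm — the unbounded last band is placed at
   its lower edge plus half the preceding width). The result records the
   convention, the OLS standard error, and the number of bands used; the
   95% CI uses Student's t with `n_used − 2` degrees of freedom (with five
   bands that is t = 3.18 — a normal quantile here would under-cover
   noticeably).

## Mask construction (ImageJ-style)

**Nuclei**: median filter (disk radius 2 px) → automatic Huang threshold →
hole filling → watershed split of touching nuclei, seeded at local maxima
of the distance transform with minimum separation 0.5× the expected nucleus
diameter (default 10 µm) → area gate 25–400 µm² (debris and clumps out).

**Marker positivity**: rolling-ball background subtraction (radius 20 px) →
white top-hat (disk radius 10 px) → automatic Otsu threshold; a nucleus is
positive iff ≥ 50% of its pixels exceed the threshold. The
fraction-of-pixels rule (rather than a mean-intensity cutoff) is robust to
partial nuclear staining; the fraction is configurable.

**Thresholds.** Both Huang (minimum fuzzy entropy) and Otsu (maximum
between-class variance) are computed exactly on the integer histogram over
the occupied gray range — which contains the global optimum over the full
16-bit range — and are verified in tests against exhaustive brute-force
search. Worth knowing: on a well-separated bimodal histogram Huang sits
just above the lower mode (a tight background class minimizes fuzziness),
while Otsu sits nearer the variance-weighted midpoint. Filter radii and
size gates are exposed in `SegmentationParams`; the values above are
defaults chosen for ~1 µm/px imaging of hiPSC-scale nuclei, not tuned
constants.

**Disrupted-region detection.** Manual annotation of disrupted areas is not
reproducible, so an automated heuristic is provided (manual masks remain
first-class inputs and take precedence in the pipeline). The thresholded,
skeletonized junction network of an intact confluent epithelium has a
characteristic line density of about `2/d` px⁻¹ (d = mean cell diameter in
px — the edge-length-per-area of a Voronoi tessellation at that density). A
sliding window (default 30 µm) measures local skeleton coverage; pixels
below `0.5 · 2/d` are disrupted, and components smaller than 500 µm² are
discarded (as are holes below the same area). The absolute cutoff — derived
from the expected density rather than from a percentile of the image at
hand — keeps the detector stable when most of the field is disrupted, where
data-derived cutoffs collapse. Two degenerate contracts: a featureless or
empty junction channel is fully disrupted (100%); a perfect network yields
an empty mask (0%). The heuristic is a stand-in for expert annotation, not
a claim of equivalence to it; on synthetic fields it recovers planted
fractions of 0.1–0.6 within ~1 percentage point at IoU ≳ 0.87.

**Apical surfaces.** Cells are the 4-connected components of the complement
of the skeletonized junction network; the 1-px skeleton belongs to no cell,
so the measured area is the pixels strictly enclosed by the junction line.
This under-reports the geometric polygon area by roughly half the cell
perimeter in pixels — about 3% at 0.5 µm/px for 30 µm cells, and
proportionally more for small cells or coarse pixels; measure at the finest
available pixel size. Border-touching cells, cells overlapping an excluded
disrupted mask, and components above 2500 µm² (unclosed network) are
dropped.

## Z-profile peak distances

For axial colocalization questions (e.g. how far below the junction plane a
receptor sits), both channels are averaged per z-slice within an ROI and
the peak-to-peak distance is reported in nm. Peaks are refined to sub-step
precision with a three-point parabolic fit (the refinement is clipped to
±0.5 step), so a planted 1.2 µm separation on a 0.3 µm grid is recovered
well within half a z-step. A peak on the first or last slice sets
`edge_peak_flag`: the parabola is undefined there and the separation is a
lower bound only.

## Micropattern radial profiles

Colonies are disks (default 700 µm diameter) located from the nuclei
channel: largest Otsu-foreground component, centroid center, minimal
enclosing circle radius. Intensities are averaged in equal-width annuli
(default 50 bins → 7 µm bins at 350 µm radius); outside-disk pixels are
excluded rather than zero-filled so edge bins are not diluted. Aggregation
across colonies reports mean and first/third quartiles per bin, with every
profile divided by the maximum of the **control condition's mean profile**
for that stain — "maximum of the control profile" does not specify
mean-of-colonies vs per-colony maxima, and the mean-profile maximum is the
stable choice; the control's normalized mean therefore peaks at exactly
1.0, and a condition at 2× control intensity reads 2.0. Profiles are
intensity-based; positive-cell-density profiles would be a natural
extension but are not implemented.

## RT-qPCR relative quantification

ΔCt = Ct_gene − Ct_housekeeping per sample and replicate (default
housekeeping GAPDH); ΔΔCt subtracts the mean ΔCt of the reference sample
for that gene; RQ = 2^−ΔΔCt with amplification efficiency fixed at 2.
ΔΔCt is computed per replicate and summarized afterwards (mean ± SEM), so
replicate variance survives the transformation; because the mean of
2^−ΔΔCt is not 2^−mean(ΔΔCt), the summary reports both (`mean_rq` and
`rq_of_mean_ddct`), labeled — the latter is exactly 1 for the reference
sample. Two identities pin the arithmetic: adding a constant to every Ct of
a sample leaves RQ unchanged, and swapping reference and test maps
RQ → 1/RQ.

## The synthetic-data generator

Monolayers: jittered-grid cell centers (spacing = mean cell diameter,
default 15 µm; uniform jitter ±0.35 spacing) with the Voronoi tessellation
as the cell map; the junction channel is the tessellation's edge network;
nuclei are soft disks of 0.32× the cell diameter at cell centers. Disrupted
patches are Gaussian bumps at `n_patches` random sites, roughened with
smoothed noise and thresholded at the exact quantile for the requested area
fraction — so the planted fraction is met to within quantile ties, and
patch outlines are irregular. Inside a patch the junction network is either
erased or replaced by bright foci (~one per cell area). Marker positivity
is a per-cell Bernoulli draw with probability given by the cell's true
distance band (cells inside a patch have distance 0 and use the first
band's probability); the defaults (0.9, 0.7, 0.5, 0.3) plant a strong
decaying gradient. Images are 16-bit unsigned with a 100-count baseline and
Gaussian read noise (default SD 50); all randomness flows from one seeded
generator, so identical spec + seed is bit-identical. The imaged field size
is a free parameter (default 512×512 px at 1 µm/px); the large-field
parameter-recovery tests use 1024×1024 px, which yields ≥ 200 cells in
every distance band at 30% disruption.

Colonies: disks with annular fate domains `(channel, inner r/R, outer r/R,
intensity)` plus a uniform DAPI disk and per-colony read noise; the ground
truth is the noise-free radial function. Time courses re-generate the
monolayer at each time point with disrupted fraction = 1 − organized
fraction and a time-point-derived seed.

What the generator does **not** emulate: optical blur and shading,
cell-shape anisotropy and crowding gradients, intensity variation within
positive nuclei, out-of-focus light, mitotic figures and debris, or any
signaling mechanism linking disruption to expression (positivity is planted
statistically, not mechanistically). Passing tests therefore establish that
the measurement chain recovers known spatial structure under realistic
noise — not that the detector matches a human annotator on real stainings.

## Problem sizes and runtime choices

Test and acceptance runs use 256–1024 px fields, 6 colonies per condition,
100-replicate slope-coverage simulations at 400 cells per band, and 50
random masks for the distance oracle; these sizes give stable statistics
while keeping a full run in tens of seconds. The per-band recovery check
asserts five simultaneous binomial intervals and uses Bonferroni-adjusted
per-band quantiles (z = 2.576) so the family confidence is 95%.

## Known limitations

- The slope's unit depends on `x_convention`; results record the convention
  and no equivalence between the two scales is implied.
- The junction-continuity detector needs the mean cell diameter as a scale
  parameter; a badly wrong value shifts the coverage cutoff.
- Huang's exhaustive scan is O(L²) in the occupied gray-level range; for
  images spanning the full 16-bit range it is exact but slow — rescale or
  pre-clip such images.
- `locate_colony`'s minimal enclosing circle is sensitive to bright debris
  connected to the colony; a fixed nominal radius can be supplied instead.
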