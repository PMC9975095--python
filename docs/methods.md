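# Methods

## Model of the measurement

A microglia in a 2D section is treated as a compact cell body (soma) plus
a set of thin processes. The activation state is summarized by the
morphology ratio, total process length divided by soma area (µm/µm²):
ramified, surveilling cells combine long processes with small somata
(large ratio), amoeboid phagocytic cells the opposite (ratio near 0).
Everything the pipeline does serves to measure that quantity — and ten
companion parameters — robustly for every object in a field.

Assumptions: inputs are single stitched 2D grayscale channels (z-stacks
are max-projected on read); staining is bright-on-dark in fluorescence
and dark-on-bright in chromogen mode; the pixel size (µm/pixel) is known
and supplied by the user — it is deliberately never guessed from file
metadata. Intensities are never rescaled, because CD68 sum intensities
are reported in raw units.

## Segmentation

**Binarization (hysteresis).** The weak threshold is the Otsu level of
the glia channel; the strong threshold sits `strong_blend` (default 0.5)
of the way from there to the image maximum. Both can be overridden as
quantiles of the positive intensities or as absolute values. Sobel edge
pixels above their own Otsu level are unioned into the weak mask to
recover faint thin processes, but only where the intensity is at least
`edge_floor` (default 0.5) of the weak threshold: a step edge has a
one-pixel gradient halo on its *outside*, and admitting it would inflate
every mask by a pixel of background. The union is closed with a 1 µm
disk; only 8-connected components containing at least one strong pixel
survive. Consequences used by the tests: the output always lies inside
the closed weak mask, and every output component contains a strong seed.

**Mask correction.** Structures smaller than `min_area_um2` (default
10 µm²) are deleted first, then enclosed holes up to `max_hole_um2`
(default 5 µm²) are filled (background taken 4-connected against the
8-connected foreground). Afterwards, single-pixel bridges are separated:
a set pixel is deleted when its removal splits its component into parts
that each meet the small-structure minimum. Candidates are found by a
local criterion (≥ 2 background 4-neighbours and locally disconnected
neighbour groups) and verified by relabelling; among valid articulation
pixels the one with the fewest neighbours is removed first, so a genuine
bridge is cut rather than a block corner next to it.

**Soma extraction.** Partial topological thinning (3 iterations ≈ 1 µm
at the default pixel size), opening with a 1.75 µm disk, dilation by
1.5 µm, intersected with the mask. Thinning recedes about one pixel per
iteration, so any structure whose half-width is below
`opening_radius + thinning depth` — i.e. every process — vanishes, while
somata (radius ≥ 3 µm in the generator's world) survive and are regrown
to their original extent. The opening radius default of 1.75 µm is the
calibrated ceiling below the smallest soma radius minus the thinning
depth; larger values silently erase the smallest cell bodies.

**Nuclei.** The nucleus channel is thresholded (Otsu, or a configurable
quantile), hole-filled, cleaned of specks below 5 µm², and split by a
watershed on the Euclidean distance transform with seeds at distance
maxima at least 1 µm apart (every component is guaranteed one seed).
Centroids — the nucleus position matrix — are per-label centers of mass,
snapped into their region when concavity puts the raw center outside. In
chromogen mode there is no nucleus channel; the centroids of the soma
regions stand in for nuclei, which is what makes the DAB arm of the
pipeline equivalent to the fluorescent arm on the same field.

**Component sorting.** Each 8-connected glia component is annotated with
the number of nucleus centroids on it: 0 → discarded (process fragments
from cells in other focal planes), 1 → single cell, ≥ 2 → cluster.

## Morphometry

The process skeleton is the topological thinning of (mask − soma).
Subtracting the soma leaves crescents of cell-body pixels hugging the
soma boundary whose skeleton arcs are pure artifacts, so skeleton pixels
closer than 3 px to the soma are removed, fragments shorter than 8 px
(≈ 2.7 µm, below the skeletonization resolution) discarded, and side
twigs shorter than 6 px hanging off junctions pruned — 6 px is just above
the rendered process half-width, the scale at which thinning artifacts
live. Skeleton length counts each orthogonal link as 1 and each diagonal
as √2 (raw pixel counts understate diagonal runs by up to 29 %). The
record's process length additionally adds, for each skeleton end adjacent
to the soma, its exact distance-transform gap to the soma boundary: the
process physically continues to the cell body and the gap is an artifact
of subtracting the soma first.

Endpoints are skeleton pixels with ≤ 1 skeleton neighbour; branch points
are pixels with ≥ 3 neighbours, 8-adjacent candidates merged into one
junction. The per-record endpoint count excludes endpoints within 5 px
(Chebyshev) of the soma so that it counts process *tips*, not the cuts
where processes meet the cell body. Percent fill is object area over its
axis-aligned bounding box (in (0, 1]; compact cells fill their box).
Span ratio is the major/minor axis ratio of the moment-equivalent
ellipse from the second central moments of the pixel coordinates;
collinear masks return a configured cap and a flag. Perimeter follows
the outer boundary by Moore-neighbour tracing, orthogonal steps 1 and
diagonal √2 — tested against the marching-squares contour within a
discretization tolerance, since the two conventions describe the same
curve only for hole-free masks. CD68 is the exact raw sum of the
activation channel under the cell mask. A zero soma area flags the
record degenerate; its ratio is reported missing and the object
classifies as activated (a body reduced to a blob with no measurable
processes).

## Classification and statistics

Two cutoffs partition the ratio scale: `ratio < t_low` activated,
`t_low ≤ ratio ≤ t_high` intermediate, larger non-activated. No published
numeric cutoffs exist for this scale, so the package defaults
`(0.10, 1.0)` are the (rounded) output of `calibrate_thresholds` — tail
midpoints between adjacent phenotype ratio distributions — on the bundled
reference scene (`synthgen.reference_scene(seed=0)`, 30 cells per
phenotype, default noise); they should be recalibrated per experiment.
Cluster records above `max_cells` (default 15) are dropped before
reporting, an outlier guard for body-area and process-length summaries.
Histograms of the ratio are built per stratum (single cells, clusters,
all) with half-open interior bins, a right-inclusive last bin, and
out-of-range values clipped into the edge bins so counts always sum to
the stratum size.

Descriptive statistics: natural-log transforms (endpoint counts shifted
by +0.5 before the log because they contain zeros), geometric mean ratios
`exp(mean log a − mean log b)` readable as fold changes, and Spearman
rank correlations with a plain Fisher-z confidence interval
(`z ± z_crit/√(n−3)`). Repeated-measures random-effects modelling with
animal-level intercepts is deliberately out of scope; these summaries
are descriptive only.

Validation mode samples single cells uniformly without replacement with
`numpy.random.default_rng(seed)`, exports class-tinted crops, averages
three replicate manual scores (rounded half up — the natural reading of
"closest whole number" at .5), maps the 4-point manual scale onto the
three classes (4 → activated, 2–3 → intermediate, 1 → non-activated), and
tallies detection and score agreement. The optional `identified` column
of the manual CSV records whether the trace itself was judged correct;
without it every matched cell counts as a true positive.

## Synthetic scenes

The generator emulates the ramified→amoeboid continuum with three
phenotypes (ranges inclusive, all µm):

| phenotype    | soma radius | processes | length | branch/step | width | CD68 |
|--------------|-------------|-----------|--------|-------------|-------|------|
| ramified     | 3.0–4.5     | 4–6       | 18–30  | 0.010       | 1.0   | 0.15 |
| intermediate | 4.5–6.0     | 2–4       | 10–16  | 0.004       | 1.2   | 0.45 |
| amoeboid     | 6.0–8.0     | 0         | —      | 0           | 1.5   | 0.90 |

Amoeboid cells carry no processes at all — the phagocytic end state is a
bare body — which also makes truth/measurement closure well defined.
Soma size and CD68 rise monotonically with activation. Processes are
persistent random walks (step = 1 px, heading drift σ = 0.03 rad/step)
leaving the soma in evenly spaced directions with ±8° jitter; branches
split off at 30–45° with length ≥ 9 µm. Geometry is constructed
non-self-intersecting by design: a polyline that re-enters the soma or
comes within 4.5 µm of a sibling (3.4 µm for a branch against its parent
beyond a 6 µm junction zone) is resampled. The margins exceed process
width plus the closing diameter, so on noise-free renderings the
pipeline sees exactly the constructed topology; the separations were
chosen from that geometric argument, not tuned against any test. Truth
(soma area πr², summed polyline lengths, one tip per polyline, one
branch point per branch event) is computed from the geometry, never from
pixels. Scenes render as three float channels (per-cell amplitudes
160–210 over zero background), with optional Gaussian PSF blur (default
σ = 0.4 µm) and additive Gaussian noise (default σ = 4, i.e. SNR ≈ 40 —
clean high-content imaging); nuclei are 2.5 µm disks at soma centers.
Chromogen renderings are `250 − glia` so noise-free inversion is exact.
The default pixel size is 0.334 µm/px, a plausible 20× high-content
sampling. Cluster specs lay somata in gently curving chains with
overlapping bodies but disjoint nuclei.

What the generator does **not** emulate: uneven illumination and
staining gradients, autofluorescence and vascular artifacts, out-of-focus
cells from other layers, overlapping processes of neighbouring cells, and
textured chromogen background. Passing the closure and proportion tests
therefore shows the measurement chain is correct on well-posed inputs; it
does not certify segmentation quality on tissue with those confounds,
where thresholds and structuring-element sizes need per-dataset review.

## Problem sizes and determinism

Closure checks use 20-cell noise-free scenes; phenotype ordering and the
60/30/10 mix-recovery run ~500 cells across four ~125-cell tiles
(~2800 px square each), sizes chosen to make binomial error bars small
while keeping a laptop run in tens of seconds. Segmentation contains no
randomness; identical inputs and configuration give identical masks,
tables and overlays byte for byte, and all sampling flows through a
single seeded generator recorded in the run provenance.

## Known limitations

Perimeter follows the outer contour only (holes do not contribute);
process length on heavily curved processes is quantized by the skeleton
lattice; endpoint counts on real tissue depend on spur pruning (6 px
default) that was calibrated at 0.334 µm/px and should scale with pixel
size; chromogen mode's soma-surrogate nuclei cannot distinguish touching
cells whose somata merge into one region; and the activation cutoffs are
dataset-dependent calibration values, not biological constants.
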