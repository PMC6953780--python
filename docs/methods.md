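# Methods

## Model and assumptions

Thresholding-based color segmentation assumes that each homogeneous object
in an RGB image shows up as a bell-shaped mode in the intensity histogram
of each color plane, so that the optimal class boundaries sit in the
valleys between modes.  The package implements three thresholders that
share this assumption and a common post-process:

* **Hierarchical-histogram thresholding** builds, per plane, a stack of
  histograms.  Level 1 is the dense classic histogram (all `L = 256` bins,
  zero counts included, so valley plateaus inside zero runs resolve to the
  run midpoint).  Each next level cuts the bin sequence at the valleys of
  the count sequence and greedily merges each bell region into bins whose
  intensity span stays within a per-channel budget `w_i`.  The iteration is
  a contraction: the bin count strictly decreases until a level reproduces
  its predecessor, so a fixed point is reached in at most `L` steps.  The
  top level thresholds the image directly — pixel intensity `v` maps to the
  representative intensity of the bin whose half-open interval
  `(previous lR, lR]` contains it, which makes the quantized plane's
  histogram identical to the top level.
* **Histon thresholding** doubles the count of pixels whose neighborhood is
  color-similar (total window color distance below `T0`), a rough-set upper
  approximation of the histogram.
* **Roughness-index thresholding** uses `rho = 1 - h/h'`, which is high
  where a mode is spatially homogeneous.  Both baselines place thresholds
  at the minima between significant profile peaks.

Regions/clusters throughout the merging stage are *global color classes*
(distinct quantized RGB triples), not connected components: merging
operates on color distance and the reported "color number" counts distinct
colors.  Connected components are used only as the region substrate of the
F/Q metrics (where they are the conventional choice; color-class regions
remain available via `regions="color"`).

## Parameters

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| `w` | global bin-merge budget, intensity units | 15 | the only parameter of the hierarchy stage |
| `trim_fraction` | tail mass excluded from the channel span | 0.01 | robustifies `w_i = w * span / L` against sparse tails; strict `>` at the cut |
| `T_n` | small-cluster pixel fraction | 0.001 | clusters with `count < T_n*M*N` are absorbed |
| `T_d` | close-cluster color distance | 20 | merging stops when all pairwise mean distances are `>= T_d` |
| `P x Q`, `T0` | baseline neighborhood and similarity threshold | 3×3, 100 | conventional small-window values; configurable |
| `height_frac`, `min_distance` | significant-peak rules | 0.2, 10 | peak height must exceed 20% of the mean peak height; peaks at least 10 apart |
| normalization target | longest image side | 320 px | bilinear, rounded half-up; nearest-neighbor available |

## Numerical choices

* Representative intensities are count-weighted means rounded half-up
  (ties upward), so results are bit-stable and displayable as 8-bit values.
* `GetMergeBin`-style grouping closes a group when the next bin's
  representative intensity exceeds the group *start* by more than `w_i`
  (guaranteeing at most `floor(span/w_i) + 1` bins per region); an
  adjacent-gap criterion is available via `criterion="gap"`.
* Zero-count merged groups are dropped: no pixel maps into them and
  weighted means stay defined.  A valley bin closes the region on its left.
* Small-cluster absorption proceeds smallest-first with re-testing of the
  grown cluster; close-cluster fusion is greedy global-minimum
  agglomeration with lowest-id tie-breaks, the survivor keeping the
  pixel-weighted mean.  Both passes are deterministic, and their
  composition is idempotent.
* MSE is the mean per-pixel Euclidean color distance (root inside the pixel
  sum); this is the scale on which thresholding results are conventionally
  reported (single digits to low tens for natural images).
* Q's logarithm is base 10; PRI/VOI/GCE are computed from the label
  contingency table (equivalent to pair enumeration, verified against
  brute-force oracles); VOI uses log2.
* BDE extracts one-sided boundaries (a pixel whose right or lower
  4-neighbor has a different label), so two parallel straight boundaries
  `k` columns apart score exactly `k`; distances use Euclidean distance
  transforms, symmetrically averaged.  A single-region map has no boundary
  pixels and contributes zero displacement.
* Degenerate inputs: an empty histogram has no span (error); a uniform
  plane gets `w_i = 0` and collapses to one bin at level 2; a single
  undersized cluster is returned unchanged.

## Synthetic study conditions

The block generator emulates the regime the method targets: `k` rectangular
color regions (vertical stripes, each far above 1% of the pixels), palette
colors drawn from a coarse RGB grid so any two differ by at least 120
(pairwise distance ≥ 120 guaranteed; larger separations by greedy
filtering), and i.i.d. Gaussian pixel noise (σ = 4 by default) rounded and
clipped to the 8-bit range.  Clipping rather than wrapping introduces
negligible bias at σ ≤ 5.  The generator is deterministic per seed and its
label map is a valid partition for the external metrics.

What it does *not* emulate: natural-image texture, gradients, shading,
anti-aliased edges, or the multi-observer ambiguity of human ground truth.
Passing the recovery tests therefore demonstrates correctness of the
algorithmic chain under its own model assumptions, not performance on
natural photographs, where mode overlap and texture make the initial color
counts far larger and the metric values non-ideal.

Problem sizes in the test-suite and acceptance runs — 64×64 random images
for conservation/termination sweeps, 96×128 block fixtures for recovery,
5×5 label maps for the brute-force metric oracles — were chosen as the
smallest sizes at which every property is non-trivially exercised.

## Known limitations

* Benchmark-scale evaluation (mean metrics over a natural-image corpus with
  human ground truth) requires the corpus itself; the package reads the
  plain-text `.seg` ground-truth dialect and scales to such runs, but ships
  no downloader.
* The exact published baseline parameterizations (`T0`, window size) for
  histon/roughness runs vary across the literature; the defaults here are
  the conventional small-window values and are configurable.
* Valley detection at levels ≥ 2 operates on bins by position, although
  bins are no longer unit-spaced; this follows the uniform treatment of the
  bin sequence across levels.
* Small satellite bins at mode edges can survive to the top level when a
  valley separates them from the mode body; they are absorbed by region
  merging rather than by the hierarchy itself.
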