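# Methods

This note documents the models, conventions and numerical choices behind
the package: what each measurement computes, what the synthetic scenes
emulate (and what they do not), and where the design was genuinely open.

## Conventions

All coordinates are `(row, col)`, 0-based, origin at the top-left pixel.
Intensities are unsigned 8- or 16-bit integers at every I/O boundary;
conversion to floating point happens inside computational routines, so
TIFF round trips are bit-exact. All spatial analysis is 2-D with
8-connectivity; skeleton pixel-class counts are reported under the
conventional "voxel" vocabulary used for such censuses, although the
implementation operates on single confocal planes. Branch lengths are
Euclidean step sums (1 per orthogonal step, √2 per diagonal step) in pixel
units; conversion to µm happens only when a pixel size is supplied, since
none is assumed by default.

## Co-localization statistics

Given channels A (probe) and B (reference) over a pixel gate (whole image,
cell, or cytoplasm — the mask is the sole gating mechanism; zero-valued
pixels inside the gate are retained):

* `regression_fit` is ordinary least squares of B on A. Orthogonal
  regression was rejected because the workflow reports a single slope of B
  against A.
* `auto_threshold` performs a Costes-style search: candidate thresholds
  step downward through the distinct intensities of A (evenly subsampled
  to at most 512 levels when A is richer than that, as in 16-bit images;
  `threshold_candidates` exposes the grid), with t_B tied through the
  regression line. At each candidate, the *below-set* is the complement
  of the co-localized quadrant — pixels with A ≤ t_A **or** B ≤ t_B — and
  the search stops at the first candidate whose below-set Pearson
  correlation is ≤ 0. A below-set correlation that is undefined (fewer
  than two pixels, or zero variance in either channel) is treated as
  uncorrelated and also stops the search; if no candidate qualifies the
  threshold falls to the channel minimum.

  *Dialect note.* The other common dialect defines the below-set as pixels
  below **both** thresholds. We implemented and measured both: with the
  intersection dialect, on realistic noisy scenes the below-set barely
  changes between adjacent candidates, its correlation hovers around zero,
  and the stopping depth behaves like a random walk — measured %Volume at
  fixed generator settings had a standard deviation of ~15 percentage
  points across seeds, and monotonicity of %Volume in the generated
  co-localized fraction failed in practice. The complement dialect anchors
  the stopping point to real structure (the set loses correlated pixels as
  the threshold descends); the same measurement had sd ≈ 0.1–0.4 points.
  Limiting cases (e.g. identical channels → thresholds at the channel
  minimum) behave identically under both dialects.
* `coloc_report` splits the scatter plot into four quadrants at the
  thresholds (strictly `>` counts as above). Rcoloc is the Pearson
  correlation over the first quadrant only; it is reported as an explicit
  `null` when that quadrant has fewer than two pixels or zero variance —
  never silently coerced to 0, because saturated-slope situations make the
  distinction meaningful. Quadrant counts always partition the gate.
* Pearson correlations are computed as
  sign(S_ab)·√(S_ab² / (S_aa·S_bb)), which returns exactly ±1.0 for
  exactly proportional inputs instead of drifting by one ulp.
* `line_profile` samples raw pixel values along the Bresenham path between
  two points (no interpolation); distances are Euclidean from the first
  endpoint to each sampled pixel center, strictly increasing from 0.
* `cytoplasm_intensity` reports mean, sample sd (ddof = 1) and pixel count
  over a gated region. Condition contrasts use background-subtracted
  means: `estimate_background` is the *mean* over pixels at least 5 px
  outside every cell. The mean, not the median, because low-count shot
  noise is right-skewed and the median under-estimates the background
  (measured: a median-based estimate biased a three-fold contrast down to
  ~2.6).
* `fold_change` is mean(condition 2)/mean(condition 1) over per-cell
  means, with a 95% percentile bootstrap CI (2000 resamples, seeded,
  resampling cells within each condition independently).

## Branched network analysis (IBNA)

Pipeline per cell/region: optional Gaussian pre-smoothing → threshold
(Otsu on the gated intensities, or manual) → optional removal of specks
(< `min_object_px`) and filling of small holes (≤ `fill_holes_px`) →
topology-preserving thinning → optional pruning of terminal spurs shorter
than `prune_px` → 8-neighbor classification (end-point ≤ 1, slab = 2,
junction > 2; isolated pixels are end-points, which completes the
partition) → graph assembly → census.

* **Thinning.** Standard 2-D thinning occasionally leaves 2×2 foreground
  blocks (diagonal crossings). `skeletonize_binary` removes them with a
  cleanup pass that deletes a block pixel only if the global 8-connected
  component count is unchanged; on 300 random blob images this produced 0
  residual blocks and 0 topology changes. Exact skeleton pixel layout is
  treated as algorithm-internal; tests assert properties (thinness,
  topology, endpoint counts), not layouts.
* **Graph.** Nodes are individual end-point pixels plus 8-connected
  components of junction pixels ("actual junctions" — deliberately
  distinct from the junction *pixel* count). Edges are maximal slab chains
  between nodes, or direct node–node pixel adjacencies; edge length
  includes the steps into the terminal node pixels (so a 5-pixel line is
  one branch of length 4). A pure cycle with no node pixels is anchored on
  a phantom node at its lexicographically smallest pixel and reported as
  one self-edge — a documented convention, since branch-list tools do not
  agree on how to report cycles. Every skeleton pixel belongs to exactly
  one node or one edge path (asserted exhaustively in tests).
* **Graph simplification** (`simplify_graph`, off by default): drops
  self-loops shorter than a merge length, contracts short
  junction–junction edges, and splices degree-2 junction nodes. Thinning
  a dilated noisy tubule can split one physical junction into two nearby
  components or leave micro-loops; these consolidations are the standard
  remedy in skeleton-census tools. Hand-computable shapes are always
  evaluated on the raw graph.
* **Normalization.** `normalize_per_cell` divides all counts (branches,
  actual junctions, pixel classes, total) by the cell count; the mean
  branch length is already a per-branch quantity and is unchanged. Double
  normalization is an error.
* **Rendering.** Exact palette, no anti-aliasing: junction violet
  (148, 0, 211), slab scarlet (255, 36, 0), end-point blue (0, 0, 255).

### Measurement settings for noisy scenes

For synthetic-scene recovery (and as pipeline defaults) we use smoothing
σ = 1.2 px, `min_object_px` = 9, `fill_holes_px` = 12, `prune_px` = 4,
`junction_merge_px` = 4. Rationale: at snr 10 the binarized tubule boundary
is ragged at the 1–2 px scale; holes below ~12 px are shot-noise artifacts
that would skeletonize into phantom loops, spurs below 4 px are boundary
noise, and junction components split by less than 4 px are one physical
junction at a 3-px tubule width.

## Cell segmentation

Nuclei: Otsu on the (optionally smoothed) nucleus channel, hole filling,
small-object removal, 8-connected labeling. Cell bodies: the cytosolic
channel carries three intensity populations (background, diffuse cell
fill, bright labeled structures), so the outline threshold is the lower
cut of a three-class multi-Otsu split; with smoothing enabled a disk-3
closing regularizes the outline. Nuclei are assigned to the cell holding
the majority of their pixels; cells without nuclei are discarded; labels
are 1..n in centroid raster order; cytoplasm = cell minus nucleus. With
smoothing disabled, clean (noise-free, blur-free) synthetic scenes segment
pixel-exactly.

## The synthetic scene generator

Each scene contains non-overlapping elliptical cells (rejection-sampled;
1000 failed placements raise an error) with offset elliptical nuclei
strictly inside. Four channels: `nucleus` (uniform foreground),
`clld` (diffuse cell fill at 25% of foreground plus the network ribbon and
vesicle-like puncta, textured in [0.7, 1.0]×foreground), `aunc`
(nanoparticle dots), `mt1mmp` (marker dots). Foreground amplitude is
10 000 on the 16-bit scale.

* **Network ground truth.** Each cell's lipophilic network is a random
  tree/forest: branches are direction-persistent random walks on the
  8-connected grid, attached to interior points of existing branches; an
  attachment splits the host branch, so the truth graph's branch and
  junction counts are exact by construction. Walks keep a clearance
  (default 6 px, Chebyshev) from existing structure and junctions keep
  ≥ 9 px separation, so the rendered tubules stay resolvable. After each
  accepted branch the noise-free ribbon is re-skeletonized and the branch
  is rejected unless the measured graph still reproduces the truth counts
  — the generator guarantees that its ideal rendering has the declared
  topology at the declared tubule width.
* **Co-localization ground truth.** Of the `aunc_dot_count` dots per cell,
  `round(coloc_fraction · n)` are centered on network skeleton pixels and
  rendered as `intensity_ratio ×` the local `clld` value over a disk
  footprint (signal accumulating on the lipophilic structure tracks the
  local membrane amount — and makes a fully co-localized noise-free scene
  exactly proportional between the channels, so Rcoloc = 1.0 exactly).
  The remaining dots are placed away from the structures, in the
  condition-specific region, at a constant amplitude of 0.704×foreground
  (×`intensity_ratio`). That constant was calibrated on the generator's
  own dot geometry so a dot carries the same expected integrated signal
  regardless of placement — otherwise a difference in co-localized
  fraction between two conditions would leak into their intensity ratio.
* **Spatial patterns.** "Perinuclear aggregated" places off-structure dots
  in a ≤10 px annulus around the nucleus; "anterior dot-like" uses a 90°
  cytoplasm sector centered on the direction opposite the nucleus offset.
  The marker channel co-varies with the dots (jittered ±1 px) under the
  anterior pattern and is placed independently under the perinuclear one.
  The geometric extents are documented inventions; the source imagery
  describes these patterns only qualitatively.
* **Condition pairs.** Condition 1: perinuclear, co-localized fraction
  0.2, unit amplitude. Condition 2: anterior, fraction 0.75, amplitude
  × `intensity_ratio`, branch target doubled (density factor 2). Seeds
  derive deterministically from the parent seed.
* **Noise model.** Gaussian PSF blur (default σ 0.8 px) of the ideal
  image; a constant background pedestal (2500); Poisson shot noise with
  photon gain chosen so mean-foreground/σ(background) equals `snr`
  (default 10); Gaussian read noise with σ = foreground/(3·snr); clip and
  round to uint16. `snr = inf` disables pedestal and noise entirely,
  making noise-free scenes exactly segmentable. The model is a standard
  fluorescence-camera abstraction, not a fit to any instrument.
* **Replicated fields.** `generate_replicated_scene` stamps one generated
  cell at k grid positions and then applies blur and noise to the
  assembled field: copies share structure but not noise.

### What the generator does not emulate

No Airy PSF or depth sectioning, no autofluorescence gradients, no cell
motility, no z-stacks, no uneven illumination, no chromatic misalignment.
Passing recovery tests on these scenes shows the *measurement chain* is
correct and unbiased under the stated noise model; it does not certify
performance on real images with structured backgrounds or out-of-focus
light.

## Validation scenarios and problem sizes

Chosen once and used by both the test suite and `scripts/acceptance.py`:

* Closed-form agreement of Pearson/OLS on 100 random 16×16 pairs (1e-12).
* Threshold-search criterion verified on 20 shuffled 8-bit 64×64 images
  and against exhaustive scans on 5-pixel cases.
* Classification vs brute-force 3×3 enumeration on 1000 random thin
  skeletons; topology/thinness of skeletonization on 100 random blobs.
* Network recovery: single cells of radius 100 px in 256² images, branch
  target 24 (branch lengths 20–36 px), 3-px tubules, snr 10; branch and
  actual-junction counts within ±10% of generator truth (39/40 dev seeds).
* Normalization consistency: k = 1..4 replicated-cell fields, noise-free
  rendering, every normalized field within ±5% of the single-cell value.
  Noise-free because the junction *pixel* count fluctuates by ±20–25% per
  copy under camera noise (thinning details near junctions), which no
  normalization can undo; count-level fields (branches, junctions,
  end-points) are additionally checked at snr 20 in the unit tests.
* %Volume vs generated co-localized fraction {0, .25, .5, .75, 1}:
  strictly increasing 10-seed means, cytoplasm-gated (extracellular
  background dominates full-image statistics, and real workflows gate by
  cells).
* Fold change: condition pairs at intensity ratio 3, 20 cells per
  condition, snr 10, 576² images; recovered ratio within [2.7, 3.3].
* Determinism: identical config + seed ⇒ byte-identical `report.json`
  (timestamps are confined to the run log).

## Known limitations

* 2-D only; "voxel" counts are pixel counts on single planes.
* The Costes search assumes a positive overall regression slope; channels
  with genuinely negative association stop at the top candidate
  (everything background), which is reported but not meaningful.
* Junction pixel counts (as opposed to actual-junction counts) are
  sensitive to thinning details and should be compared only under a fixed
  measurement configuration.
* The cell segmenter expects well-separated cells (the generator places
  them non-overlapping); touching cells would need a watershed split,
  which is out of scope.
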