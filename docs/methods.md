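# Methods

## The measurement problem

A morphogen-reporter gradient imaged over time is a smooth, monotone
intensity field corrupted by three distinct processes: (i) *biological
noise* — single cells whose reporter output deviates multiplicatively from
their neighbourhood and persists for minutes before disappearing, (ii)
*technical transients* — single-frame excursions from cosmic rays or the
detector, and (iii) *detector noise* — frame-to-frame stochastic intensity
fluctuation. The package separates (i) from (ii) and (iii) and quantifies
each, together with the gradient itself and downstream cell-level and
gene-level readouts.

## Noise-pixel classifier

Each frame is restricted to an embryo mask (supplied, or automatically the
pixels strictly above the `mask_quantile` = 0.1 intensity quantile of the
frame, edge-padded morphologically closed; a constant positive frame masks
fully, an all-zero frame not at all). For every masked pixel the neighbour
statistic *s* is the mean (or median) of the masked pixels in the square
ring of Chebyshev radius 1..`neighbourhood_radius_px` (default 1: the
8-connected ring), the pixel itself excluded. Labels are assigned strictly:

* High: I(p) > `fold_threshold`·s  (default threshold 2)
* Low:  I(p) < s / `fold_threshold`
* a fold of exactly the threshold is *not* noise.

Degenerate cases are deterministic: no masked neighbour → unclassifiable
(none); s = 0 with I(p) > 0 → High with a +inf fold recorded for review;
s = 0 with I(p) = 0 → none. Note that the strict Low rule means a
zero-intensity pixel adjacent to bright pixels is Low — the embryo mask, not
the classifier, is responsible for excluding background.

### Persistence filter

A maximal same-class run of length k frames at a fixed pixel is an event iff
k ≥ `min_frames` (default 2) **and** k·Δt > `min_duration_min` (default
6 min, strict), where Δt is the frame interval. Run duration is counted as
k·Δt: with the default 3.5-min interval a 2-frame run spans 7 min and
passes. Both criteria are enforced independently because they can disagree
at other intervals. Length-1 runs are tallied as transients at their frame;
runs of length ≥ 2 failing only the duration cut are dropped and logged
separately. A class switch (High→Low) terminates a run. Pixels are tracked
at fixed coordinates — no registration, segmentation or lineage tracking.

All decisions are intensity ratios, so detection is invariant under global
rescaling of the stack. (Peak folds can differ in the last floating-point
digits between a stack and its rescaled copy; serialized event tables round
folds to 9 significant digits.)

## Synthetic scenes

The generator emulates the study conditions of single-channel luminescence
imaging of an early embryo:

* **Geometry/calibration**: 100×100 px at 6.5 μm/pixel, 40 frames at
  3.5 min/frame by default. The frame interval is configurable because the
  acquisition interval of the bioluminescence modality is not fixed by the
  analysis; the default is chosen so that the 2-frame persistence criterion
  (7 min) is strictly stronger than the 6-min cut.
* **Gradient**: exponential I(d) = P·exp(−d/λ) from the posterior edge,
  floored at the anterior level (defaults P = 200, anterior 20, λ = 150 μm);
  linear and constant fields are available. The linear ramp reaches the
  anterior level at a distance of one full axis span, so a 50-px ramp from
  200 to 100 reads exactly 150 at column 25 from the posterior edge.
* **Unfit cells**: appear as discs of physical radius `cell_diameter_um`/2
  (≈ 0.77 px at the default calibration — one cell occupies one pixel, the
  single-cell scale at which the classifier operates). New cells arrive at
  `unfit_rate` = 0.5 expected per frame; each is High or Low with equal
  probability, with fold drawn uniformly in [2.5, 4] (reciprocal for Low).
  Lifetime is 1 + min(G, `max_lifetime_frames` − 1) frames with
  G ~ Geometric(`elimination_rate`): a memoryless stand-in for apoptotic
  removal. `elimination_rate` = 0 encodes apoptosis inhibition (lifetime
  capped at 12 frames by default, truncated at the movie end). The geometric
  draw is taken from a single uniform via the inverse CDF so that every rate
  consumes the same number of generator values — paired seeds across
  conditions then share event positions, folds and start frames, isolating
  the lifetime contrast.
* **Spikes**: single-frame events at `spike_rate` = 1 expected per frame
  with folds drawn like unfit cells.
* **Detector noise**: none, Gaussian with σ = 5% of local intensity
  (default), or Poisson with a photon-scaling factor. Applied last.
* **Determinism**: one master seed; planted events and detector noise flow
  from two documented sub-streams of it. Identical configurations give
  bit-identical stacks and ground truth.
* **Overlaps**: the most recently started event wins on shared pixels
  (applied in ascending start order, deterministically).

What the generator does **not** emulate — cell motion, optics/PSF blur,
photobleaching, embryo curvature, segmentation error — bounds what passing
tests show: they validate the classifier and statistics under the stated
forward model, not robustness to motion or optical artefacts on real movies.

`plant_exact_events` places exact numbers of well-separated events
(Chebyshev separation ≥ 5 px by default) so that benchmark scenes map one
planted feature to exactly one detectable pixel run.

## Gradient profiling

Regions divide the mask's bounding extent along the AP axis into
`n_regions` contiguous bands of equal coordinate span (not equal area);
remainder pixels are absorbed by the anterior-most bands, one each. Region
sampling draws `n_samples_per_region` (default 12, matching the per-region
sample count of the manual boundary-intensity protocol the operation
emulates; the underlying protocol counts 6 cells × 2 intercellular areas)
pixels without replacement from a caller-supplied sample mask — automatic
membrane segmentation is out of scope. SEM uses ddof = 1 (0 for a single
sample). The smoothness index is the masked median of |log(I/s)|, pooled
over frames for a stack; a median is used so that isolated outliers leave
a smooth baseline untouched.

## Spatial statistics

* **Binned frequencies**: bins are equal-width intervals over the AP extent
  of the population cells (posterior-most edge inclusive). The frequency
  unit is the embryo: per embryo per bin, marker⁺/population; bins report
  mean ± SEM across embryos. The bin count is a parameter (default 5).
* **N/C ratios**: per labelled cell, mean nuclear over mean cytoplasmic
  intensity; cells with an empty compartment or zero cytoplasmic mean are
  omitted with a warning.
* **Fisher exact test**: two-sided by minimum-likelihood summation — the sum
  of hypergeometric probabilities (margins fixed) not exceeding the observed
  table's. Implemented in exact integer arithmetic (`math.comb` numerators
  over the common denominator), so probability ties are compared without
  floating-point ambiguity; the float conversion happens once, at the end.
  A zero margin returns p = 1 with a warning. t tests and ANOVA are
  deliberately not reimplemented (use scipy/statsmodels).
* **Summaries**: linear-interpolation quartiles; inputs are sorted before
  reduction so summaries are exactly permutation-invariant.
* **Sign test**: exact one-sided binomial tail at p = ½, ties excluded;
  used by the pipeline's paired condition comparison.

## Expression gate

Records are tidy (gene, contrast, log2FC, FDR) over the two contrasts.
A gene is mosaic-specific-up iff FDR_mosaic < threshold (default 0.1), its
mosaic log2FC is positive, and it is **not** significant in the ubiquitous
contrast at the same threshold; -down analogously. "Not in ubiquitous" is
the minimal significance-only reading — no effect-size criterion — and the
threshold is a parameter. Missing contrast rows (or missing FDR values)
count as not significant, since filtered DE tables commonly omit untested
genes; duplicate (gene, contrast) rows are an error naming the offenders.
Panel annotation matches gene identifiers case-insensitively.

## Pipeline and formats

Frame indices and pixel coordinates are 0-based, origin top-left; stacks are
single-channel frame-major TIFF; tables are headed CSV with a schema-version
column; summaries are JSON. Every `run` writes a config echo (including all
defaulted parameters, so thresholds in any run are auditable) and a SHA-256
manifest; identical configurations reproduce identical checksums.

## Problem sizes and validation

The test-suite and acceptance benchmarks use 100×100×40 scenes (detection
benchmarks), 64×64×30 scenes over 20 paired seeds (elimination contrast),
60-px exponential fields (gradient recovery, compared with the closed-form
regional average P·λ/(b−a)·(e^(−a/λ)−e^(−b/λ))), exhaustive enumeration of
all 2×2 tables with margins ≤ 10 (Fisher oracle), 1000-gene DE tables with
30 + 30 planted hits, and 50 embryos × 40 cells (binned frequencies). These
sizes give Monte-Carlo standard errors comfortably inside the asserted
tolerances while keeping a full run to seconds.

## Known limitations

* The classifier assumes stationary cells; appreciable cell motion between
  frames fragments runs and deflates persistent-event counts.
* The automatic quantile mask is a heuristic; on strongly graded fields it
  excludes the lowest-intensity decile, which can include genuine anterior
  embryo pixels (and any Low events there). Supply an explicit mask when
  the embryo outline is known.
* Very bright transients (fold > ~9 over the default 8-ring) drag their
  ring neighbours below the Low threshold for that frame, inflating the
  transient tally (never the event list).
* The exact Fisher test is practical for the table sizes of embryo-count
  contrasts; for very large margins prefer an asymptotic test.
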