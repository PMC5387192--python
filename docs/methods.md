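# Methods

This note documents the statistical procedures implemented in
`epitrend`, the parameters that matter, the design of the synthetic-data
generator, and the numerical choices made where the design was genuinely
open. Units: intensities are log2 fluorescence throughout; time is hours
post fertilization (hpf); a *rank* is a position in the developmental
order of the analysed embryos.

## Data model

The input is a probe × embryo matrix of single-channel log2 intensities
(one microarray per embryo), an annotation mapping each probe to a
transcript and gene with a 3′-order rank, and per-embryo metadata
(spawn, measured percentage epiboly). Embryos span late blastula to
mid-gastrula, nominally 5–8 hpf. One array may be excluded by QC,
leaving 179 analysed embryos by default.

## Presence calling

Per array, probe intensities are a mixture of a background and an
expressed component. The background is anchored: probes whose
across-array log2 variance falls below −2 and whose mean intensity lies
in the lower of the two intensity modes (an exact 1-D two-means split of
the low-variance probes' means) define the background mean and sd for
each array. The expressed component and the mixing weight are then
estimated by EM with the background held fixed; a probe is **present**
when its posterior probability of the expressed component is at least
0.20 (inclusive). The low cutoff deliberately favours sensitivity over
specificity at this stage; the moving-window filter below removes the
resulting false positives. Degenerate arrays (no separable second mode)
are called all-absent with a warning.

The −2 variance cutoff and the 20% posterior cutoff are the method's
fixed operating points; `em_iterations` (100) and the convergence
tolerance only affect numerics.

## Expressed-probe filter, normalization, summarisation

A probe is **expressed** when at least 6 of 30 consecutive
epiboly-ordered embryos call it present (any window qualifies; both
boundaries inclusive). The retained matrix is quantile normalized (every
column mapped onto the across-column mean of order statistics, ties
receiving the average of the reference values they span) and summarised
by the arithmetic mean, probes → transcripts → genes. The mean is used
at both levels for symmetry; a transcript with no retained probes is
omitted.

Quantile normalization assumes the cross-sectional intensity
distribution is stationary over the course. Where the true distribution
drifts — e.g. when switched-off mass accumulates at the bottom of the
intensity range — the normalization redistributes that drift into every
profile as a smooth, level-dependent distortion of order 0.05–0.1 log2.
This is a genuine property of the method, not an implementation
artifact; it is the main reason switch-point recovery (below) has a few
ranks of irreducible bias/scatter.

## Developmental ordering

The 10 lowest- and 10 highest-epiboly embryos anchor the stage extremes.
Training transcripts are those with mean log2 intensity below 12 over
the low group and above 13 over the high group (increasing direction;
the reversed criterion gives the decreasing set). Embryos are ranked by
their mean over the training set — ascending for the increasing
direction, descending for the decreasing one, so time always runs
forward. Ties break by measured epiboly, then embryo id. Pseudotime maps
rank linearly onto [5, 8] hpf; linearity is the minimal assumption and
is only consumed by rate and extrapolation arithmetic.

The two directions give independent orders; their rank correlation, and
the residual variance of held-out genes around lowess trends under
competing orders (`validate_order`), are the method's internal checks.

## Trend statistics and the ten types

With embryos in developmental order:

* **Lowess fit**: span 2/3, 3 robustness iterations, over rank.
* **DTFL**: the median absolute residual around the lowess fit — the
  tightness-of-regulation statistic. Invariant under additive shifts.
* **Angle**: atan of the least-squares slope over rank (unit spacing),
  in degrees. Strictly above +0.1° ⇒ increasing; strictly below −0.1° ⇒
  decreasing; the boundary itself is flat. The threshold only has
  meaning for this pinned x-convention.
* **Continuity ratio**: mean|y − lowess| / mean|y − linear|; strictly
  above 0.95 ⇒ continuous (the curve buys little over the line). A
  perfectly linear profile (zero linear residual) is continuous with
  ratio defined as 1.
* **Edge presence**: the gene's reporting probe is the most-3′ probe
  with any present call on the gene's highest-expressed transcript.
  Fewer than 7 present calls among the first (last) 15 ordered embryos
  marks the gene as switching on (off) within the window.
* **Oscillation score**: autocorrelation of lowess-detrended residuals
  over lags 5 … n/3; the score is the maximum over candidate periods L
  of acf(L) − acf(L/2). A genuine oscillation has a positive peak at its
  period and a negative trough at half of it, so the contrast approaches
  twice the signal fraction; a smooth switch-shaped residual bend has a
  monotonically decaying acf and scores near zero. The default threshold
  is 0.5; a curated override list (for literature-confirmed oscillators)
  bypasses the score. The threshold is an artifact operating point —
  oscillator identification in this stage is classically done by eye —
  and the peak/trough contrast is this package's choice of an automated
  stand-in that does not confuse switch bends for periodicity.

The classifier is a total decision tree: oscillatory → 10; flat → 5;
increasing: edge-on → 9, else a valid geometric start → 8, else
continuous → 7, else → 6; decreasing: edge-off → 1, else a valid stop →
2, else continuous → 3, else → 4. The category → number map is
configurable; the default anchors 1 = switched off, 5 = constant,
9 = switched on, 10 = oscillatory.

Rates: FC/h = 2^(|slope| · ranks-per-hour) with
ranks-per-hour = (n−1)/3. When a valid switch point exists the slope is
re-fitted on the on-segment (between the located point and the window
edge), so the rate is not diluted by the off plateau.

## Switch-point location

Switching profiles approach their off level with a vanishing rate of
change, so a flexible curve and a straight line fitted to the whole
profile diverge most at the bend. The locator:

1. fits a line (lf1) and a lowess curve (lof1) to the ordered profile;
2. takes the crossings of the two fits — the sign changes of
   lof1 − lf1 — and, between the outermost crossings, the rank of
   maximal |lof1 − lf1| (L1);
3. fits a second line lf2 to ranks 1…L1 (stop) or L1…n (start);
4. evaluates |lf2(rank) − off level| at all n ranks; the minimising rank
   is the switch point, valid only if the minimum is below 0.05 log2
   **and** interior (a boundary minimiser means the crossing lies
   outside the sampled window).

The locator's lowess uses span 0.4: at span 2/3 the curve is too stiff
to bend around a switch in the outer third of the window, the
curve − line difference stays single-signed, and the crossing pair does
not exist. Trend statistics keep span 2/3.

The **off level** is estimated on the same scale as the analysed profile
(normalized, summarised): absence gates the estimate — an off plateau
exists only where the reporting probe has not-present calls — but the
level is the median over all observations of the edge window, because
conditioning on absent calls alone selects the noise's lower tail for
plateaus near the detection boundary (≈ −0.2 log2 bias). When the
15-embryo edge holds no absent call the window extends to the nearest
one (flagged). `locate_changepoint_refined` adds a second pass that
re-measures the off level in the 15 observations adjacent to the
first-pass crossing, which immunises the estimate against slow plateau
drifts imposed by normalization. The raw-probe-intensity variant of the
off level is retained as `off_level_from_presence`.

**Backward extrapolation**: a gene already expressed at the window start
with first level y₀, off level b and rate r (FC/h) is extrapolated to a
predicted onset t₀ = 5 − (y₀ − b)/log2(r) hpf. Gradual-up genes use
their own fitted rate; constant genes borrow the dataset's maximum
positive rate; onsets before 0 hpf precede spawning.

## Multilevel detection

Candidate genes need log2 profile variance above −0.1. 1-D k-means
(best of 25 seeded restarts) with k = 2 must achieve WSS/BSS < 0.3 with
every cluster spanning more than one third of the rank range. The k = 3
solution is consulted when the 2-means ratio is below 0.45 — between the
noiseless three-equal-levels value (1/3) and the unimodal-Gaussian value
(≈ 0.57) — and accepted under the same ratio/span criteria when it
resolves strong residual structure (WSS₃/WSS₂ < 0.3). A call is rejected
as a **temporal artifact** when any pair of levels separates by a single
rank threshold at ≥ 95% accuracy: a step in time is developmental
regulation, not multilevel expression. This deterministic screen (plus
an optional override list) replaces the visual inspection step so the
pipeline stays reproducible. Spawn linkage is the adjusted Rand index
between the level assignment and the spawn partition, with a permutation
p-value from shuffling spawn labels.

## Embryo morphometrics

From an oriented binary mask (animal–vegetal axis on x): area and
perimeter (the perimeter from tracing the sub-pixel boundary contour,
lightly smoothed to remove the raster staircase — a rasterized circle
scores roundness 0.99, a square 0.80 ≈ π/4), height = x-extent,
width = y-extent, epibolic distance = animal-pole edge to the annotated
front, percentage epiboly = 100 · distance/height, and roundness =
4πA/P². The ordering metric is the one with the largest relative change
(max − min)/min across the series — percentage epiboly in practice.
Masks are inputs; no segmentation is attempted.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with full ground truth. Its defaults define the standard study:

* **Design**: 179 embryos from 9 spawns over 5–8 hpf. Collection times
  form an even clock-time grid (one embryo per minute) jittered by
  N(0, 0.15 h) for fertilization-time uncertainty and speed differences;
  an iid-uniform draw would make the rank↔time spacing locally irregular
  enough to add several ranks of error to any rank-axis extrapolation.
  Measured epiboly is a monotone piecewise-linear map (40% at 5 hpf, 50%
  at 5.8, 55% at 7.0, 80% at 8 hpf — the mid-course stall) plus N(0, 3)
  percentage points of measurement error, clipped to [30, 90].
* **Gene levels**: trending genes anchor their mid-window level
  uniformly on [10, 14.5] log2 with the whole path kept above 10;
  constants extend down to 9.4, into the weakly expressed regime
  straddling the detection boundary. Anchoring at mid-window keeps the
  cross-sectional distribution stationary — the premise of quantile
  normalization.
* **Categories**: counts are fixed by largest-remainder allocation of
  the type proportions (composition is a study condition, not a draw);
  which gene gets which category is random. Defaults: 3.8% switched off,
  4% stopping, 21% gradual down, 5% two-phase down, 30.5% constant, 5%
  two-phase up, 22% gradual up, 5.5% starting, 2.3% switched on, and
  exactly 4 oscillators (sin, amplitude 0.5, period 0.5 h, random
  phase). Switch-on/off genes rise/fall at 1.2–2.0 log2/h with switch
  times staggered across most of the window; switched-off genes rest
  0.6–1.4 log2 above pristine background (decay leaves residual signal),
  switched-on genes rest anywhere from background up to just below the
  detection boundary. Starting/stopping genes (types 8/2) carry a basal
  plateau at 9.5–9.9 — at the presence boundary, which is what makes
  their edge-presence calls mixed — and slopes of 0.8–1.6 log2/h. Gradual
  trends move at 0.2–0.8 log2/h; two-phase genes combine a 0–0.2 with a
  0.8–1.5 log2/h segment, breaking at 35–65% of the window. Switch
  shapes use a quadratic ease-in over 0.25 h *centred* on the nominal
  switch time, so the planted time coincides with the
  plateau × extrapolated-trend intersection that the locator estimates.
* **Noise**: per-probe sd 0.25 log2, scaled per gene by a
  lognormal(σ = 0.25) factor — tightly and loosely regulated genes
  coexist, which reproduces the observed DTFL regime (median ≈ 0.15,
  ≥ 95% of genes below 0.4, a visible tail). Probe affinities are
  N(0, 0.25) offsets; 42/30/22/6% of genes carry 1/2/3/4 probes, split
  into a second transcript 30% of the time.
* **Background**: probes sized so expressed probes are 17% of the array;
  means N(8, 0.5) with 8% of background probes given elevated
  (cross-hybridisation-like) means uniform on [8.4, 10.0]. The bright
  tail matters: it provides stable mass at the bottom of the retained
  intensity distribution, without which the quantile map there is
  dominated by the time-varying switched-off mass and wobbles far more
  than a full-size array's would.
* **Multilevel genes**: 1.5% of genes, planted on flat or mild-trend
  profiles. Two-level genes (94%) place spawns at ±1.25 log2 (gap 2.5);
  three-level genes use {−1.25, 0, +1.25}; every level is carried by at
  least two spawns, and 5% of embryos defect to another level. The gap
  follows from the method's own variance filter: log2 var > −0.1 demands
  level separations near 2 log2, so closer-spaced levels would be
  undetectable by construction.

### What the generator does and does not emulate

It reproduces the features the pipeline's statistics depend on:
detectability structure (background vs expressed, boundary-straddling
plateaus), monotone trend mass for ordering, the stall-prone epiboly
marker, switch geometry, spawn-linked levels, and probe multiplicity. It
does **not** emulate array spatial artifacts, batch or hybridization
effects, probe sequence biases, saturation, or correlated gene modules
(each gene's noise is independent). Passing the recovery tests therefore
shows the chain of methods is implemented correctly and is statistically
adequate under realistic noise — not that real arrays meet these
assumptions; on real data the QC, normalization-validation and
reciprocal-ordering checks carry that burden.

### Known limitations

* Quantile normalization redistributes any drift of the intensity
  distribution into individual profiles; switch-point estimates inherit
  a bias/scatter of a few ranks from it (measured ≈ 4–5 ranks MAE under
  the standard study), and the continuity ratio of steep genes is
  slightly depressed. These effects shrink with array density but never
  vanish.
* Types 8/9 (and 2/1) blend at the presence boundary: a basal plateau
  near the detection limit yields stochastic edge-presence counts, so a
  minority of starting genes are classified as switched on (and vice
  versa). The type families (up/down/constant/oscillatory) are robust.
* The ordering is only identified up to monotone warps of time; absolute
  pseudotime rests on the linear rank map and the window's nominal
  5–8 hpf span.
* Oscillator detection assumes the ordering is locally accurate at the
  scale of the period (≈ 30 ranks); heavier ordering noise damps the
  autocorrelation contrast before it damps anything else.
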