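# Methods

This note documents the models implemented in `rangecast`, the defaults and
their rationale, the numerical choices, and what the synthetic test bed does
and does not establish about real data.

## Raster model and conventions

All stages share one projected grid (`GridSpec`): square cells, lower-left
map origin, rows stored top-to-bottom. Cross-layer operations require exact
equality of the five geometry fields; there is no reprojection. Cell
membership is half-open, `[x0, x0+cs) × (y0, y0+cs]`, so every point maps to
exactly one cell: a point on a vertical edge belongs to the cell on its
right, a point on a horizontal edge to the cell whose upper bound it is
(hence the grid's top and left edges are inside the extent, the bottom and
right edges outside). The interchange format is the ESRI ASCII grid; headers
round-trip bit-exactly and values to the written precision. Nodata cells
(sentinel or non-finite) are excluded from every statistic and are removed
nodes in the circuit solver.

Predictor selection is a greedy scan in a user-supplied priority order: a
layer is kept iff its absolute Pearson correlation (over jointly valid
cells) with every already-kept layer is below the threshold (default 0.7).
Greedy-by-priority is a deterministic generalization of "drop one of each
correlated pair"; the order encodes which member the analyst prefers.

## Synthetic landscapes and virtual species

`make_landscape` emulates the statistical structure of gridded climate and
land-cover products with Gaussian random fields: white noise smoothed by a
Gaussian kernel (σ = range/2 cells, wrap-around boundary for stationarity),
standardized to exactly zero mean and unit variance, then scaled to each
layer's mean/SD. Defaults sketch a cool boreal region at 1 km resolution:
temperature 8 ± 3 °C (autocorrelation range 12 cells), precipitation
700 ± 200 mm (range 15), percent covers clipped to [0, 100], elevation
400 m ± 400 m relief clipped at 0, and a sealed-soil mask covering the top
5 % of an independent autocorrelated field (so imperviousness is clumped,
like real built-up areas). Future periods are affine per-layer shifts
(`value × factor + shift`, percent layers re-clipped); the shipped scenario
warms by +1.5 °C (2050) and +2.5 °C (2070).

Virtual species are products of Gaussian responses
`exp(−½((x−opt)/breadth)²)^weight`. Two are shipped: a generalist
(temperature 9 ± 4 °C, wetness 40 ± 35 %) and a specialist with the same
optima, roughly half the breadths, and an extra forest requirement — so the
specialist's suitable set nests inside the generalist's. Presences are
sampled without replacement with probability proportional to suitability
and placed at cell centres.

What this test bed does **not** emulate: observation bias (roadside
sampling, effort gradients), coordinate error, non-Gaussian climate
topography, correlated multi-layer change, or land-use transitions. Passing
the recovery tests therefore shows the estimator chain is correct and
well-calibrated under clean presence-only sampling, not that real GBIF data
would behave as well.

## Occurrence cleaning and calibration areas

Cleaning is a fixed, machine-checkable rule set with a per-reason report:
drop null/non-finite coordinates, exact duplicate coordinates, out-of-extent
points; then thin to one record per cell keeping the smallest id (ties by
input order). Thinning-by-id is a convention; any deterministic rule works,
and the report makes the effect auditable. Calibration areas are strict
`elevation < cutoff` masks — 1000 m for the lowland specialist, 1500 m for
the generalist — harmonizing "below X" and "excluded above Y" phrasing into
one testable boundary semantic.

## Pseudo-absences with environmental profiling

The profiler is a per-predictor quantile envelope: the interval
[q, 1−q] (default q = 0.025) of presence values per predictor. A cell is
presence-like iff **every** profiled predictor falls inside its interval;
pseudo-absences are drawn uniformly without replacement from calibration
cells that are valid, non-presence, and **outside** the envelope. If too few
such cells exist the sampler tops up from inside-envelope cells and logs a
warning (counts in the run manifest). A one-class profiler could be slotted
behind the same `EnvelopeProfile` contract. Counts per learner: 1000 for
boosted trees and the Maxent-style learner, as many as presences for the
additive model. Ten independent replicates (seeds derived from the master
seed via `SeedSequence`) are the workflow default.

A consequence worth knowing: because the background is environmentally
dissimilar by construction, the fitted probability surface discriminates
envelope membership strongly but grades *within* the envelope weakly. This
is inherent to the profiling design, and it is why the parameter-recovery
correlation (below) sits around 0.6–0.8 per landscape rather than 0.9+.

## The ensemble

Per pseudo-absence replicate and learner the data are split 80/20 stratified
by label, the 80 % into 5 stratified folds (class proportions within ±1
record everywhere); each fold-fit is evaluated on its held-out fold. Gates
follow the workflow's stated thresholds literally: TSS ≥ 0.4 (inclusive)
and AUROC > 0.7 (strict). Weights are proportional to TSS (AUROC weighting
is a config switch); the ensemble cut point maximizes TSS on the pooled 20 %
holdout predictions of the retained fits, and that holdout evaluation is
exposed as `EnsembleModel.holdout_eval`.

Learner structure and defaults:

* **boosted_trees** — stagewise boosted trees, logistic loss. Defaults:
  depth-1 stumps, 300 stages, shrinkage 0.05. Stumps make the boosted model
  additive in the predictors and its probability surface smooth; deeper/
  faster settings (depth 2–3, rate 0.1) classify equally well but produce
  blocky, saturated surfaces that correlate poorly with a smooth truth.
* **additive_model** — per-feature cubic spline basis (5 knots) into an L2
  logistic regression (C = 1): a GAM with quadratic-penalty flavour.
  Unconstrained splines can wiggle by O(0.01) at the data boundary; tests
  treat monotonicity up to that tolerance.
* **maxent_like** — standardized features plus squares into an L2 logistic
  regression (C = 1), the presence-vs-background ≈ infinitely-weighted
  logistic regression correspondence; outputs are probabilities in [0, 1].

AUROC is computed from midranks (exactly the all-pairs Mann–Whitney
probability with ties counted half); the cut-point optimizer scans every
distinct score as a `≥` threshold and breaks ties toward the smallest.
Variable contribution is permutation-based — `1 − mean Pearson r` between
ensemble predictions on the original table and on the table with one
predictor permuted — rather than refit-without-variable: orders of magnitude
cheaper, deterministic under seed, and the two readings cannot be
distinguished from the workflow description. Constant predictions score 0
with a warning.

## Dispersal automaton

States: unsuitable, suitable-empty, occupied(age), settlement barrier,
short-distance barrier. Distance is Chebyshev (8-neighbour rings), the
standard choice for raster spread models and the one that makes the
hand-simulation oracles exact. The kernel is a base probability-vs-distance
curve linearly interpolated at each ring (default extent 5 km) multiplied by
the species' rappelling proportion (0.766 generalist, 0.59 specialist). The
default base curve (0.5 linearly down to 0.05 over 1–5 km) is a package
stand-in calibrated to nothing — the empirically derived kernels in the
motivating study are not reproduced here — so species comparisons should
rely on the *ratio* structure, which is exact.

Update rule per annual step: mature cells (age ≥ maturity, default 2 years;
initial cells start mature — they are established populations) are sources.
Each empty, suitable, non-barrier target receives **one** Bernoulli draw
with the kernel probability of its *nearest* mature source (per-source-pair
semantics available via `per_pair_draws`). Each mature source then triggers,
with the ballooning probability (0.14 / 0.029), one long-distance event:
uniform direction, uniform distance in [6, 15] cells; the landing cell is
colonized iff suitable, empty and not a settlement barrier — jumps pass over
barriers but cannot settle on them, and corridor-derived short-distance
barriers do not block ballooning. New colonists get age 0; all ages then
increment. At each period switch cells whose habitat disappeared are
decolonized. Default 30 replicates; reachable = colonized in ≥ 50 % of
replicates (threshold config-exposed; the frequency grid is always a
multiple of 1/replicates).

All randomness is drawn as full-grid arrays in a fixed order per step, so
runs that differ only in barrier masks share common random numbers. With a
non-increasing kernel this makes barrier monotonicity a theorem, not a
tendency: adding barriers can never enlarge the reachable set, which is the
mechanism behind the exact tier ordering `DispCS ⊆ Disp`.

Scenario step counts default to 30 annual steps (current→2050) and 20
(2050→2070), config-overridable.

## Connectivity

The suitability→resistance transform is the negative-exponential rescaling
`R = 100 − 99(1 − e^{−ch})/(1 − e^{−c})` with c = 8 (R is 1 at h = 1, 100 at
h = 0; larger c concentrates resistance contrast at low suitability).
Valid cells are nodes; 4-neighbours are linked with conductance
`2/(R_a + R_b)` (two half-cell resistors in series). Wall-to-wall solves run
South→North and West→East: unit total current injected in equal per-node
shares across the source edge, ground edge clamped to 0 V. The Kirchhoff
system is solved by direct sparse factorization (exact to machine precision;
at the node counts this pipeline produces, direct solves are faster and
tolerance-free compared to an iterative scheme). Components touching only
one electrode carry zero current and are reported. Node current intensity is
half the sum of absolute incident edge currents; conservation (total in =
total out, per-node balance) is checked to 1e−8 relative in the tests and
reported per run.

The consensus map multiplies the two directional *current* maps — the
workflow description is ambiguous between multiplying current maps and
multiplying resistance layers, and the literal resistance reading would make
corridors independent of the circuit solve, so the established wall-to-wall
practice is used. Electrode strips (the outer ring) are excluded from the
consensus statistic. Corridors are cells with consensus strictly above
mean + SD of valid non-electrode cells, with a 1e−9 relative tolerance so a
numerically flat field (uniform resistance) yields no spurious corridors.
The complement of the corridors feeds the DispCS run as the short-distance
barrier mask.

## Range metrics

Range size counts 1-cells (area = count × cellsize²). Centre of gravity is
by default the unweighted mean of cell-centre coordinates over the binary
suitable range (a suitability-weighted variant exists); shifts are Euclidean
distances with bearings clockwise from North. Schoener's D normalizes both
surfaces to sum 1 over shared valid cells and returns `1 − ½Σ|p−q|`,
clamped to [0, 1]; disjoint supports short-circuit to exactly 0 (the |p−q|
form leaves ~1e−16 of float residue there). The default is the continuous
(suitability-surface) overlap; binary maps are accepted as uniform masses.

## Pipeline and reproducibility

`run_pipeline` executes, per species × scenario: cleaning → calibration →
Bioc ensemble → BLU ensemble → per-period projection and binarization →
Disp automaton on the BLU maps (initial occupancy = cleaned presences ∩
current BLU binary) → resistance → wall-to-wall → DispCS automaton → metrics
table; cross-species Schoener's D per period afterwards. Every stage writes
its outputs before the next starts; a failing branch is logged and siblings
continue. One master seed derives every stage seed as
`(master × 1000003 + crc32(stage path)) mod 2³¹`, so rerunning an identical
config reproduces identical file digests. In metrics tables the Disp/DispCS
"current" rows are the currently occupied cells (the automaton's starting
state), not current suitability — the natural baseline for reachable-range
change.

## Problem sizes used in the shipped checks

The demo configuration is 50 × 50 cells, two species, 60 presences each,
2 pseudo-absence replicates, 300 background points, 10 automaton replicates
over 15 + 10 annual steps. The parameter-recovery check runs the full
workflow at 100 × 100 with 200 presences and 3 pseudo-absence replicates
(45 candidate fits) for each of three master seeds, and asserts the gated
holdout skill per seed plus a mean truth-correlation of r ≥ 0.7 across
seeds — per-landscape r varies roughly 0.6–0.8 for the structural reason
given in the pseudo-absence section. These sizes are the package's own
defaults for fast, deterministic verification; nothing in the method limits
grids to these dimensions.

## Known limitations

* No CRS handling or reprojection; all inputs must share one grid.
* The profiling envelope is axis-aligned; a strongly correlated niche would
  be profiled loosely (slot in a one-class profiler for that).
* The automaton has no demography: no density dependence, mortality, or
  propagule-pressure scaling; colonization is a pure Bernoulli process.
* Connectivity uses edge-to-edge electrodes only (no pairwise focal nodes)
  and a single resistance transform family.
* GeoTIFF and other binary raster formats are not read; convert to ESRI
  ASCII first.
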