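# Methods

## Model and assumptions

`snapcycle` reconstructs per-cycle marker trajectories from snapshot images
under three assumptions: (1) the population cycles asynchronously, so the
fraction of nuclei observed in a state equals the fraction of the cycle spent
in it; (2) every nucleus follows the same temporal program; (3) E2F
concentrations are single concave waves of quantized intensity over the cycle
(two waves for E2F4), and the EdU/pH3 staining patterns follow their known
orders (EdU: negative → diffuse → punctate → negative across S phase; pH3:
negative → punctate → diffuse → negative, ending the cycle at mitosis).

State sequences are always encoded ordinally in temporal order (EdU:
negative=0, diffuse=1, punctate=2; pH3: negative=0, punctate=1, diffuse=2).
This embedding is used wherever a squared distance is taken on a pattern
sequence; it is a package decision — the squared-distance objectives are not
defined on categories otherwise.

## Quantization

Per image and E2F channel, annotated-negative nuclei get level 0 regardless
of intensity (non-specific signal can overlap the level-1 band, and the
annotation is authoritative). Positive nuclei are binned equal-width over the
image's positive intensity range into `n_levels` levels (default 3, i.e.
levels 0–3; simulation studies use `n_levels = nb_i`):
`level = 1 + floor(n · (v − v_min)/(v_max − v_min))`, half-open bins with the
top bin closed; a degenerate image with `v_max = v_min` maps its positives to
the top level. Quantization is therefore invariant to affine intensity
rescaling per image, which is the point: level widths differ between images
because staining intensity does.

## Initialization

One vertex per non-zero joint-histogram cell; directed edges between cells
adjacent along one axis. Costs: E2F level ±1 → 0 both ways; forward state
step → 0, backward → ∞. No wrap-around edges exist between the last and first
state at a level (e.g. pH3 diffuse ↔ negative): the worked nine-cell example
has exactly 22 directed edges, which fixes this choice.

The covering sequence is found by exact iterative-deepening depth-first
search with memoized failure states and a reachability prune: for split
budgets 0, 1, 2, … the search looks for an edge-valid order visiting every
vertex, where revisiting a vertex consumes one split (cost 1) and divides its
proportion equally among its copies. This is exact because the graphs are
small (≤ ~20 vertices).

Two practical complications arise on data the original procedure never
faces:

* **Degenerate histograms.** When an E2F level switch coincides exactly with
  a state switch, the intermediate cell is never observed and the finite-cost
  graph can be disconnected — no covering sequence exists at any split
  budget. `initialize_all` then retries allowing a minimal number of
  *relaxed* transitions (a backward state edge or a jump between non-adjacent
  cells), each charged a large finite cost (1e6) so they are used only when
  unavoidable. Images that still fail are skipped when the mouse has other
  images.
* **Tie-breaking.** Minimum-cost covering sequences are heavily degenerate
  (a path graph can be walked from either end; branches can be taken in
  several orders). Since the trajectory is circular, a covering sequence is a
  cut cycle, so among minimum-cost sequences the search prefers the one whose
  wrap-around step (last cell back to first) is most plausible: the absolute
  level difference plus the forward cyclic state distance. This is resolved
  best-effort under a node budget (the primary cost is always exact);
  remaining ties fall to the lexicographically smallest cell order. Without
  this criterion, reversed or re-branched initializations are common and
  neither registration (shifts only) nor refinement can repair them.

Proportions map to bins by largest-remainder rounding (ties to the earlier
sequence element), so run lengths always sum to exactly B. Per mouse, image
trajectories are averaged arithmetically on E2F axes and by per-bin majority
vote on state axes (ties to the earlier temporal state).

## Registration

Couples containing pH3 are rotated so the final bin of the diffuse (mitotic)
run sits at bin B. If a sampled trajectory missed the diffuse run entirely
(short mitosis, finite cells), the end of the punctate run is used as a
fallback anchor; with neither pattern the couple stays unshifted. EdU couples
are then registered by exhaustive search over all B shifts against the
anchored same-genotype pH3 references, refined with cross-genotype
EdU-consistency terms in the listed triple order. E2F–E2F couples (which the
original registration step does not mention) are registered the same way
against both markers' pH3 references — they need *some* phase before entering
the assignment stage. Ties always break to the smallest shift.

## Global refinement

For `z = 1..B` (default `n_iters = B`; studies here use 25 for speed — the
remaining iterations mostly relax the locality penalty), five minimization
groups run in order: (E2F3A with EdU then pH3), (E2F8, …), (E2F4, …), then
the E2F3A–E2F8 and E2F3A–E2F4 couples; each solve permutes one mouse's couple
via `scipy.optimize.linear_sum_assignment`. Cost entries sum squared
distances of the couple's members at bin c1 to every existing reference
trajectory sharing a marker at bin c2 (cross-E2F terms referencing couples
that do not exist, e.g. E2F8–E2F4, are skipped), plus:

* a **state barrier** `BIG · 1[state(c1) ≠ state(c2)]` with
  `BIG = 1e6 · (max data entry + 1)` — large but finite so the matrix stays
  solvable while cross-state assignments are never optimal; consequently a
  couple's state sequence is bin-for-bin invariant under refinement;
* a **locality penalty** `d_circ(c1, c2)² / z` with circular bin distance —
  the division by z is the only reading under which the constraint is tight
  early and relaxes later, and circular distance respects the cycle topology.

References use current (partially updated) values within an iteration;
updates are in place, matching the sequential "one after another" phrasing.

The final per-E2F profile is a periodic cubic smoothing spline
(`scipy.interpolate.splrep`, `per=1`) through the per-bin means pooled over
all mice and couples containing the marker, clamped at zero. `smoothing=None`
uses the between-trajectory residual sum of squares around the bin means, so
the fit does not chase inter-mouse noise; `smoothing=0` interpolates the bin
means exactly.

## Corrected watershed

The nuclei component is `N = S_n − S_c` (inner minus contour score),
thresholded strictly (`N > 0`) and labelled with 8-connectivity. The
watershed runs on the inverse of `N` smoothed with a Gaussian (`sigma = 2.5`,
or 3.5 for the slower pixel classifier; "kernel size" is read as the standard
deviation since no unit is given), seeded from regional minima deeper than
5% of the range (shallower minima are suppressed to avoid
over-fragmentation — the original text does not specify seeding). A boundary
between two watershed regions that both overlap one connected component is a
candidate separation; its pixel set is the lower-label region's pixels
8-adjacent to the other region (one pixel thick, disjoint between pairs, and
a true barrier under the 8-connectivity used for components). A separation is
applied only when `Σ (S_c − S_n)` over its pixels is strictly positive.
Removed foreground pixels are merged back into the adjacent region with the
larger `N` (ties to the lower label), so outputs partition the original
foreground and splitting can never merge.

## Evaluation metrics

IoU-based matching requires `t > 0.5`, where pairing is provably unique, so
greedy pairing is optimal; an IoU exactly equal to the threshold counts as a
non-match (strict inequality). The percent-area classifier uses strict
"more than" bounds with half-open bands: E2F positive iff p > 0.35; EdU
diffuse iff p > 0.70, punctate iff 0.15 < p ≤ 0.70; pH3 diffuse iff p > 0.90,
punctate iff 0.10 < p ≤ 0.90.

## Simulation harness

Durations are uniform integers in `[1, D_max]` with
`D_max = floor(2·nb_t/(3·nb_i))` per run for single waves and EdU/pH3
patterns and `floor(nb_t/(3·nb_i))` per level for each E2F4 wave — the
readings under which a wave is guaranteed shorter than the cycle and both
E2F4 waves fit. Wave starts are uniform (E2F waves may wrap; EdU/pH3 are
placed without wrap with pH3 starting strictly after EdU; the E2F4 second
wave starts after the first ends with at least one zero bin on each side);
duration draws are rejection-sampled until the placement constraints hold,
and specs whose minimal placements cannot fit raise an error naming the
violated invariant. Corruption replaces exactly `round(f · nb_t)` distinct
bins per sequence with a uniform draw over the *other* admissible values, so
the nominal fraction equals the realized one.

`sample_nucleus_table` inverts the measurement model: each synthetic nucleus
gets a uniform random cycle time, reads its levels/states off the truth, and
receives intensity `scale_image · level` (fresh scale per image), so per-image
quantization with `n_levels = nb_i` recovers the intended level whenever the
image contains the extreme levels. What the generator does *not* emulate:
optics (PSF, shading), segmentation errors, annotation noise, spatial
correlation between neighbouring cells, or any coupling between a mouse's
E2F wave placement and its EdU/pH3 runs. The last point matters: real
biology ties E2F phases to cycle phases, while the simulator places them
independently, which produces histograms harsher than real data (revisited
cells, coincident switches) — a green end-to-end test therefore establishes
recovery under *adversarial* phase placement, and a red one may reflect that
harshness rather than an implementation defect.

MSE between estimate and truth is computed after exhaustive circular
alignment; each simulated mouse carries its own arbitrary phase while the
method registers all mice to a common anchor, so the alignment is searched
per sample. By default each marker is aligned independently (the error is
reported per marker); `alignment="sample"` shares one shift across a sample's
markers and additionally penalizes inter-marker phase incoherence.

## Known limitations

* **E2F4.** Two waves sharing level cells in a joint histogram require many
  splits to traverse truthfully; the minimum-cost principle prefers a
  low-split merged traversal, so E2F4 initializations are structurally
  compressed and downstream stages cannot recreate the second wave when the
  joint context (E2F3A, EdU/pH3 phases) does not separate the waves. E2F4
  recovery error is several times that of the single-wave markers.
* **Noise non-monotonicity.** Moderate corruption can *reduce* E2F4 error:
  scattered nuclei repopulate empty histogram cells and reconnect degenerate
  graphs, giving the covering search better routes.
* **Refinement drift.** The assignment objectives pull each couple toward the
  other couples' references with no extra weight on already-consistent ones;
  with perfectly consistent inputs the identity is a fixed point (tested),
  but with disagreeing initializations accurate and inaccurate couples meet
  in the middle, and E2F error after refinement can slightly exceed the
  post-registration error.
* No sub-bin registration; shifts and assignments are integer bins.
* The covering-sequence search is exponential in the worst case; it is exact
  for the ≤ ~20-vertex graphs that 4-level histograms produce, with only the
  secondary wrap tie-break resolved best-effort under a node budget.
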