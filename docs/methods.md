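# Methods

## The measurement model

A traced rhizoid system is a rooted geometric tree read from standard
7-column SWC (id, type, x, y, z, radius, parent; micrometres).  SWC type
codes are mapped onto the chytrid cell plan — 1 → thallus, 5 → apophysis,
3 → rhizoid, anything else → unknown — because SWC has no fungal
vocabulary.  The thallus root is the cell body, not rhizoid: edges whose
child is a thallus node are excluded from rhizoid length and area sums,
while apophysis and unknown nodes are measured as rhizoid (the apophysis is
part of the feeding structure's path).  Files are read in any node order
(two-pass parse) and written parent-before-child with full float precision,
so write∘read is the identity on the node table.  A root-only tree is legal
(a germling before germ-tube emergence) and yields zero-valued metrics
rather than errors.  Degenerate zero-length edges are dropped from
geometric sums and traversals; topological counts use the raw tree.

### Metric definitions

* **total_length** — Σ Euclidean edge lengths over rhizoid edges.
* **tips / bifurcations** — non-root nodes with 0 children / ≥ 2 children.
* **RGU** — two definitions are provided because the growth unit is
  described verbally as the distance between two bifurcations while the
  classical hyphal growth unit is the length/tips ratio.  The **ratio**
  form (total_length / n_tips) is the default and the one used in
  trajectory comparisons; the **segment** form is the mean path length
  between consecutive topological points (root, branch points, tips) and is
  undefined (NaN) on unbranched trees.
* **surface_area** — lateral conical-frustum area per edge,
  π (r_p + r_c)·√(L² + Δr²).  Whether the cell's reported surface area
  includes the thallus is ambiguous, so both variants are emitted:
  `surface_area` (rhizoid only) and `surface_area_total` (+ 4πr² root
  sphere).
* **max_euclidean** — straight-line reach from the root to the farthest
  node.
* **bifurcation angles** — at each non-root branch point, the angle between
  daughter chord directions; each chord runs from the branch point to the
  first daughter node ≥ 0.5 µm of path away, which suppresses quantisation
  noise in densely sampled traces.  More than two daughters yield all
  pairwise angles.
* **cover_area** — area of the 2-D convex hull of the XY-projected nodes
  (z is the optical axis; analysis mirrors maximum-intensity projections).
  The hull was chosen over alpha-shapes for determinism; degenerate
  (collinear) point sets give 0.

On 100 random trees every metric agrees with an independent brute-force
traversal to 1e-9 relative tolerance, and all metrics are invariant under
rigid motions and covariant under scaling (tests).

## Branch-event detection and classification

Between consecutive frames, a node with ≥ 2 children in the later frame but
< 2 (or absent) in the earlier frame is a new branch event.  Geometry is
measured at first appearance:

* the **parent filament's local axis** is the direction of the 2 µm of path
  upstream of the insertion point;
* the **distance to tip** walks downstream through pre-existing structure
  (choosing the straightest continuation at pre-existing bifurcations) to
  where the filament's tip stood in the earlier frame;
* the **branch direction** is the chord of the single new daughter or, when
  every daughter is new (a tip split), the bisector of the new daughters —
  a symmetric split straddles the established axis, so the bisector is the
  faithful reading of "parallel to the axis" for tip splits.

Classification is apical iff distance_to_tip ≤ d_tip AND axis angle ≤
theta_par, else lateral.  The thresholds (defaults d_tip = 1 µm,
theta_par = 30°) are the only free parameters and are exposed in every
interface; raising either can only move calls lateral → apical
(threshold monotonicity, tested).  When node ids are not stable across
frames, nodes are first matched greedily by nearest neighbour within 1 µm;
ambiguous matches abort with an error rather than guessing.

## Fractal analysis

Filament projections are rasterised as 1-pixel Bresenham strokes
(skeleton treatment, not fluorescence intensity) at 0.5 µm/px by default
(≈ confocal lateral sampling), on a grid anchored to the structure's
bounding box with a small margin — so translating the structure leaves the
raster, and hence Db, exactly unchanged.  Box sizes are powers of two from
2 px to a quarter of the grid's short side (≥ 4 sizes required), counted on
a fixed grid with no offset search and fitted over all sizes by least
squares; this is deterministic and needs no per-image tuning, at the cost
of a small grid-phase sensitivity (< 0.05 on realistic rasters, tested).
The analytic limits are recovered: Db = 1 for a line, 2 for a filled plane,
0 for a point.  The local map applies the same estimator in 64 px windows
on a 16 px stride (window must allow ≥ 4 box sizes); windows with < 10
foreground pixels are undefined (NaN).  Radial profiles average the defined
map values in annuli about the thallus centre (default bin width = half the
window).

## Growth rates

Rates are per-cell OLS slopes of a metric's time course, aggregated as
mean ± s.d. and s.e.m. across cells — mirroring biological replication
(n cells, mean ± s.e.m.) rather than a pooled regression.  Cells with < 3
frames are skipped with a warning.  Compartment elongation over a fixed
interval (default 30 min) takes each earlier-frame tip that has not
branched by the later frame and divides the path length grown downstream of
it by the interval; path length is used rather than displacement because
filaments curve.  The compartment diameter is twice the mean traced radius
of its nodes, and the diameter-scaled rate (rate/diameter, 1/min) is
reported alongside the raw rate.

## The growth simulator

The generator is phenomenological, chosen to reproduce the observed
statistical structure of rhizoid development rather than its mechanics:

* **Constant system elongation budget** `V` shared across active tips, not
  a per-tip rate: measured total length grows linearly in time even as tips
  multiply, which a constant per-tip rate would contradict.  Total length
  at time T is V·T to within one step's discretisation (tested).
* **Constant Poisson branch rate** `λ` per system, not per unit length: tip
  production is likewise linear in time.  Tip count at T is
  1 + Poisson(λT) across seeds (goodness-of-fit tested).
* Each event is **lateral with probability p_lat = 0.85** (dominance is
  reported without a printed ratio, so the value is exposed as
  configuration): a node is inserted at a length-uniform random point on
  the existing filament and a new tip leaves it at an in-plane angle drawn
  from N(angle_mu, angle_sigma) truncated to (0°, 180°), random side.
  Otherwise the event is **apical**: a tip splits, daughters at ± angle/2
  about its heading; both daughters are pending until their next-step
  extension, which also prevents a node splitting twice in one step.
* Tip headings random-walk with per-step angular noise (s.d.
  `tip_persistence`, default 2°/step at dt = 0.01 h); growth is planar
  (z = 0), matching cells developing along the glass bottom of a dish.
* Node identity is stable: tips grow by appending nodes, lateral insertion
  subdivides an edge without moving geometry.  A single seeded generator
  with a fixed draw order (initial heading; per step, heading noise in tip
  order, then branch arrivals) makes runs bit-identical per seed.  Arrivals
  are skipped on the final step so every logged branch is visible in the
  last frame; the event log is exact ground truth for the detector (tested
  count-for-count).

Defaults: dt = 0.01 h, hourly frames, 10 h duration, filament diameter
1.0 µm, thallus radius 2.5 µm.

### Presets

* **replete** — the published rates: V = 110.8 µm/h, λ = 4.6/h,
  angle 81.4° ± 6.3.
* **starved** — the searching phenotype.  No numeric parameters are
  published for starvation (the trajectories are graphical), so the preset
  encodes the reported directions with configuration-exposed magnitudes:
  λ halved to 2.3/h, insertion angle widened to 95°, elongation budget
  maintained (the cell keeps investing in reach).  At matched time this
  yields longer maximum Euclidean distance, higher RGU, wider angles and
  larger cover area than replete — each in ≥ 18/20 seeds (tested).
* **bead** — a searching cell that has met a chitin microbead (radius 8 µm,
  centre 20 µm from the origin, germ tube initially aimed at it, as for a
  cell that has already encountered the particle).  Edges and tips within
  2 µm of the bead surface follow a feeding regime — branch rate 9.2/h
  concentrated on the contact region, tip elongation weight 0.4 — while
  free rhizoid keeps the starved parameters.  `bead_contact_split`
  partitions any tree into contact/free subsystems by edge midpoint
  distance and returns measurable summaries; the contact subsystem has the
  lower ratio-RGU in ≥ 18/20 seeds (tested).

## Group statistics

Welch's unequal-variance t-test is the default because the underlying test
behind the published significance stars is not named; Mann-Whitney U is
offered for small samples, and the test used is recorded in every output
row.  Stars map p two-sided at 0.05/0.01/0.001; insufficient n yields
descriptives with a missing p.  No multiple-testing correction is applied
by default (stars are presented per metric); Benjamini-Hochberg adjustment
is available and off by default.

## What the synthetic data does and does not show

The generator reproduces the target statistics by construction — linear
length and tip growth, lateral dominance, the angle distribution, the
saturating RGU trajectory, phenotype direction shifts — so passing
recovery tests demonstrates that the **measurement pipeline is unbiased
and self-consistent**, not that real rhizoids follow this model.  Real
traces additionally contain tracing noise, radius variation along
filaments, non-planar growth, tip stalling/retraction and anisotropic
sampling, none of which are emulated.  Problem sizes in the test and
acceptance runs (5–20 cells, 10 h, dt = 0.01 h) match the study design of
the imaging experiments they mirror (n = 5 hourly reconstructions).

## Known limitations

* The box-count estimator uses a single fixed grid phase; values carry a
  small (< 0.05) alignment sensitivity.
* Apical/lateral thresholds are declared defaults, not fitted constants.
* The segment-form RGU averages path segments of a single frame; it is not
  a longitudinal internode statistic.
* The 3-D content of traces is preserved in measurement but the simulator
  grows planar systems; a z-noise mode would be a minor extension.
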