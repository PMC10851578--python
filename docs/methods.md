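# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Problem setting

High-density ALS over a two-layer stand returns a mixture of mature-crown,
trunk, sapling, shrub/grass and ground points. Sapling phenotyping requires
(i) heights measured against the true soil surface rather than the grass
layer, (ii) complete removal of overstory crowns *and trunks*, and (iii) a
clusterer whose spatial scale adapts to locally varying sapling size and
spacing. The pipeline addresses each in turn.

## Fine normalization

The ground/nonground split is pluggable; the built-in filter grids the
cloud at 1 m, takes per-cell minima, and rejects a cell's minimum as canopy
when it stands more than 0.5 m above the windowed median of minima
(window 5 cells). The median reference is unbiased on planar slopes, so
terrain crests are not eroded the way a morphological opening erodes them;
rejected cells are filled from the nearest trusted cells. Points within
0.25 m of the surface are ground. The filter's known limit: if occlusion
removes *all* ground returns over an area wider than the median window, the
surface locally rides up onto vegetation — the same failure mode as any
minimum-based filter.

True-ground refinement grids classified ground points at Δ = 0.5 m in x/y
(the refinement is deliberately 2D — the procedure only increments the
horizontal coordinates) and keeps exactly the per-cell lowest point as true
ground; the rest become pseudo ground at height 0. Nonground points are
normalized against the horizontally nearest true-ground point
(2D nearest-neighbor, no interpolation; a 25 m search radius, beyond which
a point is flagged noise). Negative normalized heights are clipped to 0.
Idempotence holds above the ground tolerance; points inside the 0.25 m
band are absorbed to height 0 on renormalization, by construction.

## Overstory delineation

Stratification at 5 m (strictly above = overstory) separates mature crowns
(>10 m) from saplings (≤3.5 m); a histogram-valley estimator
(`estimate_threshold`) is provided for stands where the gap sits elsewhere.

Spectral clustering uses a truncated anisotropic Gaussian affinity:
`exp(−½(d_xy²/σ_xy² + d_z²/σ_z²))`, zero beyond 5 m horizontally, with
σ_xy = 1.5 m (lateral crown scale) and σ_z = 6 m (crowns are vertically
elongated, so height differences are down-weighted). The cluster count is
the number of CHM local maxima of the stratum (0.5 m CHM, 2 m minimum peak
distance ≈ crown radius) and is overridable. For strata larger than the
landmark budget (default 500) the normalized-affinity eigenbasis is
approximated by Nyström: with landmark columns C and landmark block W,
degrees are estimated as d = C W⁺(Cᵀ1) and the embedding comes from the
eigendecomposition of MᵀM with M = D^(−1/2) C W^(−1/2). W's inverse square
root is rank-truncated at 10⁻⁶ of its largest eigenvalue — near-duplicate
landmarks otherwise make the embedding numerically worthless. Final
grouping is k-means++ with a fixed seed on the row-normalized embedding.

### Postprocessing

Candidate rules follow the stated thresholds (height > 5 m, MBR aspect
strictly in (0.7, 1.3), centroid-in-footprint, count > num_mean/2).
`num_mean` bootstraps as the median count of a seeded 10% segment sample
and continues as a running mean over accepted candidates. The
centroid test uses the 2D convex hull of the footprint: the centroid is
defined with a vertical component too, but containment is only meaningful
in plan view.

Forced splitting projects a suspect's points onto the two vertical facades
of its minimum bounding rectangle. Silhouettes are traced by an alpha shape
(Delaunay triangles with circumradius below max(3 × point spacing, 1 m);
the floor stops the shape from shattering on dense crowns, and a convex
hull is the fallback for degenerate cases — note a convex silhouette can
never show a saddle). The upper envelope is sampled as the per-bin maximum
boundary height along the facade (bin = boundary vertex spacing, at most a
tenth of the span), simplified by Douglas–Peucker with tolerance 5 × the
mean adjacent spacing of the *projected points*, and interior vertices
where the slope turns from falling to rising are the saddles. Cuts are
vertical planes at the saddles of the facade with more saddles; parts are
re-filtered and re-split recursively (depth ≤ 3), and parts or segments
with no saddle join the residual set. "Taking the derivative" is realized
as the discrete sign change — on a polyline, derivatives only exist
discretely.

Backward allocation implements the two-stage rule with the *crown radius*
(= width/2) as the direct-merge threshold: the worked P2 narrative is only
consistent with the radius reading, not the literal "crown width". After
allocation all candidate parameters are recomputed.

## Understory extraction

DBH is predicted from height by OLS on field pairs (in synthetic runs, up
to 100 overstory inventory records, mirroring a field sample of 100 mature
trees); predictions are floored at 0.02 m. The trunk buffer is a
full-height cylinder of radius 1.5 × DBH — the factor is read as a radius
multiplier, since a diameter reading would leave buffers too thin to cover
crown-lean offsets. Isolated points are removed when their 3×3×3
neighborhood of 0.3 m voxels contains ≤ 1 other point. The sapling CHM
(0.05 m, per-cell max) fills empty cells by iterative 3×3 valid-neighbor
means, restricted to cells within 0.3 m of an occupied cell so filling
never invents canopy over open ground; filling by neighbor means can never
exceed the observed maximum.

## Adaptive mean shift

Bandwidths follow `h = ∂ · radius_m / sd_m` literally (∂ = 0.5), with h in
meters, clipped to [0.3, 1.0] m: the floor is the smallest crown scale the
scanner resolves (widely spaced plantings otherwise get kernels thinner
than the point spacing), and the cap keeps an overgrown crown boundary
from widening the kernel past neighboring saplings. Seeds are strict CHM
local maxima above 0.3 m (suppressing grass) within a 1.5 m window (half
the planting spacing) after a light 0.1 m Gaussian smoothing of the CHM;
seed heights are read from the unsmoothed CHM. Crown boundaries grow from
the seed over non-increasing heights (0.03 m rise tolerance) and stop at
no-data; `radius_m` is the minimum enclosing circle of the boundary.

The mean-shift update runs in 3D with the vertical axis scaled by 0.3.
The isotropic-3D default was tried first and proved wrong: within a single
conical crown the vertical point distribution is multi-modal at these
bandwidths, and equal weighting fragments each sapling into stacked
clusters; down-weighting height recovers one mode per crown while retaining
3D membership. Pure-2D mode seeking (weight 0) is available. Convergence:
tolerance 10⁻³ m, ≤ 100 iterations; converged modes merge within
0.5 × local bandwidth; mode groups are then consolidated onto their nearest
seed (within the local bandwidth) so fragments of one crown reunite, and
groups with no nearby seed — grass clumps, trunk remnants — become noise.
Points whose kernel window empties are noise. Clusters need ≥ 3 points.

Phenotypes: height and position come from the highest member point; crown
width is the mean of the east–west and north–south extents.

## Evaluation

Matching is one-to-one: feasible pairs lie within 1 m horizontally and
1.5 m in height; the assignment maximizes matches, then minimizes total
height difference (Hungarian on a penalized cost matrix). A per-reference
greedy rule can double-assign detections, and its result can differ from
the exhaustive optimum, so the exact assignment is used. The commission
rate uses the identity `R_com = 1 − R_mat/R_det`. Canopy closure resamples
the CHM by the max rule (closure is an occupancy measure; mean-resampling
dilutes thin crowns) and reports the fraction of valid cells above the cut.

## Synthetic stands

The generator emulates the study system: a same-aged conifer overstory on
a jittered planting grid (heights 15–20 m, crown radius ≈ 0.12 × height,
cone crowns, trunk returns at 20 pts/m), saplings on a 3 m jittered grid
(1–3.5 m, planted rows and columns), grass/shrub clutter at 1 pt/m² in a
0–0.5 m band, a smooth sinusoidal terrain (default 4 m relief over 50 m,
mean slope ≈ 9°), and 243 pts/m² scanning density. Stem counts derive from
the closure target via crown coverage. Saplings carry a 0.1 m terminal
leader shoot supported by no points — the scanner misses the current-year
shoot — and a dense top whorl (≈ 6 returns within 0.15 m of the crown top)
so the crown top itself is sampled, as it is for real conifers. An
occlusion model removes non-overstory points beneath crowns with
probability 0.5 × (summed fractional crown cover), capped at 0.85, which
produces the closure-dependent sapling detectability the evaluation
measures. Determinism: every tree draws from its own spawned seed sequence,
so identical configs reproduce byte-identical clouds and adding trees does
not reshuffle existing ones.

What the generator does *not* model: waveform/intensity effects, multiple
returns per pulse, species mixtures, crown asymmetry and wind-blown lean,
understory shrub patches with coherent shape, and co-registration error
between strips. Passing tests therefore demonstrate algorithmic
correctness and the expected qualitative responses (closure vs. matching,
true- vs. pseudo-ground bias), not sensor-level realism.

## Problem sizes

Tests and examples run stands of 20–25 m on a side at the study's full
243 pts/m² density (≈ 50k–130k points, seconds per stage on one CPU); these
sizes exercise every code path including the Nyström approximation
(landmark budget 500 < overstory stratum size). The acceptance checks in
`tests/test_acceptance.py` use randomized instances ≤ 1,000 points for the
brute-force oracle comparisons, a ≤ 5,000-point five-crown tile for
Nyström fidelity, and four 25 m stands for the closure ladder.

## Known limitations

- The candidate aspect test reads the ratio as short/long; values above 1
  cannot occur, so the 1.3 bound is inert under this reading.
- Backward allocation assigns by candidate *centroids*; heavily leaning
  trees would need stem-axis distances instead.
- The bandwidth formula makes h dimensionless times meters per meter; it is
  applied literally with h in meters, and the clip range carries the
  physical scale.
- Deciduous, flat-topped crowns violate the single-apex assumption of both
  the CHM seeding and the saddle-cut repair.
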