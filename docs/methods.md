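# Methods

## Resistance surface

Three habitat layers are scored on an ordinal 1–6 resistance scale and
summed equally.

**Terrain ruggedness.** TRI(c) = √Σ(zₙ − z_c)² over the eight neighbours
(Riley neighbourhood form); edge cells use the neighbours they have, and the
index is computed over the full grid, water included (flat water contributes
only at the coastal rim). The default classification uses the fixed breaks
1–25 / 25–50 / 50–88 / 88–139 / 139–230 / 230–271 → 1…6. Bins are half-open
[lo, hi) with the final bin closed, and open-ended at both extremes: values
below the first bound take class 1 and above the last take class 6, because
the printed extremes describe one study DEM's observed range, not a law. A
Fisher–Jenks natural-breaks routine (exact O(kn²) dynamic programme) is
provided to re-derive breaks on new terrain, but the pipeline classifies
with the explicit defaults — reproducibility over re-derivation.

**Landcover.** Mature forest (never harvested, or stand age > 75 y),
bryoid/shrub/herb, and barren rock are fully permeable (1); regenerating
stands 10–75 y post-harvest are in the hyper-dense stem-exclusion stage and
score 3; snow/ice scores 6. Stands under 10 y are not covered by the class
table; they score 1 here (early-seral, forage-rich open ground, akin to the
shrub class) — configurable. Water carries no landcover resistance.

**Water.** A Euclidean distance transform (cell-centre to nearest land
cell-centre) replaces ring-buffer GIS tooling; water scores 3 / 5 / 6 at
< 1 km / 1–3 km / > 3 km from shore. Land carries no water resistance, so
the landcover and water domains are exclusive by construction.

**Cumulative surface.** Land cells sum terrain + landcover, water cells
terrain + water. A plain sum of two 1–6 layers cannot start at 1, yet the
working scale is 1–10; the raw sum is therefore mapped affinely so its
minimum is 1 and maximum 10 (a constant field maps to uniform 1). The map is
monotone, so orderings — all that resistance encodes — are preserved. Grids
can be clipped to a study boundary with a 10 km buffer (default) against
edge effects.

## Focal nodes

Node = midpoint (half the total arc length) of all reaches of one salmon
species on one stream, parts concatenated downstream→upstream. Midpoints
within 150 m of one another (the cell resolution) merge to their unweighted
mean centre; "within 150 m of one another" is implemented as single-linkage
connected components, which is deterministic and order-independent even for
chains A–B–C where A and C are farther apart. Nodes are snapped to their
containing grid cell (nearest valid cell within 2 cells if on nodata);
collisions merge, so no two nodes share a cell. With n nodes the pipeline
always reports n(n−1)/2 unordered pairs.

## Circuit model

Valid cells are nodes of a resistor network with 8-neighbour connectivity;
the edge between cells i, j carries resistance (rᵢ + rⱼ)/2, ×√2 for
diagonals (the standard raster convention; cell size cancels from the
relative comparison). For a focal pair, the conductance Laplacian system
Lv = b is solved with +1 A at the source, −1 A at the target, target
grounded. R̂ = v_s − v_t; Ĝ = 1/R̂. Current density per cell is half the
sum of absolute incident branch currents, with source and target pinned at
the injection — the conventional current-density map. Per component the
grounded Laplacian is factorised once (sparse LU) and reused across all
pairs, which makes thousands of pairwise solves cheap; solutions match a
dense pseudo-inverse oracle to better than 1e-8 relative error in tests.
The cumulative map is the unnormalised sum of unit-injection per-pair maps.
Disconnected pairs (separate islands) are data, not errors: R̂ = ∞, Ĝ = 0.

## Corridors

Cell conductance = current + ε with ε = 1e-6 × max current, so zero-current
cells stay traversable at high cost rather than blocking paths; edge cost =
inter-cell distance ÷ mean conductance. One undirected least-cost path per
node pair (Dijkstra with predecessor tracking; costs are symmetric, so
directed duplicates would be redundant). The top fraction f keeps ⌈f·n⌉
paths by lowest accumulated cost, ties broken by pair id. Corridors buffer
each top path by half the corridor width (total width 1200 m by default,
following the interpretation of "1200 m-wide corridors") and dissolve
overlaps; protected-area overlap is reported as the fraction of accumulated
path length outside the protected multipolygon.

## Transit validation

Sessions within a calendar year form one sampling season. For each
(individual, year), all unordered pairs among the individual's distinct
detected sites count as transits; the transit table covers every site pair,
with a binary outcome pooled across years and species (supporting counts
retained). Firth's penalized likelihood l*(β) = l(β) + ½ log det(XᵀWX) is
maximised by Newton iteration on the modified score
U*ᵣ = Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢᵣ with step-halving against l*;
convergence at max|U*| < 1e-8 or step < 1e-10, at most 100 iterations.
Standard errors come from (XᵀWX)⁻¹ at β̂; intervals are Wald-type (a
profile-penalized-likelihood interval would be a reasonable extension;
Wald was chosen for simplicity and because the sparse-data simulations
below show calibrated coverage). Predictors are z-standardised by default:
odds ratios of ~1.66 per SD of conductance and ~0.36 per SD of distance are
interpretable magnitudes, whereas a per-metre distance OR would be
indistinguishable from 1. Prediction curves hold distance at 5170 m — the
radius of a circle with the 84 km² average coastal male black bear home
range.

## Synthetic data

The generator emulates the study system's data shapes, not its geography:

- **Terrain** — Gaussian random fields with a k^−1.8 power-law spectrum,
  normalised to [0, relief]; sea level is placed at the (1 − land_fraction)
  elevation quantile, which yields coherent islands and fjords.
- **Landcover** — snow/ice above the top snow fraction of land elevation, a
  barren band below the snowline, shrub openings and contiguous
  regenerating patches from thresholded autocorrelated noise (regen patch
  area ≈ regen_fraction of land; stand age uniform 10–75 y).
- **Hydrology** — streams start on high interior ground and follow a greedy
  descent of the distance-to-water transform (ties broken downhill), so
  every stream reaches the coast and stays on land. Reach lengths are
  log-normal, truncated to the observed [19 m, 11.3 km], with σ = 1 on the
  log scale and the location parameter solved so the truncated *mean* is
  1.7 km, matching the three published summaries of the real reach-length
  distribution.
- **Snag sites** — a jittered rectangular grid snapped to land: "evenly
  spaced, with noise". Spacing and detection rates are otherwise
  unconstrained by published values.
- **Detections** — half-normal encounter model, the standard spatial
  capture–recapture form: P(detect) = p₀·exp(−d²/2σ²) from each
  individual's home-range centre (uniform on land), per site × year ×
  session. Study-scale defaults (66 grizzly + 199 black individuals,
  σ = 5170 m, p₀ = 0.3, 5 years × 2 sessions) are kept on the model type;
  the pipeline's default run config scales these down (24 individuals,
  σ = 1500 m, p₀ = 0.08) because study-scale pressure on a ~81 km² toy
  landscape saturates every site pair, whereas the validation design is
  specifically about sparse, unbalanced outcomes.
- **Transits** — Bernoulli(expit(β₀ + β_G z(Ĝ) + β_d z(d))), the exact
  structure the validation fits; `calibrate_intercept` solves β₀ by
  bisection for a target base rate (e.g. the sparse 54/2145 ≈ 2.5%).

One master seed fans out to sub-generators by fixed offsets; every
generator is bit-reproducible per seed. What passing tests show is that the
method implementation is correct and recovers known simulated effects; they
cannot show that the expert-assigned resistance values describe real bear
movement — that question needs the field data, and the synthetic landscape
deliberately carries no information about it. Real-data features not
emulated: salmon run phenology (no within-season dynamics by design),
spatial bias in snag placement, genotyping error, and species differences
in movement.

## Problem sizes and numerical choices

Tests and the acceptance script run on 60×60–80×80 grids (150 m cells,
9–12 km extents) with 6–20 focal nodes, and on the full 66-site / 2145-pair
validation design with 200 Monte-Carlo replicates — sizes chosen so the
whole suite completes in seconds while exercising every code path,
including multi-island disconnection. Solver tolerances: sparse LU
factorisation (exact to machine precision) for the Laplacian solves; Firth
convergence at max|U*| < 1e-8. The Monte-Carlo recovery check requires mean
estimates within 2 Monte-Carlo SE of truth and Wald coverage in
[0.92, 0.98] at 200 replicates.

## Known limitations

- The affine 1–10 rescale of the cumulative surface is one reading of an
  ambiguous published scale; any monotone map preserves path and current
  orderings up to the nonlinearity of the sum, but absolute R̂ values are
  scale-dependent.
- Per-pair current maps are accumulated unnormalised; alternative
  normalisations would reweight pinch points.
- The snapping search radius (2 cells) can reject nodes in heavily masked
  regions; place nodes on or near valid cells.
- Wald intervals undercover in more extreme sparsity than simulated here;
  profile-penalized intervals are not implemented.
- The greedy stream-routing is not a hydrological flow model; streams are
  plausible polylines, not watershed-consistent drainage.
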