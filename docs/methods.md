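# Methods

This note documents the models and procedures `ecoprov` implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic tests do and do not demonstrate.

## Input model

The pipeline consumes a regular lat/lon surface field carrying, per cell,
the biomass of 51 plankton types partitioned into 7 biogeochemical
functional groups (2 pico-prokaryotes, 2 pico-eukaryotes, 5
coccolithophores, 5 diazotrophs, 11 diatoms, 10 mixotrophic dinoflagellates,
16 zooplankton), four nutrient supply rates (N, Fe, P, Si; mmol/m³/yr) and
an ice-cover fraction. Grids are cell-centred, latitude in [−90, 90],
longitude in [−180, 180); depth and time are out of scope — the intended
source is a long-term mean surface state. Group biomass is validated
against per-type sums at 10⁻⁶ relative tolerance whenever both are present.

## Preprocessing

* **Masking.** A cell is retained iff its *total* (summed over the 7
  groups) biomass is ≥ 1.2×10⁻³ mg Chl/m³ and ice fraction ≤ 0.7. The
  threshold is interpreted per-cell-total because the masking rule speaks of
  "a biomass" for the grid cell; a per-group interpretation is available via
  `per_group=True`.
* **Transform.** Natural log of the 7 biomass columns (a cell can retain a
  zero in one group while passing the total-biomass mask, so zeros are
  floored at ε_log = 10⁻¹⁰ — far below any realistic biomass — before the
  log), then per-column min-max to [0, 1], then per-column standardisation
  (population variance, so unit variance is exact). The two normalisation
  conventions ("all data in [0, 1]" and "zero mean, unit variance") cannot
  hold simultaneously; they are applied in that order and *both* stages are
  kept retrievable in `FeatureMatrix.intermediates` so either convention can
  be consumed downstream. Nutrient fluxes are not logged by default
  (`log_fluxes=True` switches this). Constant columns standardise to 0 with
  a warning rather than an error.

## t-SNE embedding

* **Affinities.** Per-point Gaussian bandwidths are calibrated by bisection
  on the precision β = 1/2σ² until each row's perplexity matches the target
  within 10⁻⁶ (contract: 10⁻⁴). Joint affinities are symmetrised,
  p_ij = (p(j|i)+p(i|j))/2n. When the target is unreachable — for example
  exactly duplicated rows bound the row entropy below by the log of the
  duplicate count — the closest achievable calibration is kept and a warning
  is emitted.
* **Objective.** KL(P‖Q) with the Student-t kernel normalised over all
  pairs (the standard symmetric formulation; a row-conditional
  normalisation of q is not compatible with a joint p and is not used).
* **Optimiser (exact backend, n ≤ 5000).** Gradient descent from a seeded
  N(0, 10⁻⁴) initialisation: learning rate 200, early exaggeration 12 for
  the first quarter of the iterations, momentum 0.5 then 0.8, per-coordinate
  adaptive gains, 300 iterations total by default. The full KL trace
  (against the unexaggerated P) is recorded per iteration; runs are
  bit-reproducible from the seed. These optimiser settings follow common
  t-SNE practice and are recorded in the output sidecar; the method treats
  reproducibility as a property to be demonstrated by repeated realizations,
  not by tuning optimiser details.
* **Barnes-Hut backend (n > 5000).** scikit-learn's implementation with the
  same perplexity/iterations; it reports only the final KL.
* **Defaults.** Perplexity 400 and 300 iterations are the reference-scale
  operating point (~40 000 retained 1° cells). With `scale_to_n` the
  pipeline rescales perplexity proportionally (floor 5) for smaller inputs;
  perplexity must always be < n.

## DBSCAN clustering

Closed Euclidean ε-neighbourhoods; a core point has ≥ min_pts neighbours
(itself included); clusters are density-connected components, labelled in
discovery order under a fixed ascending-index visit, making the run
deterministic. Border points reachable from several clusters go to the
first-discovered (lowest-id) cluster — the only genuinely order-dependent
outcome in DBSCAN. A cluster left with fewer than min_pts members (possible
when its border points were claimed by an earlier cluster) is dissolved into
noise, so every reported province satisfies the minimum-membership rule.

* **Defaults** ε = 0.39, min_pts = 100 at the reference scale; min_pts
  warns above ~135, where a robust ε plateau is unlikely to exist. For
  smaller inputs min_pts scales as round(100·n/40000) with floor 5.
* **ε selection.** `scan_eps` records cluster count ("connectivity") and
  coverage over an ε grid (auto-grid: geometric from below the
  nearest-neighbour distance to beyond the embedding diameter, so the
  all-noise and single-cluster regimes are always bracketed). `select_eps`
  finds maximal runs of ε where the count stays ≥ 2 and adjacent counts
  change by ≤ 10 % (relative — about ±10 at a few hundred clusters),
  requires evidence of both the noise/over-fit regime at smaller ε and the
  under-fit (≤ 1 cluster) regime at larger ε around the run, and picks the
  highest-coverage ε within the largest stable plateau (ties → larger ε).
  This is a declared numerical operationalisation of what is otherwise a
  visual elbow-reading; the scan table is exported so a user can always
  inspect the curves.

## Bray-Curtis dissimilarity

BC(a, b) = 1 − 2 Σ min(aₜ, bₜ)/(Σ aₜ + Σ bₜ) on linear biomass — never on
the logged/standardised clustering features. Evaluated either on the 51
types (default: community structure at full resolution) or the 7 group
sums. Province mean assemblages are cos(latitude)-weighted by default
("area-averaged" on a regular grid; `area_weighted=False` disables).
Intraprovince BC (homogeneity) is the mean BC between member cells and the
province mean; the global summary is reported both cell-weighted and
province-weighted, since the two differ whenever province sizes do and
published global figures rarely say which was used. Interprovince BC (the
aggregation distance) is the BC between province means; the matrix is
symmetric with an exactly zero diagonal. Both-all-zero assemblages are
rejected (0/0). `benchmark_bc` computes the same statistics under any
user-supplied reference partition of the retained cells (e.g. a rasterised
expert-drawn province map); `shuffled_benchmark` provides a self-contained
null — the pipeline's own labels randomly reassigned, preserving cluster
sizes while destroying coherence.

## Aggregation into AEPs

The interprovince BC matrix defines a complete weighted graph (BC as
distance). "Most dominant / highly connected" is operationalised as the
connectivity score Σⱼ (1 − BCᵢⱼ) — the simplest monotone total-similarity
ranking; the graph is exported so alternative rankings (e.g. thresholded
degree, or spatial size) can be applied externally. At complexity k the
top-k provinces by score (ties → lower id) are dominants; every other
province maps to the dominant with minimal BC (ties → lower dominant id).
k = m is the identity, k = 1 a single AEP; the mapping is idempotent by
construction. Province identity is *not* tracked across realizations — the
complexity scan aggregates statistics, not label matchings.

`complexity_scan` reruns only the stochastic stage across R realizations
(distinct embedding seeds expanded deterministically from one global seed;
DBSCAN reuses the selected parameters), computes the cell-weighted mean
intraprovince BC of the AEP partition per (k, realization), and reports per
k the mean, the degeneracy 2σ (sample σ across realizations) and the
worst-realization value. k_min is the smallest k with worst-realization
mean below the benchmark *and* 2σ ≤ 1.5 × the full-complexity 2σ. The 1.5
factor is a configuration default (`two_sigma_factor`); no published cutoff
for "relatively small" degeneracy exists, so the scan table is always
exported and a scan with no qualifying k is returned flagged rather than
failing.

## Synthetic data generator

`SyntheticSpec` plants known province structure so every stage can be
verified against ground truth:

* **blobs** — Gaussian clusters in the 11-D feature space (log-space for
  biomass); provinces laid out as spatially contiguous Voronoi patches.
* **curved_manifolds** — each province occupies a quadratic 1-D curve
  c + t·u + t²·v (t ~ U(−1,1), u ⊥ v random unit 11-vectors, amplitude 1.5
  in log units) with transverse noise: deliberately non-Gaussian shapes that
  defeat centroid clustering, verified by a Henze-Zirkler multivariate
  normality check that blob provinces pass and curved provinces fail.
* **zonal_bands** — blob features, provinces as latitude bands.

Default conditions: 40×80 or smaller grids; per-province group means drawn
from N(ln 5, 1) in log-biomass (inter-province spread ~1), lognormal(0, 1)
flux means around 1 mmol/m³/yr; iid noise sd 0.25 in log space (moderate
relative to that spread; flux noise is multiplicative, clipped at 0); a
polar ice band (fraction in (0.75, 1]) poleward of 70°; 5 % of eligible
cells rescaled below the biomass mask threshold; fixed per-province
Dirichlet(2) composition weights expand the 7 groups to 51 types so
type-level and group-level BC can be compared. Same seed ⇒ bit-identical
field; the generator's bookkeeping (iced/low-biomass counts) is exposed in
`attrs` for cross-checking against independent re-scans.

What the generator does **not** emulate: seasonality, depth structure,
spatially correlated noise, realistic coastlines/bathymetry, or the
continuum of community gradients in real model output — planted provinces
are genuinely discrete. Passing tests therefore demonstrate that the
pipeline recovers discrete non-Gaussian structure where it exists and that
every operation obeys its contracts; they do not demonstrate that a given
real ocean field contains such structure.

## Numerical choices and degenerate inputs

* Perplexity calibration: bisection tolerance 10⁻⁶ on the row perplexity,
  200 iterations max, warning on unreachable targets.
* KL evaluation: q floored at 10⁻¹²; p = 0 terms contribute 0.
* DBSCAN neighbourhoods are closed (distance ≤ ε); ties documented above.
* Empty survivor sets, all-zero assemblage pairs, single-province BC
  matrices, out-of-range complexities and malformed files all raise
  `ValidationError` with diagnostic counts (CLI exit code 2); non-finite
  optimisation states raise `NumericalError` (exit code 3).
* CSVs are written at %.17g and parsed with round-trip float precision, so
  field and artifact round-trips are bit-exact; the NetCDF dialect uses
  xarray's scipy (NetCDF-3) backend.

## Problem sizes used in the test suite

Unit and property tests run on grids from 1×3 up to 24×48. The end-to-end
recovery checks use a 40×80 grid with 5 planted provinces (≈ 2430 retained
cells after masking), perplexity 24 and min_pts 6 (both scaled from the
reference operating point), and R = 2 realizations for the complexity scan;
at these sizes the full suite completes in roughly six minutes on one CPU
while exercising both cluster geometries end to end.

## Known limitations

* The exact t-SNE backend is O(n²) memory and time; above 5000 points the
  Barnes-Hut backend loses the per-iteration KL trace.
* ε selection assumes the scan brackets both extreme regimes; very coarse
  grids can miss narrow plateaus (the error message says to widen the grid).
* Aggregation uses one realization's province set for the final AEP map;
  cross-realization label matching (province tracking) is not implemented.
* Area weighting assumes a regular lat/lon grid; irregular grids would need
  explicit cell areas.
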