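# ecoprov

Unsupervised identification and aggregation of marine **eco-provinces** —
regions of the surface ocean with coherent plankton community structure and
nutrient supply — from gridded ecosystem-model output.

## The problem and the method

Ecosystem models resolve dozens of interacting plankton types whose
covariance structure is strongly non-Gaussian, so centroid clustering
(K-means and relatives) cannot carve the ocean into faithful community-level
regions. `ecoprov` implements a density-based pipeline that can:

1. **Dimensionality reduction by ecology.** The 51 plankton-type biomasses
   are summed into 7 biogeochemical functional groups (pico-prokaryotes,
   pico-eukaryotes, coccolithophores, diazotrophs, diatoms, mixotrophic
   dinoflagellates, zooplankton); together with 4 nutrient supply rates
   (N, Fe, P, Si) each grid cell becomes an 11-dimensional vector *x*.
2. **Masking and normalisation.** Cells with total biomass < 1.2×10⁻³
   mg Chl/m³ or ice cover > 70 % are discarded; biomass columns are
   log-transformed, then min-max scaled to [0, 1], then standardised to zero
   mean and unit variance.
3. **t-SNE embedding.** Per-point Gaussian bandwidths σᵢ are calibrated by
   bisection so each conditional distribution
   p(j|i) = exp(−‖xᵢ−xⱼ‖²/2σᵢ²) / Σₖ exp(−‖xᵢ−xₖ‖²/2σᵢ²)
   attains a prescribed perplexity 2^H (default 400 at the reference scale of
   ~40 000 cells), and a 3-D map **y** minimises KL(P‖Q) against the
   heavy-tailed Student-t kernel qᵢⱼ ∝ (1+‖yᵢ−yⱼ‖²)⁻¹.
4. **DBSCAN clustering.** Provinces are density-connected sets in the
   embedding (defaults ε = 0.39, minimum membership 100 at the reference
   scale); unassigned points are noise. ε is chosen by scanning a grid and
   selecting from the stable plateau of the cluster-count ("connectivity")
   curve, favouring coverage.
5. **Aggregation into AEPs.** Province distances are Bray-Curtis
   dissimilarities between mean assemblages,
   BC(a, b) = 1 − 2 Σₜ min(aₜ, bₜ) / (Σₜ aₜ + Σₜ bₜ);
   the k most-connected provinces (connectivity score Σⱼ (1−BCᵢⱼ)) become
   dominants and every province nests under its nearest dominant. Because
   t-SNE is stochastic, the pipeline is repeated R times (default 10) and
   the minimum robust complexity k_min is the smallest k whose
   worst-realization intraprovince BC beats a benchmark partition while the
   2σ spread across realizations (the *degeneracy*) stays small.

A synthetic-field generator with planted province structure (Gaussian blobs,
curved 1-D manifolds in feature space, or zonal bands, plus a polar ice band
and a low-biomass tail) makes every stage testable against ground truth.

## Worked example

```bash
ecoprov generate --out field.csv --n-lat 24 --n-lon 48 --n-provinces 3 \
    --noise-sd 0.2 --seed 1 --truth-out truth.csv
ecoprov -v run-all --input field.csv --out-dir out --seed 7 \
    --realizations 2 --scale-to-n --scan-eps
```

prints (timings vary):

```
ecoprov INFO preprocess: 821 of 1152 cells retained (0.03s)
ecoprov INFO embedding r0: n=821 perplexity=8 kl=1.1798 (3.96s)
ecoprov INFO embedding r1: n=821 perplexity=8 kl=1.2119 (4.02s)
ecoprov INFO eps scan: chose eps=12.5744 min_pts=5 (0.37s)
ecoprov INFO dbscan r0: 3 provinces, coverage 1.000
ecoprov INFO dbscan r1: 3 provinces, coverage 1.000
ecoprov INFO benchmark intraprovince BC: 0.2057 (pipeline r0: 0.0792)
ecoprov INFO pipeline done: k_min=2, AEP intraprovince BC 0.1078
provinces (r0): 3; benchmark BC 0.2057; k_min 2; AEP intraprovince BC 0.1078
```

Reading this: all 3 planted provinces were found with full coverage; the
pipeline's provinces are far more homogeneous (intraprovince BC 0.079) than
a size-matched random partition of the same cells (0.206), and nesting them
to complexity 2 still beats that benchmark (0.108), so k_min = 2 here. The
output directory holds every intermediate as CSV with provenance headers
plus JSON sidecars: `features.csv`, `embedding_r*.csv`, `eps_scan.csv`,
`labels_r*.csv`, `interprovince_bc_r0.csv`, `complexity_scan.csv`,
`aep_mapping.csv`, and back-projected `province_grid.csv` / `aep_grid.csv`
maps (noise and masked cells carry −1).

The same stages are available as library calls (`generate_field`,
`apply_masks`, `transform_features`, `embed`, `scan_eps`/`select_eps`/
`dbscan`, `bray_curtis`/`intraprovince_bc`/`interprovince_bc`,
`aggregate`/`complexity_scan`/`back_project`) and as individual CLI
subcommands (`generate`, `preprocess`, `embed`, `cluster`, `dissimilarity`,
`run-all`, `plot`).

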