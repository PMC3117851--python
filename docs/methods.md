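# Methods

`betaproc` implements a process-explicit community-assembly framework
for inferring the strengths of **dispersal limitation** and
**environmental filtering** from taxonomic, phylogenetic and functional
β-diversity. This note documents the model, its parameters, the
numerical choices, and what the synthetic data do and do not show.

## The generative model

One replicate simulation runs six steps.

1. **Process strengths.** A point in process space is a pair
   `(n, d)`: `n` is the variance of the Gaussian niche function
   (squared z-score units; large `n` = broad niches = weak filtering)
   and `d` the variance of the Gaussian dispersal kernel (large `d` =
   weak dispersal limitation). Expectation grids span
   `10^-4 … 10` in half-decade steps (11 values per axis).

2. **Landscape.** `n_sites` local sites receive `D_S` spatial
   coordinates and `D_E` environmental values, all z-scored.
   Environmental axis *i* is constructed as
   `ρ·S_i + sqrt(1−ρ²)·noise⊥` with the noise Gram–Schmidt-
   orthogonalized against every spatial column, so the realized sample
   covariance σ_ES equals the requested target *exactly* (default 0.7,
   i.e. a space–environment R² near 0.5) and is exactly 0 for i ≠ j.
   Exact construction removes Monte-Carlo slop from the quantity the
   whole variance-partitioning analysis is conditioned on; the
   trade-off is that replicate-to-replicate variation in realized
   environmental structure, which a looser generator would add, is
   absent (see *Limitations*).

3. **Phylogeny and trait–range coevolution.** A pure-birth tree is
   grown to 500 extant species (birth 0.1, death 0; death < birth is
   supported, with extinct lineages pruned). Species environmental
   optima `T` (their functional traits) and range centroids `R` then
   evolve along the tree by multivariate Brownian motion whose
   per-unit-time increment covariance couples trait axis *i* to spatial
   axis *j* by

   σ_TR(i, j) = (e^−d + e^−n · σ_ES(i, j)) / (2 · D_S).

   The dispersal term `e^−d` → 1 under extreme dispersal limitation
   (lineages cannot move, so traits stay collocated with relatives) and
   → 0 when dispersal is unlimited. The filtering term is a declining
   fraction of σ_ES: filtering can couple traits to space only through
   a spatially structured environment. The denominator keeps the
   covariance summed over dimensions inside [0, 1] for z-scored axes.
   The covariance function is injected as a strategy, so an alternative
   algebra can be swapped in without touching the pipeline. With the
   default form the 1-D strong/strong covariance is 0.975 at
   σ_ES = 0.95 and 0.65 at σ_ES = 0.3, and the realized tip
   correlations reproduce the tight / absent trait–centroid
   relationships expected in the strong- and weak-process regimes.
   Tip values are standardized to z-scores after simulation (root state
   at the origin; standardization is monotone, so ranks are preserved).

4. **Abundances.** Global relative abundances are drawn from a
   lognormal SAD (meanlog 0, sdlog 1 — the shape is not pinned down by
   any constraint we reproduce, so the standard-lognormal default is
   exposed in config) and assigned to species by a uniform random
   permutation, leaving no phylogenetic or trait signal in abundance.

5. **Assembly.** Each site draws `J = 10,000` individuals with
   replacement (one multinomial draw per site): incidence probability
   ∝ `F_i · exp(−Δspace²/2d) · exp(−Δenv²/2n)` with Euclidean
   distances over all axes. Weights are computed in log space with the
   per-site maximum subtracted before exponentiation — at `n = 10^-4`
   the raw Gaussian weights underflow (exp of order −5000), and the
   log-space path preserves the extreme-strength regime instead of
   producing all-zero probability vectors. Fixed-`J` assembly is the
   default (equal resource supply across sites); a fixed-richness
   sampler is available but not used by the pipeline.

6. **β-diversity and partitioning.** Eight metrics are computed for
   all site pairs: Bray–Curtis and taxonomic Sørensen; phylogenetic
   PW, NN and branch-length SOR on the cophenetic/branch structure of
   the phylogeny; functional PW, NN and SOR on a UPGMA dendrogram of
   Euclidean trait distances. Variance in each metric is partitioned
   against the pairwise spatial and environmental distance vectors
   into space-only, environment-only, shared and residual fractions
   using unadjusted R² from three least-squares fits (space, env,
   both); turnover rates are the partial slopes of the joint fit, with
   bounded metrics regressed in similarity orientation. The unique
   fractions and the residual are non-negative by construction; the
   shared fraction can be negative (suppression). Fractions sum to 1.

## Design choices where the design was open

- **Functional PW/NN distances.** Both direct Euclidean trait
  distances and dendrogram cophenetic distances are supported; the
  pipeline default is the dendrogram. At the extreme corner
  (`n = d = 10^-4`) direct trait distances make the environment-only
  fraction of functional PW essentially deterministic (0.47–0.74
  across replicate sets, because with one dominant species per site
  the between-site trait distance nearly equals the environmental
  distance), whereas the dendrogram's step-function distances flatten
  fine trait structure and yield the moderate values (~0.1–0.4) that
  characterize the reference behaviour of this metric. Set
  `functional_distance="traits"` to switch.
- **Saturated responses.** At extreme process strengths many replicate
  sets show complete turnover at every site pair; the β matrix is then
  constant and the partition undefined. Such replicates raise a
  documented error, are excluded from cell means, and are counted
  (surfaces record per-cell completed counts). A spread below
  `1e-9 · max(1, |y|max)` is treated as zero variance: R² on rounding
  noise is meaningless.
- **Quadrant consistency.** A replicate is "consistent" when the
  dominant unique variance fraction identifies the dominant process
  (`d/n` and `space_only/env_only` on opposite sides of 1). Cells on
  the `d = n` diagonal are excluded by default (no quadrant applies);
  replicates with undefined component ratios are excluded from the
  denominator by default and reported, or kept as not-consistent with
  `denominator="all"` — a saturated replicate is itself a case where
  the intuitive expectation fails, and the summary percentages quoted
  for this framework are computed that way.
- **Matching bands for inference.** A region of plausible process
  strengths is the set of lattice points where the interpolated
  expectation lies within a band of the empirical value. The default
  band is `max(0.25·|v|, 0.01, 2.576·sd)`, where `sd` is the
  interpolated per-cell replicate standard deviation: an empirical
  value is a single realization, so cells whose replicate scatter
  could plausibly have produced it must match. The 2.576 multiplier
  (two-sided 99%) keeps joint coverage near 94% when six constraints
  (three metrics × two unique fractions) are intersected; with a
  25%-of-value band alone, the intersection is routinely empty because
  realization scatter dwarfs the band near the corners. An explicit
  tolerance is used verbatim.
- **Landscapes per replicate.** Each replicate draws a fresh
  landscape, so surfaces marginalize over site configurations; a fixed
  landscape is available in config.
- **Seeds.** Every replicate's generator derives from the master seed
  keyed by `(cell index, replicate index)` via `SeedSequence` spawn
  keys, so any single replicate reproduces in isolation and grid runs
  are byte-identical under a fixed config + seed.

## Problem sizes used by the shipped checks

The packaged end-to-end checks run the standard scenario (20 sites,
σ_ES 0.7, 500 species, J = 10,000) with reduced replication relative
to the 100-replicate reference surfaces: the 11×11 consistency grid
uses 10 replicates per cell (binomial SE ≈ 1.2 points per metric at
1,100 classifications), corner fractions average 20 replicate sets,
and parameter recovery uses a 6×6 grid at 20 replicates per cell.
These sizes were chosen so the estimates' sampling error is small
against the tolerances being checked.

## What the synthetic data are, and are not

The generator produces communities whose only structuring processes
are abundance sampling, Gaussian dispersal around evolved range
centroids, and Gaussian filtering on evolved optima. Real data add, at
least: competition and other biotic interactions, species-varying
niche and dispersal breadths, non-Gaussian kernels, range shapes
richer than a centroid, unmeasured environmental axes, and sampling
error in the community table itself. Passing checks therefore show
that the *inference machinery* recovers known process strengths when
the world matches the model's assumptions — the best-case test — not
that those assumptions hold for any empirical system. The
environment-space covariance is exact by construction here; empirical
σ_ES is estimated and noisy, which weakens partitioning in ways these
simulations do not exhibit.

## Known limitations

- Only the centroid of a range is modelled; dispersal from range edges
  is out of scope.
- One niche breadth and one dispersal breadth are shared by all
  species; the framework estimates an average process strength.
- Inference compares magnitudes of variance fractions; no permutation
  tests or p-values are computed, by design.
- Bilinear interpolation on the log-process plane is intentionally
  simple; surfaces with sharp ridges between grid nodes will be
  smoothed through, so coarse grids should be read as coarse.
- The quadrant-consistency percentage depends visibly on how saturated
  replicates enter the denominator (see above); both conventions are
  reported by the tools.
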