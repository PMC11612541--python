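# Methods

`stressbiomes` maps assemblage-level abiotic stress tolerance strategies of
woody plants from species tolerance coordinates and environmental
descriptors to **stress tolerance biomes** (STBs) and **polytolerance
hotspots**. This note documents the model, the synthetic world the tests
run against, the numerical choices, and the limitations.

## The tolerance space and the analysis chain

Species-level multi-stress tolerance is summarised by two coordinates in a
triangular *stress tolerance space* (STS): axis 1 is a trade-off between
drought tolerance and waterlogging/cold tolerance; axis 2 is a shade
tolerance spectrum. The triangle's vertices are occupied by specialists
(drought at (1, −0.5), shade at (0, 1), waterlogging/cold at (−1, −0.5) by
default); its edges by species tolerating two stressors at once
(polytolerance); its interior by low-intermediate generalists.

The pipeline runs the following stages per plant functional type (PFT:
deciduous angiosperms, evergreen angiosperms, evergreen gymnosperms):

1. **Aggregation.** Occurrence points are cleaned (non-finite coordinates,
   out-of-range longitude/latitude, exact duplicates, points at (0, 0)) and
   binned into congruent flat-top hexagons of fixed area *A* (default
   7500 km²; circumradius R = √(2A/(3√3))). The assemblage of a (hexagon,
   PFT) is its set of distinct species; assemblage values are unweighted
   presence-based means of the species' axis coordinates and log10 traits
   (PH, SSD, SM, LA, LN, SLA). Assemblages with fewer than `min_species`
   (default 3) species are dropped. Points on shared cell boundaries go to
   the smaller hexagon id, making the binning a deterministic partition.
2. **Dimension reduction.** Each variable block — 22 climate variables,
   8 soil variables, 6 log10 traits — is standardised and reduced by
   correlation-matrix PCA. The number of retained components per block is
   chosen by Horn's parallel analysis (observed eigenvalue > mean eigenvalue
   of size-matched standard-normal matrices, evaluated sequentially;
   `paran_iter` default 1000). Retained components are varimax-rotated with
   Kaiser row-normalisation; rotated scores are the regression scores
   Z·L(LᵀL)⁻¹. Component signs are fixed so each column's largest-|loading|
   entry is positive. A cross-block Pearson report warns when any two
   retained components (or elevation/TRI/TWI) correlate above 0.54.
3. **Forest models.** Six random-forest regressions ({axis 1, axis 2} ×
   3 PFTs) predict the assemblage axis means from the retained components
   plus elevation, terrain roughness (TRI) and topographic wetness (TWI).
   Defaults: 500 trees, mtry = ⌊p/3⌋, minimum node size 5, bootstrap on,
   fixed seed. Variable importance is the mean RMSE increase over `n_perm`
   (default 500) column permutations, reported with its full distribution;
   marginal effects come from partial dependence on an equispaced grid over
   the 1st–99th percentile range; prediction uncertainty is the
   between-tree standard deviation. Geographic coordinates are *not*
   predictors; instead, spatially blocked cross-validation (k-means blocks
   on hexagon centers, default 5 folds) produces out-of-fold residuals that
   are regressed on x and y — a significant slope flags spatial structure
   the forest missed. The blocked-k-means construction is this package's
   choice of spatial fold design.
4. **Fuzzy biomes.** The per-hexagon predicted axis pairs are clustered by
   fuzzy c-means (Euclidean; fuzziness m = 2; membership
   u_ik = 1/Σ_j (d_ik/d_ij)^{2/(m−1)}; a point coinciding with a centroid
   gets full membership there). The number of clusters is selected over
   K ∈ 2..8 by the fuzzy silhouette index — crisp silhouettes weighted by
   (u_p − u_q)^α with α = 1 — using the best-objective partition of 99
   random restarts per K; degenerate restarts (an empty hard cluster) are
   discarded. With K = 4, each triangle vertex claims its nearest centroid
   (the three claims must be distinct, otherwise labelling aborts); the
   leftover cluster is *low-intermediate*. Its membership column is removed
   and rows renormalised, giving ternary memberships to drought / shade /
   waterlogging-cold; the hard STB label is the row argmax (ties broken
   drought < shade < waterlogging/cold).
5. **Polytolerance and hotspots.** A hexagon is polytolerant when its two
   largest ternary memberships both lie in the closed split band
   [0.4, 0.6]; the pair identifies the class (shade–drought or
   shade–waterlogging/cold; a drought–waterlogging/cold split is flagged
   `excluded_pair` and reported but not mapped). The reading of "split
   membership" as *both top-two memberships inside the band, endpoints
   inclusive* is this package's documented operationalisation. Polytolerant
   hexagon centers are turned into a continuous surface by a
   compact-support triweight kernel K(u) = (1−u²)³ (u ≤ 1) with fixed
   radius 711,000 planar units (≈10,000 km²), evaluated at hexagon centers
   and normalised to a maximum of 1; the (35/32) kernel constant is omitted
   because normalisation cancels it. The normalised surface is banded into
   0.2–0.4 / 0.4–0.6 / 0.6–0.8 / 0.8–1 (half-open, last closed) as relative
   probability of finding polytolerant assemblages.
6. **Characterisation.** Each STB and polytolerance class is summarised by
   the mean/sd/5–95th percentiles of the retained components and topography
   inside it, and by its cumulative percentage overlap with a categorical
   vegetation layer (potential natural vegetation classes), computed from
   per-hexagon modal classes — equal cell areas make cell-count fractions
   area fractions. Sub-cell area weighting is out of scope; callers supply
   one class per hexagon.

## The synthetic world

Real inputs (occurrence archives, climate and soil rasters) are replaced
by a generator that reproduces the statistical structure the analysis
assumes, so every stage is testable offline.

* **Species.** Pools of 547 / 134 / 106 species for the three PFTs.
  Coordinates are drawn from a four-component Gaussian mixture — the three
  vertices plus the triangle centroid, equal weights, dispersion
  `group_dispersion` — and rejected to the triangle (cap 10,000 rounds).
  Each trait is exp(log-mean + loading·axes + N(0, 0.25)), so traits are
  strictly positive and log-trait–axis correlations carry the configured
  signs (stature traits rise toward drought and shade tolerance; the leaf
  economics pair SLA/LN falls along the shade axis).
* **Landscape.** A hexagon lattice over a 2600 × 2800 km planar rectangle
  (~1100 cells of 7500 km²). Two latent gradients run linearly across it
  (g1 west–east spanning −1.3..1.3, g2 south–north spanning −0.8..1.3, in
  STS units). Every environmental variable is loading·(g1, g2, nuisance
  factors) + N(0, 0.25): climate bundles load mainly on g2 plus two
  climate-only nuisance factors, soil bundles on g1 plus one soil-only
  factor, so parallel analysis retains about 3 climate, 2 soil and 2 trait
  components without inflating cross-block correlations. A categorical
  vegetation layer thresholds g1 (wet_boreal / temperate / xeric), and each
  cell records the planted strategy group whose center is nearest its
  latent position (`true_group`, the recovery ground truth).
* **Occurrences.** Each species' count in each cell is Poisson with
  intensity 3·exp(−d²/(2·0.22²)) where d is the distance between the cell's
  latent environment and the species' own STS coordinates — a Gaussian
  suitability kernel that sorts assemblages along the gradients. Points are
  jittered uniformly within their hexagon. All generators are deterministic
  in (config, seed).

**Default dispersion.** At the default `group_dispersion = 0.10` the four
planted groups are well separated: the fuzzy silhouette selects K = 4 and
the recovered hard labels match the planted groups with adjusted Rand
index ≈ 0.81–0.87 end to end. Split-membership (polytolerant) assemblages
are then essentially absent — consistent with polytolerance being rare —
so polytolerance and hotspot behaviour is additionally exercised under a
looser *edge-mass* scenario (`group_dispersion = 0.2`), which spreads
vertex-group mass along the triangle edges and yields polytolerant shares
at the sub-percent to percent level.

**What the generator does not emulate:** phylogenetic structure, spatial
autocorrelation of sampling effort, abundance structure (occurrence counts
are suitability-driven only), raw tolerance scores behind the STS
coordinates, and geodesy (coordinates are abstract equal-area planar
meters). Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted structure, not performance on real archives.

## Numerical choices

* Fuzzy c-means stops when max |ΔU| < 1e−5 (or 300 iterations); the
  objective is non-increasing and asserted so in debug mode. Restart seeds
  are spawned from one master seed.
* Varimax iterates the SVD-based update until the criterion improves by
  < 1e−8 relative; communalities are preserved to 1e−10.
* Parallel analysis uses the mean of the random eigenvalues (no upper
  centile), the convention of the common retention tools.
* Hexagon edge ties go to the smaller id (tolerance 1e−6 on tied
  distances); KD-tree nearest-center lookup is exact for hexagon lattices
  because the lattice Voronoi diagram is the hexagons themselves.
* Ternary renormalisation cannot divide by zero for m > 1 memberships
  (every row keeps positive mass on all clusters); this is asserted, not
  handled.
* One master seed deterministically spawns per-stage seeds, so stages are
  independently reproducible; reruns with the same config produce
  byte-identical CSVs.

## Problem sizes used in the checked runs

The test suite and the acceptance script run the full default world
(~1100 cells, 787 species, ~650–780 assemblages per PFT) with model
settings scaled for a single CPU: 120 trees, 10 permutation repeats, 30
clustering restarts in the end-to-end run; 99 restarts and 12–15 selection
seeds in the K-recovery measurement; 20 seeds in the planted-driver and
planted-trend recovery rates. Library defaults (500 trees, 500
permutations, 99 restarts) are unchanged.

## Known limitations

* Occurrence cleaning covers coordinate validity and exact duplicates
  only; environmental-space and geographic thinning filters used on real
  archives are out of scope and must be applied upstream.
* The spatial-CV fold construction (blocked k-means) and the
  per-hexagon KDE evaluation are documented package choices where several
  reasonable designs exist.
* With K ≠ 4 selected, ternary labelling is undefined and the pipeline
  reports memberships only; real-data runs should inspect the silhouette
  profile before forcing K = 4.
* Percentage overlaps use modal classes per hexagon, not sub-cell area
  fractions.
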