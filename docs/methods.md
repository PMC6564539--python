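# Methods

## The analysis model

`covnet` implements a group-level structural covariance network analysis.
For each group of subjects, the value of a morphometric measure at each of
R cortical ROIs is residualized by ordinary least squares on an intercept,
age, sex, age×sex, and the subject's *global measure* (the mean across ROI
columns — mean cortical thickness, or total gyrification up to a constant
absorbed by the regression coefficient).  The ROI × ROI Pearson correlation
matrix of these residuals defines the covariance network.  An edge is
*eligible* iff its correlation is positive and significant two-sided at
level α, using t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom; negative
correlations are excluded on the usual grounds that they do not reflect
direct anatomical coupling.  At each density d of a grid, the
m = round(d·R(R−1)/2) strongest eligible edges (round half away from zero;
ties in r broken lexicographically by ROI index, making thresholding
deterministic) form an unweighted undirected graph.  Edge sets are nested
across densities by construction.

Graph metrics follow the standard unweighted formulas: mean nodal
clustering coefficient (degree < 2 contributes 0), transitivity
(3·triangles / connected triples), local efficiency (mean over nodes of the
global efficiency of the neighborhood subgraph; degree < 2 contributes 0),
global efficiency (mean inverse geodesic distance; unreachable pairs
contribute 0), characteristic path length (mean geodesic distance; defined
only on connected graphs), unnormalized Brandes betweenness, Louvain
modularity with max-Q selection over seeded restarts, hubs at
≥ mean + k·SD (sample SD; k = 2 by default; a constant statistic yields no
hubs), and small-worldness σ = γ/λ with γ and λ the clustering and
path-length ratios against the mean of 20 degree-preserving
double-edge-swap null graphs (10 swaps per edge).

Groups are compared by the Functional Data Analysis (FDA) summary: each
metric's curve over the shared density grid is integrated by the
trapezoidal rule, and the observed area difference for a group pair is
referred to a permutation null in which subject-to-group labels are
reshuffled (group sizes preserved) and all group networks are rebuilt on
the same grid.  The two-sided p-value is (1 + #{|null| ≥ |observed|}) /
(1 + n_perm), so p is never zero and ties count as extreme.  Regional
(per-ROI) tests of FDA-integrated degree or betweenness are corrected by
Benjamini–Hochberg FDR within each group pair's family of R tests.

Cognitive subtyping precedes the network stage: six test scores are
residualized on age and education (the IDED error count is first
transformed to −log10(errors + 1) so that, like the other tests, higher is
better and its right skew is tamed), z-scored per test, and partitioned by
Euclidean k-means (k = 3 by default, 50 k-means++ restarts, fixed seed).
Clusters are renumbered by descending mean profile so labels are stable.
Subjects missing a single test are imputed with the age/education
regression prediction, which places them at the residual-space column mean
(neutral for clustering); more than one missing test violates the inclusion
rule and is rejected.

## Fragmentation and the path-length convention

Comparing groups at matched density requires one fixed grid for observed
and permuted cohorts alike.  At the sparse end of the grid an occasional
graph — more often a relabeled (permuted) cohort — fragments.  Dropping
such permutations would bias the null and, at thresholds near the
connectivity transition, discard most of it.  `covnet` therefore keeps
every permutation and makes every curve metric well defined on fragmented
graphs: clustering, transitivity and the efficiencies are naturally
defined, and the path-length curve uses the *penalized* convention, in
which an unreachable pair contributes distance n (one more than the longest
possible path).  On connected graphs this equals the characteristic path
length exactly; on fragmented graphs it grows, treating fragmentation as
the extreme of poor integration — consistent in direction with global
efficiency.  Observed and permuted cohorts receive identical treatment, so
the permutation test is exact under exchangeability; the number of
fragmented graphs encountered is reported as a diagnostic
(`n_fragmented`).  The strict `characteristic_path_length` (which refuses
fragmented input) remains the descriptive statistic at the minimum density,
where connectivity is guaranteed by construction.

The minimum density search itself scans a density grid from a floor
(default 0.01) upward and returns the smallest value at which every
group's graph is a single connected component (union-find on the
thresholded adjacency); if no density ≤ 0.5 works — densities above 50%
are not biologically meaningful for structural networks — it fails with
per-group component counts.  The default *comparison* grid, however, is a
fixed a-priori band (0.05–0.095 in steps of 0.005, ten densities) rather
than a d_min-anchored one: a grid anchored at the exact connectivity
threshold of the observed cohort is maximally unstable under relabeling,
whereas a fixed sparse band keeps the density sweep informative and the
test exact.  Both behaviours are available (`grid_start: null` anchors at
d_min); descriptive outputs (modules, hubs, σ) are always computed at
d_min when it exists.

## The synthetic cohort generator

The generator emulates the statistical structure this pipeline assumes, at
parameters chosen to resemble a mid-sized clinical morphometry cohort:
three groups of 60 subjects, 148 ROIs by default (60 in the simulation
studies, for tractability), cortical thickness baseline 2.5 mm with
residual SD 0.15 mm, age uniform on [25, 60] years with −0.005 mm/yr
thinning, sex Bernoulli(0.8) with a +0.05 mm offset.  Ages, sexes and ROI
values are drawn from numpy's PCG64 via `SeedSequence(seed)` with
deterministically spawned child streams, so equal seeds give bit-identical
cohorts across runs and platforms.

Each group's target correlation matrix is an explicit factor model —
positive definite by construction because every component is a factor
loading and each node's idiosyncratic variance stays positive (total
structured variance is capped at 0.95 per node):

* **block factors**: ROIs are split into `n_blocks` (default 4) planted
  modules; within-block correlation `within_block_r` (default 0.45),
  nominal between-block level `between_block_r` (default 0.1);
* **homotopic pairs**: consecutive same-block ROIs are coupled toward 0.7,
  emulating the dominant bilateral correlations of real morphometry;
* **bridge factors**: a few strong (0.5) inter-block pairs per block pair,
  anchored at the nodes with the lowest global loading, whose block
  loading is discounted (×0.8) — connector regions;
* a **global factor** with heterogeneous loadings √(between_r)·(1+hᵢ),
  hᵢ uniform on ±0.8 and mean-centered;
* **secondary signed modes** (3 modes of variance 0.1 with ±1 loadings)
  that add broad positive and negative correlation tails.

The heterogeneity is not decoration: regressing each ROI on the global
mean removes the rank-one component s·sᵀ/S of the covariance, which
*exactly* cancels any uniform between-block correlation (a constant
between-block level is a global factor).  Real covariance networks remain
connected after global-signal removal because regions load heterogeneously
on the global mode and because specific strong inter-regional couplings
(homotopy, inter-lobe bridges) survive the regression.  The generator
plants those same features; without them, density thresholding of
residual correlations can never produce a connected graph, and the
minimum-density search correctly rejects.  A consequence worth knowing:
the realized mean within-block correlation is somewhat below the nominal
`within_block_r` (anchors are discounted and budgets capped), and the
post-residualization correlations are lower still, by roughly the mean
off-diagonal correlation.

`plant_topology_contrast` raises one group's `within_block_r` by a chosen
delta (default studies use +0.25), producing the segregation-up /
integration-down signature — higher clustering, transitivity and path
length, lower global efficiency — that the comparison stage must detect.
Cognitive scores come from planted K × 6 centroids in z units mapped onto
test-native scales (the IDED column as a right-skewed error count
⌊exp(2 − 0.8z)⌋), with linear age and education effects and Gaussian
within-cluster noise (SD 0.5 z).

What the generator does **not** emulate: cortical surfaces or vertex data,
scanner or segmentation noise, site effects, non-Gaussian morphometry
marginals, spatial autocorrelation of neighbouring ROIs, or any attempt to
match a specific cohort's effect sizes.  Passing tests therefore show that
the pipeline's statistics behave correctly under a known generative law of
the assumed form — not that a particular clinical result would replicate.

## Simulation studies and their sizes

The validation suite (`tests/test_acceptance.py`) runs, at sizes chosen to
keep a full run within minutes on one CPU:

* **metric oracles** — all metrics against exhaustive enumeration
  (triangles/triples, hand-rolled BFS, shortest-path enumeration) on 200
  random graphs of ≤ 12 nodes, at 1e-10;
* **type-I calibration** — 100 no-contrast replicates (3 × 60 subjects ×
  60 ROIs, ten densities, 200 permutations): the rejection count at
  α = .05 must fall in the central 95% interval of Binomial(100, 0.05),
  i.e. 1–10.  A permutation test is exact under exchangeability for any
  statistic on any fixed grid, so this checks the engine, not the grid;
* **directional power** — 20 replicates with delta 0.25 planted in one
  group: the four-metric signature must be significant in the right
  direction against both other groups in ≥ 80% of replicates;
* **cluster recovery** — centroids 1.5 z apart (3 within-cluster SD) must
  be recovered with ARI ≥ 0.9 over 20 seeds;
* **small-world sanity** — a Watts–Strogatz ring (n = 100, k = 6,
  p = 0.1) gives σ > 1 and an Erdős–Rényi graph (n = 100, p = 0.1) gives
  σ ∈ [0.8, 1.2], each against 20 degree-preserving nulls;
* **determinism** — two full pipeline runs from one config are
  byte-identical.

## Numerical and design choices

* OLS residuals use the pseudoinverse (`lstsq`), so redundant design
  columns (e.g. a single-sex group) are harmless; a design with no
  covariate variation is rejected.
* Constant ROI columns get correlation 0 with a warning and can never form
  eligible edges.
* If fewer eligible edges exist than a density requests, all are kept and
  the achieved density is reported in a warning.
* Louvain uses 20 seeded restarts with max-Q selection; module ids are
  renumbered by descending module size for determinism.  Betweenness is
  unnormalized (pair-fraction sums), matching the magnitudes conventional
  in 148-node covariance studies.
* The IDED log transform uses base 10 with offset +1 (error counts can be
  0).  Residuals are z-scored per test before k-means because the tests
  live on incommensurate scales.
* The permutation unit is the subject: reshuffling subject-to-group labels
  with preserved group sizes is the only reading under which "preserving
  the original sample sizes" is meaningful, and it is the standard scheme
  for covariance-network group comparisons.
* Every pipeline output is delimited text with fixed numeric formatting;
  the JSON manifest records the grid, seeds, permutation and fragmentation
  counts, and a hash of the configuration (excluding the output path), so
  rerunning a config is byte-identical.

## Known limitations

* With ~60 subjects per group the significance threshold for a single
  correlation is r ≈ 0.25, so eligible-edge supply is limited and the
  informative density band is sparse (hence the 0.05–0.095 default grid).
  Larger cohorts widen the band toward the 0.07–0.46 sweeps used in the
  literature.
* Regional permutation testing recomputes betweenness for every ROI,
  density and permutation; it is disabled by default
  (`n_perm_regional: 0`) and intended for moderate settings.
* The spherical ROI layout in the BrainNet export is a deterministic
  placeholder; supply an atlas centroid table for anatomically meaningful
  plots.
* Module composition across groups is matched by maximum Jaccard overlap
  and described, not statistically compared.
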