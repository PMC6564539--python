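# covnet

Group-level **structural covariance network** analysis of regional brain
morphometry, with cognitive subtyping and a fully synthetic validation
cohort.

Structural covariance networks treat the correlation of a morphometric
measure (cortical thickness in mm, or the local gyrification index) across
subjects as a proxy for shared anatomical organisation: two regions whose
thickness co-varies across a cohort are taken to be "connected".  Given a
subjects × ROIs morphometry table, covariates, and a cognitive test
battery, `covnet`:

1. **subtypes** subjects by k-means on age/education-residualized cognitive
   scores (six tests; the IDED error count is log-transformed and
   sign-flipped first), labelling clusters by descending mean profile;
2. **builds one network per group**: each ROI is residualized on age, sex,
   age×sex and the subject's global measure; residuals are correlated
   (ROI × ROI Pearson *r*); edges that are positive and significant at
   *p* < .05 are *eligible*; density thresholding keeps the *m* =
   round(d·R(R−1)/2) strongest eligible edges at each density *d* of a
   grid, with the minimum density defined as the smallest value at which
   every group's graph is one connected component;
3. **measures** each binary graph: clustering coefficient *C*, transitivity
   *T*, local and global efficiency *E*<sub>loc</sub>, *E*<sub>glob</sub>,
   characteristic path length *L*, Louvain modularity *Q* (max-*Q* over
   seeded restarts), betweenness and degree, hubs (≥ mean + 2 SD), and
   small-worldness σ = γ/λ against 20 degree-preserving (Maslov–Sneppen)
   null graphs;
4. **compares groups** by Functional Data Analysis: each metric's curve
   over the density grid is integrated (area under the curve), and the
   area difference between groups is tested against a null distribution
   obtained by permuting subject-to-group labels (group sizes preserved)
   and rebuilding all networks on the same grid; regional (per-ROI) tests
   get Benjamini–Hochberg FDR correction;
5. **exports** module membership and degree as BrainNet-Viewer `.node` /
   `.edge` text files.

Because real morphometry cohorts of this kind are not publicly deposited,
the package ships a first-class synthetic-cohort generator
(`covnet.synthetic`) whose correlation structure is known by construction —
planted ROI blocks, homotopic pairs, inter-block bridges, a heterogeneous
global factor — so every stage can be validated end to end.

## Worked example

`examples/05_group_comparison.py` plants a +0.25 within-block correlation
increase in group 2 of a three-group cohort (60 subjects/group, 60 ROIs)
and runs the FDA permutation test over densities 0.05–0.095:

```
FDA areas (group 2 carries the planted contrast):
  clustering         g0=0.0156  g1=0.0131  g2=0.0221
  transitivity       g0=0.0202  g1=0.0171  g2=0.0319
  path_length        g0=0.2492  g1=0.2524  g2=2.1867
  global_efficiency  g0=0.0143  g1=0.0149  g2=0.0054

comparisons involving the contrast group:
  clustering         g0 vs g2: diff=-0.0065  p=0.015 *
  transitivity       g0 vs g2: diff=-0.0116  p=0.005 *
  path_length        g0 vs g2: diff=-1.9375  p=0.005 *
  global_efficiency  g0 vs g2: diff=+0.0088  p=0.005 *
```

Negative differences for clustering/transitivity/path length mean the
contrast group is **higher**; the positive difference for global efficiency
means it is **lower** — the classic "more segregated, less integrated"
signature that a uniform strengthening of within-module covariance
produces.  *p* = 0.005 is the permutation floor, (1+0)/(1+200).

Each script in `examples/` is a short narrative of one capability
(simulation, cognitive profiles, network construction, metric panel, group
comparison, full pipeline + BrainNet export).  A thin CLI mirrors the
stages:

```bash
covnet simulate --out cohort/ --seed 1
covnet cluster --cognitive cohort/cognitive.tsv --out clusters/
covnet run-all --out run/ --seed 1
```

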