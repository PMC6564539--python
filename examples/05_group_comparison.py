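"""Compare groups on FDA-integrated metric curves with a permutation test.

One group gets a planted increase of +0.25 in within-block correlation.
Metric curves are built over a shared density grid, summarized by area
under the curve (FDA), and tested against a null of subject-label
permutations.  The planted group should show higher clustering,
transitivity and path length, and lower global efficiency.
"""

import numpy as np

from covnet import (
    CohortSpec,
    compare_global_metrics,
    generate_morphometry,
    plant_topology_contrast,
)

spec = plant_topology_contrast(
    CohortSpec(group_sizes=(60, 60, 60), n_rois=60, seed=9),
    delta_within_r=0.25, target_group=2,
)
cohort = generate_morphometry(spec)

grid = np.round(0.05 + 0.005 * np.arange(10), 10)
comp = compare_global_metrics(
    cohort.morphometry, cohort.covariates, cohort.group_labels, grid,
    metric_names=["clustering", "transitivity", "path_length", "global_efficiency"],
    n_perm=200, seed=1,
)

print(f"grid: {grid[0]:.3f}-{grid[-1]:.3f}, {comp.n_perm} permutations")
print("\nFDA areas (group 2 carries the planted contrast):")
for metric in ("clustering", "transitivity", "path_length", "global_efficiency"):
    areas = "  ".join(f"g{g}={comp.fda[g][metric]:.4f}" for g in (0, 1, 2))
    print(f"  {metric:18s} {areas}")
print("\ncomparisons involving the contrast group:")
r = comp.results
for _, row in r[(r.group_b == 2)].iterrows():
    tag = "*" if row.p_value < 0.05 else " "
    print(f"  {row.metric:18s} g{row.group_a} vs g2: "
          f"diff={row.fda_diff:+.4f}  p={row.p_value:.3f} {tag}")
# Negative diffs for clustering/transitivity/path length mean group 2 is
# higher; a positive diff for global efficiency means group 2 is lower —
# the segregation-up / integration-down signature of the planted contrast.
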