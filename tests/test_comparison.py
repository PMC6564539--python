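"""FDA comparison tests: integration, p-values, FDR, hubs, modules."""

import numpy as np
import pandas as pd
import pytest

from covnet import comparison as comp
from covnet.synthetic import CohortSpec, generate_morphometry


class TestFdaIntegrate:
    def test_rectangle(self):
        d = np.array([0.07, 0.46])
        assert comp.fda_integrate(d, np.array([2.0, 2.0])) == pytest.approx(0.78)

    def test_triangle(self):
        # linear ramp 0 -> 1 over [0, 0.5] has area 0.25
        d = np.array([0.0, 0.5])
        assert comp.fda_integrate(d, np.array([0.0, 1.0])) == pytest.approx(0.25)
        d = np.linspace(0, 0.5, 11)
        assert comp.fda_integrate(d, 2 * d) == pytest.approx(0.25)

    def test_refinement_oracle(self):
        rng = np.random.default_rng(0)
        d = np.sort(rng.uniform(0.05, 0.5, 5))
        v = rng.normal(size=5)
        # piecewise-linear curve: fine Riemann sum over the interpolant
        fine = np.linspace(d[0], d[-1], 200001)
        riemann = np.trapezoid(np.interp(fine, d, v), fine)
        assert comp.fda_integrate(d, v) == pytest.approx(riemann, abs=1e-6)

    def test_bad_grids_rejected(self):
        with pytest.raises(ValueError):
            comp.fda_integrate(np.array([0.1]), np.array([1.0]))
        with pytest.raises(ValueError):
            comp.fda_integrate(np.array([0.2, 0.1]), np.array([1.0, 1.0]))


class TestPercentilePvalue:
    def test_zero_observed_symmetric_null(self):
        null = np.concatenate([np.linspace(-1, 1, 100)])
        assert comp.percentile_pvalue(0.0, null) >= 0.5

    def test_extreme_observed_999_nulls(self):
        null = np.random.default_rng(0).normal(size=999)
        obs = np.abs(null).max() + 1.0
        assert comp.percentile_pvalue(obs, null) == pytest.approx(1 / 1000)

    def test_tie_counts_as_extreme(self):
        null = np.array([1.0, 2.0, 3.0])
        assert comp.percentile_pvalue(3.0, null) == pytest.approx(2 / 4)

    def test_never_zero(self):
        assert comp.percentile_pvalue(1e9, np.zeros(50)) > 0


class TestFdrCorrect:
    def test_bh_thresholds(self):
        p = np.array([0.001, 0.02, 0.03, 0.5])
        assert comp.fdr_correct(p, q=0.05).tolist() == [True, True, True, False]

    def test_all_ones_empty(self):
        assert not comp.fdr_correct(np.ones(10)).any()

    def test_single_p_reduces_to_alpha(self):
        assert comp.fdr_correct(np.array([0.04])).tolist() == [True]
        assert comp.fdr_correct(np.array([0.06])).tolist() == [False]


class TestFdaHubs:
    def test_identical_curves_no_hubs(self):
        node_fda = {0: np.full(20, 3.3)}
        assert comp.fda_hubs(node_fda, [f"r{i}" for i in range(20)]) == {0: []}

    def test_dominating_node_flagged(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(10, 1, 30)
        vals[7] = vals.mean() + 6 * vals.std()
        names = [f"r{i}" for i in range(30)]
        hubs = comp.fda_hubs({0: vals}, names)
        assert "r7" in hubs[0]

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 5, 25)
        vals[3] = 40
        names = [f"r{i}" for i in range(25)]
        assert comp.fda_hubs({0: vals}, names) == comp.fda_hubs({0: vals * 9.1}, names)


class TestModuleReport:
    def test_pure_lobe_module(self):
        names = ["a", "b", "c", "d"]
        lobes = {"a": "occipital", "b": "occipital", "c": "frontal", "d": "frontal"}
        report = comp.module_report({0: np.array([0, 0, 1, 1])}, names, lobes)
        occ = report[report.module == 0].iloc[0]
        assert occ.pct_occipital == 100.0 and occ.pct_frontal == 0.0

    def test_identical_partitions_full_jaccard(self):
        names = [f"r{i}" for i in range(9)]
        lobes = {n: "frontal" for n in names}
        part = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        report = comp.module_report({0: part, 1: part.copy()}, names, lobes)
        assert (report[report.group == 1].jaccard == 1.0).all()

    def test_missing_lobe_rejected(self):
        with pytest.raises(ValueError, match="lobe"):
            comp.module_report({0: np.array([0, 0])}, ["x", "y"], {"x": "frontal"})

    def test_planted_blocks_recovered(self):
        from covnet.metrics import modularity_louvain
        from covnet.network import build_group_stack, residualize_rois

        spec = CohortSpec(group_sizes=(150,), n_rois=24, n_blocks=2,
                          within_block_r=0.6, between_block_r=0.05,
                          bridges_per_block_pair=1, homotopic_r=0.0, seed=6)
        cohort = generate_morphometry(spec)
        res = residualize_rois(cohort.morphometry, cohort.covariates)
        stack = build_group_stack(res, np.array([0.35, 0.4]))
        _, labels = modularity_louvain(stack.adjacency[1], seed=0)
        part = cohort.block_partition
        # best Jaccard match of each planted block against detected modules
        for blk in np.unique(part):
            planted = set(np.flatnonzero(part == blk))
            jac = max(
                len(planted & set(np.flatnonzero(labels == m)))
                / len(planted | set(np.flatnonzero(labels == m)))
                for m in np.unique(labels)
            )
            assert jac >= 0.8


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(group_sizes=(14, 14), n_rois=16, n_blocks=2, seed=30)
    return generate_morphometry(spec)


class TestPermutationEngine:
    def test_deterministic_given_seed(self, small_cohort):
        grid = np.array([0.15, 0.2, 0.25])
        kw = dict(n_perm=4, seed=5, metric_names=["clustering"])
        a = comp.compare_global_metrics(
            small_cohort.morphometry, small_cohort.covariates,
            small_cohort.group_labels, grid, **kw)
        b = comp.compare_global_metrics(
            small_cohort.morphometry, small_cohort.covariates,
            small_cohort.group_labels, grid, **kw)
        assert a.results.equals(b.results)

    def test_group_relabeling_invariance(self, small_cohort):
        grid = np.array([0.15, 0.2, 0.25])
        labels = small_cohort.group_labels
        a = comp.compare_global_metrics(
            small_cohort.morphometry, small_cohort.covariates, labels, grid,
            n_perm=50, seed=2, metric_names=["clustering"])
        swapped = 1 - labels
        b = comp.compare_global_metrics(
            small_cohort.morphometry, small_cohort.covariates, swapped, grid,
            n_perm=50, seed=2, metric_names=["clustering"])
        # |area difference| and its p-value do not depend on group names
        assert abs(a.results.fda_diff.iloc[0]) == pytest.approx(
            abs(b.results.fda_diff.iloc[0]))
        assert a.results.p_value.iloc[0] == pytest.approx(b.results.p_value.iloc[0])

    def test_single_group_rejected(self, small_cohort):
        with pytest.raises(ValueError, match=">= 2 groups"):
            comp.compare_global_metrics(
                small_cohort.morphometry, small_cohort.covariates,
                np.zeros(28, dtype=int), np.array([0.1, 0.2]), n_perm=2)

    def test_regional_engine_runs_and_corrects(self, small_cohort):
        grid = np.array([0.15, 0.2])
        reg = comp.compare_regional_metric(
            small_cohort.morphometry, small_cohort.covariates,
            small_cohort.group_labels, grid, statistic="degree",
            n_perm=20, seed=1)
        assert len(reg.results) == 16          # one row per ROI per pair
        assert set(reg.results.columns) >= {"roi", "p_value", "fdr_significant"}
        assert reg.results.p_value.between(0, 1).all()
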