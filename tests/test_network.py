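"""Network-construction tests: residualization, correlation, thresholding."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from covnet import network as net
from covnet.metrics import n_components


def make_tables(n=8, r=5, seed=0):
    rng = np.random.default_rng(seed)
    morph = pd.DataFrame(
        rng.normal(2.5, 0.2, (n, r)),
        columns=[f"roi_{i}" for i in range(r)],
        index=[f"s{i}" for i in range(n)],
    )
    cov = pd.DataFrame(
        {"age": rng.uniform(25, 60, n), "sex": rng.integers(0, 2, n).astype(float)},
        index=morph.index,
    )
    return morph, cov


class TestResidualizeRois:
    def test_roi_equal_to_global_gives_zero(self):
        morph, cov = make_tables(n=10, r=1)
        res = net.residualize_rois(morph, cov)
        # single-ROI table: the ROI IS the global measure -> perfect fit
        assert np.allclose(res.to_numpy(), 0, atol=1e-10)

    def test_orthogonality_to_design(self):
        morph, cov = make_tables(n=12, r=6, seed=3)
        res = net.residualize_rois(morph, cov).to_numpy()
        age = cov["age"].to_numpy()
        sex = cov["sex"].to_numpy()
        glob = morph.to_numpy().mean(axis=1)
        for col in (np.ones(12), age, sex, age * sex, glob):
            assert np.allclose(res.T @ col, 0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        morph, cov = make_tables(n=6, r=3, seed=7)
        res = net.residualize_rois(morph, cov).to_numpy()
        y = morph.to_numpy()
        x = np.column_stack([
            np.ones(6), cov["age"], cov["sex"], cov["age"] * cov["sex"], y.mean(axis=1),
        ])
        beta = np.linalg.pinv(x.T @ x) @ x.T @ y
        assert np.allclose(res, y - x @ beta, atol=1e-10)

    def test_too_few_subjects_rejected(self):
        morph, cov = make_tables(n=4)
        with pytest.raises(ValueError, match=">= 5 subjects"):
            net.residualize_rois(morph, cov)

    def test_collinear_design_rejected(self):
        morph, cov = make_tables(n=8)
        cov["age"] = 40.0
        morph.loc[:, :] = 2.5  # constant global measure too
        with pytest.raises(ValueError, match="collinear"):
            net.residualize_rois(morph, cov)


class TestCorrelationMatrix:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 1))
        data = np.hstack([x, x, -x])
        corr, n = net.correlation_matrix(data)
        assert n == 10
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(5, 3))
        corr, _ = net.correlation_matrix(x)
        for i in range(3):
            for j in range(3):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_column_warned_and_zeroed(self):
        x = np.random.default_rng(1).normal(size=(8, 3))
        x[:, 1] = 4.2
        with pytest.warns(UserWarning, match="constant"):
            corr, _ = net.correlation_matrix(x)
        assert np.all(corr[1, [0, 2]] == 0)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            net.correlation_matrix(np.ones((3, 5)))


class TestEligibility:
    def test_zero_and_negative_ineligible(self):
        corr = np.array([[1.0, 0.0, -0.9], [0.0, 1.0, 0.5], [-0.9, 0.5, 1.0]])
        mask = net.edge_eligibility(corr, n_subjects=30)
        assert not mask[0, 1] and not mask[0, 2]

    def test_t_distribution_oracle(self):
        # r = 0.3 with n = 67 -> t ~ 2.5355 on 65 df, two-sided p ~ 0.0137
        r, n = 0.3, 67
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert t == pytest.approx(2.5355, abs=1e-4)
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(0.0137, abs=5e-4)
        corr = np.array([[1.0, r], [r, 1.0]])
        assert net.edge_eligibility(corr, n)[0, 1]
        # the same r is not significant at n = 20
        assert not net.edge_eligibility(corr, 20)[0, 1]

    def test_diagonal_never_eligible(self):
        corr = np.eye(4)
        assert not net.edge_eligibility(corr, 50).any()


class TestDensityThreshold:
    def test_edge_count_arithmetic(self):
        assert net.n_edges_at_density(148, 0.07) == 761
        assert net.n_edges_at_density(148, 0.46) == 5004

    def test_keeps_strongest_edges(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 8))
        corr, n = net.correlation_matrix(x)
        mask = np.ones_like(corr, bool)
        np.fill_diagonal(mask, False)
        adj = net.threshold_by_density(corr, mask, 1 / 28)  # m = 1
        iu = np.triu_indices(8, 1)
        assert adj[iu].sum() == 1
        i, j = np.argwhere(np.triu(adj, 1))[0]
        assert corr[i, j] == corr[iu].max()

    def test_tie_breaking_deterministic(self):
        corr = np.full((4, 4), 0.5)
        np.fill_diagonal(corr, 1.0)
        mask = np.ones_like(corr, bool)
        np.fill_diagonal(mask, False)
        adj = net.threshold_by_density(corr, mask, 2 / 6)
        # all r tie at 0.5: lexicographically first pairs (0,1), (0,2) win
        assert adj[0, 1] == 1 and adj[0, 2] == 1 and adj.sum() == 4

    def test_short_supply_warns(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.9
        mask = corr > 0.5
        np.fill_diagonal(mask, False)
        with pytest.warns(UserWarning, match="achieved density"):
            adj = net.threshold_by_density(corr, mask, 0.5)
        assert adj.sum() == 2

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            net.threshold_by_density(np.eye(3), np.zeros((3, 3), bool), 0.0)
        with pytest.raises(ValueError):
            net.threshold_by_density(np.eye(3), np.zeros((3, 3), bool), 0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_edge_sets(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(30, 12))
        corr, n = net.correlation_matrix(x)
        mask = net.edge_eligibility(corr, n, alpha=0.5)
        prev = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for d in (0.05, 0.1, 0.2, 0.3, 0.4):
                adj = net.threshold_by_density(corr, mask, d)
                if prev is not None:
                    assert np.all(adj >= prev)
                prev = adj


class TestMinDensity:
    def brute_force(self, corrs, masks, increment=0.01):
        for k in range(1, int(round(0.5 / increment)) + 1):
            d = round(k * increment, 10)
            ok = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for c, m in zip(corrs, masks):
                    if n_components(net.threshold_by_density(c, m, d)) != 1:
                        ok = False
                        break
            if ok:
                return d
        return None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        corrs, masks = [], []
        for _ in range(2):
            x = rng.normal(size=(25, 10)) + 0.8 * rng.normal(size=(25, 1))
            corr, n = net.correlation_matrix(x)
            corrs.append(corr)
            masks.append(net.edge_eligibility(corr, n, alpha=0.5))
        expected = self.brute_force(corrs, masks)
        if expected is None:
            with pytest.raises(ValueError):
                net.find_min_density(corrs, masks)
        else:
            assert net.find_min_density(corrs, masks) == expected

    def test_four_node_enumeration(self):
        # correlations sorted: (0,1)=.9 > (2,3)=.8 > (1,2)=.7 > rest
        corr = np.eye(4)
        pairs = {(0, 1): 0.9, (2, 3): 0.8, (1, 2): 0.7, (0, 2): 0.3, (0, 3): 0.2, (1, 3): 0.1}
        for (i, j), r in pairs.items():
            corr[i, j] = corr[j, i] = r
        mask = np.ones((4, 4), bool)
        np.fill_diagonal(mask, False)
        # spanning needs the 3 strongest edges: m = 3 -> density 3/6 = 0.5
        assert net.find_min_density([corr], [mask], floor=1 / 6, increment=1 / 6) == pytest.approx(0.5)

    def test_disconnected_by_construction_rejected(self):
        corr = np.eye(6)
        corr[0, 1] = corr[1, 0] = corr[2, 3] = corr[3, 2] = corr[4, 5] = corr[5, 4] = 0.9
        mask = corr > 0.5
        np.fill_diagonal(mask, False)
        with pytest.raises(ValueError, match="component counts"):
            net.find_min_density([corr], [mask])


class TestScaleInvariance:
    def test_affine_rescaling_of_rois(self):
        rng = np.random.default_rng(11)
        morph = pd.DataFrame(rng.normal(2.5, 0.2, (20, 6)))
        cov = pd.DataFrame({"age": rng.uniform(25, 60, 20), "sex": rng.integers(0, 2, 20)})
        # per-ROI affine rescale changes the global measure too, so compare
        # pure correlation structure after residualizing on the same design
        res1 = net.residualize_rois(morph, cov)
        corr1, _ = net.correlation_matrix(res1)
        scaled = morph * 3.7
        res2 = net.residualize_rois(scaled, cov)
        corr2, _ = net.correlation_matrix(res2)
        assert np.allclose(corr1, corr2, atol=1e-10)


def test_density_grid_bounds():
    grid = net.density_grid(0.07, 0.46, 0.01)
    assert grid[0] == 0.07 and grid[-1] == 0.46 and len(grid) == 40
    with pytest.raises(ValueError):
        net.density_grid(0.0, 0.3)
    with pytest.raises(ValueError):
        net.density_grid(0.1, 0.6)
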