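"""Tree preparation, Brownian covariance and GLS/OLS regression."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from codonfold.phylo_gls import (PhyloCovariance, brownian_covariance,
                                 gls_fit, make_ultrametric, ols_fit,
                                 prune_and_merge, range_robustness,
                                 taxon_scan)
from codonfold.synthetic_data import simulate_tree


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _tip_distance_matrix(tree: dendropy.Tree) -> dict:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [l.taxon for l in tree.leaf_node_iter()]
    out = {}
    for t1 in taxa:
        for t2 in taxa:
            out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


class TestPruneAndMerge:
    def test_keep_all_is_identity(self):
        tree = simulate_tree(10, seed=3)
        tips = {l.taxon.label for l in tree.leaf_node_iter()}
        before = _tip_distance_matrix(tree)
        pruned = prune_and_merge(tree, tips)
        after = _tip_distance_matrix(pruned)
        for key, d in after.items():
            assert d == pytest.approx(before[key])

    def test_unifurcation_merged_by_summing(self):
        pruned = prune_and_merge(_tree("((A:1,B:1):1,C:2);"), {"A", "C"})
        nw = pruned.as_string(schema="newick")
        assert "A:2.0" in nw and "C:2.0" in nw
        assert len(pruned.seed_node.child_nodes()) == 2

    def test_pairwise_distances_preserved_on_subset(self):
        tree = simulate_tree(15, seed=4)
        before = _tip_distance_matrix(tree)
        keep = {"S001", "S004", "S007", "S011", "S015"}
        after = _tip_distance_matrix(prune_and_merge(tree, keep))
        for (a, b), d in after.items():
            assert d == pytest.approx(before[(a, b)])

    def test_unknown_tip_rejected(self):
        with pytest.raises(KeyError, match="nosuch"):
            prune_and_merge(_tree("(A:1,B:1);"), {"A", "nosuch"})


class TestMakeUltrametric:
    def test_already_ultrametric_unchanged(self):
        tree = simulate_tree(12, seed=5)
        before = _tip_distance_matrix(tree)
        after = _tip_distance_matrix(make_ultrametric(tree))
        for key, d in after.items():
            assert d == pytest.approx(before[key], abs=1e-9)

    def test_two_tip_mean_path(self):
        u = make_ultrametric(_tree("(A:1,B:3);"))
        nw = u.as_string(schema="newick")
        assert "A:2.0" in nw and "B:2.0" in nw

    def test_root_to_tip_variance_vanishes(self):
        rng = np.random.default_rng(6)
        tree = simulate_tree(20, seed=6)
        for edge in tree.preorder_edge_iter():
            if edge.length:
                edge.length *= rng.uniform(0.2, 3.0)  # break ultrametricity
        u = make_ultrametric(tree)
        cov = brownian_covariance(u)
        depths = np.diag(cov.V)
        assert np.var(depths) < 1e-12 * np.mean(depths) ** 2
        assert all(e.length is None or e.length > 0
                   for e in u.preorder_edge_iter())


class TestBrownianCovariance:
    def test_star_tree_identity(self):
        cov = brownian_covariance(_tree("(A:1,B:1,C:1,D:1);"))
        assert np.allclose(cov.V, np.eye(4))

    def test_three_tip_reading(self):
        cov = brownian_covariance(_tree("((A:0.5,B:0.5):0.5,C:1);"))
        i = {t: k for k, t in enumerate(cov.tip_ids)}
        assert cov.V[i["A"], i["B"]] == pytest.approx(0.5)
        assert cov.V[i["A"], i["C"]] == 0.0
        assert np.allclose(np.diag(cov.V), 1.0)

    def test_yule_tree_psd(self):
        for seed in range(5):
            cov = brownian_covariance(simulate_tree(30, seed=seed))
            assert np.linalg.eigvalsh(cov.V).min() >= -1e-10

    def test_non_ultrametric_warns(self):
        with pytest.warns(UserWarning, match="not ultrametric"):
            brownian_covariance(_tree("(A:1,B:3);"))


FIXTURE_TIPS = ["A", "B", "C", "D", "E"]
# extension of the 3-tip example: two cherries plus an outgroup
FIXTURE_V = np.array([
    [1.0, 0.5, 0.2, 0.2, 0.0],
    [0.5, 1.0, 0.2, 0.2, 0.0],
    [0.2, 0.2, 1.0, 0.7, 0.0],
    [0.2, 0.2, 0.7, 1.0, 0.0],
    [0.0, 0.0, 0.0, 0.0, 1.0],
])
FIXTURE_Y = np.array([1.2, 0.9, -0.3, -0.1, 0.4])
FIXTURE_X = np.array([0.8, 1.1, -0.9, -0.5, 0.1])


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        y, x = rng.normal(size=12), rng.normal(size=12)
        g = gls_fit(y, x, np.eye(12))
        o = ols_fit(y, x)
        assert abs(g.slope - o.slope) < 1e-10
        assert abs(g.p_value - o.p_value) < 1e-10
        assert abs(g.r2 - o.r2) < 1e-10

    def test_perfect_fit(self):
        x = np.arange(6, dtype=float)
        fit = gls_fit(2 * x + 1, x, np.eye(6))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matrix_algebra_oracle_on_fixture(self):
        # independent closed-form evaluation with explicit inverses
        cov = PhyloCovariance(FIXTURE_TIPS, FIXTURE_V, 1.0)
        fit = gls_fit(FIXTURE_Y, FIXTURE_X, cov)
        X = np.column_stack([np.ones(5), FIXTURE_X])
        Vi = np.linalg.inv(FIXTURE_V)
        beta = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ FIXTURE_Y
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        u = FIXTURE_Y - X @ beta
        e = np.ones(5)
        ybar = (e @ Vi @ FIXTURE_Y) / (e @ Vi @ e)
        r2 = 1 - (u @ Vi @ u) / ((FIXTURE_Y - ybar * e) @ Vi
                                 @ (FIXTURE_Y - ybar * e))
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_invariant_to_covariance_rescaling(self):
        cov1 = PhyloCovariance(FIXTURE_TIPS, FIXTURE_V, 1.0)
        cov2 = PhyloCovariance(FIXTURE_TIPS, 7.3 * FIXTURE_V, 7.3)
        f1 = gls_fit(FIXTURE_Y, FIXTURE_X, cov1)
        f2 = gls_fit(FIXTURE_Y, FIXTURE_X, cov2)
        assert f1.slope == pytest.approx(f2.slope)
        assert f1.p_value == pytest.approx(f2.p_value)
        assert f1.r2 == pytest.approx(f2.r2)

    def test_discrete_predictor_centering_and_f_test(self):
        rng = np.random.default_rng(2)
        groups = np.array(["a"] * 6 + ["b"] * 6)
        y = np.where(groups == "a", 1.0, -1.0) + rng.normal(0, 0.1, 12)
        fit = gls_fit(y, groups, np.eye(12), discrete=True)
        assert fit.intercept is None
        assert len(fit.slopes) == 2
        assert fit.p_value < 1e-6
        # centered response: level effects symmetric around zero
        assert fit.slopes.sum() == pytest.approx(0.0, abs=0.1)

    def test_collinear_design_rejected(self):
        x = np.column_stack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(np.linalg.LinAlgError):
            gls_fit(np.arange(8.0), x, np.eye(8))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            gls_fit([1.0, 2.0], [1.0, 2.0], np.eye(2))


class TestOls:
    def test_slope_one_perfect(self):
        x = np.arange(10, dtype=float)
        fit = ols_fit(x, x)
        assert fit.slope == pytest.approx(1.0) and fit.r2 == pytest.approx(1.0)

    def test_orthogonal_response_zero_slope(self):
        x = np.array([-1.0, 1.0] * 5)
        y = np.ones(10)
        assert ols_fit(y, x).slope == pytest.approx(0.0)

    def test_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=15), rng.normal(size=15)
        X = np.column_stack([np.ones(15), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        fit = ols_fit(y, x)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)


class TestRangeRobustness:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(4)
        species = [f"s{i}" for i in range(12)]
        cols = list(range(0, 301, 10))
        mat = pd.DataFrame(rng.normal(size=(12, 31)), index=species,
                           columns=cols)
        cov = PhyloCovariance(species, np.eye(12), 1.0)
        return mat, cov

    def test_cell_count(self, cohort):
        mat, cov = cohort
        trait = pd.Series(np.arange(12.0), index=mat.index)
        table = range_robustness(mat, trait, cov)
        assert len(table) == 31 * 32 // 2  # 31 singles + 465 longer = 496

    def test_constant_trait_flagged(self, cohort):
        mat, cov = cohort
        trait = pd.Series(1.0, index=mat.index)
        table = range_robustness(mat, trait, cov)
        assert (table.flag == "skipped").all()

    def test_self_regression_r2_one(self, cohort):
        mat, cov = cohort
        cols = [c for c in mat.columns if 100 <= c <= 300]
        trait = mat[cols].mean(axis=1)
        table = range_robustness(mat, trait, cov)
        row = table[(table.start_offset == 100) & (table.end_offset == 300)]
        assert row.r2.iloc[0] == pytest.approx(1.0)


class TestTaxonScan:
    def _setup(self, n_taxa, members_per_taxon, seed=0):
        rng = np.random.default_rng(seed)
        species, paths = [], {}
        for t in range(n_taxa):
            for m in range(members_per_taxon):
                sp = f"t{t}_m{m}"
                species.append(sp)
                paths[sp] = ["Root", f"Taxon{t}"]
        cols = list(range(0, 301, 10))
        mat = pd.DataFrame(rng.normal(size=(len(species), 31)),
                           index=species, columns=cols)
        trait = pd.Series(rng.normal(size=len(species)), index=species)
        cov = PhyloCovariance(species, np.eye(len(species)), 1.0)
        return mat, trait, cov, paths

    def test_small_taxa_excluded(self):
        mat, trait, cov, paths = self._setup(3, 8)
        table = taxon_scan(mat, trait, cov, paths, min_n=9)
        assert set(table.taxon) == {"Root"}  # only the 24-species root

    def test_single_taxon_bh_identity(self):
        mat, trait, cov, paths = self._setup(1, 10)
        paths = {sp: ["OnlyTaxon"] for sp in mat.index}
        table = taxon_scan(mat, trait, cov, paths, min_n=9)
        assert len(table) == 1
        assert table.p_adj.iloc[0] == pytest.approx(table.p_raw.iloc[0])

    def test_bh_on_ties_keeps_value(self):
        # 10 taxa with identical raw p stay at that p after BH
        from statsmodels.stats.multitest import multipletests
        _, p_adj, _, _ = multipletests([0.01] * 10, method="fdr_bh")
        assert np.allclose(p_adj, 0.01)

    def test_qualifying_taxa_counted(self):
        mat, trait, cov, paths = self._setup(4, 10)
        table = taxon_scan(mat, trait, cov, paths, min_n=9)
        assert set(table.taxon) == {"Root", "Taxon0", "Taxon1", "Taxon2",
                                    "Taxon3"}
        assert (table.n >= 9).all()
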