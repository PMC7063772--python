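"""Cross-species profile summaries: correlations, MIC, PCA, clustering,
and the weak-profile classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonfold.mic import _equipartition, mic_score, mic_statistic
from codonfold.profile_stats import (characteristic_profiles, pca_profiles,
                                     region_correlation,
                                     weak_dlfe_classifier, predict_weak)
from codonfold.traits_cub import SpeciesTraits

GRID = list(range(0, 301, 10))


def _matrix(rows: np.ndarray, prefix="sp") -> pd.DataFrame:
    return pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(len(rows))],
                        columns=GRID)


class TestRegionCorrelation:
    def test_region_against_itself(self):
        rng = np.random.default_rng(0)
        mat = _matrix(rng.normal(size=(8, 31)))
        out = region_correlation(mat, regions={"X": (0, 10), "Y": (0, 10)})
        assert out.rho.iloc[0] == pytest.approx(1.0)

    def test_region_against_negation(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 31))
        base[:, 20:] = -base[:, :11][:, :11]
        mat = _matrix(base)
        out = region_correlation(mat, regions={"X": (0, 100),
                                               "Y": (200, 300)})
        # X mean is column 0..10 mean; construct exact negation instead
        vals = rng.normal(size=8)
        mat2 = _matrix(np.zeros((8, 31)))
        mat2[0] = vals
        mat2[300] = -vals
        out = region_correlation(mat2, regions={"X": (0,), "Y": (300,)})
        assert out.rho.iloc[0] == pytest.approx(-1.0)

    def test_five_species_toy_matches_rank_arithmetic(self):
        mat = _matrix(np.zeros((5, 31)))
        a = np.array([0.1, 0.5, 0.3, 0.9, 0.7])
        b = np.array([1.0, 2.0, 1.5, 3.0, 2.5])
        mat[0], mat[300] = a, b
        out = region_correlation(mat, regions={"X": (0,), "Y": (300,)})
        # hand rank computation: both vectors share the same ranking
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        rho_hand = 1 - 6 * np.sum((ra - rb) ** 2) / (5 * 24)
        assert out.rho.iloc[0] == pytest.approx(rho_hand) == 1.0
        # exact permutation p for n=5: 1/5! * (# orderings as extreme)
        assert out.p_value.iloc[0] == pytest.approx(2 / 120)

    def test_degenerate_region_flagged(self):
        mat = _matrix(np.zeros((6, 31)))
        mat[0] = 1.0
        out = region_correlation(mat, regions={"X": (0,), "Y": (300,)})
        assert out.flag.iloc[0] == "degenerate"
        assert np.isnan(out.rho.iloc[0])


class TestMic:
    def test_constant_input_zero(self):
        x = np.linspace(0, 1, 50)
        assert mic_statistic(x, np.ones(50)) == 0.0
        assert mic_statistic(np.ones(50), x) == 0.0

    def test_noiseless_linear_relation(self):
        x = np.linspace(0, 1, 200)
        assert mic_statistic(x, x) >= 0.99
        assert mic_statistic(x, -3 * x + 2) >= 0.99

    def test_noiseless_nonmonotone_relation(self):
        x = np.linspace(0, 1, 200)
        assert mic_statistic(x, np.sin(4 * np.pi * x)) > 0.6

    def test_dp_matches_brute_force_grids(self):
        # exact DP (superclumps disabled) vs exhaustive x-cut search for
        # 2x2..3x3 grids on all-distinct small samples
        rng = np.random.default_rng(2)
        for n in (8, 10, 12):
            for rep in range(6):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                for a, b in itertools.product((2, 3), repeat=2):
                    rows = _equipartition(y, b)
                    best = 0.0
                    order = np.argsort(x)
                    for cuts in itertools.combinations(range(1, n), a - 1):
                        edges = [0, *cuts, n]
                        cols = np.empty(n, dtype=int)
                        for ci in range(len(edges) - 1):
                            cols[order[edges[ci]:edges[ci + 1]]] = ci
                        c_xy = np.zeros((a, rows.max() + 1))
                        np.add.at(c_xy, (cols, rows), 1)
                        px = c_xy.sum(1) / n
                        py = c_xy.sum(0) / n
                        mi = 0.0
                        for i in range(a):
                            for j in range(c_xy.shape[1]):
                                pij = c_xy[i, j] / n
                                if pij > 0:
                                    mi += pij * np.log(pij / (px[i] * py[j]))
                        best = max(best, mi)
                    from codonfold.mic import _AxisState, _axis_mi
                    state = _AxisState(x, y, b)
                    dp = _axis_mi(state, n, a, c=0)
                    assert dp == pytest.approx(best, abs=1e-12)

    def test_permutation_p_calibrated_under_independence(self):
        rng = np.random.default_rng(3)
        n_reject = 0
        for rep in range(20):
            x = rng.uniform(size=60)
            y = rng.uniform(size=60)
            _, p = mic_score(x, y, permutations=99, seed=rep)
            n_reject += p <= 0.05
        assert n_reject <= 2  # p > 0.05 in >= 90% of replicates

    def test_detects_nonlinear_split_dependence(self):
        # two diverging branches: no linear relation, strong dependence
        rng = np.random.default_rng(4)
        x = rng.uniform(40, 70, 200)
        sign = np.where(rng.random(200) < 0.5, 1.0, -1.0)
        y = sign * 0.02 * (x - 40) + rng.normal(0, 0.03, 200)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 < 0.05
        assert mic_statistic(x, y) > 0.3

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            mic_statistic([1.0, 2.0], [1.0, 2.0])


class TestPca:
    def test_identical_rows_degenerate(self):
        mat = _matrix(np.tile(np.linspace(0, 1, 31), (5, 1)))
        out = pca_profiles(mat, bootstrap=0)
        assert out.degenerate

    def test_two_clusters_separated_on_pc1(self):
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(5)
        up = np.linspace(-1, 1, 31) + rng.normal(0, 0.05, (10, 31))
        down = -np.linspace(-1, 1, 31) + rng.normal(0, 0.05, (10, 31))
        mat = _matrix(np.vstack([up, down]))
        out = pca_profiles(mat, bootstrap=0)
        labels = [0] * 10 + [1] * 10
        score = silhouette_score(out.coordinates[["pc1"]], labels)
        assert score > 0.5

    def test_orthonormal_components_and_variance_budget(self):
        rng = np.random.default_rng(6)
        mat = _matrix(rng.normal(size=(20, 31)))
        out = pca_profiles(mat, bootstrap=0)
        G = out.components @ out.components.T
        assert np.allclose(G, np.eye(len(G)), atol=1e-8)
        assert out.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_bootstrap_angles_stable_for_strong_axis(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0, 3, 30)
        axis = np.linspace(-1, 1, 31)
        mat = _matrix(scores[:, None] * axis + rng.normal(0, 0.1, (30, 31)))
        out = pca_profiles(mat, bootstrap=100, seed=0)
        assert np.nanmedian(out.bootstrap_angles_deg[:, 0]) < 10.0


class TestCharacteristicProfiles:
    def test_identical_profiles_single_cluster(self):
        mat = _matrix(np.tile(np.sin(np.linspace(0, 3, 31)), (6, 1)))
        centroids, members = characteristic_profiles(mat)
        assert len(centroids) == 1
        assert members.nunique() == 1

    def test_anticorrelated_groups_split_in_two(self):
        rng = np.random.default_rng(8)
        base = np.sin(np.linspace(0, 3, 31))
        rows = np.vstack([base + rng.normal(0, 0.02, 31) for _ in range(5)]
                         + [-base + rng.normal(0, 0.02, 31) for _ in range(5)])
        mat = _matrix(rows)
        centroids, members = characteristic_profiles(mat, 0.8)
        assert len(centroids) == 2
        first, second = members.iloc[:5], members.iloc[5:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_every_member_within_threshold(self):
        rng = np.random.default_rng(9)
        mat = _matrix(rng.normal(size=(15, 31)))
        threshold = 0.8
        centroids, members = characteristic_profiles(mat, threshold)
        for sp in mat.index:
            c = centroids.loc[members[sp]].to_numpy()
            v = mat.loc[sp].to_numpy()
            dc, dv = c - c.mean(), v - v.mean()
            dist = 1 - (dc @ dv) / (np.linalg.norm(dc) * np.linalg.norm(dv))
            assert dist < threshold

    def test_single_species(self):
        mat = _matrix(np.linspace(0, 1, 31)[None, :])
        centroids, members = characteristic_profiles(mat)
        assert len(centroids) == 1 and members.iloc[0] == 1


class TestWeakClassifier:
    def test_rule_clauses(self):
        weak_gc = SpeciesTraits("a", gc_percent=30.0, enc_prime=45.0,
                                opt_temp_c=37.0, endosymbiont=False)
        benign = SpeciesTraits("b", gc_percent=50.0, enc_prime=45.0,
                               opt_temp_c=37.0, endosymbiont=False)
        assert predict_weak(weak_gc) and not predict_weak(benign)

    def test_rule_truth_table(self):
        # the 4-clause disjunction over every trait combination
        for endo, gc_low, encp_high, temp_high in itertools.product(
                [False, True], repeat=4):
            t = SpeciesTraits(
                "x", endosymbiont=endo,
                gc_percent=30.0 if gc_low else 50.0,
                enc_prime=58.0 if encp_high else 45.0,
                opt_temp_c=80.0 if temp_high else 37.0)
            assert predict_weak(t) == (endo or gc_low or encp_high
                                       or temp_high)

    def test_missing_traits_are_rule_false(self):
        assert not predict_weak(SpeciesTraits("x"))

    def test_observed_label_from_profile_std(self):
        flat = np.full(31, 0.5)            # std 0 -> observed weak
        strong = np.linspace(-1, 1, 31)    # std >> 0.14
        mat = _matrix(np.vstack([flat, strong]))
        traits = {"sp0": SpeciesTraits("sp0", endosymbiont=True),
                  "sp1": SpeciesTraits("sp1", gc_percent=50.0)}
        out = weak_dlfe_classifier(mat, traits)
        assert out.table.observed_weak.tolist() == [True, False]
        assert out.table.predicted_weak.tolist() == [True, False]
        assert out.precision == 1.0 and out.recall == 1.0
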