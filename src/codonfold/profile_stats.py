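"""Cross-species summaries of ΔLFE profiles.

A cohort's profiles form a species × 31 matrix (window offsets 0-300
nt on the 10-nt grid, one anchor).  This module provides the
between-region Spearman correlations, PCA display coordinates with a
bootstrap stability check, taxon characteristic profiles by
agglomerative clustering under correlation distance, and the
four-trait rule predicting which species have weak (flat) profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .mic import mic_score, mic_statistic  # noqa: F401  (re-exported)
from .traits_cub import SpeciesTraits

__all__ = [
    "profile_matrix", "region_correlation", "pca_profiles",
    "characteristic_profiles", "weak_dlfe_classifier", "ClassifierOutput",
    "mic_score", "mic_statistic",
    "DEFAULT_REGIONS", "WEAK_STD_THRESHOLD",
]

# named profile regions (window offsets, nt); A = positive start,
# B = transition-peak zone, C = negative mid, D = positive end
DEFAULT_REGIONS = {
    "A": (0, 10),
    "B": tuple(range(20, 81, 10)),
    "C": tuple(range(200, 301, 10)),
    "D": (0, 10),  # on the end-anchored matrix
}

WEAK_STD_THRESHOLD = 0.14


def profile_matrix(results, max_span: int = 300, step: int = 10) -> pd.DataFrame:
    """Stack species DLFEResults into a species × offsets matrix."""
    grid = list(range(0, max_span + 1, step))
    rows = {}
    for r in results:
        s = pd.Series(r.mean_dlfe, index=r.positions)
        rows[r.species_id] = s.reindex(grid)
    df = pd.DataFrame(rows).T
    df.columns = grid
    return df


def _spearman(a: np.ndarray, b: np.ndarray, exact_below: int = 10
              ) -> tuple[float, float]:
    rho, p = stats.spearmanr(a, b)
    n = len(a)
    if n < exact_below and np.isfinite(rho):
        # exact permutation p for tiny cohorts
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        obs = abs(np.corrcoef(ra, rb)[0, 1])
        count = total = 0
        for perm in itertools.permutations(rb):
            r = abs(np.corrcoef(ra, perm)[0, 1])
            count += r >= obs - 1e-12
            total += 1
        p = count / total
    return float(rho), float(p)


def region_correlation(matrix: pd.DataFrame,
                       regions: dict[str, tuple] | None = None,
                       end_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman correlations between per-species region means.

    Region "D" is read from ``end_matrix`` when given (the positive-end
    region lives on the end-anchored profile); all other regions from
    ``matrix``.  Degenerate (constant) region vectors are flagged with
    rho = NaN.
    """
    regions = regions or DEFAULT_REGIONS
    values = {}
    for name, offsets in regions.items():
        src = end_matrix if (name == "D" and end_matrix is not None) else matrix
        cols = [o for o in offsets if o in src.columns]
        values[name] = src[cols].mean(axis=1)
    rows = []
    for r1, r2 in itertools.combinations(regions, 2):
        paired = pd.concat([values[r1], values[r2]], axis=1, join="inner").dropna()
        a, b = paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
        if len(paired) < 4 or np.all(a == a[0]) or np.all(b == b[0]):
            rows.append({"region_1": r1, "region_2": r2, "rho": np.nan,
                         "p_value": np.nan, "n": len(paired),
                         "flag": "degenerate"})
            continue
        rho, p = _spearman(a, b)
        rows.append({"region_1": r1, "region_2": r2, "rho": rho, "p_value": p,
                     "n": len(paired), "flag": ""})
    return pd.DataFrame(rows)


@dataclass
class PCAProfiles:
    coordinates: pd.DataFrame          # species × first 2 components
    explained_variance_ratio: np.ndarray
    components: np.ndarray             # (n_components, 31)
    degenerate: bool
    bootstrap_angles_deg: np.ndarray | None = None  # (resamples, n_components)


def pca_profiles(matrix: pd.DataFrame, n_components: int = 3,
                 bootstrap: int = 500, seed: int | None = None) -> PCAProfiles:
    """PCA of profile vectors with a bootstrap component-angle check.

    Components are orthonormal, fitted on column-mean-centered data.
    ``bootstrap`` resamples species with replacement and records the
    angle between each resampled component and the original (small
    angles = stable axes); 0 disables it.
    """
    X = matrix.to_numpy(dtype=float)
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    if np.allclose(X.var(axis=0), 0):
        coords = pd.DataFrame(np.zeros((X.shape[0], 2)), index=matrix.index,
                              columns=["pc1", "pc2"])
        return PCAProfiles(coords, np.zeros(2), np.zeros((2, X.shape[1])), True)
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    coords = pd.DataFrame(Z[:, :2], index=matrix.index, columns=["pc1", "pc2"])
    angles = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        angles = np.empty((bootstrap, n_components))
        for r in range(bootstrap):
            idx = rng.integers(0, X.shape[0], size=X.shape[0])
            sub = X[idx]
            if np.allclose(sub.var(axis=0), 0):
                angles[r] = np.nan
                continue
            p2 = PCA(n_components=n_components, svd_solver="full").fit(sub)
            cos = np.abs(np.sum(p2.components_ * pca.components_, axis=1))
            angles[r] = np.degrees(np.arccos(np.clip(cos, 0, 1)))
    return PCAProfiles(coords, pca.explained_variance_ratio_,
                       pca.components_, False, angles)


def characteristic_profiles(matrix: pd.DataFrame, dist_threshold: float = 0.8
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Taxon characteristic profiles by correlation-distance clustering.

    Agglomerative clustering (average linkage, distance 1 − Pearson r);
    K is the smallest cluster count for which every member profile is
    within ``dist_threshold`` correlation distance of its cluster
    centroid (the mean profile).  Default thresholds: 0.8 for
    start-anchored, 1.3 for end-anchored cohorts.  Returns (centroids
    dataframe indexed by cluster id, membership series per species).
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n == 1:
        centroids = pd.DataFrame([X[0]], index=[1], columns=matrix.columns)
        return centroids, pd.Series([1], index=matrix.index)

    def corr_dist(u, v):
        du, dv = u - u.mean(), v - v.mean()
        denom = np.linalg.norm(du) * np.linalg.norm(dv)
        if denom == 0:
            return 0.0 if np.allclose(u, v) else 1.0
        return float(1 - (du @ dv) / denom)

    D = pdist(X, metric=corr_dist)
    Z = linkage(D, method="average")
    for k in range(1, n + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        ok = True
        centroids = {}
        for cl in np.unique(labels):
            members = X[labels == cl]
            cen = members.mean(axis=0)
            centroids[cl] = cen
            if any(corr_dist(m, cen) >= dist_threshold for m in members):
                ok = False
                break
        if ok:
            cen_df = pd.DataFrame.from_dict(centroids, orient="index")
            cen_df.columns = matrix.columns
            counts = pd.Series(labels, index=matrix.index)
            return cen_df.sort_index(), counts
    raise RuntimeError("unreachable: singleton clusters always satisfy threshold")


@dataclass
class ClassifierOutput:
    table: pd.DataFrame   # species_id, profile_std, observed_weak, predicted_weak
    precision: float
    recall: float


def predict_weak(traits: SpeciesTraits) -> bool:
    """Four-clause disjunction predicting a weak (flat) ΔLFE profile.

    endosymbiont, or genomic GC < 38%, or genomic ENc' > 56.5, or
    optimum growth temperature > 58 °C; a missing trait makes its
    clause false.
    """
    return bool(
        (traits.endosymbiont is True)
        or (traits.gc_percent is not None and traits.gc_percent < 38.0)
        or (traits.enc_prime is not None and traits.enc_prime > 56.5)
        or (traits.opt_temp_c is not None and traits.opt_temp_c > 58.0)
    )


def weak_dlfe_classifier(matrix: pd.DataFrame,
                         traits: dict[str, SpeciesTraits],
                         std_threshold: float = WEAK_STD_THRESHOLD
                         ) -> ClassifierOutput:
    """Observed vs predicted weak-ΔLFE labels with cohort precision/recall.

    Observed label: standard deviation of the species' start-anchored
    31-position profile below ``std_threshold``.  Species absent from
    ``traits`` are predicted not-weak (all clauses false).
    """
    rows = []
    for sp in matrix.index:
        vec = matrix.loc[sp].to_numpy(dtype=float)
        std = float(np.nanstd(vec))
        t = traits.get(sp, SpeciesTraits(species_id=sp))
        rows.append({"species_id": sp, "profile_std": std,
                     "observed_weak": std < std_threshold,
                     "predicted_weak": predict_weak(t)})
    df = pd.DataFrame(rows).set_index("species_id")
    tp = int((df.observed_weak & df.predicted_weak).sum())
    fp = int((~df.observed_weak & df.predicted_weak).sum())
    fn = int((df.observed_weak & ~df.predicted_weak).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return ClassifierOutput(df, precision, recall)
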