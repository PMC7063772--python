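"""Phylogenetically controlled regression.

Closely related species are not independent observations: under a
Brownian-motion null, a trait's covariance between two species equals
the evolutionary time they share (root to most recent common
ancestor).  Generalized least squares with that covariance matrix V
tests trait associations while absorbing phylogenetic structure;
ordinary least squares is kept alongside for comparison, since the
contrast between the two is itself informative.

Tree preparation: prune to the analysed species (merging the resulting
single-child nodes by summing branch lengths, so tip-to-tip path
lengths are untouched), then smooth to an ultrametric tree by the
mean-path method — node ages are averaged bottom-up and each subtree
is rescaled multiplicatively so every tip sits at the same depth.
Only relative depths matter: GLS estimates and tests are invariant to
a global rescaling of V.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhyloCovariance", "RegressionResult",
    "prune_and_merge", "make_ultrametric", "brownian_covariance",
    "gls_fit", "ols_fit", "range_robustness", "taxon_scan",
]


# ---------------------------------------------------------------- trees

def prune_and_merge(tree: dendropy.Tree, keep_tips: set[str]) -> dendropy.Tree:
    """Prune a tree to ``keep_tips``, preserving tip-to-tip path lengths.

    Unused leaves and inner nodes are removed and single-child inner
    nodes merged by summing branch lengths.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(keep_tips) - tips
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(list(keep_tips))
    # drop a zero-length root unifurcation if pruning left one
    seed = pruned.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (seed.edge.length or 0.0)
        pruned.seed_node = child
        child.parent_node = None
        seed = child
    return pruned


def make_ultrametric(tree: dendropy.Tree) -> dendropy.Tree:
    """Mean-path ultrametric smoothing (relative depths only).

    Bottom-up, each node's age is set to the mean over children of
    (child branch + child age); top-down, every child subtree is
    rescaled by the factor making its tips land exactly at the parent's
    age.  Branch lengths stay positive; an already-ultrametric tree is
    returned unchanged up to floating error.
    """
    out = tree.clone(depth=1)
    age: dict = {}
    for node in out.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            age[node] = 0.0
        else:
            paths = [(k.edge.length or 0.0) + age[k] for k in kids]
            if any(p <= 0 for p in paths):
                raise ValueError("non-positive root-to-tip path; "
                                 "branch lengths must be positive")
            age[node] = float(np.mean(paths))
    # top-down multiplicative rescale so each subtree's tips reach the
    # parent's age exactly
    scale = {out.seed_node: 1.0}
    for node in out.preorder_node_iter():
        for k in node.child_nodes():
            path = (k.edge.length or 0.0) + age[k]
            f = scale[node] * (age[node] / path)
            k.edge.length = (k.edge.length or 0.0) * f
            scale[k] = f
    return out


@dataclass
class PhyloCovariance:
    """Brownian variance-covariance matrix over an ordered tip set."""

    tip_ids: list[str]
    V: np.ndarray
    tree_depth: float

    def subset(self, ids: list[str]) -> "PhyloCovariance":
        idx = [self.tip_ids.index(i) for i in ids]
        return PhyloCovariance(list(ids), self.V[np.ix_(idx, idx)],
                               self.tree_depth)


def brownian_covariance(tree: dendropy.Tree,
                        tol: float = 1e-6) -> PhyloCovariance:
    """V[i, j] = root-to-MRCA depth of tips i and j; diag = tree depth.

    Warns (but proceeds) if the tree is not ultrametric within ``tol``
    relative to its depth.
    """
    tree = tree.clone(depth=1)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    n = len(tips)
    index = {t: i for i, t in enumerate(tips)}
    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        for k in node.child_nodes():
            depth[k] = depth[node] + (k.edge.length or 0.0)
    tip_depths = np.array([depth[l] for l in tree.leaf_node_iter()])
    max_depth = float(tip_depths.max())
    if max_depth > 0 and (tip_depths.max() - tip_depths.min()) > tol * max_depth:
        import warnings
        warnings.warn("tree is not ultrametric; using root-to-MRCA depths",
                      stacklevel=2)
    V = np.zeros((n, n))
    below: dict = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            i = index[node.taxon.label]
            V[i, i] = depth[node]
            below[node] = [i]
            continue
        groups = [below[k] for k in kids]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        V[i, j] = V[j, i] = depth[node]
        below[node] = [i for g in groups for i in g]
    return PhyloCovariance(tips, V, max_depth)


# ----------------------------------------------------------- regression

@dataclass
class RegressionResult:
    slopes: np.ndarray
    slope_names: list[str]
    intercept: float | None
    r2: float
    p_value: float
    slope_p_values: np.ndarray
    n: int
    method: str

    @property
    def slope(self) -> float:
        """First non-intercept coefficient (single-predictor shortcut)."""
        return float(self.slopes[0])


def _design(x, intercept: bool, discrete: bool):
    x = np.asarray(x)
    if discrete:
        levels = sorted(set(x.tolist()))
        X = np.column_stack([(x == lv).astype(float) for lv in levels])
        return X, [str(lv) for lv in levels], False
    if x.ndim == 1:
        x = x[:, None]
    names = [f"x{j}" for j in range(x.shape[1])]
    if intercept:
        X = np.column_stack([np.ones(len(x)), x])
        return X, names, True
    return x.astype(float), names, False


def gls_fit(y, x, cov: PhyloCovariance | np.ndarray | None = None,
            intercept: bool = True, discrete: bool = False,
            method_name: str = "gls") -> RegressionResult:
    """Closed-form GLS under Brownian covariance V.

    β = (X'V⁻¹X)⁻¹X'V⁻¹y with two-sided t-tests on each coefficient;
    the fit p-value is the slope t-test for a single continuous
    predictor and the joint F-test otherwise.  R² follows
    1 − û'V⁻¹û / (Y−Ȳe)'V⁻¹(Y−Ȳe) with Ȳ the intercept of the
    equivalent intercept-only GLS and e the first design column.
    Discrete predictors become unordered-factor dummies with no
    intercept, and y is centered to mean 0.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if discrete:
        y = y - y.mean()
    X, names, has_intercept = _design(x, intercept, discrete)
    k = X.shape[1]
    if n < k + 1:
        raise ValueError(f"n={n} too small for {k} coefficients")
    if cov is None:
        V = np.eye(n)
    else:
        V = cov.V if isinstance(cov, PhyloCovariance) else np.asarray(cov)
    if V.shape != (n, n):
        raise ValueError("covariance matrix does not match data length")
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        import warnings
        warnings.warn("singular V; adding jitter ridge", stacklevel=2)
        V = V + 1e-10 * np.trace(V) / n * np.eye(n)
        L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("collinear design (X'V^-1X singular)")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    dof = n - k
    sigma2 = float(resid_w @ resid_w) / dof if dof > 0 else np.nan
    se = np.sqrt(np.maximum(np.diag(sigma2 * np.linalg.inv(XtX)), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    coef_p = 2 * stats.t.sf(np.abs(tvals), dof)

    # R-squared by the GLS formula; e is the first design column
    e = X[:, 0]
    ew = np.linalg.solve(L, e)
    ybar = float((ew @ yw) / (ew @ ew))
    denom_w = yw - ybar * ew
    denom = float(denom_w @ denom_w)
    num = float(resid_w @ resid_w)
    r2 = 1.0 - num / denom if denom > 0 else np.nan

    slope_idx = np.arange(1, k) if has_intercept else np.arange(k)
    slopes = beta[slope_idx]
    slope_p = coef_p[slope_idx]
    if len(slope_idx) == 1:
        p_value = float(slope_p[0])
    else:
        # joint F-test that all (non-intercept) coefficients are zero
        rss1 = num
        rss0 = float(denom_w @ denom_w) if has_intercept else float(yw @ yw)
        q = len(slope_idx)
        if rss1 <= 0:
            p_value = 0.0
        else:
            F = ((rss0 - rss1) / q) / (rss1 / dof)
            p_value = float(stats.f.sf(F, q, dof))
    return RegressionResult(
        slopes=slopes,
        slope_names=[names[i - 1] if has_intercept else names[i]
                     for i in slope_idx] if not discrete
        else [names[i] for i in slope_idx],
        intercept=float(beta[0]) if has_intercept else None,
        r2=r2, p_value=p_value, slope_p_values=slope_p, n=n,
        method=method_name)


def ols_fit(y, x, intercept: bool = True,
            discrete: bool = False) -> RegressionResult:
    """Ordinary least squares (GLS with identity covariance)."""
    return gls_fit(y, x, cov=None, intercept=intercept, discrete=discrete,
                   method_name="ols")


# ------------------------------------------------- robustness and scans

def _aligned(dlfe_matrix: pd.DataFrame, trait: pd.Series,
             cov: PhyloCovariance):
    species = [s for s in dlfe_matrix.index
               if s in trait.index and not pd.isna(trait[s])
               and s in cov.tip_ids]
    return species


def range_robustness(dlfe_matrix: pd.DataFrame, trait: pd.Series,
                     cov: PhyloCovariance, min_n: int = 3) -> pd.DataFrame:
    """GLS of ΔLFE on a trait at every position and contiguous subrange.

    ``dlfe_matrix``: species × window offsets (columns in nt).  Rows:
    one per (start_offset, end_offset) cell — 31 single positions plus
    all 31·32/2 − 31 longer subranges — with the mean ΔLFE over the
    subrange as the response.  Cells with fewer than ``min_n`` species
    or a degenerate trait are flagged and skipped.
    """
    offsets = list(dlfe_matrix.columns)
    species = _aligned(dlfe_matrix, trait, cov)
    rows = []
    for a in range(len(offsets)):
        for b in range(a, len(offsets)):
            sub = dlfe_matrix.loc[species, offsets[a]:offsets[b]]
            resp = sub.mean(axis=1)
            ok = resp.notna() & trait.loc[species].notna()
            ids = list(resp.index[ok])
            row = {"start_offset": offsets[a], "end_offset": offsets[b],
                   "n": len(ids)}
            tvals = trait.loc[ids]
            if len(ids) < min_n or tvals.nunique() < 2:
                row.update(slope=np.nan, slope_sign=0, r2=np.nan,
                           p_value=np.nan, flag="skipped")
            else:
                fit = gls_fit(resp.loc[ids].to_numpy(), tvals.to_numpy(),
                              cov.subset(ids))
                row.update(slope=fit.slope, slope_sign=int(np.sign(fit.slope)),
                           r2=fit.r2, p_value=fit.p_value, flag="")
            rows.append(row)
    return pd.DataFrame(rows)


def _taxa_at_all_ranks(taxon_paths: dict[str, list[str]]) -> dict[str, list[str]]:
    """taxon name -> member species, over every rank in the paths."""
    members: dict[str, list[str]] = {}
    for sp, path in taxon_paths.items():
        for taxon in path:
            members.setdefault(taxon, []).append(sp)
    return members


def taxon_scan(dlfe_matrix: pd.DataFrame, trait: pd.Series,
               cov: PhyloCovariance, taxon_paths: dict[str, list[str]],
               position_range: tuple[int, int] = (0, 300),
               min_n: int = 9, alpha: float = 0.05) -> pd.DataFrame:
    """Per-taxon GLS with Benjamini-Hochberg correction across taxa.

    Every taxonomic group (any rank) with at least ``min_n`` usable
    species is fit separately: p from the GLS on the mean ΔLFE over
    ``position_range``, reported R² the median of per-position R²
    within the range; p-values are BH-adjusted over the taxa tested.
    """
    species = _aligned(dlfe_matrix, trait, cov)
    cols = [c for c in dlfe_matrix.columns
            if position_range[0] <= c <= position_range[1]]
    rows = []
    for taxon, members in sorted(_taxa_at_all_ranks(taxon_paths).items()):
        ids = [s for s in members if s in species]
        if len(ids) < min_n:
            continue
        tvals = trait.loc[ids]
        if tvals.nunique() < 2:
            continue
        sub_cov = cov.subset(ids)
        region_mean = dlfe_matrix.loc[ids, cols].mean(axis=1)
        fit = gls_fit(region_mean.to_numpy(), tvals.to_numpy(), sub_cov)
        r2s = []
        for c in cols:
            resp = dlfe_matrix.loc[ids, c]
            if resp.notna().all():
                r2s.append(gls_fit(resp.to_numpy(), tvals.to_numpy(), sub_cov).r2)
        rows.append({"taxon": taxon, "n": len(ids),
                     "slope_sign": int(np.sign(fit.slope)),
                     "median_r2": float(np.median(r2s)) if r2s else np.nan,
                     "p_raw": fit.p_value})
    df = pd.DataFrame(rows, columns=["taxon", "n", "slope_sign", "median_r2",
                                     "p_raw"])
    if len(df):
        rej, p_adj, _, _ = multipletests(df["p_raw"], alpha=alpha,
                                         method="fdr_bh")
        df["p_adj"] = p_adj
        df["significant"] = rej
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df
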