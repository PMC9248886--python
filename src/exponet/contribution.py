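"""Attribute clinical-marker variation to exposome categories.

For each outcome (a cytokine or clinical blood test), the exposome
features linked to it in the correlation network are reduced per
category (chemical, biological, environmental) by PCA, keeping the
smallest leading set of components whose cumulative explained variance
exceeds 80%.  The kept component scores from all categories are the
predictors of an ordinary least-squares model whose R-squared measures
how much of the outcome the exposome explains.  A single-response PLS
model over the same predictors yields VIP (variable importance in
projection) scores, and each category's contribution share is

    share_c = R^2 * (sum of VIP over category c's components) / (sum of all VIP)

so the shares sum exactly to R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .core_io import OmicsBlock, logger
from .corrnet import CorrelationNetwork

CATEGORIES = ("chemical", "biological", "environmental")


@dataclass
class CategoryPCs:
    """Kept principal components of one exposome category."""

    category: str
    scores: np.ndarray  # samples x kept components
    explained: np.ndarray  # variance fraction per kept component
    n_kept: int


@dataclass
class ContributionResult:
    outcome_id: str
    r2: float
    vip: np.ndarray
    shares: dict[str, float] = field(default_factory=dict)
    outcome_variance: float = float("nan")

    @property
    def dominant_category(self) -> str:
        return max(self.shares, key=lambda c: self.shares[c])


def pca_reduce(
    matrix: np.ndarray,
    var_threshold: float = 0.80,
    standardize: bool = True,
    category: str = "",
) -> CategoryPCs:
    """PCA on a samples x features matrix, keeping components to > var_threshold.

    Columns are z-scored by default (heterogeneous units across exposome
    features), the covariance eigen-decomposition is taken, and the
    smallest number of leading components whose cumulative explained-
    variance fraction strictly exceeds ``var_threshold`` is kept.  Sign
    convention: the largest-magnitude loading of each component is
    positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        keep_cols = sd > 0
        X = X[:, keep_cols] / sd[keep_cols]
    if X.shape[1] == 0 or not np.any(X.std(axis=0) > 0):
        raise ValueError("zero-variance block: PCA undefined")
    # SVD of the centered matrix == eigen-decomposition of the covariance
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    explained_all = s**2 / np.sum(s**2)
    nonzero = s > s[0] * 1e-12 if s[0] > 0 else s > 0
    u, s, vt = u[:, nonzero], s[nonzero], vt[nonzero]
    explained_all = explained_all[nonzero]
    cum = np.cumsum(explained_all)
    n_kept = int(np.searchsorted(cum, var_threshold, side="right") + 1)
    n_kept = min(n_kept, s.size)
    # deterministic sign: largest-|loading| entry of each component positive
    for a in range(n_kept):
        j = int(np.argmax(np.abs(vt[a])))
        if vt[a, j] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    scores = u[:, :n_kept] * s[:n_kept]
    return CategoryPCs(category=category, scores=scores,
                       explained=explained_all[:n_kept], n_kept=n_kept)


def fit_r2(y: np.ndarray, X: np.ndarray, ridge: bool = False, ridge_alpha: float = 1e-6) -> float:
    """R-squared of an OLS fit of y on X (with intercept).

    Errors when the outcome is constant or there are at least as many
    predictors as samples; ``ridge=True`` substitutes a lightly
    regularized fit in the latter case.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant outcome: R^2 undefined")
    if n <= p + 1 and not ridge:
        raise ValueError(f"{n} samples cannot identify {p} predictors plus intercept; "
                         "reduce predictors or pass ridge=True")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if ridge:
        beta = np.linalg.solve(Xc.T @ Xc + ridge_alpha * np.eye(p), Xc.T @ yc)
    else:
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    rss = float(np.sum((yc - Xc @ beta) ** 2))
    return 1.0 - rss / tss


def pls_vip(y: np.ndarray, X: np.ndarray, n_components: int) -> np.ndarray:
    """VIP scores from a single-response PLS regression.

    VIP_j = sqrt( p * sum_a[ SS_a * (w_ja/||w_a||)^2 ] / sum_a SS_a )
    with p predictors, weight vectors w_a and SS_a the y-variance
    explained by component a.  The mean squared VIP is always 1.
    """
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components={n_components} infeasible for X of shape {X.shape}")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("degenerate X: constant predictor column")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    W = pls.x_weights_  # p x A
    T = pls.x_scores_  # n x A
    q = pls.y_loadings_.ravel()  # A
    ss = q**2 * np.sum(T**2, axis=0)  # y-variance captured per component
    if np.sum(ss) == 0:
        raise ValueError("PLS explains no outcome variance; VIP undefined")
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ss) / np.sum(ss))
    return vip


def linked_features(network: CorrelationNetwork, outcome: tuple[str, str]) -> dict[str, list[str]]:
    """Exposome features significantly correlated with one outcome node,
    grouped by their ome label."""
    grouped: dict[str, list[str]] = {}
    for ome, feat in network.neighbors(outcome):
        grouped.setdefault(ome, []).append(feat)
    for feats in grouped.values():
        feats.sort()
    return grouped


def contributions(
    outcome_id: str,
    outcome_values: pd.Series,
    blocks_by_category: dict[str, OmicsBlock],
    corr_network: CorrelationNetwork | None = None,
    outcome_ome: str = "cytokine",
    var_threshold: float = 0.80,
    n_components: int | None = None,
    feature_mode: str = "linked",
    ridge: bool = False,
) -> ContributionResult | None:
    """Decompose one outcome's variance into per-category shares.

    ``feature_mode="linked"`` (default) admits only the exposome features
    significantly correlated with this outcome in ``corr_network``;
    ``"all"`` uses every feature of every category block.  Returns None
    (with a log entry) when no features qualify.
    """
    samples = list(outcome_values.index)
    y = outcome_values.to_numpy(dtype=float)
    if feature_mode == "linked":
        if corr_network is None:
            raise ValueError("feature_mode='linked' requires a correlation network")
        grouped = linked_features(corr_network, (outcome_ome, outcome_id))
    elif feature_mode == "all":
        grouped = {cat: blk.feature_ids for cat, blk in blocks_by_category.items()}
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")

    pcs: list[CategoryPCs] = []
    for cat in sorted(blocks_by_category):
        feats = [f for f in grouped.get(cat, []) if f in set(blocks_by_category[cat].feature_ids)]
        if not feats:
            continue
        sub = blocks_by_category[cat].data.loc[feats, samples].to_numpy(dtype=float).T
        try:
            pcs.append(pca_reduce(sub, var_threshold=var_threshold, category=cat))
        except ValueError:
            logger.info("contributions(%s): category %s has no usable variance", outcome_id, cat)
    if not pcs:
        logger.info("contributions(%s): no linked exposome features; outcome skipped", outcome_id)
        return None

    X = np.hstack([c.scores for c in pcs])
    labels = [c.category for c in pcs for _ in range(c.n_kept)]
    n, p = X.shape
    r2 = fit_r2(y, X, ridge=ridge)
    if n_components is None:
        n_components = min(p, 5, n - 2)
        n_components = max(n_components, 1)
    vip = pls_vip(y, X, n_components=n_components)
    total_vip = float(np.sum(vip))
    shares = {}
    for cat in sorted(blocks_by_category):
        cat_vip = float(sum(v for v, lab in zip(vip, labels) if lab == cat))
        shares[cat] = r2 * cat_vip / total_vip
    return ContributionResult(outcome_id=outcome_id, r2=r2, vip=vip, shares=shares,
                              outcome_variance=float(np.var(y, ddof=1)))


def explained_variation_summary(results: list[ContributionResult]) -> dict[str, float]:
    """Aggregate per-outcome R^2 into overall explained variation.

    Reports both the plain mean of R^2 across outcomes and the mean
    weighted by each outcome's observed variance; both are labelled so
    downstream consumers choose deliberately.
    """
    if not results:
        return {"mean_r2": float("nan"), "variance_weighted_r2": float("nan"), "n_outcomes": 0}
    r2s = np.array([r.r2 for r in results])
    w = np.array([r.outcome_variance for r in results])
    return {
        "mean_r2": float(np.mean(r2s)),
        "variance_weighted_r2": float(np.sum(r2s * w) / np.sum(w)),
        "n_outcomes": len(results),
    }
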