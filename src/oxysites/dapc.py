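"""Discriminant analysis of principal components (DAPC).

The feature matrix is first reduced by PCA, retaining the minimum number of
components explaining ~90% of the variance; the number of sequence groups is
then inferred by k-means over a range of k, scored with BIC; finally a
linear discriminant analysis on the retained PC scores yields axes (LDs)
maximizing between-group relative to within-group variance. Discriminant
loadings are composed back through the PCA rotation onto the original
site x descriptor variables, and the sites whose aggregated |loading| reach
the 90th percentile are mapped to their 1-based alignment codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .site_encoding import N_DESCRIPTORS, SiteFeatureMatrix

__all__ = ["PCAModel", "DAPCResult", "fit_pca", "infer_groups", "fit_dapc", "top_loading_sites"]

RIDGE = 1e-8  # on the within-group covariance; guards singleton groups


@dataclass
class PCAModel:
    column_means: np.ndarray
    loadings: np.ndarray            # variables x retained PCs, orthonormal columns
    eigenvalues: np.ndarray         # all nonzero eigenvalues, nonincreasing
    retained_count: int
    cumulative_variance: float      # fraction explained by the retained PCs
    column_scales: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.column_means
        if self.column_scales is not None:
            Xc = Xc / self.column_scales
        return Xc @ self.loadings


@dataclass
class DAPCResult:
    k: int
    assignments: np.ndarray          # row -> group label in 0..k-1
    bic_curve: dict[int, float]
    ld_scores: np.ndarray            # rows x n_ld
    ld_var_prop: np.ndarray          # per-LD fraction of discriminant variance
    var_loadings: np.ndarray         # original variables x n_ld
    row_ids: list[str]
    site_order: list[int]
    top_sites: dict[int, list[int]] = field(default_factory=dict)  # LD (1-based) -> codons

    @property
    def n_ld(self) -> int:
        return self.ld_scores.shape[1]


def fit_pca(
    X: SiteFeatureMatrix | np.ndarray,
    var_target: float = 0.90,
    scale: bool = False,
) -> PCAModel:
    """Centered PCA retaining the minimal PC count reaching `var_target`
    cumulative variance (capped at n_rows - 1 and at matrix rank).

    No unit-variance scaling by default: the z-descriptors are already on
    comparable published scales.
    """
    M = X.values if isinstance(X, SiteFeatureMatrix) else np.asarray(X, dtype=float)
    n = M.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 rows")
    means = M.mean(axis=0)
    Xc = M - means
    scales = None
    if scale:
        scales = Xc.std(axis=0, ddof=1)
        scales[scales == 0] = 1.0
        Xc = Xc / scales
    # SVD of the centered matrix; eigenvalues of the covariance = s^2/(n-1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("zero-variance feature matrix")
    eig = (s[:rank] ** 2) / (n - 1)
    cum = np.cumsum(eig) / eig.sum()
    retained = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    retained = min(retained, n - 1, rank)
    return PCAModel(
        column_means=means,
        loadings=Vt[:retained].T,
        eigenvalues=eig,
        retained_count=retained,
        cumulative_variance=float(cum[retained - 1]),
        column_scales=scales,
    )


def _bic(pc_scores: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a spherical Gaussian mixture with per-cluster variances,
    evaluated at the k-means partition.

    The per-cluster variance term is what lets the criterion stop at the
    true k: a criterion built on the pooled WSS alone (n ln(WSS/n) + k ln n)
    keeps rewarding splits of a genuinely homogeneous cluster, because
    k-means removes a roughly constant fraction of a cluster's WSS per
    split regardless of whether any real structure is present.
    """
    n, d = pc_scores.shape
    total_var = float(pc_scores.var())
    # variance floor (1% of the overall per-dimension variance) blocks the
    # mixture-likelihood degeneracy where shaving off a near-coincident pair
    # of rows sends a cluster variance, and hence the BIC, to -infinity
    floor = 0.01 * total_var + 1e-300
    loglik = 0.0
    for g in range(k):
        pts = pc_scores[labels == g]
        m = len(pts)
        if m == 0:
            continue
        wss_g = float(((pts - pts.mean(axis=0)) ** 2).sum())
        s2 = max(wss_g / (m * d), floor)
        loglik += (
            -0.5 * m * d * np.log(2 * np.pi * s2)
            - wss_g / (2 * s2)
            + m * np.log(m / n)
        )
    n_params = k * d + k + (k - 1)  # means, variances, mixing weights
    return -2.0 * loglik + n_params * np.log(n)


def infer_groups(
    pc_scores: np.ndarray,
    k_max: int | None = None,
    n_starts: int = 25,
    seed: int = 0,
) -> tuple[int, np.ndarray, dict[int, float]]:
    """k-means over k = 1..k_max scored by a spherical-mixture BIC;
    returns the argmin, ties broken toward the smallest k (the minimum number
    of gene groups)."""
    pc_scores = np.asarray(pc_scores, dtype=float)
    n = pc_scores.shape[0]
    if k_max is None:
        k_max = min(n - 1, 10)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > n - 1:
        raise ValueError(f"k_max = {k_max} exceeds n_rows - 1 = {n - 1}")
    bic_curve: dict[int, float] = {}
    labels_of: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
            labels = km.fit_predict(pc_scores)
        bic_curve[k] = _bic(pc_scores, labels, k)
        labels_of[k] = labels
    best_k = min(bic_curve, key=lambda k: (round(bic_curve[k], 12), k))
    return best_k, labels_of[best_k], bic_curve


def fit_dapc(
    pc_scores: np.ndarray,
    assignments: np.ndarray,
    pca: PCAModel,
    row_ids: list[str],
    site_order: list[int],
) -> DAPCResult:
    """Linear discriminant analysis on retained PC scores.

    Solves the generalized symmetric eigenproblem B a = l W a for the
    between-group (B) and within-group (W) covariance of the PC scores;
    `ld_var_prop` is each discriminant eigenvalue over their sum, LD scores
    are row projections, and variable loadings are the discriminant
    coefficients composed back through the PCA rotation.
    """
    pc_scores = np.asarray(pc_scores, dtype=float)
    assignments = np.asarray(assignments)
    groups = np.unique(assignments)
    k = len(groups)
    if k < 2:
        raise ValueError("no discriminant axes: need at least 2 groups")
    n, p = pc_scores.shape
    grand = pc_scores.mean(axis=0)
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for g in groups:
        pts = pc_scores[assignments == g]
        mu = pts.mean(axis=0)
        d = (mu - grand)[:, None]
        B += len(pts) * (d @ d.T)
        r = pts - mu
        W += r.T @ r
    B /= n
    W = W / n + RIDGE * np.eye(p)
    eigvals, eigvecs = scipy.linalg.eigh(B, W)
    order = np.argsort(eigvals)[::-1]
    n_ld = min(k - 1, p)
    eigvals = np.clip(eigvals[order][:n_ld], 0.0, None)
    A = eigvecs[:, order][:, :n_ld]                      # PC-space coefficients
    # sign convention: largest-magnitude element of each composed loading positive
    var_loadings = pca.loadings @ A                      # original variables x LDs
    for j in range(n_ld):
        i = int(np.argmax(np.abs(var_loadings[:, j])))
        if var_loadings[i, j] < 0:
            var_loadings[:, j] *= -1
            A[:, j] *= -1
    ld_scores = (pc_scores - grand) @ A
    total = eigvals.sum()
    props = eigvals / total if total > 0 else np.full(n_ld, 1.0 / n_ld)
    return DAPCResult(
        k=k,
        assignments=assignments.astype(int),
        bic_curve={},
        ld_scores=ld_scores,
        ld_var_prop=props,
        var_loadings=var_loadings,
        row_ids=list(row_ids),
        site_order=list(site_order),
    )


def top_loading_sites(result: DAPCResult, percentile: float = 90.0) -> dict[int, list[int]]:
    """Per LD, aggregate |loading| over each site's five descriptors (sum)
    and report the 1-based codons at or above the given percentile of the
    aggregate distribution (ties at the threshold included)."""
    m = len(result.site_order)
    out: dict[int, list[int]] = {}
    for j in range(result.n_ld):
        agg = np.abs(result.var_loadings[:, j]).reshape(m, N_DESCRIPTORS).sum(axis=1)
        thr = np.percentile(agg, percentile)
        codons = [result.site_order[i] for i in range(m) if agg[i] >= thr - 1e-12]
        out[j + 1] = sorted(codons)
    result.top_sites = out
    return out


def run_dapc(
    X: SiteFeatureMatrix,
    var_target: float = 0.90,
    k_max: int | None = None,
    n_starts: int = 25,
    seed: int = 0,
    percentile: float = 90.0,
) -> DAPCResult:
    """PCA -> group inference -> discriminant fit -> top-loading codons."""
    pca = fit_pca(X, var_target=var_target)
    scores = pca.transform(X.values)
    k, labels, bic_curve = infer_groups(scores, k_max=k_max, n_starts=n_starts, seed=seed)
    if k < 2:
        raise ValueError("BIC selected a single group; no discriminant axes")
    result = fit_dapc(scores, labels, pca, X.row_ids, X.site_order)
    result.bic_curve = bic_curve
    top_loading_sites(result, percentile=percentile)
    return result
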