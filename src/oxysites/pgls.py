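"""Phylogenetic generalized least squares with Pagel's lambda.

The error covariance is sigma^2 * V(lambda), where V(lambda) keeps the
diagonal of the Brownian shared-branch-length matrix C and multiplies its
off-diagonals by lambda in [~0, 1]. lambda may be held fixed (the
"no phylogenetic influence" convention uses a value near zero) or profiled
out by bounded 1-D maximum likelihood. Backward model reduction drops terms
by nested F-tests until every remaining term is significant at the working
level (0.1 by convention here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .io_model import GeneTree

__all__ = [
    "PhyloCovariance",
    "PGLSFit",
    "build_covariance",
    "lambda_transform",
    "gls_fit",
    "fit_lambda_ml",
    "anova_reduce",
]

LAMBDA_BOUNDS = (1e-6, 1.0)


@dataclass
class PhyloCovariance:
    """Shared root-to-tip branch-length matrix for an ordered set of rows.

    C[i, j] is the depth of the MRCA of tips i and j; C[i, i] the root-to-tip
    distance of tip i. Several rows (paralogs) may point at the same tip, in
    which case they share that tip's covariance structure.
    """

    row_order: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.C, self.C.T):
            raise ValueError("phylogenetic covariance must be symmetric")

    def V(self, lam: float) -> np.ndarray:
        return lambda_transform(self.C, lam)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: off-diagonals scaled by lam, diagonal unchanged."""
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def build_covariance(
    tree: GeneTree,
    rows: list[str],
    tip_of_row: dict[str, str] | None = None,
) -> PhyloCovariance:
    """Shared-path-length covariance for the given rows.

    `tip_of_row` maps row ids to tree tip labels (identity by default).
    """
    tip_of_row = tip_of_row or {r: r for r in rows}
    t = tree.tree
    depth = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        d = (depth[parent] if parent is not None else 0.0) + (node.edge.length or 0.0)
        depth[node] = d
    leaf_by_label = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}
    missing = [r for r in rows if tip_of_row[r] not in leaf_by_label]
    if missing:
        raise ValueError(f"rows without a matching tree tip: {missing}")
    # ancestor sets give MRCA depth without relying on taxon bitmasks
    anc: dict[str, list] = {}
    for label, leaf in leaf_by_label.items():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[label] = chain
    n = len(rows)
    C = np.zeros((n, n))
    for i in range(n):
        li = tip_of_row[rows[i]]
        set_i = set(id(x) for x in anc[li])
        C[i, i] = depth[leaf_by_label[li]]
        for j in range(i + 1, n):
            lj = tip_of_row[rows[j]]
            if li == lj:
                C[i, j] = C[j, i] = depth[leaf_by_label[li]]
                continue
            mrca = next(x for x in anc[lj] if id(x) in set_i)
            C[i, j] = C[j, i] = depth[mrca]
    if np.trace(C) <= 0:
        raise ValueError("tree has zero root-to-tip depth")
    return PhyloCovariance(row_order=list(rows), C=C)


@dataclass
class PGLSFit:
    """A fitted P_crit ~ LDs generalized least-squares model."""

    terms: list[str]                 # design column names, intercept first
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    lam: float
    sigma2: float                    # ML scale: RSS_V / n
    loglik: float
    r2: float
    n: int
    rss: float                       # whitened residual sum of squares
    lambda_boundary: bool = False
    lambda_mode: str = "fixed"
    dropped_terms: list[str] = field(default_factory=list)

    def summary_rows(self) -> list[dict]:
        return [
            {
                "effect": name,
                "estimate": float(b),
                "SE": float(s),
                "t": float(tv),
                "p": float(pv),
            }
            for name, b, s, tv, pv in zip(self.terms, self.beta, self.se, self.t, self.p)
        ]


def _whiten(V: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError as e:
        raise ValueError("lambda-transformed covariance is not positive definite") from e


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    terms: list[str] | None = None,
    lam: float = np.nan,
) -> PGLSFit:
    """GLS via Cholesky whitening: beta = (X'V^-1 X)^-1 X'V^-1 y.

    SEs use sigma^2_unbiased = RSS_V / (n - p); the reported log-likelihood
    is the ML profile (sigma^2_ML = RSS_V / n). R^2 compares RSS_V against
    the intercept-only GLS fit under the same V.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} rows but {p} parameters")
    L = _whiten(V)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    xtx = Xw.T @ Xw
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"singular design (cond={cond:.3g}); collinear columns among {terms}")
    beta = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2_hat = rss / dof
    cov_beta = sigma2_hat * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * scipy.stats.t.sf(np.abs(tvals), dof)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + n + logdetV)
    # intercept-only baseline under the same V
    ones_w = scipy.linalg.solve_triangular(L, np.ones(n), lower=True)
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(((yw - mu * ones_w) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return PGLSFit(
        terms=list(terms) if terms is not None else [f"x{j}" for j in range(p)],
        beta=beta,
        se=se,
        t=tvals,
        p=pvals,
        lam=float(lam),
        sigma2=sigma2_ml,
        loglik=loglik,
        r2=r2,
        n=n,
        rss=rss,
    )


def _profile_loglik(lam: float, y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    try:
        return gls_fit(y, X, lambda_transform(C, lam), lam=lam).loglik
    except ValueError:
        return -np.inf


def fit_lambda_ml(
    y: np.ndarray,
    X: np.ndarray,
    C: np.ndarray,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
    terms: list[str] | None = None,
    tol: float = 1e-6,
) -> PGLSFit:
    """Profile maximum likelihood for Pagel's lambda by bounded 1-D search.

    The bounded optimum is compared against both bounds (the profile can be
    monotone); boundary hits are flagged, and a lambda estimate at the lower
    bound is reported as 0 in downstream tables.
    """
    lo, hi = bounds
    res = scipy.optimize.minimize_scalar(
        lambda lam: -_profile_loglik(lam, y, X, C),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [lo, float(res.x), hi]
    lls = [_profile_loglik(lam, y, X, C) for lam in candidates]
    if not any(np.isfinite(ll) for ll in lls):
        raise ValueError("non-finite likelihood across the lambda range")
    best = int(np.argmax(lls))
    lam_hat = candidates[best]
    fit = gls_fit(y, X, lambda_transform(C, lam_hat), terms=terms, lam=lam_hat)
    fit.lambda_boundary = best != 1 or abs(lam_hat - lo) < 10 * tol or abs(lam_hat - hi) < 10 * tol
    fit.lambda_mode = "ml"
    return fit


def _term_deletion_pvalues(
    y: np.ndarray, X: np.ndarray, V: np.ndarray, terms: list[str]
) -> dict[str, float]:
    """F-test p-value for deleting each non-intercept column, nested at a
    common V (lambda held fixed within one elimination step)."""
    full = gls_fit(y, X, V, terms=terms)
    n, p = X.shape
    out = {}
    for j, name in enumerate(terms):
        if name == "(Intercept)":
            continue
        keep = [c for c in range(p) if c != j]
        red = gls_fit(y, X[:, keep], V, terms=[terms[c] for c in keep])
        f = (red.rss - full.rss) / (full.rss / (n - p))
        out[name] = float(scipy.stats.f.sf(max(f, 0.0), 1, n - p))
    return out


def anova_reduce(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[str],
    C: np.ndarray,
    lambda_mode: str = "ml",
    fixed_lambda: float = 0.001,
    alpha: float = 0.1,
) -> PGLSFit:
    """Backward elimination of LD terms by term-deletion F-tests.

    At each step the single worst term with p >= alpha is dropped and the
    model refit (re-optimizing lambda between steps in ML mode). If every
    LD is dropped the intercept-only fit is returned, flagged via
    `dropped_terms` covering all candidates.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    terms = list(terms)
    if "(Intercept)" not in terms:
        raise ValueError("design must include an (Intercept) column")
    dropped: list[str] = []

    def _fit(Xc: np.ndarray, tc: list[str]) -> PGLSFit:
        if lambda_mode == "ml":
            return fit_lambda_ml(y, Xc, C, terms=tc)
        fit = gls_fit(y, Xc, lambda_transform(C, fixed_lambda), terms=tc, lam=fixed_lambda)
        fit.lambda_mode = "fixed"
        return fit

    while True:
        current = _fit(X, terms)
        ld_terms = [t for t in terms if t != "(Intercept)"]
        if not ld_terms:
            current.dropped_terms = dropped
            return current
        pvals = _term_deletion_pvalues(y, X, lambda_transform(C, current.lam), terms)
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            current.dropped_terms = dropped
            return current
        j = terms.index(worst)
        X = np.delete(X, j, axis=1)
        terms.pop(j)
        dropped.append(worst)
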