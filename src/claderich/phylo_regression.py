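"""OLS and phylogenetic generalized least squares with Pagel's lambda.

Under Brownian-motion evolution the covariance of a trait across the tips
of a tree is proportional to shared root-to-tip path length.  PGLS fits a
linear model whose error covariance is that matrix, optionally shrunk
toward a star phylogeny by Pagel's lambda (a multiplier on the
off-diagonal entries, profiled by maximum likelihood over [0, 1]).  The
tree-transform parameters delta and kappa are fixed at 1.

The coefficient of determination for GLS fits is computed on the whitened
scale against the GLS-fitted intercept-only null under the same
covariance — the conventional GLS r^2.  An OLS-style r^2 on the raw
residuals is also recorded (``r_squared_ols_scale``) since published
analyses are not always explicit about which definition they report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .tree_io import TimeTree


@dataclass
class RegressionResult:
    """Coefficients and fit summaries for one linear model."""

    coefficients: np.ndarray          # intercept first, then slopes
    std_errors: np.ndarray
    r_squared: float
    adjusted_r_squared: float
    p_values: np.ndarray              # two-sided, aligned with coefficients
    model_p_value: float              # F-test against intercept-only null
    n_obs: int
    log_likelihood: float
    lambda_pagel: float | None = None
    r_squared_ols_scale: float = field(default=np.nan)

    @property
    def slope_p_values(self) -> np.ndarray:
        return self.p_values[1:]


def phylo_covariance(
    tree: TimeTree, tip_order: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of a (reduced) tree.

    Entry (i, j) is the shared root-to-tip path length of tips i and j in
    Myr; the diagonal holds each tip's root-to-tip distance (constant for
    an ultrametric tree).  Returns (matrix, tip order used).
    """
    labels = tip_order if tip_order is not None else sorted(tree.tip_labels)
    n = len(labels)
    if n < 3:
        raise ValueError("phylogenetic covariance requires at least 3 tips")
    index = {lab: i for i, lab in enumerate(labels)}
    depths = tree.root_to_tip_distances()
    missing = [lab for lab in labels if lab not in depths]
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    root_depth = tree.node_depths()[tree.root_id]

    C = np.zeros((n, n))
    for lab in labels:
        C[index[lab], index[lab]] = depths[lab]
    # shared path of i,j = depth of their MRCA measured from the root
    # = root_age - mrca_age on an ultrametric tree; computed bottom-up.
    node_depth = tree.node_depths()
    below: dict[int, list[int]] = {}
    for nd in tree._dtree.postorder_node_iter():
        if nd.is_leaf():
            below[nd.cr_id] = (
                [index[nd.taxon.label]] if nd.taxon.label in index else []
            )
            continue
        kids = [below[ch.cr_id] for ch in nd.child_nodes()]
        shared = root_depth - node_depth[nd.cr_id]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        C[i, j] = C[j, i] = shared
        below[nd.cr_id] = [i for k in kids for i in k]

    eig_min = float(np.linalg.eigvalsh(C).min())
    if eig_min < -1e-8 * np.trace(C):
        raise ValueError(
            f"covariance matrix is not PSD (min eigenvalue {eig_min:g})"
        )
    return C, labels


def pagel_transform(C: np.ndarray, lambda_pagel: float) -> np.ndarray:
    """Multiply off-diagonal entries of C by lambda, keeping the diagonal."""
    if not (0 <= lambda_pagel <= 1):
        raise ValueError(f"lambda must be in [0, 1], got {lambda_pagel}")
    out = lambda_pagel * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.column_stack([np.ones(len(x)), x])


def gls_fit(x: np.ndarray, y: np.ndarray, C: np.ndarray) -> RegressionResult:
    """Generalized least squares with known error covariance C.

    ``x`` holds the predictor column(s) without intercept; an intercept is
    prepended.  beta = (X' C^-1 X)^-1 X' C^-1 y, computed via Cholesky
    whitening.  Slope p-values are two-sided t with n - p - 1 df; r^2 is
    measured on the whitened scale against the GLS intercept-only null.
    """
    X = _design(x)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n != len(y) or n != C.shape[0]:
        raise ValueError("x, y and C dimensions do not align")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")
    try:
        L = linalg.cholesky(C, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(
            f"singular covariance matrix (cond={np.linalg.cond(C):.3g})"
        ) from exc
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)

    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    df_resid = n - k
    sigma2 = rss / df_resid if df_resid > 0 else np.nan
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p_values = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    # intercept-only GLS null under the same covariance
    ones_w = Xw[:, 0]
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    null_resid = yw - ones_w * mu
    tss = float(null_resid @ null_resid)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    p_slopes = k - 1
    adj = (
        1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
    )
    if p_slopes > 0 and rss > 0:
        F = ((tss - rss) / p_slopes) / (rss / df_resid)
        model_p = float(stats.f.sf(F, p_slopes, df_resid))
    else:
        model_p = np.nan

    sigma2_ml = rss / n
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_C + n)

    # OLS-style r^2 on the raw (unwhitened) residual scale, for reference
    resid_raw = y - X @ beta
    tss_raw = float(np.sum((y - y.mean()) ** 2))
    r2_raw = 1.0 - float(resid_raw @ resid_raw) / tss_raw if tss_raw > 0 else 0.0

    return RegressionResult(
        coefficients=beta,
        std_errors=se,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        adjusted_r_squared=float(adj),
        p_values=p_values,
        model_p_value=model_p,
        n_obs=n,
        log_likelihood=float(ll),
        r_squared_ols_scale=float(r2_raw),
    )


def ols_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares (identity covariance); lambda not defined."""
    n = len(np.asarray(y))
    return gls_fit(x, y, np.eye(n))


def pgls_fit(
    x: np.ndarray,
    y: np.ndarray,
    reduced_tree: TimeTree | None = None,
    C: np.ndarray | None = None,
    tip_order: list[str] | None = None,
) -> RegressionResult:
    """PGLS with Pagel's lambda profiled by maximum likelihood over [0, 1].

    The covariance substrate is taken from ``reduced_tree`` (one tip per
    clade; rows of ``x``/``y`` must follow ``tip_order``) or passed
    directly as ``C``.  The profile is optimized by bounded scalar search
    (tolerance 1e-6) and checked against both endpoints.
    """
    if C is None:
        if reduced_tree is None:
            raise ValueError("provide either reduced_tree or C")
        C, _ = phylo_covariance(reduced_tree, tip_order=tip_order)
    if len(np.asarray(y)) < 4:
        raise ValueError("PGLS requires at least 4 observations")

    def negll(lam: float) -> float:
        return -gls_fit(x, y, pagel_transform(C, lam)).log_likelihood

    res = optimize.minimize_scalar(
        negll, bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"lambda profile optimization failed: {res}")
    candidates = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, float(res.x))]
    _, lam_hat = min(candidates, key=lambda t: t[0])
    out = gls_fit(x, y, pagel_transform(C, lam_hat))
    out.lambda_pagel = lam_hat
    return out
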