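"""Consolidating AUCs across deciles, states and contrasts.

AUC estimates are first "squeezed" toward 0.5 to keep them off the [0, 1]
boundary, then logit transformed.  Per-decile (and, for the sedation arm,
per-state) summaries come from a generalized least squares fit whose
weight matrix is the inverse of the bootstrap-replicate covariance of the
logit AUCs — a full covariance matrix, not the diagonal of weighted least
squares, so the dependence between deciles is accounted for.  The
across-contrast consolidation stacks per-contrast blocks with a
block-diagonal covariance (fixed-effect pooling; heterogeneity is
reported descriptively as the SD of per-contrast slopes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit as _logit

__all__ = [
    "SqueezeParams",
    "GlsModel",
    "DesignSpec",
    "MetaSummary",
    "squeeze_auc",
    "logit_transform",
    "inv_logit",
    "squeezed_logit",
    "build_state_decile_design",
    "gls_fit",
    "meta_summary",
]


@dataclass
class SqueezeParams:
    """n_brains = twice the number of participants in the contrast."""

    n_brains: int

    def __post_init__(self) -> None:
        if self.n_brains < 2:
            raise ValueError("n_brains must be >= 2")


def squeeze_auc(theta, params: SqueezeParams | int):
    """Shrink AUC toward 0.5: theta* = ((n - 1) theta + 0.5) / n."""
    n = params.n_brains if isinstance(params, SqueezeParams) else SqueezeParams(params).n_brains
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    out = ((n - 1) * theta + 0.5) / n
    return float(out) if out.ndim == 0 else out


def logit_transform(p):
    """ln(p / (1 - p)); requires p strictly inside (0, 1) (squeeze first)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("logit requires values strictly inside (0, 1)")
    out = _logit(p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def squeezed_logit(theta, n_brains: int):
    """Convenience composition used on bootstrap replicate matrices."""
    return logit_transform(squeeze_auc(theta, n_brains))


@dataclass
class DesignSpec:
    states: list[str]
    deciles: np.ndarray
    rows: list[tuple[str, int]]          # (state, decile) per design row
    columns: list[str]                   # 2 * n_states labels


@dataclass
class GlsModel:
    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    columns: list[str] | None = None


@dataclass
class MetaSummary:
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    per_contrast_slopes: np.ndarray
    heterogeneity_sd: float


def build_state_decile_design(
    states: list[str], deciles=range(1, 11)
) -> tuple[DesignSpec, np.ndarray]:
    """Kronecker design [1, decile-1] x state indicators.

    One row per (state, decile); columns are a per-state intercept
    (the decile-1 value, since the slope covariate is centered at
    decile = 1) followed by a per-state slope on (decile - 1).
    """
    if not states:
        raise ValueError("need at least one state")
    deciles = np.asarray(list(deciles), dtype=int)
    n_states = len(states)
    rows = [(s, int(d)) for s in states for d in deciles]
    X = np.zeros((len(rows), 2 * n_states))
    for r, (s, d) in enumerate(rows):
        j = states.index(s)
        X[r, j] = 1.0
        X[r, n_states + j] = d - 1
    columns = [f"intercept[{s}]" for s in states] + [f"slope[{s}]" for s in states]
    spec = DesignSpec(states=list(states), deciles=deciles, rows=rows, columns=columns)
    return spec, X


def _regularize(sigma: np.ndarray, eps_scale: float = 1e-8) -> np.ndarray:
    """Ridge the covariance when its smallest eigenvalue is below
    eps = eps_scale * mean(diag)."""
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    sigma = 0.5 * (sigma + sigma.T)
    eps = eps_scale * float(np.mean(np.diag(sigma)))
    if eps <= 0:
        eps = eps_scale
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < eps:
        sigma = sigma + (eps - min(min_eig, 0.0)) * np.eye(sigma.shape[0])
    return sigma


def gls_fit(
    y: np.ndarray,
    X: np.ndarray,
    sigma_hat: np.ndarray,
    columns: list[str] | None = None,
) -> GlsModel:
    """GLS with known covariance: W = Sigma^-1,
    beta = (X'WX)^-1 X'Wy, SE = sqrt(diag((X'WX)^-1)).

    The sandwich covariance collapses to (X'WX)^-1 exactly because the
    weight matrix is the inverse of the assumed error covariance.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X are not conformable")
    sigma = _regularize(sigma_hat)
    if sigma.shape[0] != y.shape[0]:
        raise ValueError("Sigma_hat and y are not conformable")
    W = np.linalg.inv(sigma)
    XtWX = X.T @ W @ X
    if np.linalg.matrix_rank(XtWX) < XtWX.shape[0]:
        bad = _collinear_columns(X, columns)
        raise np.linalg.LinAlgError(f"X'WX is singular; collinear columns: {bad}")
    XtWX_inv = np.linalg.inv(XtWX)
    beta = XtWX_inv @ X.T @ W @ y
    se = np.sqrt(np.diag(XtWX_inv))
    return GlsModel(y=y, X=X, W=W, beta_hat=beta, se=se, columns=columns)


def _collinear_columns(X: np.ndarray, columns: list[str] | None) -> list[str]:
    names = columns or [f"col{j}" for j in range(X.shape[1])]
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[j] for j in range(X.shape[1]) if diag[j] <= tol]


def meta_summary(
    auc_tables: list[np.ndarray],
    covariances: list[np.ndarray],
    n_brains: list[int] | None = None,
    pre_transformed: bool = False,
) -> MetaSummary:
    """Fixed-effect pooling of per-contrast decile curves.

    Each contrast supplies one AUC per decile plus the replicate
    covariance of its (squeezed, logit) AUCs.  Contrast blocks are
    stacked with a block-diagonal covariance and fit with a common
    intercept (decile 1) and a common linear decile slope on the logit
    scale.  Per-contrast slopes are also fit separately to report
    between-contrast heterogeneity descriptively.
    """
    if len(auc_tables) != len(covariances):
        raise ValueError("need one covariance per contrast")
    n_deciles = len(np.asarray(auc_tables[0]).ravel())
    ys, blocks = [], []
    for i, (aucs, cov) in enumerate(zip(auc_tables, covariances)):
        aucs = np.asarray(aucs, dtype=float).ravel()
        if aucs.size != n_deciles:
            raise ValueError("mismatched decile grids across contrasts")
        if pre_transformed:
            ys.append(aucs)
        else:
            if n_brains is None:
                raise ValueError("n_brains required when passing raw AUCs")
            ys.append(squeezed_logit(aucs, n_brains[i]))
        blocks.append(_regularize(cov))
    y = np.concatenate(ys)
    from scipy.linalg import block_diag

    sigma = block_diag(*blocks)
    dec = np.arange(1, n_deciles + 1, dtype=float)
    x_dec = np.tile(dec - 1, len(auc_tables))
    X = np.column_stack([np.ones_like(x_dec), x_dec])
    fit = gls_fit(y, X, sigma, columns=["intercept", "slope"])

    slopes = []
    for yi, cov in zip(ys, blocks):
        Xi = np.column_stack([np.ones(n_deciles), dec - 1])
        slopes.append(gls_fit(yi, Xi, cov).beta_hat[1])
    slopes = np.asarray(slopes)
    het = float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0
    return MetaSummary(
        intercept=float(fit.beta_hat[0]),
        slope=float(fit.beta_hat[1]),
        se_intercept=float(fit.se[0]),
        se_slope=float(fit.se[1]),
        per_contrast_slopes=slopes,
        heterogeneity_sd=het,
    )
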