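"""Restricted maximum likelihood for small Gaussian mixed models.

The phenotype models used here have one or two crossed random effects on
top of a fixed-effect design, so a general sparse mixed-model machine is
unnecessary.  The engine profiles the residual variance analytically and
optimizes the restricted likelihood over the variance ratio(s)
``lambda_i = sigma2_i / sigma2_e``:

* one random effect -> bounded 1-D search on ``log lambda`` (ratio bounded
  in [1e-8, 1e8], tolerance 1e-8);
* several random effects -> Nelder-Mead on the vector of log ratios.

All solves use the Woodbury identity, so the cost is O(n q^2) for n
observations and q random-effect levels; n up to ~1e5 with small q is fine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

LOG_RATIO_LO = np.log(1e-8)
LOG_RATIO_HI = np.log(1e8)


@dataclass
class REMLResult:
    """Fitted mixed model with profiled variance components."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_resid: float
    sigma2_random: dict = field(default_factory=dict)
    loglik: float = np.nan
    df_resid: int = 0
    degenerate: bool = False


def _profiled(y, X, Zs, log_lams):
    """Restricted log-likelihood with sigma2_e profiled out.

    Returns (loglik, beta, XtVinvX, sigma2_e).  ``XtVinvX`` is in units of
    1/sigma2_e, i.e. cov(beta) = sigma2_e * inv(XtVinvX).
    """
    n, p = X.shape
    lams = np.exp(np.clip(log_lams, LOG_RATIO_LO, LOG_RATIO_HI))
    if Zs:
        U = np.hstack([np.sqrt(l) * Z for l, Z in zip(lams, Zs)])
        q = U.shape[1]
        A = np.eye(q) + U.T @ U
        cf = cho_factor(A)
        logdet_V0 = 2.0 * np.sum(np.log(np.diag(cf[0])))

        def vinv(B):
            return B - U @ cho_solve(cf, U.T @ B)
    else:
        logdet_V0 = 0.0

        def vinv(B):
            return B

    VX = vinv(X)
    Vy = vinv(y)
    XtVX = X.T @ VX
    Xty = X.T @ Vy
    cfx = cho_factor(XtVX)
    beta = cho_solve(cfx, Xty)
    quad = float(y @ Vy - Xty @ beta)
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom for REML")
    sigma2 = max(quad / df, 0.0)
    logdet_XtVX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    if sigma2 <= 0.0 or not np.isfinite(sigma2):
        # all-residuals-zero degenerate fit
        return np.inf, beta, XtVX, 0.0
    ll = -0.5 * (df * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_V0 + logdet_XtVX)
    return ll, beta, XtVX, sigma2


def reml_fit(y, X, Zs=(), names=()):
    """REML fit of ``y = X beta + sum_i Z_i u_i + e``.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design (must be full column rank)
    Zs : sequence of (n, q_i) random-effect indicator matrices
    names : labels for the random effects (for the variance dict)
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Zs = [np.asarray(Z, dtype=float) for Z in Zs]
    names = list(names) if names else [f"z{i}" for i in range(len(Zs))]
    n, p = X.shape

    if not Zs:
        ll, beta, XtVX, sigma2 = _profiled(y, X, [], np.empty(0))
        return _finalize(ll, beta, XtVX, sigma2, [], names, n, p)

    if len(Zs) == 1:
        res = optimize.minimize_scalar(
            lambda t: -_profiled(y, X, Zs, np.array([t]))[0],
            bounds=(LOG_RATIO_LO, LOG_RATIO_HI),
            method="bounded",
            options={"xatol": 1e-8},
        )
        opt = np.array([res.x])
    else:
        x0 = np.zeros(len(Zs))
        res = optimize.minimize(
            lambda t: -_profiled(y, X, Zs, t)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        opt = np.clip(res.x, LOG_RATIO_LO, LOG_RATIO_HI)

    ll, beta, XtVX, sigma2 = _profiled(y, X, Zs, opt)
    return _finalize(ll, beta, XtVX, sigma2, np.exp(opt), names, n, p)


def _finalize(ll, beta, XtVX, sigma2, lams, names, n, p):
    degenerate = not np.isfinite(ll)
    cov = sigma2 * np.linalg.inv(XtVX) if sigma2 > 0 else np.zeros_like(XtVX)
    # ratios pinned at the lower bound are boundary solutions: variance -> 0
    sig_rand = {
        nm: (0.0 if lam <= 1.5e-8 else float(lam * sigma2))
        for nm, lam in zip(names, lams)
    }
    return REMLResult(
        beta=beta,
        cov_beta=cov,
        sigma2_resid=float(sigma2),
        sigma2_random=sig_rand,
        loglik=float(ll) if np.isfinite(ll) else np.nan,
        df_resid=n - p,
        degenerate=degenerate,
    )


def indicator(labels) -> np.ndarray:
    """Dense 0/1 indicator matrix for a label vector (columns sorted)."""
    labels = np.asarray(labels)
    cats = np.unique(labels)
    return (labels[:, None] == cats[None, :]).astype(float)
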