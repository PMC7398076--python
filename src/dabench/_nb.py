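"""Vectorized negative-binomial and zero-inflated NB fitting machinery.

All routines operate on a features x samples count matrix ``Y`` and are
vectorized across features.  The NB is parameterized by its mean ``mu`` and
dispersion ``phi`` (variance = mu + phi * mu^2); ``phi = 0`` is the Poisson
limit.  Means follow a log link with per-sample offsets, so for an
intercept-only model ``mu_fj = exp(beta_f + offset_j)``.

These primitives back the goodness-of-fit module, the edgeR-style DA
methods, the ZINB observational weights and the parametric simulator.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_PHI_MIN = 1e-8
_LOG_PHI_LO, _LOG_PHI_HI = -12.0, 6.0


def nb_logpmf(Y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Elementwise NB(mu, phi) log pmf; phi may be scalar or (F, 1)."""
    mu = np.maximum(mu, 1e-12)
    phi = np.maximum(np.asarray(phi, dtype=float), 0.0)
    if np.all(phi < _PHI_MIN):
        return Y * np.log(mu) - mu - gammaln(Y + 1.0)
    phi = np.maximum(phi, _PHI_MIN)
    alpha = 1.0 / phi  # NB size parameter
    return (
        gammaln(Y + alpha)
        - gammaln(alpha)
        - gammaln(Y + 1.0)
        + alpha * np.log(alpha / (alpha + mu))
        + Y * np.log(mu / (alpha + mu))
    )


def nb_zero_prob(mu: np.ndarray, phi) -> np.ndarray:
    """P(Y = 0) under NB(mu, phi); Poisson limit exp(-mu) as phi -> 0."""
    phi = np.asarray(phi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.empty(np.broadcast(mu, phi).shape)
    small = np.broadcast_to(phi < _PHI_MIN, out.shape)
    mu_b = np.broadcast_to(mu, out.shape)
    phi_b = np.broadcast_to(np.maximum(phi, _PHI_MIN), out.shape)
    out[small] = np.exp(-mu_b[small])
    ns = ~small
    out[ns] = np.exp(-np.log1p(phi_b[ns] * mu_b[ns]) / phi_b[ns])
    return out


def fit_nb_intercept(
    Y: np.ndarray,
    offset: np.ndarray,
    phi=None,
    common_dispersion: bool = False,
    weights: np.ndarray | None = None,
    maxiter: int = 50,
):
    """Intercept-only NB ML fit per feature with log offsets.

    Returns ``(beta, phi, mu)`` where ``beta`` is (F,), ``phi`` is scalar
    (common) or (F,) and ``mu`` is the (F, n) fitted mean matrix.  When
    ``phi`` is passed it is held fixed.
    """
    Y = np.asarray(Y, dtype=float)
    F, n = Y.shape
    if weights is None:
        weights = np.ones_like(Y)
    # closed-form start: weighted mean on the offset scale
    s = np.exp(offset)[None, :]
    beta = np.log(
        np.maximum((weights * Y).sum(1), 0.5) / (weights * s).sum(1)
    )
    if phi is None:
        # alternate beta | phi and phi | beta
        phi_cur = np.full(1 if common_dispersion else F, 0.1)
        for _ in range(4):
            beta = _newton_beta(Y, beta, offset, phi_cur, weights, maxiter)
            mu = np.exp(beta[:, None] + offset[None, :])
            phi_cur = _ml_dispersion(Y, mu, weights, common=common_dispersion)
        phi = phi_cur if not common_dispersion else float(np.atleast_1d(phi_cur)[0])
    beta = _newton_beta(Y, beta, offset, phi, weights, maxiter)
    mu = np.exp(beta[:, None] + offset[None, :])
    return beta, phi, mu


def _phi_col(phi, F):
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        return np.full((F, 1), float(phi))
    return phi.reshape(-1, 1)


def _newton_beta(Y, beta, offset, phi, weights, maxiter=50, tol=1e-10):
    F, n = Y.shape
    phi_c = _phi_col(phi, F)
    beta = beta.copy()
    for _ in range(maxiter):
        mu = np.exp(np.clip(beta[:, None] + offset[None, :], -700, 700))
        denom = 1.0 + phi_c * mu
        score = (weights * (Y - mu) / denom).sum(1)
        info = (weights * mu / denom).sum(1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _ml_dispersion(Y, mu, weights, common=False, lo=_LOG_PHI_LO, hi=_LOG_PHI_HI):
    """Golden-section ML of log-dispersion given fitted means.

    Vectorized across features for per-feature dispersion; scalar search on
    the pooled likelihood when ``common`` is True.
    """
    F = Y.shape[0]

    def negll(logphi):
        phi = np.exp(logphi)
        if common:
            ll = (weights * nb_logpmf(Y, mu, phi)).sum()
            return -ll
        ll = (weights * nb_logpmf(Y, mu, phi.reshape(-1, 1))).sum(1)
        return -ll

    if common:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        return np.array([np.exp(res.x)])
    a = np.full(F, lo)
    b = np.full(F, hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(50):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = negll(c), negll(d)
        left = fc < fd  # minimum lies in [a, d]
        b = np.where(left, d, b)
        a = np.where(left, a, c)
    return np.exp((a + b) / 2.0)


# -- general small-design NB GLM (vectorized over features) -------------------

def fit_nb_glm(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi,
    weights: np.ndarray | None = None,
    maxiter: int = 50,
    tol: float = 1e-8,
):
    """NB GLM with log link for every feature at once.

    Parameters
    ----------
    Y : (F, n) counts; X : (n, p) design; offset : (n,) log offsets;
    phi : scalar or (F,) dispersions; weights : optional (F, n) prior
    observation weights.

    Returns dict with ``beta`` (F, p), ``mu`` (F, n), ``loglik`` (F,),
    ``cov`` (F, p, p) inverse Fisher information, and ``converged`` (F,).
    """
    Y = np.asarray(Y, dtype=float)
    F, n = Y.shape
    p = X.shape[1]
    if weights is None:
        weights = np.ones_like(Y)
    phi_c = _phi_col(phi, F)

    beta = np.zeros((F, p))
    beta[:, 0] = np.log(np.maximum(Y.mean(1), 0.5)) - np.log(np.exp(offset).mean())
    converged = np.zeros(F, dtype=bool)
    ll_old = np.full(F, -np.inf)
    for _ in range(maxiter):
        eta = np.clip(beta @ X.T + offset[None, :], -700, 30)
        mu = np.exp(eta)
        W = weights * mu / (1.0 + phi_c * mu)  # Fisher weights
        z = eta - offset[None, :] + (Y - mu) / np.maximum(mu, 1e-12)
        XtWX = np.einsum("np,fn,nq->fpq", X, W, X)
        XtWX += 1e-8 * np.eye(p)[None, :, :]
        XtWz = np.einsum("np,fn,fn->fp", X, W, z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.clip(new - beta, -3, 3)
        beta = beta + delta
        eta = np.clip(beta @ X.T + offset[None, :], -700, 30)
        mu = np.exp(eta)
        ll = (weights * nb_logpmf(Y, mu, phi_c)).sum(1)
        converged = np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0)
        if converged.all():
            break
        ll_old = ll
    W = weights * mu / (1.0 + phi_c * mu)
    XtWX = np.einsum("np,fn,nq->fpq", X, W, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(XtWX)
    return {"beta": beta, "mu": mu, "loglik": ll, "cov": cov, "converged": converged}


def estimate_dispersion_trended(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    prior_df: float = 10.0,
    robust: bool = False,
):
    """Per-feature ML dispersion shrunk toward a lowess mean-dispersion trend.

    The shrinkage is a prior-df weighted average on the log scale:
    ``log phi_shrunk = (prior_df * trend + df * mle) / (prior_df + df)``
    with ``df = n - p``.  With ``robust=True`` the raw per-feature ML values
    are returned (no shrinkage), mimicking the liberal behavior of robust
    per-feature dispersion estimation.
    """
    Y = np.asarray(Y, dtype=float)
    F, n = Y.shape
    p = X.shape[1]
    # pilot fit at a moderate dispersion to get means
    fit = fit_nb_glm(Y, X, offset, 0.1, maxiter=25)
    mu = np.maximum(fit["mu"], 1e-8)
    phi_ml = _ml_dispersion(Y, mu, np.ones_like(Y), common=False)
    phi_ml = np.clip(phi_ml, 1e-6, 100.0)
    if robust:
        return phi_ml
    logmean = np.log(np.maximum(Y.mean(1), 1e-8))
    trend = _lowess_trend(logmean, np.log(phi_ml))
    df = max(n - p, 1)
    logphi = (prior_df * trend + df * np.log(phi_ml)) / (prior_df + df)
    return np.exp(logphi)


def _lowess_trend(x: np.ndarray, y: np.ndarray, frac: float = 0.5) -> np.ndarray:
    import statsmodels.api as sm

    if len(np.unique(x)) < 5:
        return np.full_like(y, y.mean())
    fitted = sm.nonparametric.lowess(y, x, frac=frac, return_sorted=False)
    # guard against NaN from degenerate windows
    bad = ~np.isfinite(fitted)
    if bad.any():
        fitted[bad] = y.mean()
    return fitted


# -- ZINB ---------------------------------------------------------------------

def fit_zinb(
    Y: np.ndarray,
    offset: np.ndarray,
    common_dispersion: bool = True,
    epsilon: float = 1e10,
    maxiter: int = 60,
    tol: float = 1e-6,
):
    """Intercept-only ZINB fit via EM with a common (or per-feature) dispersion.

    Model per cell: with probability ``pi_f`` a structural zero, else
    NB(mu_fj, phi) with ``mu_fj = exp(beta_f + offset_j)``.  With an
    intercept-only mean model, no latent factors and a common dispersion the
    ridge penalty (``epsilon``) of the penalized formulation vanishes, so
    this is plain ML; the argument is accepted for interface stability.

    Returns dict with ``beta`` (F,), ``pi`` (F,), ``phi`` (scalar or (F,)),
    ``mu`` (F, n), ``loglik`` (F,) observed-data log-likelihoods and
    ``converged`` (F,).
    """
    del epsilon  # no-op under intercept-only / common dispersion (see docstring)
    Y = np.asarray(Y, dtype=float)
    F, n = Y.shape
    zeros = Y == 0
    zf = zeros.mean(1)
    pi = np.clip(0.5 * zf, 1e-6, 1 - 1e-6)
    beta, phi, mu = fit_nb_intercept(Y, offset, common_dispersion=True)
    phi = np.atleast_1d(phi)[0] if common_dispersion else np.full(F, float(np.atleast_1d(phi)[0]))
    ll_old = -np.inf
    converged = np.zeros(F, dtype=bool)
    for _ in range(maxiter):
        phi_c = _phi_col(phi if not common_dispersion else np.array(phi), F)
        nb0 = nb_zero_prob(mu, phi_c)
        # E-step: posterior probability a zero cell is structural
        denom = pi[:, None] + (1.0 - pi[:, None]) * nb0
        z = np.where(zeros, pi[:, None] / np.maximum(denom, 1e-300), 0.0)
        # M-step
        pi = np.clip(z.mean(1), 1e-8, 1 - 1e-8)
        w = 1.0 - z
        beta = _newton_beta(Y, beta, offset, phi, w, maxiter=25)
        mu = np.exp(beta[:, None] + offset[None, :])
        phi_new = _ml_dispersion(Y, mu, w, common=common_dispersion)
        phi = float(phi_new[0]) if common_dispersion else phi_new
        ll = zinb_loglik(Y, mu, pi, phi if not common_dispersion else np.array(phi))
        total = ll.sum()
        rel = abs(total - ll_old) / (abs(total) + 1.0)
        ll_old = total
        if rel < tol:
            converged[:] = True
            break
    # near-convergence at iteration cap still yields usable estimates
    if not converged.any() and rel < 1e-4:
        converged[:] = True
    return {
        "beta": beta,
        "pi": pi,
        "phi": phi,
        "mu": mu,
        "loglik": ll,
        "converged": converged,
    }


def zinb_loglik(Y, mu, pi, phi):
    phi_c = _phi_col(phi, Y.shape[0])
    logp_nb = nb_logpmf(Y, mu, phi_c)
    zeros = Y == 0
    pi_c = np.asarray(pi).reshape(-1, 1)
    mix = np.where(
        zeros,
        np.log(np.maximum(pi_c + (1 - pi_c) * np.exp(logp_nb), 1e-300)),
        np.log1p(-pi_c) + logp_nb,
    )
    return mix.sum(1)


def zinb_zero_prob(mu, pi, phi):
    """Marginal P(Y = 0) = pi + (1 - pi) * NB0."""
    phi_c = _phi_col(phi, np.asarray(mu).shape[0])
    nb0 = nb_zero_prob(mu, phi_c)
    pi_c = np.asarray(pi).reshape(-1, 1)
    return pi_c + (1 - pi_c) * nb0
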