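"""Per-feature fits of five candidate count models and goodness-of-fit scoring.

Five distributions commonly assumed by differential-abundance methods are fit
per feature under a homogeneous-samples (intercept-only) design:

* ``NB``     — negative binomial on raw counts with library-size offsets;
* ``ZINB``   — zero-inflated NB with a common dispersion (EM);
* ``ZIG``    — zero-inflated Gaussian mixture on log2(count+1) with CSS
  offsets and a logistic zero-rate on log library size;
* ``HURDLE`` — two-part model: logistic detection rate with a detection-rate
  (CDR) covariate plus a Gaussian on the positive log-scale counts;
* ``DM``     — Dirichlet-multinomial on the per-sample composition.

Each fit reports, per feature, an estimated mean count and an estimated zero
probability.  Goodness of fit is scored as the RMSE across features of the
mean difference (MD, on the log2(mean+1) scale) and of the zero-probability
difference (ZPD, model P(0) minus observed zero frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from . import _nb
from .core import CountTable, zero_fraction
from .norm import NormFactors, transform_counts

__all__ = ["FitResult", "GofSummary", "fit_model", "gof_summary", "rank_models"]

MODELS = ("NB", "ZINB", "ZIG", "HURDLE", "DM")


@dataclass
class FitResult:
    """Per-feature estimates for one model on one table."""

    model: str
    feature_ids: pd.Index
    est_mean: np.ndarray          # per-feature mean, on the scale in `mean_scale`
    zero_prob: np.ndarray         # per-feature P(zero), in [0, 1]
    mean_scale: str               # "count" or "log2p1"
    params: dict = field(default_factory=dict)
    converged: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.converged is None:
            self.converged = np.ones(len(self.feature_ids), dtype=bool)
        zp = np.asarray(self.zero_prob)
        if np.any((zp[np.isfinite(zp)] < -1e-9) | (zp[np.isfinite(zp)] > 1 + 1e-9)):
            raise ValueError("zero_prob outside [0, 1]: model fit bug")
        self.zero_prob = np.clip(zp, 0.0, 1.0)

    def mean_log2p1(self) -> np.ndarray:
        """Estimated mean on the log2(mean + 1) comparison scale."""
        if self.mean_scale == "log2p1":
            return np.asarray(self.est_mean, dtype=float)
        return np.log2(np.asarray(self.est_mean, dtype=float) + 1.0)


@dataclass
class GofSummary:
    model: str
    md: pd.Series      # per-feature estimated - observed mean (log2(.+1) scale)
    zpd: pd.Series     # per-feature model P(0) - observed zero frequency
    n_excluded: int    # non-converged features excluded from the RMSEs

    @property
    def rmse_mean(self) -> float:
        return float(np.sqrt(np.mean(self.md.dropna() ** 2)))

    @property
    def rmse_zpd(self) -> float:
        return float(np.sqrt(np.mean(self.zpd.dropna() ** 2)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"MD": self.md, "ZPD": self.zpd})


def fit_model(
    ct: CountTable,
    model: str,
    norm: NormFactors | None = None,
    common_dispersion: bool = False,
    epsilon: float = 1e10,
    scale_scheme: str | None = None,
) -> FitResult:
    """Fit one of the five candidate models per feature (intercept-only).

    ``norm`` supplies offsets for the count models (TSS library sizes when
    omitted).  ``scale_scheme`` selects the log transform for the Gaussian
    models (ZIG: ``css_log_thousand`` / ``css_log_median``; HURDLE:
    ``log2_cpm`` / ``log2_median_libsize``) and is required for them.
    """
    if ct.n_samples < 3:
        raise ValueError("model fitting needs at least 3 samples")
    model = model.upper()
    Y = ct.matrix().astype(float)
    lib = ct.library_sizes.to_numpy().astype(float)
    if norm is None:
        offset = np.log(lib)
    else:
        offset = norm.log_offsets().to_numpy()

    if model == "NB":
        return _fit_nb(ct, Y, offset, common_dispersion)
    if model == "ZINB":
        return _fit_zinb(ct, Y, offset, epsilon)
    if model == "ZIG":
        if scale_scheme is None:
            scale_scheme = "css_log_median"
        if scale_scheme not in ("css_log_thousand", "css_log_median"):
            raise ValueError("ZIG requires a CSS scale scheme")
        return _fit_zig(ct, scale_scheme)
    if model == "HURDLE":
        if scale_scheme is None:
            scale_scheme = "log2_median_libsize"
        if scale_scheme not in ("log2_cpm", "log2_median_libsize"):
            raise ValueError("HURDLE requires a CPM or median-library scale scheme")
        return _fit_hurdle(ct, scale_scheme)
    if model == "DM":
        return _fit_dm(ct, Y, lib)
    raise ValueError(f"unknown model {model!r}, expected one of {MODELS}")


def _fit_nb(ct, Y, offset, common_dispersion) -> FitResult:
    beta, phi, mu = _nb.fit_nb_intercept(Y, offset, common_dispersion=common_dispersion)
    phi_arr = np.atleast_1d(np.asarray(phi, dtype=float))
    phi_c = phi_arr.reshape(-1, 1) if phi_arr.size > 1 else np.full((Y.shape[0], 1), phi_arr[0])
    p0 = _nb.nb_zero_prob(mu, phi_c)
    return FitResult(
        model="NB",
        feature_ids=ct.feature_ids,
        est_mean=mu.mean(1),
        zero_prob=p0.mean(1),
        mean_scale="count",
        params={"beta": beta, "phi": phi, "mu": mu},
    )


def _fit_zinb(ct, Y, offset, epsilon) -> FitResult:
    fit = _nb.fit_zinb(Y, offset, common_dispersion=True, epsilon=epsilon)
    p0 = _nb.zinb_zero_prob(fit["mu"], fit["pi"], np.array(fit["phi"]))
    est_mean = ((1.0 - fit["pi"])[:, None] * fit["mu"]).mean(1)
    return FitResult(
        model="ZINB",
        feature_ids=ct.feature_ids,
        est_mean=est_mean,
        zero_prob=p0.mean(1),
        mean_scale="count",
        params={
            "beta": fit["beta"],
            "phi": fit["phi"],
            "pi": fit["pi"],
            "mu": fit["mu"],
        },
        converged=fit["converged"],
    )


def _fit_zig(ct, scale_scheme, max_em_iter: int = 100, tol: float = 1e-6) -> FitResult:
    """Zero-inflated Gaussian mixture on log2(count + 1) with CSS offsets.

    Zeros arise from a point mass at zero with per-sample probability
    modeled by a logistic regression on log library size (shared across
    features); the continuous part is Gaussian with a per-feature intercept
    plus a common coefficient on the CSS offset.
    """
    mat, off = transform_counts(ct, scale_scheme)
    Yl = mat.to_numpy()
    off = off.to_numpy()
    F, n = Yl.shape
    zeros = ct.matrix() == 0
    loglib = np.log(ct.library_sizes.to_numpy().astype(float))
    Xz = np.column_stack([np.ones(n), (loglib - loglib.mean()) / (loglib.std() + 1e-12)])

    # init: pi_j from overall zero rate, Gaussian params from positive cells
    coef = np.zeros(2)
    coef[0] = np.log(max(zeros.mean(), 1e-3) / max(1 - zeros.mean(), 1e-3))
    npos = np.maximum((~zeros).sum(1), 1)
    b0 = np.where(zeros, 0.0, Yl).sum(1) / npos
    eta = 0.0  # common coefficient on the offset
    sigma2 = np.full(F, max(np.var(Yl[~zeros]) if (~zeros).any() else 1.0, 1e-4))
    ll_old = -np.inf
    for _ in range(max_em_iter):
        pi_j = expit(Xz @ coef)
        mu_mat = b0[:, None] + eta * off[None, :]
        dens = np.exp(-0.5 * (Yl - mu_mat) ** 2 / sigma2[:, None]) / np.sqrt(
            2 * np.pi * sigma2[:, None]
        )
        # E-step: only zero cells can be point-mass members
        num = pi_j[None, :]
        den = num + (1 - pi_j)[None, :] * np.maximum(dens, 1e-300)
        z = np.where(zeros, num / den, 0.0)
        w = 1.0 - z
        # M-step: weighted per-feature regression on [1, offset]
        sw = w.sum(1) + 1e-12
        swo = (w * off[None, :]).sum(1)
        swoo = (w * off[None, :] ** 2).sum(1)
        swy = (w * Yl).sum(1)
        swoy = (w * off[None, :] * Yl).sum(1)
        # common eta: pooled normal equations given per-feature intercepts
        # solve jointly: b0_f = (swy - eta*swo)/sw ; eta from pooled residual
        denom_eta = (swoo - swo**2 / sw).sum()
        if denom_eta > 1e-10:
            eta = float((swoy - swo * swy / sw).sum() / denom_eta)
        b0 = (swy - eta * swo) / sw
        resid = Yl - (b0[:, None] + eta * off[None, :])
        sigma2 = np.maximum((w * resid**2).sum(1) / sw, 1e-6)
        # logistic M-step on pooled responsibilities (IRLS, 2 params)
        coef = _logistic_weighted(Xz, z, zeros)
        pi_j = expit(Xz @ coef)
        mu_mat = b0[:, None] + eta * off[None, :]
        dens = np.exp(-0.5 * (Yl - mu_mat) ** 2 / sigma2[:, None]) / np.sqrt(
            2 * np.pi * sigma2[:, None]
        )
        ll = np.where(
            zeros,
            np.log(np.maximum(pi_j[None, :] + (1 - pi_j)[None, :] * dens, 1e-300)),
            np.log1p(-pi_j)[None, :] + np.log(np.maximum(dens, 1e-300)),
        ).sum()
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    # model zero probability is the mixing weight (sample-driven, feature-shared)
    p0 = np.full(F, float(pi_j.mean()))
    # expected log2(count+1): zeros contribute 0 on this scale
    est_mean = ((1 - pi_j)[None, :] * mu_mat).mean(1)
    return FitResult(
        model="ZIG",
        feature_ids=ct.feature_ids,
        est_mean=est_mean,
        zero_prob=p0,
        mean_scale="log2p1",
        params={
            "logistic_coef": coef,
            "gauss_mean": b0,
            "offset_coef": eta,
            "gauss_var": sigma2,
            "pi_sample": pi_j,
        },
    )


def _logistic_weighted(X, z, mask):
    """IRLS for a pooled binomial-fraction logistic fit.

    Response per sample j: total structural-zero responsibility over
    features (only zero cells contribute), out of F trials.
    """
    F = z.shape[0]
    succ = z.sum(0)
    tot = np.full(X.shape[0], float(F))
    coef = np.zeros(X.shape[1])
    for _ in range(50):
        p = expit(X @ coef)
        W = tot * p * (1 - p) + 1e-9
        grad = X.T @ (succ - tot * p)
        H = X.T @ (W[:, None] * X) + 1e-9 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        coef = coef + np.clip(step, -5, 5)
        if np.max(np.abs(step)) < 1e-10:
            break
    return coef


def _fit_hurdle(ct, scale_scheme) -> FitResult:
    """MAST-style two-part fit with the sample detection rate as covariate."""
    mat, _ = transform_counts(ct, scale_scheme)
    Yl = mat.to_numpy()
    pos = ct.matrix() > 0
    F, n = Yl.shape
    cdr = pos.mean(0)  # fraction of detected features per sample
    X = np.column_stack([np.ones(n), cdr - cdr.mean()])
    det_coef, p_det, det_ok = _logistic_rows(pos.astype(float), X)
    # Gaussian on positives: per-feature WLS with indicator weights
    w = pos.astype(float)
    beta_g, mu_pos, gauss_ok = _wls_rows(Yl, X, w)
    resid = np.where(pos, Yl - mu_pos, 0.0)
    npos = pos.sum(1)
    sigma2 = (resid**2).sum(1) / np.maximum(npos - 2, 1)
    converged = det_ok & gauss_ok & (npos >= 2)
    p0 = 1.0 - p_det.mean(1)
    est_mean = (p_det * mu_pos).mean(1)
    return FitResult(
        model="HURDLE",
        feature_ids=ct.feature_ids,
        est_mean=est_mean,
        zero_prob=p0,
        mean_scale="log2p1",
        params={
            "detection_coef": det_coef,
            "gauss_coef": beta_g,
            "gauss_var": np.asarray(sigma2),
            "cdr": cdr,
        },
        converged=converged,
    )


def _logistic_rows(D, X, maxiter=60):
    """Per-feature logistic regression, shared design, vectorized IRLS."""
    F, n = D.shape
    p = X.shape[1]
    beta = np.zeros((F, p))
    mean_d = np.clip(D.mean(1), 1e-3, 1 - 1e-3)
    beta[:, 0] = np.log(mean_d / (1 - mean_d))
    ok = np.ones(F, dtype=bool)
    for _ in range(maxiter):
        eta = np.clip(beta @ X.T, -30, 30)
        mu = expit(eta)
        W = np.maximum(mu * (1 - mu), 1e-9)
        z = eta + (D - mu) / W
        XtWX = np.einsum("np,fn,nq->fpq", X, W, X) + 1e-8 * np.eye(p)[None]
        XtWz = np.einsum("np,fn,fn->fp", X, W, z)
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.clip(new - beta, -3, 3)
        beta += step
        if np.max(np.abs(step)) < 1e-8:
            break
    # separation guard: enormous coefficients -> flag, clamp probabilities
    ok &= np.all(np.abs(beta) < 30, axis=1)
    mu = expit(np.clip(beta @ X.T, -30, 30))
    return beta, mu, ok


def _wls_rows(Yl, X, w):
    """Per-feature weighted least squares with a shared design."""
    F, n = Yl.shape
    p = X.shape[1]
    XtWX = np.einsum("np,fn,nq->fpq", X, w, X) + 1e-8 * np.eye(p)[None]
    XtWy = np.einsum("np,fn,fn->fp", X, w, Yl)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    fitted = beta @ X.T
    ok = np.isfinite(beta).all(axis=1)
    return beta, fitted, ok


def _fit_dm(ct, Y, lib, maxiter=500, tol=1e-9) -> FitResult:
    """Dirichlet-multinomial ML via the standard fixed-point iteration."""
    F, n = Y.shape
    # method-of-moments start from mean relative abundances
    P = Y / lib[None, :]
    pbar = np.maximum(P.mean(1), 1e-10)
    pbar = pbar / pbar.sum()
    alpha = pbar * 10.0
    for _ in range(maxiter):
        a0 = alpha.sum()
        num = (_digamma(Y + alpha[:, None]) - _digamma(alpha)[:, None]).sum(1)
        den = (_digamma(lib + a0) - _digamma(a0)).sum()
        new = alpha * np.maximum(num, 1e-12) / max(den, 1e-12)
        new = np.maximum(new, 1e-10)
        if np.max(np.abs(new - alpha) / (alpha + 1e-12)) < tol:
            alpha = new
            break
        alpha = new
    a0 = alpha.sum()
    est_mean = (lib[None, :] * (alpha / a0)[:, None]).mean(1)
    # beta-binomial marginal P(Y_f = 0 | n_j, alpha_f, a0 - alpha_f)
    b = a0 - alpha
    logp0 = (
        gammaln(a0)
        + gammaln(b[:, None] + lib[None, :])
        - gammaln(a0 + lib[None, :])
        - gammaln(b)[:, None]
    )
    p0 = np.exp(np.clip(logp0, -745, 0)).mean(1)
    return FitResult(
        model="DM",
        feature_ids=ct.feature_ids,
        est_mean=est_mean,
        zero_prob=p0,
        mean_scale="count",
        params={"alpha": alpha, "alpha0": float(a0)},
    )


def _digamma(x):
    from scipy.special import digamma

    return digamma(x)


def gof_summary(
    fit: FitResult, ct: CountTable, observed_mean: str = "log2_mean_count"
) -> GofSummary:
    """Score a fit: MD and ZPD per feature plus their RMSEs.

    ``observed_mean`` selects the comparison convention for the observed
    side: ``"log2_mean_count"`` (log2 of the mean count plus 1, the default)
    or ``"mean_log2_count"`` (mean of log2(count + 1)).
    """
    if not fit.feature_ids.equals(ct.feature_ids):
        raise ValueError("fit and table cover different feature sets")
    Y = ct.matrix().astype(float)
    if observed_mean == "log2_mean_count":
        obs = np.log2(Y.mean(1) + 1.0)
    elif observed_mean == "mean_log2_count":
        obs = np.log2(Y + 1.0).mean(1)
    else:
        raise ValueError(f"unknown observed_mean convention {observed_mean!r}")
    _, freq0 = zero_fraction(ct)
    md = fit.mean_log2p1() - obs
    zpd = fit.zero_prob - freq0.to_numpy()
    excl = ~fit.converged
    md = np.where(excl, np.nan, md)
    zpd = np.where(excl, np.nan, zpd)
    return GofSummary(
        model=fit.model,
        md=pd.Series(md, index=ct.feature_ids, name="MD"),
        zpd=pd.Series(zpd, index=ct.feature_ids, name="ZPD"),
        n_excluded=int(excl.sum()),
    )


def rank_models(summaries: pd.DataFrame) -> pd.DataFrame:
    """Average GOF rank of each model across datasets.

    ``summaries`` is a tidy frame with columns ``model``, ``dataset`` and one
    or both of ``rmse_mean`` / ``rmse_zpd``.  Within each dataset models are
    ranked 1..K by RMSE (1 = best, mean ranks for ties); ranks are then
    averaged across datasets.  Returns models x metrics average-rank table.
    """
    metrics = [c for c in ("rmse_mean", "rmse_zpd") if c in summaries.columns]
    if not metrics:
        raise ValueError("summaries must contain rmse_mean and/or rmse_zpd")
    if summaries["model"].nunique() < 2:
        raise ValueError("need at least 2 models to rank")
    out = {}
    for metric in metrics:
        ranks = (
            summaries.pivot(index="model", columns="dataset", values=metric)
            .rank(axis=0, method="average")
        )
        out[metric] = ranks.mean(axis=1)
    return pd.DataFrame(out)
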