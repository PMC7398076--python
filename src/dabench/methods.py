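"""Built-in differential-abundance methods behind a uniform contract.

Every method takes a :class:`~dabench.core.CountTable` plus a two-level group
factor and returns a :class:`DAResult` with, per feature: a signed
coefficient (group2 vs group1, log2-fold-change-like), a test statistic, a
raw p value (or a missing-reason code), a BH-adjusted p value and an optional
rank score.  The catalog spans the method families compared in microbiome
benchmarking:

================================  ===============  =================================
name                              normalization    test
================================  ===============  =================================
nb_glm_lrt_tmm                    TMM              NB GLM likelihood-ratio
nb_glm_lrt_poscounts              poscounts        NB GLM likelihood-ratio
nb_glm_wald_poscounts             poscounts        NB GLM Wald
nb_glm_robust_tmm                 TMM              quasi-likelihood F, raw dispersion
moderated_t_tmm                   TMM              voom-style moderated t
wilcoxon_tss                      TSS              rank-sum on log-normalized data
zig_css_median                    CSS              ZIG EM + moderated t
dirichlet_clr_wilcoxon            none (CLR)       Monte-Carlo Dirichlet + rank-sum
betabin_wald                      none             beta-binomial Wald
betabin_lrt                       none             beta-binomial likelihood-ratio
hurdle_cdr                        median libsize   two-part chi-square (df 2)
nb_glm_lrt_tmm_zinbweights        TMM              weighted F with ZINB weights
moderated_t_tmm_zinbweights       TMM              moderated t with ZINB weights
================================  ===============  =================================

Shared primitives — ZINB observational weights, empirical-Bayes variance
moderation and Benjamini-Hochberg adjustment — live here too and are reused
by several methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit, gammaln

from . import _nb
from .core import CountTable
from .fits import FitResult, _logistic_rows, _wls_rows
from .norm import compute_norm_factors, transform_counts

__all__ = [
    "DAResult",
    "MethodSpec",
    "CATALOG",
    "run_da",
    "register_method",
    "adjust_bh",
    "empirical_bayes_moderation",
    "zinb_observational_weights",
]


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class DAResult:
    """Per-feature output of one DA method run."""

    method: str
    table: pd.DataFrame  # index feature_id; coef, stat, raw_p, adj_p, rank_score, missing_reason

    def __post_init__(self):
        t = self.table
        for col in ("coef", "stat", "raw_p", "adj_p", "rank_score", "missing_reason"):
            if col not in t.columns:
                t[col] = np.nan if col != "missing_reason" else ""
        both = t[["raw_p", "adj_p"]].dropna()
        if (both["adj_p"] < both["raw_p"] - 1e-12).any():
            raise ValueError("adj_p < raw_p: BH contract violated")

    def ranked_features(self) -> list[str]:
        """Deterministic total order: raw p (or rank score), missing last.

        Ties broken by (|statistic| descending, feature id).
        """
        t = self.table.copy()
        if t["raw_p"].notna().any():
            key = t["raw_p"]
        else:
            key = -t["rank_score"].abs()
        order = pd.DataFrame(
            {
                "missing": key.isna().astype(int),
                "key": key.fillna(np.inf),
                "negstat": -t["stat"].abs().fillna(0.0),
            },
            index=t.index,
        )
        order["fid"] = order.index
        return order.sort_values(["missing", "key", "negstat", "fid"]).index.tolist()


def _make_result(method, feature_ids, coef, stat, raw_p, reason=None, rank_score=None):
    raw_p = np.asarray(raw_p, dtype=float)
    tab = pd.DataFrame(
        {
            "coef": np.asarray(coef, dtype=float),
            "stat": np.asarray(stat, dtype=float),
            "raw_p": raw_p,
            "adj_p": adjust_bh(raw_p),
            "rank_score": (
                np.asarray(rank_score, dtype=float)
                if rank_score is not None
                else np.nan
            ),
            "missing_reason": reason if reason is not None else "",
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return DAResult(method=method, table=tab)


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def adjust_bh(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up over the present (non-missing) p values.

    Missing entries stay missing and do not count toward m.
    """
    p = np.asarray(raw_p, dtype=float)
    out = np.full(p.shape, np.nan)
    present = np.isfinite(p)
    if not present.any():
        return out
    vals = p[present]
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = vals.size
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[present] = res
    return out


def empirical_bayes_moderation(residual_variances, residual_df):
    """Shrink per-feature variances toward a common prior (moderated t setup).

    Moment matching on log s^2 (scaled-F fit): estimates prior df ``d0`` and
    prior variance ``s0^2``, then returns the posterior variances
    ``(d0*s0^2 + d*s^2) / (d0 + d)`` and the augmented df ``d0 + d``.
    ``d0 = inf`` (all variances equal) collapses every variance to s0^2.

    Returns ``(s2_tilde, df_total, d0, s0_sq)``.
    """
    s2 = np.asarray(residual_variances, dtype=float)
    df = np.broadcast_to(np.asarray(residual_df, dtype=float), s2.shape).copy()
    if (df < 1).any():
        raise ValueError("residual df must be >= 1")
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        d0, s0 = np.inf, float(np.nanmean(s2[ok])) if ok.any() else 1.0
    else:
        z = np.log(s2[ok])
        from scipy.special import digamma, polygamma

        e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
        emean = e.mean()
        n = e.size
        evar = ((e - emean) ** 2).sum() / (n - 1) - np.mean(polygamma(1, df[ok] / 2.0))
        if evar <= 0:
            d0 = np.inf
            s0 = float(np.exp(emean))
        else:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s0 + df * np.where(ok, s2, s0)) / (d0 + df)
        df_total = d0 + df
    return s2_tilde, df_total, d0, s0


def _trigamma_inverse(x, iters=50):
    from scipy.special import polygamma

    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def zinb_observational_weights(ct: CountTable, fit: FitResult) -> pd.DataFrame:
    """Posterior probability each count is from the NB component.

    Weight 1 for positive counts; for a zero count the weight is
    ``(1 - pi) NB0 / (pi + (1 - pi) NB0)`` where NB0 is the NB zero
    probability at the cell's fitted mean.  Used as observation weights in
    the weighted NB GLM / moderated-t methods to discount excess zeros.
    """
    if fit.model != "ZINB":
        raise ValueError("weights require a ZINB fit")
    if not fit.feature_ids.equals(ct.feature_ids):
        raise ValueError("fit and table cover different feature sets")
    mu = fit.params["mu"]
    if mu.shape != ct.counts.shape:
        raise ValueError("fit was produced on a table of different shape")
    pi = fit.params["pi"][:, None]
    phi = np.asarray(fit.params["phi"], dtype=float)
    phi_c = phi.reshape(-1, 1) if phi.ndim else np.full((mu.shape[0], 1), float(phi))
    nb0 = _nb.nb_zero_prob(mu, phi_c)
    w_zero = (1 - pi) * nb0 / np.maximum(pi + (1 - pi) * nb0, 1e-300)
    W = np.where(ct.matrix() == 0, w_zero, 1.0)
    return pd.DataFrame(W, index=ct.feature_ids, columns=ct.sample_ids)


# ---------------------------------------------------------------------------
# catalog and dispatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethodSpec:
    """Catalog entry: what to run and which normalization it rests on."""

    name: str
    normalization: str  # TMM / poscounts / CSS / TSS / none
    test: str
    options: tuple = field(default_factory=tuple)
    uses_pvalues: bool = True


CATALOG: dict[str, MethodSpec] = {
    s.name: s
    for s in [
        MethodSpec("nb_glm_lrt_tmm", "TMM", "lrt"),
        MethodSpec("nb_glm_lrt_poscounts", "poscounts", "lrt"),
        MethodSpec("nb_glm_wald_poscounts", "poscounts", "wald"),
        MethodSpec("nb_glm_robust_tmm", "TMM", "qlf_robust"),
        MethodSpec("moderated_t_tmm", "TMM", "moderated_t"),
        MethodSpec("wilcoxon_tss", "TSS", "ranksum"),
        MethodSpec("zig_css_median", "CSS", "zig_moderated_t"),
        MethodSpec("dirichlet_clr_wilcoxon", "none", "mc_ranksum"),
        MethodSpec("betabin_wald", "none", "wald"),
        MethodSpec("betabin_lrt", "none", "lrt"),
        MethodSpec("hurdle_cdr", "median_libsize", "chisq_sum"),
        MethodSpec("nb_glm_lrt_tmm_zinbweights", "TMM", "weighted_f"),
        MethodSpec("moderated_t_tmm_zinbweights", "TMM", "moderated_t_weighted"),
    ]
}

_PLUGINS: dict[str, object] = {}


def register_method(name: str, runner, normalization: str = "none",
                    uses_pvalues: bool = True) -> None:
    """Register an external method: ``runner(ct, x01, seed) -> DAResult``.

    Lets outputs of tools not re-implemented here enter every evaluation
    engine through the same contract.
    """
    _PLUGINS[name] = runner
    CATALOG[name] = MethodSpec(name, normalization, "plugin", uses_pvalues=uses_pvalues)


def _encode_groups(ct: CountTable, group_labels):
    g = pd.Series(group_labels)
    if len(g) != ct.n_samples:
        raise ValueError("group_labels length does not match the number of samples")
    g.index = ct.sample_ids
    levels = sorted(g.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"exactly 2 groups required, got {levels}")
    x = (g.astype(str) == levels[1]).to_numpy().astype(float)
    if x.sum() < 2 or (1 - x).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return x, levels


def run_da(ct: CountTable, group_labels, method: str, seed: int = 0, **options) -> DAResult:
    """Run a catalog (or registered plugin) method; never mutates ``ct``.

    Coefficients are signed group2 vs group1 where group1 is the
    lexicographically first label (the reference level).  ``options`` are
    forwarded to the method runner (e.g. ``prevalence_filter=None`` to
    disable the rank-sum prefilters, ``n_draws`` for the Monte-Carlo
    Dirichlet method).
    """
    if method not in _PLUGINS and method not in CATALOG:
        raise KeyError(f"unknown method {method!r}; registered: {sorted(CATALOG)}")
    x, _ = _encode_groups(ct, group_labels)
    if method in _PLUGINS:
        return _PLUGINS[method](ct, x, seed, **options)
    runner = _RUNNERS[method]
    return runner(ct, x, seed, **options)


# ---------------------------------------------------------------------------
# NB GLM family (edgeR/DESeq2-like)
# ---------------------------------------------------------------------------

def _nb_offsets(ct, scheme):
    nf = compute_norm_factors(ct, scheme)
    return nf.log_offsets().to_numpy()


def _run_nb_glm(ct, x, scheme, test, weights=None):
    Y = ct.matrix().astype(float)
    F, n = Y.shape
    offset = _nb_offsets(ct, scheme)
    X_full = np.column_stack([np.ones(n), x])
    X_null = np.ones((n, 1))
    robust = test == "qlf_robust"
    phi = _nb.estimate_dispersion_trended(Y, X_full, offset, robust=robust)
    full = _nb.fit_nb_glm(Y, X_full, offset, phi, weights=weights)
    null = _nb.fit_nb_glm(Y, X_null, offset, phi, weights=weights)
    coef = full["beta"][:, 1] / np.log(2.0)  # log2 fold change
    lrt = np.maximum(2.0 * (full["loglik"] - null["loglik"]), 0.0)
    ok = full["converged"] & null["converged"]
    reason = np.where(ok, "", "no_convergence")
    if test == "lrt":
        stat = lrt
        p = stats.chi2.sf(stat, df=1)
    elif test == "wald":
        se = np.sqrt(np.maximum(full["cov"][:, 1, 1], 1e-300))
        stat = full["beta"][:, 1] / se
        p = 2.0 * stats.norm.sf(np.abs(stat))
    elif test == "qlf_robust":
        # quasi-likelihood F: LRT scaled by the deviance-based QL dispersion
        dev = 2.0 * (
            _nb.nb_logpmf(Y, np.maximum(Y, 1e-8), _nb._phi_col(phi, F)).sum(1)
            - full["loglik"]
        )
        df_res = max(n - 2, 1)
        s2 = np.maximum(dev / df_res, 1e-8)
        stat = lrt / s2
        p = stats.f.sf(stat, 1, df_res)
    elif test == "weighted_f":
        # ZINB-weighted F test with residual df = sum(weights) - p
        df_res = np.maximum(weights.sum(1) - 2.0, 1.0)
        stat = lrt
        p = stats.f.sf(stat, 1, df_res)
    else:  # pragma: no cover
        raise ValueError(test)
    p = np.where(ok, p, np.nan)
    return coef, stat, p, reason


def _runner_nb(scheme, test):
    def run(ct, x, seed, **_):
        coef, stat, p, reason = _run_nb_glm(ct, x, scheme, test)
        name = {
            ("TMM", "lrt"): "nb_glm_lrt_tmm",
            ("poscounts", "lrt"): "nb_glm_lrt_poscounts",
            ("poscounts", "wald"): "nb_glm_wald_poscounts",
            ("TMM", "qlf_robust"): "nb_glm_robust_tmm",
        }[(scheme, test)]
        return _make_result(name, ct.feature_ids, coef, stat, p, reason)

    return run


def _runner_nb_zinbweights(ct, x, seed, **_):
    fit = _fit_zinb_for_weights(ct)
    W = zinb_observational_weights(ct, fit).to_numpy()
    coef, stat, p, reason = _run_nb_glm(ct, x, "TMM", "weighted_f", weights=W)
    return _make_result("nb_glm_lrt_tmm_zinbweights", ct.feature_ids, coef, stat, p, reason)


def _fit_zinb_for_weights(ct):
    from .fits import fit_model

    return fit_model(ct, "ZINB", common_dispersion=True)


# ---------------------------------------------------------------------------
# limma-voom style moderated t
# ---------------------------------------------------------------------------

def _run_voom(ct, x, extra_weights=None):
    Y = ct.matrix().astype(float)
    F, n = Y.shape
    nf = compute_norm_factors(ct, "TMM")
    eff_lib = nf.effective_library_sizes.to_numpy()
    logcpm = np.log2((Y + 0.5) / (eff_lib[None, :] + 1.0) * 1e6)
    X = np.column_stack([np.ones(n), x])
    # pilot OLS to get the mean-variance trend
    beta, fitted, _ = _wls_rows(logcpm, X, np.ones_like(logcpm))
    resid = logcpm - fitted
    df_res = n - 2
    s = np.sqrt(np.maximum((resid**2).sum(1) / df_res, 1e-12))
    mean_logcount = logcpm.mean(1) + np.log2(eff_lib.mean() + 1.0) - np.log2(1e6)
    trend = _nb._lowess_trend(mean_logcount, np.sqrt(s))
    # per-observation fitted log-count -> predicted sqrt(sd) -> weights
    fitted_count = fitted + np.log2(eff_lib[None, :] + 1.0) - np.log2(1e6)
    order = np.argsort(mean_logcount)
    pred = np.interp(
        fitted_count, mean_logcount[order], trend[order]
    )
    w = 1.0 / np.maximum(pred, 1e-4) ** 4
    if extra_weights is not None:
        w = w * extra_weights
    beta, fitted, _ = _wls_rows(logcpm, X, w)
    resid = logcpm - fitted
    if extra_weights is not None:
        df_f = np.maximum(extra_weights.sum(1) - 2.0, 1.0)
    else:
        df_f = np.full(F, float(df_res))
    s2 = (w * resid**2).sum(1) / df_f
    # unscaled variance of the group coefficient from the WLS normal equations
    XtWX = np.einsum("np,fn,nq->fpq", X, w, X) + 1e-10 * np.eye(2)[None]
    unscaled = np.linalg.inv(XtWX)[:, 1, 1]
    s2_tilde, df_total, d0, s0 = empirical_bayes_moderation(s2, df_f)
    tstat = beta[:, 1] / np.sqrt(np.maximum(s2_tilde * unscaled, 1e-300))
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return beta[:, 1], tstat, p


def _runner_voom(ct, x, seed, **_):
    coef, stat, p = _run_voom(ct, x)
    return _make_result("moderated_t_tmm", ct.feature_ids, coef, stat, p)


def _runner_voom_zinbweights(ct, x, seed, **_):
    fit = _fit_zinb_for_weights(ct)
    W = zinb_observational_weights(ct, fit).to_numpy()
    coef, stat, p = _run_voom(ct, x, extra_weights=W)
    return _make_result("moderated_t_tmm_zinbweights", ct.feature_ids, coef, stat, p)


# ---------------------------------------------------------------------------
# rank-sum on log-normalized data (Seurat-like)
# ---------------------------------------------------------------------------

def _runner_wilcoxon(ct, x, seed, prevalence_filter=0.1, logfc_filter=0.25):
    Y = ct.matrix().astype(float)
    lib = ct.library_sizes.to_numpy().astype(float)
    data = np.log1p(Y / lib[None, :] * 1e4)  # LogNormalize, scale 1e4
    g2 = x == 1
    coef = data[:, g2].mean(1) - data[:, ~g2].mean(1)
    prevalence = (Y > 0).mean(1)
    reason = np.array([""] * Y.shape[0], dtype=object)
    testable = np.ones(Y.shape[0], dtype=bool)
    if prevalence_filter is not None:
        low = prevalence < prevalence_filter
        testable &= ~low
        reason[low] = "low_prevalence"
    if logfc_filter is not None:
        weak = np.abs(coef) < logfc_filter
        sel = weak & testable
        testable &= ~weak
        reason[sel] = "low_effect"
    p = np.full(Y.shape[0], np.nan)
    stat = np.full(Y.shape[0], np.nan)
    if testable.any():
        sub = data[testable]
        res = stats.mannwhitneyu(
            sub[:, g2], sub[:, ~g2], axis=1, alternative="two-sided",
            use_continuity=True,
        )
        stat[testable] = res.statistic
        pv = np.asarray(res.pvalue, dtype=float)
        # all-tied features: exchangeable ranks, p = 1 by convention
        allsame = np.all(sub == sub[:, [0]], axis=1)
        pv = np.where(allsame | ~np.isfinite(pv), 1.0, pv)
        p[testable] = np.minimum(pv, 1.0)
    return _make_result("wilcoxon_tss", ct.feature_ids, coef, stat, p, reason)


# ---------------------------------------------------------------------------
# ZIG mixture EM + moderated t (metagenomeSeq-like)
# ---------------------------------------------------------------------------

def _runner_zig(ct, x, seed, max_em_iter=30, tol=1e-6):
    mat, off = transform_counts(ct, "css_log_median")
    Yl = mat.to_numpy()
    off = off.to_numpy()
    F, n = Yl.shape
    zeros = ct.matrix() == 0
    loglib = np.log(ct.library_sizes.to_numpy().astype(float))
    Xz = np.column_stack([np.ones(n), (loglib - loglib.mean()) / (loglib.std() + 1e-12)])
    X = np.column_stack([np.ones(n), x, off])  # CSS offset as free covariate
    from .fits import _logistic_weighted

    coef_z = np.array([np.log(max(zeros.mean(), 1e-3) / max(1 - zeros.mean(), 1e-3)), 0.0])
    w = (~zeros).astype(float)
    beta, fitted, _ = _wls_rows(Yl, X, np.ones_like(Yl))
    sigma2 = np.maximum(((Yl - fitted) ** 2).mean(1), 1e-6)
    ll_old = -np.inf
    for _ in range(max_em_iter):
        pi_j = expit(Xz @ coef_z)
        dens = np.exp(-0.5 * (Yl - fitted) ** 2 / sigma2[:, None]) / np.sqrt(
            2 * np.pi * sigma2[:, None]
        )
        den = pi_j[None, :] + (1 - pi_j)[None, :] * np.maximum(dens, 1e-300)
        z = np.where(zeros, pi_j[None, :] / den, 0.0)
        w = 1.0 - z
        beta, fitted, _ = _wls_rows(Yl, X, w)
        sw = w.sum(1) + 1e-12
        sigma2 = np.maximum((w * (Yl - fitted) ** 2).sum(1) / sw, 1e-6)
        coef_z = _logistic_weighted(Xz, z, zeros)
        ll = np.where(
            zeros,
            np.log(np.maximum(pi_j[None, :] + (1 - pi_j)[None, :] * dens, 1e-300)),
            np.log1p(-pi_j)[None, :] + np.log(np.maximum(dens, 1e-300)),
        ).sum()
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            break
        ll_old = ll
    df_f = np.maximum(w.sum(1) - X.shape[1], 1.0)
    s2 = (w * (Yl - fitted) ** 2).sum(1) / df_f
    XtWX = np.einsum("np,fn,nq->fpq", X, w, X) + 1e-10 * np.eye(X.shape[1])[None]
    unscaled = np.linalg.inv(XtWX)[:, 1, 1]
    s2_tilde, df_total, d0, s0 = empirical_bayes_moderation(
        np.maximum(s2, 1e-12), df_f
    )
    tstat = beta[:, 1] / np.sqrt(np.maximum(s2_tilde * unscaled, 1e-300))
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return _make_result("zig_css_median", ct.feature_ids, beta[:, 1], tstat, p)


# ---------------------------------------------------------------------------
# Monte-Carlo Dirichlet + CLR + rank-sum (ALDEx2-like)
# ---------------------------------------------------------------------------

def _runner_aldex(ct, x, seed, n_draws=128):
    Y = ct.matrix().astype(float) + 0.5
    F, n = Y.shape
    g2 = x == 1
    rng = np.random.default_rng(seed)
    psum = np.zeros(F)
    esum = np.zeros(F)
    for _ in range(n_draws):
        # Dirichlet draw per sample via normalized gammas
        G = rng.standard_gamma(Y)
        P = G / G.sum(0)
        logp = np.log(P)
        clr = logp - logp.mean(0)
        # iqlr denominator: features whose CLR variance is within the IQR
        v = clr.var(1)
        q1, q3 = np.quantile(v, [0.25, 0.75])
        invar = (v >= q1) & (v <= q3)
        if invar.any():
            clr = logp - logp[invar].mean(0)
        res = stats.mannwhitneyu(
            clr[:, g2], clr[:, ~g2], axis=1, alternative="two-sided"
        )
        pv = np.asarray(res.pvalue, dtype=float)
        psum += np.where(np.isfinite(pv), pv, 1.0)
        esum += clr[:, g2].mean(1) - clr[:, ~g2].mean(1)
    p = psum / n_draws
    coef = esum / n_draws / np.log(2.0)
    return _make_result("dirichlet_clr_wilcoxon", ct.feature_ids, coef, np.abs(coef), p)


# ---------------------------------------------------------------------------
# beta-binomial regression (corncob-like)
# ---------------------------------------------------------------------------

def _bb_negll_terms(y, n, mu, rho):
    # a, b from mean/correlation parameterization
    denom = (1.0 - rho) / rho
    a = mu * denom
    b = (1.0 - mu) * denom
    return -(
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + betaln(y + a, n - y + b) - betaln(a, b)
    )


def _bb_negll(params, y, n, x, null):
    if null:
        b0, c0 = params[0], params[-1]
        eta = b0
    else:
        b0, b1, c0 = params
        eta = b0 + b1 * x
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    rho = np.clip(expit(c0), 1e-8, 1 - 1e-8)
    return float(_bb_negll_terms(y, n, mu, rho).sum())


def _bb_negll_grad(params, y, n, x, null):
    """Negative log-likelihood and its gradient (logit links on mu and rho)."""
    from scipy.special import digamma

    if null:
        b0, c0 = params[0], params[-1]
        eta = np.full_like(y, b0)
    else:
        b0, b1, c0 = params
        eta = b0 + b1 * x
    eta = np.clip(eta, -30, 30)
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    rho = np.clip(expit(np.clip(c0, -30, 30)), 1e-8, 1 - 1e-8)
    t = (1.0 - rho) / rho
    a = mu * t
    b = (1.0 - mu) * t
    nll = float(_bb_negll_terms(y, n, mu, rho).sum())
    dab = digamma(n + a + b)
    dcom = digamma(a + b)
    ga = -(digamma(y + a) - dab - digamma(a) + dcom)
    gb = -(digamma(n - y + b) - dab - digamma(b) + dcom)
    dmu = mu * (1.0 - mu)
    g_eta = (ga - gb) * t * dmu
    g_c0 = float((ga * (-a) + gb * (-b)).sum())  # since da/dc0=-a, db/dc0=-b
    if null:
        grad = np.array([float(g_eta.sum()), g_c0])
    else:
        grad = np.array([float(g_eta.sum()), float((g_eta * x).sum()), g_c0])
    return nll, grad


def _fit_betabin_feature(y, n, x, null=False):
    from scipy.optimize import minimize

    phat = np.clip((y.sum() + 0.5) / (n.sum() + 1.0), 1e-8, 1 - 1e-8)
    b0 = np.log(phat / (1 - phat))
    start = np.array([b0, -2.0]) if null else np.array([b0, 0.0, -2.0])
    res = minimize(
        _bb_negll_grad, start, args=(y, n, x, null), method="L-BFGS-B", jac=True,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    ok = res.success or res.status == 1  # status 1: hit maxiter near optimum
    if not ok:
        # line-search failures near the parameter-space boundary: polish
        # derivative-free from the best point found
        res = minimize(
            _bb_negll, res.x, args=(y, n, x, null), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 300},
        )
        ok = np.isfinite(res.fun)
    return res.x, -res.fun, bool(ok and np.isfinite(res.fun))


def _runner_betabin(test):
    def run(ct, x, seed, **_):
        Y = ct.matrix().astype(float)
        lib = ct.library_sizes.to_numpy().astype(float)
        F = Y.shape[0]
        coef = np.full(F, np.nan)
        stat = np.full(F, np.nan)
        p = np.full(F, np.nan)
        reason = np.array([""] * F, dtype=object)
        for f in range(F):
            y = Y[f]
            full, llf, ok_f = _fit_betabin_feature(y, lib, x, null=False)
            if not ok_f or not np.isfinite(llf):
                reason[f] = "no_convergence"
                continue
            coef[f] = full[1] / np.log(2.0)
            if test == "lrt":
                nullp, lln, ok_n = _fit_betabin_feature(y, lib, x, null=True)
                if not ok_n:
                    reason[f] = "no_convergence"
                    continue
                stat[f] = max(2.0 * (llf - lln), 0.0)
                p[f] = stats.chi2.sf(stat[f], df=1)
            else:  # Wald from the observed information (finite differences)
                se = _bb_wald_se(full, y, lib, x)
                if not np.isfinite(se) or se <= 0:
                    reason[f] = "no_convergence"
                    coef[f] = np.nan
                    continue
                stat[f] = full[1] / se
                p[f] = 2.0 * stats.norm.sf(abs(stat[f]))
        name = "betabin_lrt" if test == "lrt" else "betabin_wald"
        return _make_result(name, ct.feature_ids, coef, stat, p, reason)

    return run


def _bb_wald_se(params, y, n, x, h=1e-4):
    k = len(params)
    H = np.zeros((k, k))
    f0 = _bb_negll(params, y, n, x, null=False)
    for i in range(k):
        for j in range(i, k):
            pij = params.copy(); pij[i] += h; pij[j] += h
            pi_ = params.copy(); pi_[i] += h
            pj_ = params.copy(); pj_[j] += h
            H[i, j] = H[j, i] = (
                _bb_negll(pij, y, n, x, False) - _bb_negll(pi_, y, n, x, False)
                - _bb_negll(pj_, y, n, x, False) + f0
            ) / h**2
    try:
        cov = np.linalg.inv(H + 1e-8 * np.eye(k))
    except np.linalg.LinAlgError:
        return np.nan
    v = cov[1, 1]
    return np.sqrt(v) if v > 0 else np.nan


# ---------------------------------------------------------------------------
# hurdle chi-square (MAST-like)
# ---------------------------------------------------------------------------

def _runner_hurdle(ct, x, seed, **_):
    mat, _ = transform_counts(ct, "log2_median_libsize")
    Yl = mat.to_numpy()
    pos = ct.matrix() > 0
    F, n = Yl.shape
    cdr = pos.mean(0)
    cdr_c = cdr - cdr.mean()
    X_full = np.column_stack([np.ones(n), x, cdr_c])
    X_null = np.column_stack([np.ones(n), cdr_c])
    D = pos.astype(float)
    # discrete part: logistic LRT for the group term
    ll_full_d = _logistic_ll(D, X_full)
    ll_null_d = _logistic_ll(D, X_null)
    lrt_d = np.maximum(2.0 * (ll_full_d - ll_null_d), 0.0)
    # continuous part: Gaussian LRT on the positive cells
    w = D
    npos = pos.sum(1)
    rss_full, beta_full = _wls_rss(Yl, X_full, w)
    rss_null, _ = _wls_rss(Yl, X_null, w)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt_c = npos * np.log(np.maximum(rss_null, 1e-300) / np.maximum(rss_full, 1e-300))
    lrt_c = np.where(npos > X_full.shape[1], np.maximum(lrt_c, 0.0), 0.0)
    stat = lrt_d + lrt_c
    p = stats.chi2.sf(stat, df=2)
    testable = (npos >= 2) & (npos <= n)
    reason = np.where(testable, "", "too_few_positive")
    p = np.where(testable, p, np.nan)
    coef = beta_full[:, 1]
    return _make_result("hurdle_cdr", ct.feature_ids, coef, stat, p, reason)


def _logistic_ll(D, X):
    beta, mu, _ = _logistic_rows(D, X)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return (D * np.log(mu) + (1 - D) * np.log1p(-mu)).sum(1)


def _wls_rss(Yl, X, w):
    beta, fitted, _ = _wls_rows(Yl, X, w)
    rss = (w * (Yl - fitted) ** 2).sum(1)
    return rss, beta


# ---------------------------------------------------------------------------

_RUNNERS = {
    "nb_glm_lrt_tmm": _runner_nb("TMM", "lrt"),
    "nb_glm_lrt_poscounts": _runner_nb("poscounts", "lrt"),
    "nb_glm_wald_poscounts": _runner_nb("poscounts", "wald"),
    "nb_glm_robust_tmm": _runner_nb("TMM", "qlf_robust"),
    "moderated_t_tmm": _runner_voom,
    "wilcoxon_tss": _runner_wilcoxon,
    "zig_css_median": _runner_zig,
    "dirichlet_clr_wilcoxon": _runner_aldex,
    "betabin_wald": _runner_betabin("wald"),
    "betabin_lrt": _runner_betabin("lrt"),
    "hurdle_cdr": _runner_hurdle,
    "nb_glm_lrt_tmm_zinbweights": _runner_nb_zinbweights,
    "moderated_t_tmm_zinbweights": _runner_voom_zinbweights,
}
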