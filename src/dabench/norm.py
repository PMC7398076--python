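"""Sample scaling factors and count transformations.

Implements the normalizations used by the fitted models and DA methods:

* TMM — trimmed mean of M-values; a relative scaling factor on top of the
  library size, with geometric mean 1 across samples.
* poscounts — median-of-ratios size factors using the geometric mean of the
  positive counts as the per-feature reference (robust to zeros).
* CSS — cumulative sum scaling: per-sample sum of counts up to a data-driven
  quantile chosen by an instability criterion.
* TSS — total sum scaling (the library size itself).

and the log-scale transforms (logCPM, median-library-size rescaling, CLR,
and the two CSS offset conventions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountTable

__all__ = ["NormFactors", "compute_norm_factors", "transform_counts"]

SCHEMES = ("TMM", "poscounts", "CSS", "TSS")
TRANSFORMS = (
    "log2_cpm",
    "log2_median_libsize",
    "clr",
    "css_log_thousand",
    "css_log_median",
)

# TMM internals (standard constants for the doubly trimmed mean, exposed here
# because an off-by-one in the trim changes every downstream offset).
TMM_LOGRATIO_TRIM = 0.30
TMM_ABUNDANCE_TRIM = 0.05

# CSS instability threshold: smallest relative increase of the quantile
# spread that stops the search.
CSS_REL_CHANGE = 0.1
CSS_FALLBACK_QUANTILE = 0.5


@dataclass
class NormFactors:
    """Per-sample scaling factors for one scheme.

    ``factors`` are positive reals, one per sample.  For TMM they are
    relative factors with geometric mean 1 (multiply by the library size to
    get an effective library size); for poscounts they are median-of-ratio
    size factors; for CSS they are cumulative sums up to the chosen
    quantile; for TSS they equal the library sizes.
    """

    scheme: str
    factors: pd.Series
    library_sizes: pd.Series
    quantile: float | None = None  # CSS only

    def __post_init__(self):
        if (self.factors <= 0).any():
            bad = self.factors.index[self.factors <= 0].tolist()
            raise ValueError(f"non-positive normalization factor for samples {bad}")

    @property
    def effective_library_sizes(self) -> pd.Series:
        """Library size times factor (meaningful for TMM); else the factor scale."""
        if self.scheme == "TMM":
            return self.library_sizes * self.factors
        return self.factors

    def log_offsets(self) -> pd.Series:
        """Natural-log offsets for count GLMs (log effective library size)."""
        return np.log(self.effective_library_sizes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.factors.index, "factor": self.factors.to_numpy()}
        )


def compute_norm_factors(ct: CountTable, scheme: str = "TMM") -> NormFactors:
    """Compute per-sample normalization factors under the given scheme."""
    if ct.n_samples < 2:
        raise ValueError("need at least 2 samples")
    lib = ct.library_sizes.astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"all-zero sample(s) {bad}: normalization factor undefined")
    if scheme == "TSS":
        factors = lib.copy()
        quantile = None
    elif scheme == "TMM":
        factors = pd.Series(_tmm(ct.matrix().astype(float), lib.to_numpy()),
                            index=ct.sample_ids)
        quantile = None
    elif scheme == "poscounts":
        factors = pd.Series(_poscounts(ct.matrix().astype(float)), index=ct.sample_ids)
        quantile = None
    elif scheme == "CSS":
        f, quantile = _css(ct.matrix().astype(float))
        factors = pd.Series(f, index=ct.sample_ids)
    else:
        raise ValueError(f"unknown scheme {scheme!r}, expected one of {SCHEMES}")
    return NormFactors(scheme, factors, lib, quantile)


# -- TMM ----------------------------------------------------------------------

def _tmm(Y: np.ndarray, lib: np.ndarray) -> np.ndarray:
    n = Y.shape[1]
    # reference sample: upper quartile of scaled counts closest to the mean
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(n)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.array([_tmm_pair(Y[:, j], lib[j], Y[:, ref], lib[ref]) for j in range(n)])
    # geometric-mean-1 convention
    return f / np.exp(np.mean(np.log(f)))


def _tmm_pair(y, ny, r, nr) -> float:
    pos = (y > 0) & (r > 0)
    if not pos.any():
        return 1.0
    y, r = y[pos], r[pos]
    py, pr = y / ny, r / nr
    M = np.log2(py / pr)
    A = 0.5 * np.log2(py * pr)
    # precision weights: inverse asymptotic variance of M
    w = 1.0 / ((ny - y) / (ny * y) + (nr - r) / (nr * r))
    if np.max(np.abs(M)) < 1e-6:  # pure depth change: factor 1 exactly
        return 1.0
    k = len(M)
    loM = np.floor(k * TMM_LOGRATIO_TRIM) + 1
    hiM = k - loM + 1
    loA = np.floor(k * TMM_ABUNDANCE_TRIM) + 1
    hiA = k - loA + 1
    from scipy.stats import rankdata

    rM, rA = rankdata(M), rankdata(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():
        return 1.0
    return float(2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))


# -- poscounts ----------------------------------------------------------------

def _poscounts(Y: np.ndarray) -> np.ndarray:
    n = Y.shape[1]
    logY = np.zeros_like(Y)
    np.log(Y, where=Y > 0, out=logY)
    # geometric mean of the positive counts, with exponent 1/n over all samples
    g = np.exp(logY.sum(axis=1) / n)
    g[(Y > 0).sum(axis=1) == 0] = 0.0
    usable = g > 0
    if not usable.any():
        raise ValueError("poscounts: no feature with a positive geometric mean")
    ratios = Y[usable] / g[usable, None]  # zero ratios included in the median
    s = np.median(ratios, axis=0)
    if (s <= 0).any():
        # extremely sparse sample: fall back to the mean of positive ratios
        for j in np.flatnonzero(s <= 0):
            posr = ratios[ratios[:, j] > 0, j]
            if posr.size == 0:
                raise ValueError(f"poscounts: undefined factor for sample {j}")
            s[j] = posr.mean()
    return s


# -- CSS ----------------------------------------------------------------------

def _css(Y: np.ndarray):
    n = Y.shape[1]
    grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    # per-sample quantiles of the positive counts along the grid
    q = np.zeros((len(grid), n))
    for j in range(n):
        pos = Y[Y[:, j] > 0, j]
        if pos.size == 0:
            raise ValueError(f"all-zero sample at index {j}: CSS factor undefined")
        q[:, j] = np.quantile(pos, grid)
    ref = q.mean(axis=1)
    spread = np.median(np.abs(q - ref[:, None]), axis=1)
    chosen = None
    prev = None
    for i, l in enumerate(grid):
        if prev is not None and prev > 0:
            if (spread[i] - prev) / prev > CSS_REL_CHANGE and l >= 0.5:
                chosen = float(l)
                break
        prev = spread[i]
    if chosen is None:
        chosen = CSS_FALLBACK_QUANTILE
    factors = np.empty(n)
    for j in range(n):
        pos = Y[Y[:, j] > 0, j]
        cutoff = np.quantile(pos, chosen)
        factors[j] = Y[Y[:, j] <= cutoff, j].sum()
        if factors[j] <= 0:
            factors[j] = pos.min()
    return factors, chosen


# -- transforms ---------------------------------------------------------------

def transform_counts(
    ct: CountTable,
    scheme: str,
    pseudocount: float = 1.0,
    norm: NormFactors | None = None,
):
    """Transform counts to the log scale used by the Gaussian models.

    Returns ``(matrix, offsets)`` where ``matrix`` is a features x samples
    DataFrame and ``offsets`` a per-sample Series of additive log-scale
    offsets (zero except for the CSS variants, whose offset enters the
    regression instead of rescaling the counts).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    Y = ct.matrix().astype(float)
    lib = ct.library_sizes.to_numpy().astype(float)
    zero_off = pd.Series(0.0, index=ct.sample_ids, name="offset")

    if scheme == "log2_cpm":
        mat = np.log2(Y * 1e6 / lib + pseudocount)
        return _as_df(mat, ct), zero_off
    if scheme == "log2_median_libsize":
        mat = np.log2(Y * np.median(lib) / lib + pseudocount)
        return _as_df(mat, ct), zero_off
    if scheme == "clr":
        X = (Y + pseudocount) / (Y + pseudocount).sum(axis=0)
        logx = np.log(X)
        mat = logx - logx.mean(axis=0)
        return _as_df(mat, ct), zero_off
    if scheme in ("css_log_thousand", "css_log_median"):
        if norm is None or norm.scheme != "CSS":
            norm = compute_norm_factors(ct, "CSS")
        s = norm.factors.to_numpy().astype(float)
        if scheme == "css_log_thousand":
            off = np.log2(s / 1000.0 + 1.0)
        else:
            off = np.log2(s / np.median(s))
        mat = np.log2(Y + pseudocount)
        return _as_df(mat, ct), pd.Series(off, index=ct.sample_ids, name="offset")
    raise ValueError(f"unknown transform {scheme!r}, expected one of {TRANSFORMS}")


def _as_df(mat: np.ndarray, ct: CountTable) -> pd.DataFrame:
    return pd.DataFrame(mat, index=ct.feature_ids, columns=ct.sample_ids)
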