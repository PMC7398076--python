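"""Parametric NB/ZINB count simulator with DA injection and power evaluation.

The simulator draws feature-by-sample count tables from templates — either
estimated from a real table (per-feature relative means, a common dispersion
and, for ZINB, per-feature zero-inflation probabilities, plus an empirical
library-size pool) — or from the bundled synthetic 16S-like / WMS-like
templates, which emulate the two platforms' depth and sparsity regimes
(16S: libraries around 5x10^3 reads and zero fractions in the 0.55-0.83
range; WMS: libraries >= 10^6 with zero fractions 0.35-0.89).

Differential abundance is injected by multiplying relative means in group 2
by a fold effect, either plainly (up-half multiplied, down-half divided,
then renormalized — which perturbs every feature's relative mean) or with
*compensation*, which balances the up- and down-scaling so that the total
mass of the flagged set is conserved and non-flagged features are untouched
by the renormalization.  A *sparsity effect* additively shifts the ZINB
mixing probabilities of DA features in group 2 (clamped to [0, 1]).

``power_evaluation`` scores methods on simulated data: TPR/FPR at an
adjusted-p threshold and partial AUROC over FPR in [0, 0.1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nb
from .core import CountTable
from .methods import run_da

__all__ = [
    "TemplateParams",
    "SimulationDesign",
    "SimulatedDataset",
    "estimate_template",
    "builtin_template",
    "inject_da",
    "apply_sparsity_effect",
    "simulate_dataset",
    "power_evaluation",
]


@dataclass
class TemplateParams:
    """Distributional template a simulation draws from."""

    relative_means: np.ndarray       # r_f > 0, sums to 1
    dispersion: float                # common phi >= 0
    zero_inflation: np.ndarray | None  # pi_f in [0,1] (ZINB) or None (NB)
    library_sizes: np.ndarray        # empirical pool, resampled with replacement
    distribution: str                # "NB" or "ZINB"
    feature_ids: list = field(default_factory=list)

    def __post_init__(self):
        r = np.asarray(self.relative_means, dtype=float)
        if (r <= 0).any():
            raise ValueError("relative means must be positive")
        if abs(r.sum() - 1.0) > 1e-9:
            raise ValueError("relative means must sum to 1")
        self.relative_means = r
        if self.distribution not in ("NB", "ZINB"):
            raise ValueError("distribution must be NB or ZINB")
        if self.distribution == "ZINB":
            pi = np.asarray(self.zero_inflation, dtype=float)
            if ((pi < 0) | (pi > 1)).any():
                raise ValueError("zero-inflation probabilities must lie in [0, 1]")
            self.zero_inflation = pi
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.feature_ids:
            self.feature_ids = [f"F{i:04d}" for i in range(len(r))]

    @property
    def n_features(self) -> int:
        return len(self.relative_means)


@dataclass
class SimulationDesign:
    """One cell of the simulation grid."""

    distribution: str = "NB"
    n_per_group: int = 20            # grid values: 10, 20, 40
    da_proportion: float = 0.10      # grid values: 0.10, 0.50
    fold_effect: float = 2.0         # grid values: 2, 5
    compensation: bool = False
    sparsity_effect: float = 0.0     # grid values: 0, 0.05, 0.15 (ZINB only)
    replicates: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.fold_effect <= 1:
            raise ValueError("fold_effect must be > 1")
        if self.sparsity_effect < 0:
            raise ValueError("sparsity_effect must be >= 0")
        if self.distribution == "NB":
            self.sparsity_effect = 0.0  # no mixing parameter to act on


@dataclass
class SimulatedDataset:
    table: CountTable
    truth: pd.DataFrame       # feature_id index; is_da (bool), direction (up/down/"")
    params: dict              # realized per-group parameters


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def estimate_template(ct: CountTable, distribution: str = "NB") -> TemplateParams:
    """Fit a template to a (filtered) real table.

    NB: intercept-only per-feature means with library-size offsets and a
    common ML dispersion.  ZINB: the same via EM with per-feature
    zero-inflation.  Relative means are the fitted means normalized to sum
    to 1; library sizes are kept as the empirical pool.
    """
    Y = ct.matrix().astype(float)
    lib = ct.library_sizes.to_numpy().astype(float)
    offset = np.log(lib)
    if distribution == "NB":
        beta, phi, _ = _nb.fit_nb_intercept(Y, offset, common_dispersion=True)
        r = np.exp(beta)
        pi = None
        phi = float(np.atleast_1d(phi)[0])
    elif distribution == "ZINB":
        fit = _nb.fit_zinb(Y, offset, common_dispersion=True)
        r = np.exp(fit["beta"])
        pi = fit["pi"].copy()
        phi = float(fit["phi"])
        if not fit["converged"].all():
            import warnings

            warnings.warn("ZINB template: EM stopped before full convergence",
                          stacklevel=2)
    else:
        raise ValueError("distribution must be NB or ZINB")
    r = r / r.sum()
    return TemplateParams(
        relative_means=r,
        dispersion=phi,
        zero_inflation=pi,
        library_sizes=lib.copy(),
        distribution=distribution,
        feature_ids=list(ct.feature_ids),
    )


def builtin_template(kind: str, n_features: int = 900, seed: int = 7) -> TemplateParams:
    """Bundled synthetic 16S-like / WMS-like templates (no download needed).

    ``kind="16s"``: NB-style depth around 5x10^3 reads with a heavy-tailed
    log-normal composition and moderate over-dispersion, yielding overall
    zero fractions around 0.6-0.8.  ``kind="wms"``: ZINB with libraries
    around 10^6-10^7 and per-feature zero inflation, yielding zero fractions
    around 0.4-0.7 despite the depth.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    kind = kind.lower()
    if kind == "16s":
        logr = rng.normal(0.0, 2.6, size=n_features)
        r = np.exp(logr)
        r /= r.sum()
        lib = np.exp(rng.normal(np.log(5e3), 0.35, size=200)).astype(int)
        lib = np.maximum(lib, 1500)
        return TemplateParams(r, dispersion=1.2, zero_inflation=None,
                              library_sizes=lib.astype(float), distribution="NB")
    if kind == "wms":
        logr = rng.normal(0.0, 3.0, size=n_features)
        r = np.exp(logr)
        r /= r.sum()
        pi = rng.beta(1.2, 2.0, size=n_features)
        # target depths sit above 10^6 so that realized library sizes (after
        # zero-inflation mass loss) stay in the WMS regime
        lib = np.exp(rng.normal(np.log(5e6), 0.5, size=200)).astype(int)
        lib = np.maximum(lib, 2_000_000)
        return TemplateParams(r, dispersion=1.5, zero_inflation=pi,
                              library_sizes=lib.astype(float), distribution="ZINB")
    raise ValueError("kind must be '16s' or 'wms'")


# ---------------------------------------------------------------------------
# DA injection
# ---------------------------------------------------------------------------

def inject_da(
    template: TemplateParams,
    proportion: float,
    fold_effect: float,
    compensation: bool = False,
    seed: int = 0,
    _max_redraws: int = 20,
):
    """Inject DA into group-2 relative means; group 1 keeps the template.

    Flags ``round(proportion * F)`` features uniformly without replacement.
    Without compensation, half the flagged features are multiplied by the
    fold effect and the rest divided by it, then everything is renormalized
    to sum to 1 (so unflagged relative means shift too).  With compensation,
    ``floor(k / (1 + fold_effect))`` of the flagged features are multiplied
    by the fold effect and the remaining flagged means by
    ``(a/b) * (1 - fold_effect) + 1`` where a (b) is the flagged up (down)
    mass — conserving the flagged total so unflagged features are untouched
    after renormalization.

    Returns ``(r_group1, r_group2, truth)``; truth has boolean ``is_da`` and
    ``direction`` ("up"/"down" = over-/under-abundant in group 2).
    """
    if not (0 < proportion < 1):
        raise ValueError("proportion must be in (0, 1)")
    r = template.relative_means
    F = len(r)
    k = int(round(proportion * F))
    if k < 2:
        raise ValueError(f"round(proportion * F) = {k} < 2: nothing to inject")
    rng = np.random.default_rng(seed)
    for _ in range(_max_redraws):
        flagged = rng.choice(F, size=k, replace=False)
        if compensation:
            n_up = int(np.floor(k / (1.0 + fold_effect)))
            n_up = max(n_up, 1)
        else:
            n_up = k // 2
        up = flagged[:n_up]
        down = flagged[n_up:]
        a = r[up].sum()
        b = r[down].sum()
        if b <= 0 or len(down) == 0:
            continue  # degenerate draw: redraw from the same stream
        r2 = r.copy()
        if compensation:
            mult_down = (a / b) * (1.0 - fold_effect) + 1.0
            if mult_down <= 0:
                continue
            r2[up] = r[up] * fold_effect
            r2[down] = r[down] * mult_down
        else:
            r2[up] = r[up] * fold_effect
            r2[down] = r[down] / fold_effect
        r2_raw = r2.copy()  # pre-normalization values (exact fold ratios)
        r2 = r2 / r2.sum()
        direction = np.array([""] * F, dtype=object)
        direction[up] = "up"
        direction[down] = "down"
        is_da = np.zeros(F, dtype=bool)
        is_da[flagged] = True
        truth = pd.DataFrame(
            {"is_da": is_da, "direction": direction},
            index=pd.Index(template.feature_ids, name="feature_id"),
        )
        truth.attrs["r2_unnormalized"] = r2_raw
        return r.copy(), r2, truth
    raise RuntimeError("inject_da: could not draw a non-degenerate flag set")


def apply_sparsity_effect(
    template: TemplateParams, truth: pd.DataFrame, sparsity_effect: float
):
    """Per-group ZINB mixing probabilities after the sparsity effect.

    In group 2, down-regulated features gain ``sparsity_effect`` zeros and
    up-regulated features lose as much, clamped to [0, 1]; group 1 and
    unflagged features keep the template values.
    """
    if template.distribution != "ZINB" and sparsity_effect != 0:
        raise ValueError("sparsity effect requires a ZINB template")
    pi = (
        template.zero_inflation.copy()
        if template.zero_inflation is not None
        else np.zeros(template.n_features)
    )
    pi1 = pi.copy()
    pi2 = pi.copy()
    if sparsity_effect:
        d = truth["direction"].to_numpy()
        pi2[d == "down"] = np.clip(pi2[d == "down"] + sparsity_effect, 0.0, 1.0)
        pi2[d == "up"] = np.clip(pi2[d == "up"] - sparsity_effect, 0.0, 1.0)
    return pi1, pi2


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _rng_streams(seed: int, replicate_index: int):
    """Independent child streams so grid axes don't reshuffle each other."""
    root = np.random.SeedSequence([seed & 0x7FFFFFFF, replicate_index])
    flags, libs, counts = root.spawn(3)
    return (
        np.random.default_rng(flags),
        np.random.default_rng(libs),
        np.random.default_rng(counts),
    )


def simulate_dataset(
    design: SimulationDesign,
    template: TemplateParams,
    replicate_index: int = 0,
    inject: bool = True,
) -> SimulatedDataset:
    """Draw one two-group dataset from the template under the design.

    Library sizes are resampled with replacement from the template's pool;
    each cell is NB(lib_j * r_f^(group), phi), with ZINB zeros added with the
    (possibly sparsity-shifted) mixing probability.  ``inject=False`` gives
    a null dataset (both groups from the template).  Fully reproducible from
    ``(design.seed, replicate_index)``.
    """
    if design.distribution != template.distribution:
        raise ValueError("design and template distributions differ")
    rng_flags, rng_libs, rng_counts = _rng_streams(design.seed, replicate_index)
    F = template.n_features
    if inject:
        r1, r2, truth = inject_da(
            template,
            design.da_proportion,
            design.fold_effect,
            design.compensation,
            seed=rng_flags.integers(2**31 - 1),
        )
    else:
        r1 = r2 = template.relative_means.copy()
        truth = pd.DataFrame(
            {"is_da": np.zeros(F, dtype=bool), "direction": [""] * F},
            index=pd.Index(template.feature_ids, name="feature_id"),
        )
    if template.distribution == "ZINB":
        pi1, pi2 = apply_sparsity_effect(template, truth, design.sparsity_effect)
    else:
        pi1 = pi2 = None
    n = design.n_per_group
    lib = rng_libs.choice(template.library_sizes, size=2 * n, replace=True)
    groups = np.array(["group1"] * n + ["group2"] * n, dtype=object)
    R = np.where(
        (groups == "group2")[None, :], r2[:, None], r1[:, None]
    )
    mu = lib[None, :] * R
    phi = design_phi = template.dispersion
    if design_phi > 0:
        size = 1.0 / phi
        p = size / (size + mu)
        counts = rng_counts.negative_binomial(size, np.clip(p, 1e-12, 1.0))
    else:
        counts = rng_counts.poisson(mu)
    if template.distribution == "ZINB":
        PI = np.where((groups == "group2")[None, :], pi2[:, None], pi1[:, None])
        dropout = rng_counts.random(counts.shape) < PI
        counts = np.where(dropout, 0, counts)
    sample_ids = [f"S{j:03d}" for j in range(2 * n)]
    ct = CountTable(
        pd.DataFrame(counts, index=template.feature_ids, columns=sample_ids),
        sample_meta=pd.DataFrame(
            {"subject_id": sample_ids, "group": groups, "center": "sim"},
            index=sample_ids,
        ),
    )
    return SimulatedDataset(
        table=ct,
        truth=truth,
        params={
            "r_group1": r1,
            "r_group2": r2,
            "pi_group1": pi1,
            "pi_group2": pi2,
            "dispersion": template.dispersion,
            "replicate_index": replicate_index,
        },
    )


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def _partial_auroc(scores, truth, max_fpr=0.1):
    """Raw partial area under the ROC (FPR in [0, max_fpr]); NaN-safe.

    ``scores``: higher = more DA (missing handled by the caller).  Returns
    the raw area (perfect classifier: max_fpr).
    """
    order = np.argsort(-scores, kind="mergesort")
    t = truth[order]
    P = t.sum()
    N = (~t).sum()
    if P == 0 or N == 0:
        return np.nan
    tpr = np.cumsum(t) / P
    fpr = np.cumsum(~t) / N
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    # interpolate TPR at max_fpr and integrate the step curve up to there
    keep = fpr <= max_fpr
    f = fpr[keep]
    tp = tpr[keep]
    if f[-1] < max_fpr:
        tp_at = np.interp(max_fpr, fpr, tpr)
        f = np.concatenate([f, [max_fpr]])
        tp = np.concatenate([tp, [tp_at]])
    return float(np.trapezoid(tp, f))


def power_evaluation(
    datasets: list[SimulatedDataset],
    methods: list[str],
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """TPR/FPR at an adjusted-p threshold plus pAUROC, averaged over replicates.

    Missing p values rank last (score below every tested feature).  Returns
    one row per method with ``tpr``, ``fpr``, ``pauroc_raw``,
    ``pauroc_norm`` (raw / 0.1) and ``n_failed`` replicate count.
    """
    if not datasets:
        raise ValueError("need at least one simulated dataset")
    acc: dict[str, dict[str, list]] = {
        m: {"tpr": [], "fpr": [], "pauroc": []} for m in methods
    }
    failed = {m: 0 for m in methods}
    for i, sim in enumerate(datasets):
        truth = sim.truth["is_da"].to_numpy()
        labels = sim.table.sample_meta["group"].to_numpy()
        for m in methods:
            try:
                res = run_da(sim.table, labels, m, seed=seed + 101 * i)
            except Exception:
                failed[m] += 1
                continue
            tab = res.table
            called = (tab["adj_p"] < alpha).fillna(False).to_numpy()
            P = truth.sum()
            N = (~truth).sum()
            acc[m]["tpr"].append((called & truth).sum() / P if P else np.nan)
            acc[m]["fpr"].append((called & ~truth).sum() / N if N else np.nan)
            if tab["raw_p"].notna().any():
                scores = -tab["raw_p"].to_numpy()
            else:
                scores = tab["rank_score"].abs().to_numpy()
            scores = np.where(np.isfinite(scores), scores, -np.inf)
            acc[m]["pauroc"].append(_partial_auroc(scores, truth))
    rows = []
    for m in methods:
        pauroc = float(np.nanmean(acc[m]["pauroc"])) if acc[m]["pauroc"] else np.nan
        rows.append(
            {
                "method": m,
                "tpr": float(np.nanmean(acc[m]["tpr"])) if acc[m]["tpr"] else np.nan,
                "fpr": float(np.nanmean(acc[m]["fpr"])) if acc[m]["fpr"] else np.nan,
                "pauroc_raw": pauroc,
                "pauroc_norm": pauroc / 0.1 if np.isfinite(pauroc) else np.nan,
                "n_failed": failed[m],
            }
        )
    return pd.DataFrame(rows).set_index("method")
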