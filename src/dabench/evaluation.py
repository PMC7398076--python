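"""Evaluation engines: type-I error on mock splits, CAT concordance, enrichment.

Three complementary real-data evaluations of DA methods:

* **Type I error** — samples of a presumed-null dataset are repeatedly split
  into two arbitrary groups; a calibrated test's raw p values should be
  uniform (Kolmogorov-Smirnov distance) and its false positive rate should
  match the nominal threshold.
* **Concordance** — Concordance At the Top (CAT): the fraction of shared
  features in the top-i of two ranked lists, i = 1..R, summarized by its
  area under the curve.  Within-method concordance (WMC) compares a method
  with itself across random data halves; between-method concordance (BMC)
  compares methods on the same half.
* **Enrichment** — with aerobic/anaerobic annotations and a comparison where
  the expected direction is known, directional Fisher exact tests,
  Haldane-Anscombe log odds ratios, TP-FP curves over ranking thresholds and
  mutual findings across representative methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountTable
from .methods import DAResult, run_da

__all__ = [
    "CATCurve",
    "mock_labelings",
    "type_one_error_summary",
    "cat_curve",
    "cat_auc",
    "concordance_analysis",
    "enrichment_analysis",
    "tp_fp_difference_curve",
    "mutual_findings",
]

METABOLISM_CLASSES = ("aerobic", "anaerobic", "facultative")


# ---------------------------------------------------------------------------
# mock splits / type I error
# ---------------------------------------------------------------------------

def mock_labelings(n_samples: int, B: int, seed: int = 0) -> list[np.ndarray]:
    """B balanced random two-group labelings of ``n_samples`` samples.

    Group 1 gets ceil(n/2) samples, group 2 floor(n/2).  Labelings are
    distinct whenever combinatorially possible and reproducible by seed.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples for a balanced mock split")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n1 = (n_samples + 1) // 2
    from math import comb

    max_distinct = comb(n_samples, n1)
    seen = set()
    out = []
    attempts = 0
    while len(out) < B:
        perm = rng.permutation(n_samples)
        labels = np.full(n_samples, "group2", dtype=object)
        labels[perm[:n1]] = "group1"
        key = tuple(labels)
        attempts += 1
        if key in seen and len(seen) < max_distinct and attempts < 1000 * B:
            continue
        seen.add(key)
        out.append(labels)
    return out


def type_one_error_summary(
    ct: CountTable,
    methods: list[str],
    B: int = 1000,
    alphas: tuple = (0.01, 0.05, 0.1),
    seed: int = 0,
    n_quantiles: int = 100,
    method_options: dict | None = None,
):
    """Per-method KS statistics and FPR over B mock two-group comparisons.

    For each mock dataset and method, the raw p values are compared to
    U(0, 1) (two-sided KS sup distance) and the fraction below each nominal
    alpha is recorded.  Also returns an averaged qq curve: for each
    theoretical quantile the mean of the observed p-value quantiles across
    mocks.

    Returns ``(summary, qq)``: a tidy frame (method, replicate, ks,
    fpr_<alpha>...) and a frame of averaged observed quantiles per method.
    """
    labelings = mock_labelings(ct.n_samples, B, seed=seed)
    theo = (np.arange(n_quantiles) + 0.5) / n_quantiles
    rows = []
    qq_acc: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    failures: dict[str, int] = {m: 0 for m in methods}
    for b, labels in enumerate(labelings):
        for m in methods:
            try:
                opts = (method_options or {}).get(m, {})
                res = run_da(ct, labels, m, seed=seed + 7919 * b, **opts)
            except Exception:
                failures[m] += 1
                continue
            p = res.table["raw_p"].dropna().to_numpy()
            if p.size == 0:
                failures[m] += 1
                continue
            ks = stats.kstest(p, "uniform").statistic
            row = {"method": m, "replicate": b, "ks": float(ks), "n_tested": p.size}
            for a in alphas:
                row[f"fpr_{a}"] = float((p < a).mean())
            rows.append(row)
            qq_acc[m].append(np.quantile(p, theo))
    summary = pd.DataFrame(rows)
    qq = pd.DataFrame(
        {m: np.mean(v, axis=0) for m, v in qq_acc.items() if v},
        index=pd.Index(theo, name="theoretical_quantile"),
    )
    summary.attrs["failures"] = failures
    return summary, qq


# ---------------------------------------------------------------------------
# CAT
# ---------------------------------------------------------------------------

@dataclass
class CATCurve:
    """Concordance-at-the-top values C_1..C_R between two ranked lists.

    ``values[i-1]`` is |top_i(L) ∩ top_i(M)| / i.  When the common feature
    universe has fewer than R elements the trailing entries are NaN and
    ``truncated`` is set.
    """

    values: np.ndarray
    R: int
    truncated: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        finite = v[np.isfinite(v)]
        if ((finite < -1e-12) | (finite > 1 + 1e-12)).any():
            raise ValueError("CAT values must lie in [0, 1]")
        self.values = v


def cat_curve(listA, listB, R: int = 100) -> CATCurve:
    """CAT curve between two complete rankings of the same feature universe."""
    A = list(listA)
    B = list(listB)
    if len(set(A)) != len(A) or len(set(B)) != len(B):
        raise ValueError("ranked lists must not contain duplicate ids")
    if set(A) != set(B):
        raise ValueError("ranked lists must cover the same feature universe")
    F = len(A)
    truncated = R > F
    upto = min(R, F)
    values = np.full(R, np.nan)
    setA: set = set()
    setB: set = set()
    inter = 0
    for i in range(upto):
        a, b = A[i], B[i]
        if a == b:
            inter += 1
        else:
            if a in setB:
                inter += 1
            if b in setA:
                inter += 1
        setA.add(a)
        setB.add(b)
        values[i] = inter / (i + 1)
    return CATCurve(values=values, R=R, truncated=truncated)


def cat_auc(curve: CATCurve) -> float:
    """Rectangle-rule area under the CAT curve, in [0, 1].

    When the curve is truncated (universe smaller than R) the mean is taken
    over the available ranks only.
    """
    v = curve.values[np.isfinite(curve.values)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())


# ---------------------------------------------------------------------------
# concordance analysis (random halves)
# ---------------------------------------------------------------------------

def _dedup_subjects(ct: CountTable, rng) -> CountTable:
    meta = ct.sample_meta
    if "subject_id" not in meta.columns or (meta["subject_id"] == "absent").all():
        return ct
    ids = list(ct.sample_ids)
    rng.shuffle(ids)
    keep = []
    seen = set()
    for s in ids:
        subj = meta.loc[s, "subject_id"]
        if subj == "absent" or subj not in seen:
            keep.append(s)
            seen.add(subj)
    keep = [s for s in ct.sample_ids if s in set(keep)]
    return ct.subset_samples(keep)


def _stratified_half_split(sample_ids, groups, rng):
    half1, half2 = [], []
    for g in np.unique(groups):
        ids = [s for s, gg in zip(sample_ids, groups) if gg == g]
        rng.shuffle(ids)
        k = len(ids) // 2
        half1.extend(ids[:k])
        half2.extend(ids[k : 2 * k])
    return half1, half2


def concordance_analysis(
    ct: CountTable,
    group_labels,
    methods: list[str],
    n_splits: int = 100,
    R: int = 100,
    seed: int = 0,
    dedup_subjects: bool = True,
):
    """Within- and between-method concordance over random half splits.

    Each split halves the samples (stratified by group); every method is run
    on both halves.  WMC is the CAT AUC of a method against itself across
    halves; BMC the CAT AUC between two methods within the same half
    (averaged over the two halves).  Both are averaged over ``n_splits``.

    Returns ``(wmc, bmc, n_failed)``: a Series per method, a symmetric
    DataFrame (diagonal = WMC) and a failure tally.
    """
    rng = np.random.default_rng(seed)
    full_ids = list(ct.sample_ids)
    g_full = pd.Series(np.asarray(group_labels, dtype=object), index=full_ids)
    if len(g_full) != len(full_ids):
        raise ValueError("group_labels must align with the samples")
    if dedup_subjects:
        ct = _dedup_subjects(ct, rng)
    g = g_full.loc[ct.sample_ids]
    counts = g.value_counts()
    if (counts < 4).any():
        raise ValueError("each group needs >= 4 samples to split in half")
    wmc_acc = {m: [] for m in methods}
    bmc_acc: dict[tuple, list] = {}
    n_failed = {m: 0 for m in methods}
    for s in range(n_splits):
        ids1, ids2 = _stratified_half_split(list(ct.sample_ids), g.to_numpy(), rng)
        halves = [ct.subset_samples(ids1), ct.subset_samples(ids2)]
        labels = [g.loc[ids1].to_numpy(), g.loc[ids2].to_numpy()]
        rankings: dict[tuple, list] = {}
        for m in methods:
            for h in (0, 1):
                try:
                    res = run_da(halves[h], labels[h], m, seed=seed + 31 * s + h)
                    rankings[(m, h)] = res.ranked_features()
                except Exception:
                    n_failed[m] += 1
        for m in methods:
            if (m, 0) in rankings and (m, 1) in rankings:
                wmc_acc[m].append(
                    cat_auc(cat_curve(rankings[(m, 0)], rankings[(m, 1)], R))
                )
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                vals = []
                for h in (0, 1):
                    if (m1, h) in rankings and (m2, h) in rankings:
                        vals.append(
                            cat_auc(cat_curve(rankings[(m1, h)], rankings[(m2, h)], R))
                        )
                if vals:
                    bmc_acc.setdefault((m1, m2), []).append(float(np.mean(vals)))
    wmc = pd.Series({m: float(np.mean(v)) if v else np.nan for m, v in wmc_acc.items()})
    bmc = pd.DataFrame(np.nan, index=methods, columns=methods)
    for m in methods:
        bmc.loc[m, m] = wmc[m]
    for (m1, m2), vals in bmc_acc.items():
        bmc.loc[m1, m2] = bmc.loc[m2, m1] = float(np.mean(vals))
    return wmc, bmc, n_failed


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _da_set_with_direction(da: DAResult, alpha, top_fraction):
    t = da.table
    if t["raw_p"].notna().any():
        sel = t["adj_p"] < alpha
    else:  # importance-ranked method: top fraction of the universe
        k = max(int(round(top_fraction * len(t))), 1)
        ranked = da.ranked_features()[:k]
        sel = t.index.isin(ranked)
        sel = pd.Series(sel, index=t.index)
    direction = np.where(t["coef"] > 0, "UP", np.where(t["coef"] < 0, "DOWN", ""))
    return pd.Series(sel, index=t.index), pd.Series(direction, index=t.index)


def enrichment_analysis(
    da: DAResult,
    annotations: pd.Series,
    alpha: float = 0.1,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Directional enrichment of metabolism classes among the DA features.

    Six one-sided ("greater") Fisher exact tests: {aerobic, anaerobic,
    facultative} x {UP, DOWN}.  Features annotated "absent"/"unassigned" are
    excluded from the contingency universe.  Log odds ratios use the
    Haldane-Anscombe +0.5 correction (+1 per cell for the variance).

    Returns a frame with class, direction, count (DA in that class and
    direction), fisher_p, log_or, var_log_or.
    """
    ann = annotations.reindex(da.table.index).fillna("absent").astype(str)
    sel, direction = _da_set_with_direction(da, alpha, top_fraction)
    if sel.any() and (direction[sel] == "").all():
        raise ValueError("all selected features lack a direction (zero coefficients)")
    universe = ann.isin(METABOLISM_CLASSES)
    rows = []
    for cls in METABOLISM_CLASSES:
        for direc in ("UP", "DOWN"):
            in_set = sel & (direction == direc) & universe
            in_cls = (ann == cls) & universe
            a = int((in_set & in_cls).sum())
            b = int((~in_set & in_cls & universe).sum())
            c = int((in_set & ~in_cls & universe).sum())
            d = int((~in_set & ~in_cls & universe).sum())
            if a + b + c + d == 0 or (a + c) == 0:
                pval, lor, var = 1.0, 0.0, np.nan
            else:
                _, pval = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
                lor = float(np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))))
                var = float(
                    1 / (a + 1) + 1 / (b + 1) + 1 / (c + 1) + 1 / (d + 1)
                )
            rows.append(
                {
                    "class": cls,
                    "direction": direc,
                    "count": a,
                    "fisher_p": float(pval),
                    "log_or": lor,
                    "var_log_or": var,
                }
            )
    return pd.DataFrame(rows)


def tp_fp_difference_curve(
    da: DAResult,
    annotations: pd.Series,
    thresholds=None,
) -> pd.DataFrame:
    """TP - FP along the ranking, at top-K% thresholds.

    Putative TP: aerobic features called UP plus anaerobic called DOWN;
    putative FP: the reverse.  Facultative and unannotated features are
    ignored.  Default thresholds: 1%..20% of the feature universe.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.201, 0.01), 4)
    ann = annotations.reindex(da.table.index).fillna("absent").astype(str)
    ranked = da.ranked_features()
    direction = pd.Series(
        np.where(da.table["coef"] > 0, "UP",
                 np.where(da.table["coef"] < 0, "DOWN", "")),
        index=da.table.index,
    )
    F = len(ranked)
    rows = []
    for thr in thresholds:
        k = int(round(thr * F))
        top = ranked[:k]
        a_up = sum(1 for f in top if ann[f] == "aerobic" and direction[f] == "UP")
        an_dn = sum(1 for f in top if ann[f] == "anaerobic" and direction[f] == "DOWN")
        a_dn = sum(1 for f in top if ann[f] == "aerobic" and direction[f] == "DOWN")
        an_up = sum(1 for f in top if ann[f] == "anaerobic" and direction[f] == "UP")
        rows.append(
            {"threshold": float(thr), "tp": a_up + an_dn, "fp": a_dn + an_up,
             "tp_minus_fp": a_up + an_dn - a_dn - an_up}
        )
    return pd.DataFrame(rows)


def mutual_findings(
    results: list[DAResult],
    direction: str,
    min_methods: int,
    alpha: float = 0.1,
    top_fraction: float = 0.10,
) -> pd.Series:
    """Features called DA in the given direction by >= min_methods methods.

    Returns the supporting-method count per qualifying feature, sorted
    descending.  Representative-method selection (one per normalization) is
    the caller's responsibility via the catalog labels.
    """
    if direction not in ("UP", "DOWN"):
        raise ValueError("direction must be 'UP' or 'DOWN'")
    counts: dict[str, int] = {}
    for res in results:
        sel, direc = _da_set_with_direction(res, alpha, top_fraction)
        for f in res.table.index[sel & (direc == direction)]:
            counts[f] = counts.get(f, 0) + 1
    s = pd.Series(counts, dtype=int)
    s = s[s >= min_methods]
    return s.sort_values(ascending=False)
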