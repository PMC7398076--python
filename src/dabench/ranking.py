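"""Rank aggregation of methods across evaluation criteria.

Each evaluation engine yields one number per method (KS median, |FPR -
alpha|, average WMC, TP - FP at a threshold, pAUROC ...).  Methods are
ranked within each criterion (mean ranks for ties, direction configurable),
ranks are averaged across criteria and min-max normalized to [0, 1] via
``(avg_rank - 1) / (K - 1)`` — 0 is the uniformly best method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["aggregate_ranks", "DEFAULT_DIRECTIONS"]

#: criterion name -> whether a *lower* raw value is better
DEFAULT_DIRECTIONS = {
    "ks": "lower",
    "fpr_deviation": "lower",
    "wmc": "higher",
    "tp_minus_fp": "higher",
    "pauroc": "higher",
}


def aggregate_ranks(
    values: pd.DataFrame,
    directions: dict[str, str] | None = None,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate per-criterion method scores into a normalized average rank.

    Parameters
    ----------
    values
        methods x criteria frame of raw scores; NaN marks a criterion that
        is unavailable for a method (e.g. no p values -> no type-I column).
    directions
        per-criterion "lower"/"higher" = which raw value is better; defaults
        from :data:`DEFAULT_DIRECTIONS`, else "lower".
    weights
        optional per-criterion weights (default 1).

    Returns a frame with per-criterion ranks, the (weighted) average rank
    over the criteria available for each method, the normalized rank in
    [0, 1] (lower = better) and a ``complete`` flag.
    """
    if values.shape[1] == 0:
        raise ValueError("empty criteria set")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 methods to rank")
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    weights = weights or {}
    K = values.shape[0]
    ranks = pd.DataFrame(index=values.index)
    for crit in values.columns:
        col = values[crit]
        if col.notna().sum() < 2:
            raise ValueError(f"criterion {crit!r} present for fewer than 2 methods")
        ascending = directions.get(crit, "lower") == "lower"
        ranks[f"rank_{crit}"] = col.rank(ascending=ascending, method="average")
    w = np.array([weights.get(c, 1.0) for c in values.columns])
    rank_mat = ranks.to_numpy()
    avail = np.isfinite(rank_mat)
    wsum = (avail * w[None, :]).sum(1)
    avg = np.nansum(rank_mat * w[None, :], axis=1) / wsum
    out = ranks.copy()
    out["avg_rank"] = avg
    out["normalized_rank"] = (avg - 1.0) / (K - 1.0) if K > 1 else 0.0
    out["complete"] = avail.all(axis=1)
    return out.sort_values("normalized_rank")
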