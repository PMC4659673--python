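"""Estimated-overall-variation cue-saliency statistic.

For an acoustic parameter with per-category means x_1..x_K the statistic is

    sum over all K(K-1)/2 unordered category pairs of |x_i - x_j|
    ------------------------------------------------------------
                     sum over categories of |x_k|

a dimensionless proportion: 0 iff all category means are equal, invariant to
a positive rescaling of the parameter, but NOT invariant to translation (the
denominator uses absolute means), so its value depends on the parameter's
natural zero.  With six tone categories the numerator runs over the 15 tone
contrasts; the computation generalizes to any K >= 2 (e.g. the 4 stress
conditions with 6 pairs).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["estimated_overall_variation", "saliency_table"]


def estimated_overall_variation(means) -> float:
    """The saliency proportion for one parameter's per-category means.

    Returns ``nan`` when all means are zero (undefined ratio).  Raises
    ``ValueError`` for fewer than 2 categories or non-finite input.
    """
    m = np.asarray(list(means), dtype=float)
    if m.size < 2:
        raise ValueError("need at least 2 category means")
    if not np.all(np.isfinite(m)):
        raise ValueError("category means must be finite")
    denom = float(np.abs(m).sum())
    if denom == 0:
        return float("nan")
    num = float(sum(abs(a - b) for a, b in combinations(m, 2)))
    return num / denom


def saliency_table(
    features: pd.DataFrame,
    group_col: str = "category",
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Rank acoustic parameters by estimated overall variation.

    ``features`` is a per-token table (or already a per-category table of
    means — grouping by a unique key is a no-op).  Per parameter, category
    means are computed and the statistic applied; the result has columns
    ``parameter``, ``variation`` (proportion), ``percent`` (rounded to the
    nearest integer, the reporting convention), and ``rank`` (1 = most
    salient).  Raises ``KeyError`` for a missing parameter column.
    """
    if group_col not in features.columns:
        raise KeyError(f"missing grouping column {group_col!r}")
    if parameters is None:
        parameters = [c for c in features.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(features[c])]
    for p in parameters:
        if p not in features.columns:
            raise KeyError(f"missing parameter column {p!r}")
    cat_means = features.groupby(group_col)[parameters].mean()
    if len(cat_means) < 2:
        raise ValueError("need at least 2 categories")
    rows = []
    for p in parameters:
        v = estimated_overall_variation(cat_means[p].to_numpy())
        rows.append({"parameter": p, "variation": v,
                     "percent": int(round(v * 100)) if np.isfinite(v) else np.nan})
    out = pd.DataFrame(rows).sort_values("variation", ascending=False,
                                         kind="stable", ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
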