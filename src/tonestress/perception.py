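"""Aggregation of AXB discrimination data: latency trimming, accuracy and
latency summaries, and acoustic-perceptual correlation tables.

Latency analysis follows the convention of the emulated study: only
correctly answered trials enter, and within each subject x test x contrast
cell latencies more than 2 SD above or below the cell mean are removed
(single pass).  Timeouts count as errors for accuracy and never contribute a
latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .templates import TONES

__all__ = [
    "trim_latencies",
    "summarize",
    "pearson",
    "tone_stress_correlation",
    "CorrelationTable",
    "acoustic_perceptual_table",
]

_CELL = ["subject", "test", "contrast"]


def trim_latencies(trials: pd.DataFrame, n_sd: float = 2.0) -> tuple[pd.DataFrame, float]:
    """Remove extreme latencies from correct trials, cell-wise.

    A latency is removed when |x - cell mean| > n_sd * cell SD (sample SD;
    cells with fewer than 3 correct trials, or zero SD, keep everything).
    Returns the trial table with trimmed rows dropped and the fraction of
    correct-trial latencies removed.  Incorrect and timeout trials pass
    through untouched.
    """
    correct = trials["correct"] & trials["latency_ms"].notna()
    lat = trials.loc[correct, _CELL + ["latency_ms"]]
    if lat.empty:
        return trials.copy(), 0.0
    g = lat.groupby(_CELL)["latency_ms"]
    mean = g.transform("mean")
    sd = g.transform("std").fillna(0.0)
    n = g.transform("size")
    outlier = (n >= 3) & (sd > 0) & ((lat["latency_ms"] - mean).abs() > n_sd * sd)
    keep = trials.index.difference(lat.index[outlier])
    fraction = float(outlier.sum()) / float(len(lat))
    return trials.loc[keep].copy(), fraction


def summarize(trials: pd.DataFrame, per_contrast: bool = False,
              trim: bool = True) -> pd.DataFrame:
    """Accuracy and trimmed mean latency per group x test (x contrast).

    Accuracy is the proportion of correct trials (timeouts incorrect);
    latency is the mean over correct, trim-surviving trials.  Empty groups
    are simply absent.  The per-cell trimmed fraction of correct-trial
    latencies is reported alongside.
    """
    trimmed, frac = trim_latencies(trials) if trim else (trials, 0.0)
    keys = ["group", "test"] + (["contrast"] if per_contrast else [])

    acc = trials.groupby(keys)["correct"].mean().rename("accuracy")
    lat = (trimmed[trimmed["correct"]]
           .groupby(keys)["latency_ms"].mean().rename("mean_latency_ms"))
    n_subj = trials.groupby(keys)["subject"].nunique().rename("n_subjects")
    out = pd.concat([acc, lat, n_subj], axis=1).reset_index()
    out["trimmed_fraction"] = frac
    return out


def pearson(x, y) -> float:
    """Sample Pearson correlation; ``nan`` when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def tone_stress_correlation(trials: pd.DataFrame) -> pd.DataFrame:
    """Per group: Pearson r between subjects' tone and stress accuracies."""
    acc = (trials.groupby(["group", "subject", "test"])["correct"]
           .mean().unstack("test"))
    rows = []
    for group, sub in acc.groupby(level="group"):
        rows.append({"group": group, "n": len(sub),
                     "r": pearson(sub["tone"], sub["stress"])})
    return pd.DataFrame(rows)


@dataclass
class CorrelationTable:
    """Symmetric Pearson correlation matrix with its unit of analysis."""

    data: pd.DataFrame  # the joined accuracy + feature table (one row per unit)
    corr: pd.DataFrame  # full symmetric correlation matrix
    n: int
    unit: str  # "tone_level" or "contrast_level"


def _per_contrast_accuracy(trials: pd.DataFrame) -> pd.DataFrame:
    tone = trials[trials["test"] == "tone"]
    return (tone.groupby(["contrast", "group"])["correct"]
            .mean().unstack("group"))


def acoustic_perceptual_table(
    trials: pd.DataFrame,
    features: pd.DataFrame,
    unit: str = "tone_level",
    parameters: list[str] | None = None,
) -> CorrelationTable:
    """Correlate group tone-perception accuracies with acoustic parameters.

    ``features`` is a per-token table with a ``category`` column holding tone
    labels.  Two units of analysis are supported:

    * ``tone_level`` (n = 6): per-tone feature means; a tone's accuracy is
      the mean accuracy of the 5 contrasts containing it.
    * ``contrast_level`` (n = 15): per-contrast accuracy against the absolute
      difference of the two tones' feature means.

    Parameters constant across units yield ``nan`` rows in the matrix.
    Raises ``KeyError`` when features and trials cannot be joined.
    """
    if "category" not in features.columns:
        raise KeyError("features need a 'category' column with tone labels")
    if parameters is None:
        parameters = [c for c in features.columns
                      if c != "category" and pd.api.types.is_numeric_dtype(features[c])]
    tone_means = features.groupby("category")[parameters].mean()
    acc = _per_contrast_accuracy(trials)
    groups = list(acc.columns)

    if unit == "tone_level":
        rows = []
        for tone in TONES:
            if tone not in tone_means.index:
                raise KeyError(f"no feature rows for {tone}")
            row = {"unit": tone}
            for grp in groups:
                among = [c for c in acc.index if tone in c.split("-")]
                row[f"{grp}_accuracy"] = float(acc.loc[among, grp].mean())
            row.update(tone_means.loc[tone, parameters].to_dict())
            rows.append(row)
    elif unit == "contrast_level":
        rows = []
        for contrast in acc.index:
            a, b = contrast.split("-")
            if a not in tone_means.index or b not in tone_means.index:
                raise KeyError(f"no feature rows for contrast {contrast}")
            row = {"unit": contrast}
            for grp in groups:
                row[f"{grp}_accuracy"] = float(acc.loc[contrast, grp])
            for p in parameters:
                row[p] = abs(float(tone_means.loc[a, p] - tone_means.loc[b, p]))
            rows.append(row)
    else:
        raise ValueError("unit must be 'tone_level' or 'contrast_level'")

    data = pd.DataFrame(rows).set_index("unit")
    corr = data.corr(method="pearson")
    return CorrelationTable(data=data, corr=corr, n=len(data), unit=unit)
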