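"""F0 contour feature battery for one vowel token.

The measures quantify tone height (F0 average, onset, offset), overall
contour (general slope = displacement / duration, displacement = offset -
onset), and the fall/rise decomposition around the F0 minimum (fall and rise
displacements, times and slopes, plus the rise-to-fall ratios).  The major
slope is the contour's perceptually dominant leg: the rise slope for rising
categories, the fall slope for the falling category, and the general slope
for level categories.

Units: durations and times in ms, F0 in Hz, slopes in Hz/s.  (The corpus
these measures emulate labels its slopes "Hz/ms", but every magnitude there
is numerically consistent with Hz per second — e.g. -25.54 Hz over 230.64 ms
is -110.7 Hz/s; this package computes and reports Hz/s.)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .track import F0Track

__all__ = [
    "ContourFeatures",
    "basic_measures",
    "general_slope",
    "fall_rise_decompose",
    "rf_ratios",
    "major_slope",
    "classify_contour",
    "features_from_track",
    "feature_table",
    "CLASSIFICATION_RANGES",
]

#: Major-slope intervals (Hz/s) that separate the contour classes, from the
#: 95% confidence ranges of the template corpus.
CLASSIFICATION_RANGES = {
    "rising": (270.0, 410.0),
    "level": (-130.0, -70.0),
    "falling": (-260.0, -200.0),
}


@dataclass
class ContourFeatures:
    """The full measure battery for one vowel token."""

    duration_ms: float
    f0_avg: float
    f0_onset: float
    f0_offset: float
    general_slope: float
    displacement: float
    f0_min: float
    f0_min_time_ms: float
    fall_displacement: float
    fall_time_ms: float
    fall_slope: float
    rise_displacement: float
    rise_time_ms: float
    rise_slope: float
    rf_d_ratio: float
    rf_t_ratio: float
    major_slope: float = np.nan
    contour_class: str = ""
    degenerate_decomposition: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


class InsufficientDataError(ValueError):
    """Raised when a track has too few voiced frames for a measure."""


def _voiced(track: F0Track, minimum: int) -> tuple[np.ndarray, np.ndarray]:
    t, f = track.voiced_times(), track.voiced_f0()
    if f.size < minimum:
        raise InsufficientDataError(
            f"need >= {minimum} voiced frames, got {f.size}"
        )
    return t, f


def basic_measures(track: F0Track) -> tuple[float, float, float, float]:
    """(duration_ms, f0_avg, f0_onset, f0_offset).

    Onset/offset are the first/last voiced frame values, the average is the
    mean over voiced frames, and duration is the voiced span.
    """
    t, f = _voiced(track, 2)
    return (
        float((t[-1] - t[0]) * 1000.0),
        float(np.mean(f)),
        float(f[0]),
        float(f[-1]),
    )


def general_slope(f0_onset: float, f0_offset: float, duration_ms: float) -> float:
    """(offset - onset) / duration, in Hz/s, signed."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    return (f0_offset - f0_onset) / (duration_ms / 1000.0)


def _median3(x: np.ndarray) -> np.ndarray:
    """3-point running median (edges passed through)."""
    if x.size < 3:
        return x.copy()
    out = x.copy()
    stacked = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def fall_rise_decompose(track: F0Track) -> dict:
    """Split the contour at the F0 minimum into a falling and a rising leg.

    The minimum is located on a 3-frame median-smoothed copy of the voiced
    track (earliest frame on ties), then refined to the raw minimum among the
    located frame's immediate neighbors; displacements and times use the raw
    frame values at the located index so that fall + rise displacement equals the
    overall displacement and fall + rise time equals the duration, exactly.
    A minimum at the first or last voiced frame leaves one leg with zero time
    (slope reported as 0) and flags the decomposition degenerate.
    """
    t, f = _voiced(track, 3)
    smoothed = _median3(f)
    i_s = int(np.argmin(smoothed))  # argmin takes the earliest tie
    # the median flattens a sharp corner; refine to the raw minimum among the
    # smoothed argmin's immediate neighbors (earliest on ties)
    lo = max(0, i_s - 1)
    i_min = lo + int(np.argmin(f[lo:i_s + 2]))
    f_min = float(f[i_min])
    fall_disp = f_min - float(f[0])
    rise_disp = float(f[-1]) - f_min
    fall_time = float((t[i_min] - t[0]) * 1000.0)
    rise_time = float((t[-1] - t[i_min]) * 1000.0)
    degenerate = i_min == 0 or i_min == f.size - 1
    return {
        "f0_min": f_min,
        "f0_min_time_ms": float((t[i_min] - t[0]) * 1000.0),
        "fall_displacement": fall_disp,
        "fall_time_ms": fall_time,
        "fall_slope": fall_disp / (fall_time / 1000.0) if fall_time > 0 else 0.0,
        "rise_displacement": rise_disp,
        "rise_time_ms": rise_time,
        "rise_slope": rise_disp / (rise_time / 1000.0) if rise_time > 0 else 0.0,
        "degenerate": degenerate,
    }


def rf_ratios(fall_displacement: float, fall_time_ms: float,
              rise_displacement: float, rise_time_ms: float) -> tuple[float, float]:
    """Rise-to-fall ratios of displacement magnitude and of leg duration.

    Undefined ratios (zero fall displacement or time) come back as ``nan``
    rather than raising.
    """
    d_ratio = (abs(rise_displacement) / abs(fall_displacement)
               if fall_displacement != 0 else np.nan)
    t_ratio = rise_time_ms / fall_time_ms if fall_time_ms > 0 else np.nan
    return float(d_ratio), float(t_ratio)


def major_slope(features: ContourFeatures, contour_class: str) -> float:
    """Rise slope for rising, fall slope for falling, general slope for level."""
    if contour_class == "rising":
        return features.rise_slope
    if contour_class == "falling":
        return features.fall_slope
    if contour_class == "level":
        return features.general_slope
    raise ValueError(f"unknown contour class {contour_class!r}")


def classify_contour(major_slope_hz_s: float) -> str:
    """Assign rising/level/falling by the fixed major-slope intervals;
    values outside every interval are 'unclassified'."""
    for cls, (lo, hi) in CLASSIFICATION_RANGES.items():
        if lo <= major_slope_hz_s <= hi:
            return cls
    return "unclassified"


def features_from_track(track: F0Track, contour_class: str | None = None) -> ContourFeatures:
    """Compute the full battery from one track.

    ``contour_class`` selects the major-slope leg; if omitted it is taken
    from the track's metadata, falling back to classification by general
    slope sign thresholds being unavailable — the class must then be given.
    The fall/rise decomposition is always computed; for level-class tokens it
    is diagnostic only.
    """
    if contour_class is None:
        contour_class = track.meta.get("contour_class", "")
    duration_ms, f0_avg, f0_onset, f0_offset = basic_measures(track)
    gs = general_slope(f0_onset, f0_offset, duration_ms)
    dec = fall_rise_decompose(track)
    d_ratio, t_ratio = rf_ratios(
        dec["fall_displacement"], dec["fall_time_ms"],
        dec["rise_displacement"], dec["rise_time_ms"],
    )
    feats = ContourFeatures(
        duration_ms=duration_ms,
        f0_avg=f0_avg,
        f0_onset=f0_onset,
        f0_offset=f0_offset,
        general_slope=gs,
        displacement=f0_offset - f0_onset,
        f0_min=dec["f0_min"],
        f0_min_time_ms=dec["f0_min_time_ms"],
        fall_displacement=dec["fall_displacement"],
        fall_time_ms=dec["fall_time_ms"],
        fall_slope=dec["fall_slope"],
        rise_displacement=dec["rise_displacement"],
        rise_time_ms=dec["rise_time_ms"],
        rise_slope=dec["rise_slope"],
        rf_d_ratio=d_ratio,
        rf_t_ratio=t_ratio,
        contour_class=contour_class,
        degenerate_decomposition=dec["degenerate"],
    )
    if contour_class:
        feats.major_slope = major_slope(feats, contour_class)
    return feats


def feature_table(tracks: list[F0Track], labels: list[str] | None = None,
                  classes: list[str] | None = None) -> pd.DataFrame:
    """One-row-per-token feature table.

    ``labels`` are category labels (tone or stress condition) stored in a
    ``category`` column; ``classes`` are contour classes per token (default:
    from track metadata).
    """
    rows = []
    for i, trk in enumerate(tracks):
        cls = classes[i] if classes is not None else None
        feats = features_from_track(trk, cls)
        row = feats.as_dict()
        row["category"] = labels[i] if labels is not None else trk.meta.get("label", "")
        rows.append(row)
    return pd.DataFrame(rows)
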