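"""Acoustic extraction: autocorrelation pitch tracking, mean intensity, WAV
I/O, and the token acceptance filters.

The pitch tracker is a normalized-autocorrelation design in the Praat
tradition: per analysis frame the normalized autocorrelation is evaluated
over the candidate lag range, an octave cost penalizes longer lags, the peak
is refined by parabolic interpolation, and frames whose peak correlation
falls below the voicing threshold are marked unvoiced.  Edge frames use the
valid (asymmetric) part of the analysis window, with the frame time reported
at the temporal centroid of the samples actually used, and the finished track
is linearly extrapolated to the segment edges so that onset/offset measures
are not biased toward the vowel interior on fast contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

from .track import F0Track

__all__ = [
    "REF_PRESSURE_PA",
    "FULL_SCALE_PA",
    "VowelSegment",
    "TokenRecord",
    "read_wav",
    "write_wav",
    "track_pitch",
    "mean_intensity",
    "intensity_contour",
    "apply_acceptance_filters",
]

#: Reference pressure for dB SPL (2e-5 Pa).
REF_PRESSURE_PA = 2e-5
#: Calibration: pressure corresponding to digital full scale.  sqrt(2) Pa puts
#: a full-scale sine at 1 Pa RMS = 94 dB SPL, the conventional calibration-tone
#: level.  The corpus the templates emulate presupposes some such calibration
#: without stating it; this one is the package's fixed choice.
FULL_SCALE_PA = np.sqrt(2.0)

DEFAULT_SR = 44_100


@dataclass(frozen=True)
class VowelSegment:
    """Half-open time interval [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def slice(self, fs: float) -> slice:
        return slice(int(round(self.start * fs)), int(round(self.end * fs)))


@dataclass
class TokenRecord:
    """One token's bookkeeping: identity, segments, screening measures."""

    token_id: str
    category: str
    path: str = ""
    segments: list = field(default_factory=list)
    duration_ms: float = np.nan
    intensity_db: float = np.nan
    accept: bool | None = None
    reason: str = ""


# ---------------------------------------------------------------------------
# WAV I/O (RIFF PCM; resampled to 44.1 kHz on read if needed)
# ---------------------------------------------------------------------------

def read_wav(path, target_fs: int = DEFAULT_SR) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1], mono, resampled to ``target_fs``."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if fs != target_fs:
        from scipy.signal import resample_poly
        from math import gcd

        g = gcd(int(target_fs), int(fs))
        data = resample_poly(data, target_fs // g, fs // g)
        fs = target_fs
    return data, fs


def write_wav(path, wave: np.ndarray, fs: int = DEFAULT_SR) -> None:
    """Write 16-bit PCM mono WAV; clips at full scale."""
    pcm = np.clip(np.asarray(wave, dtype=float), -1.0, 1.0)
    wavfile.write(path, fs, np.round(pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Pitch tracking
# ---------------------------------------------------------------------------

def _frame_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized autocorrelation r(tau) for tau = 0..max_lag.

    Normalization divides by the energies of the two overlapping stretches,
    which keeps r amplitude-invariant and unbiased at long lags.
    """
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    num = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    c2 = np.cumsum(x * x)
    total = c2[-1]
    lags = np.arange(max_lag + 1)
    e0 = c2[n - 1 - lags]  # energy of x[0 : n-tau]
    e1 = total - np.concatenate(([0.0], c2[: max_lag]))  # energy of x[tau : n]
    den = np.sqrt(e0 * e1) + 1e-30
    return num / den


def _clean(f0: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Interpolate short unvoiced gaps, then keep only the longest voiced run."""
    f0 = f0.copy()
    voiced = np.isfinite(f0)
    if voiced.sum() < 2:
        return f0
    idx = np.flatnonzero(voiced)
    # interpolate interior gaps of <= max_gap frames
    for a, b in zip(idx[:-1], idx[1:]):
        if 1 < b - a <= max_gap + 1:
            f0[a + 1:b] = np.interp(np.arange(a + 1, b), [a, b], [f0[a], f0[b]])
    # find the longest voiced run and silence everything else
    voiced = np.isfinite(f0)
    runs = []
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(voiced)))
    best = max(runs, key=lambda r: r[1] - r[0])
    mask = np.zeros_like(voiced)
    mask[best[0]:best[1]] = True
    f0[~mask] = np.nan
    return f0


def track_pitch(
    wave: np.ndarray,
    fs: int = DEFAULT_SR,
    fmin: float = 75.0,
    fmax: float = 500.0,
    hop_s: float = 0.010,
    window_s: float = 0.030,
    voicing_threshold: float = 0.45,
    octave_cost: float = 0.03,
    segment: VowelSegment | None = None,
    extend_to_edges: bool = True,
) -> F0Track:
    """Track F0 over ``wave`` (or over ``segment`` of it).

    Returns an :class:`F0Track` with ``nan`` at unvoiced frames.  Raises
    ``ValueError`` on empty input or ``fmin >= fmax``.
    """
    if fmin >= fmax:
        raise ValueError("fmin must be < fmax")
    wave = np.asarray(wave, dtype=float)
    offset_s = 0.0
    if segment is not None:
        wave = wave[segment.slice(fs)]
        offset_s = segment.start
    if wave.size == 0:
        raise ValueError("empty audio")

    n = wave.size
    w2 = int(round(window_s * fs / 2))
    lag_min = max(2, int(np.floor(fs / fmax)))
    lag_max_global = int(np.ceil(fs / fmin))
    peak = np.max(np.abs(wave)) or 1.0

    centers = np.arange(0, n, int(round(hop_s * fs)))
    times, f0 = [], []
    for c in centers:
        i0, i1 = max(0, c - w2), min(n, c + w2)
        x = wave[i0:i1]
        t = (i0 + i1 - 1) / 2.0 / fs  # centroid of the valid window
        times.append(t + offset_s)
        nv = len(x)
        lag_max = min(lag_max_global, (nv - 1) // 2)
        if lag_max <= lag_min or np.sqrt(np.mean(x * x)) < 1e-6 * peak:
            f0.append(np.nan)
            continue
        x = x - x.mean()
        r = _frame_acf(x, lag_max)
        lags = np.arange(lag_min, lag_max + 1)
        score = r[lags] - octave_cost * np.log2(lags / lag_min)
        k = lags[int(np.argmax(score))]
        if r[k] < voicing_threshold:
            f0.append(np.nan)
            continue
        # parabolic refinement of the correlation peak
        if lag_min < k < lag_max:
            denom = r[k - 1] - 2 * r[k] + r[k + 1]
            delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom < 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        est = fs / (k + delta)
        f0.append(est if fmin <= est <= fmax else np.nan)

    f0_arr = _clean(np.asarray(f0))
    times_arr = np.asarray(times)

    if extend_to_edges and np.isfinite(f0_arr[:2]).all() and times_arr[0] > offset_s:
        slope = (f0_arr[1] - f0_arr[0]) / (times_arr[1] - times_arr[0])
        v0 = f0_arr[0] - slope * (times_arr[0] - offset_s)
        times_arr = np.concatenate(([offset_s], times_arr))
        f0_arr = np.concatenate(([v0], f0_arr))
    end_t = offset_s + (n - 1) / fs
    if extend_to_edges and np.isfinite(f0_arr[-2:]).all() and times_arr[-1] < end_t:
        slope = (f0_arr[-1] - f0_arr[-2]) / (times_arr[-1] - times_arr[-2])
        f0_arr = np.concatenate((f0_arr, [f0_arr[-1] + slope * (end_t - times_arr[-1])]))
        times_arr = np.concatenate((times_arr, [end_t]))

    return F0Track(times_arr, f0_arr, hop=hop_s,
                   meta={"fmin": fmin, "fmax": fmax, "window_s": window_s})


# ---------------------------------------------------------------------------
# Intensity
# ---------------------------------------------------------------------------

def mean_intensity(
    wave: np.ndarray,
    fs: int = DEFAULT_SR,
    segment: VowelSegment | None = None,
    calibration_pa: float = FULL_SCALE_PA,
    floor_db: float = -100.0,
) -> float:
    """Energy-mean level in dB re 2e-5 Pa over ``wave`` (or ``segment``).

    Silence returns ``floor_db`` rather than -inf.  Raises ``ValueError`` on
    an empty segment.
    """
    wave = np.asarray(wave, dtype=float)
    if segment is not None:
        wave = wave[segment.slice(fs)]
    if wave.size == 0:
        raise ValueError("empty segment")
    msq = float(np.mean((wave * calibration_pa) ** 2))
    if msq <= 0:
        return floor_db
    return max(10.0 * np.log10(msq / REF_PRESSURE_PA**2), floor_db)


def intensity_contour(
    wave: np.ndarray,
    fs: int = DEFAULT_SR,
    hop_s: float = 0.010,
    window_s: float = 0.030,
    segment: VowelSegment | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time level contour (frame times s, dB); frames mirror track_pitch."""
    wave = np.asarray(wave, dtype=float)
    offset_s = 0.0
    if segment is not None:
        wave = wave[segment.slice(fs)]
        offset_s = segment.start
    if wave.size == 0:
        raise ValueError("empty audio")
    w2 = int(round(window_s * fs / 2))
    centers = np.arange(0, wave.size, int(round(hop_s * fs)))
    times, db = [], []
    for c in centers:
        x = wave[max(0, c - w2): c + w2]
        times.append(offset_s + c / fs)
        msq = float(np.mean((x * FULL_SCALE_PA) ** 2))
        db.append(10.0 * np.log10(msq / REF_PRESSURE_PA**2) if msq > 0 else -100.0)
    return np.asarray(times), np.asarray(db)


# ---------------------------------------------------------------------------
# Acceptance filters
# ---------------------------------------------------------------------------

def apply_acceptance_filters(
    records: list[TokenRecord],
    duration_window_ms: tuple[float, float] = (800.0, 1000.0),
    intensity_window_db: tuple[float, float] = (50.0, 66.0),
    duration_warn_ms: tuple[float, float] = (700.0, 1000.0),
) -> list[TokenRecord]:
    """Screen tokens for total duration and mean intensity.

    A token is accepted iff its duration lies in the selection window
    (default 800-1000 ms) and its mean intensity in 50-66 dB.  Tokens inside
    the looser screening window (700-1000 ms) but outside the selection
    window get a "duration-warn" reason; everything is retained with its
    accept flag and reason code rather than dropped.
    """
    out = []
    for rec in records:
        reasons = []
        d, i = rec.duration_ms, rec.intensity_db
        if not (duration_window_ms[0] <= d <= duration_window_ms[1]):
            if duration_warn_ms[0] <= d <= duration_warn_ms[1]:
                reasons.append("duration-warn")
            else:
                reasons.append("duration")
        if not (intensity_window_db[0] <= i <= intensity_window_db[1]):
            reasons.append("intensity")
        out.append(replace(rec, accept=not reasons, reason=",".join(reasons)))
    return out
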