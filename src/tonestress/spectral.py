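"""Spectral balance: band energies in four fixed frequency bands over a
stable vowel portion, converted to duration-normalized dB SPL.

Bands follow the Sluijter & van Heuven convention: B1 0-500 Hz, B2 500-1000
Hz, B3 1000-2000 Hz, B4 2000-4000 Hz.  Band energy is the integral of squared
band-filtered pressure over the analysis window; the SPL conversion

    SPL = 10 log10( energy / (time * 4e-10) )

divides out the window duration so that levels are comparable across vowels
of different lengths (4e-10 Pa^2 is the squared 2e-5 Pa reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .extraction import FULL_SCALE_PA, VowelSegment, intensity_contour
from .track import F0Track

__all__ = [
    "BANDS",
    "SPL_REF_PA2S",
    "SpectralProfile",
    "band_energy",
    "spl_from_energy",
    "stable_window",
    "spectral_profile",
]

#: The four analysis bands in Hz.
BANDS = ((0.0, 500.0), (500.0, 1000.0), (1000.0, 2000.0), (2000.0, 4000.0))
#: Reference for the SPL conversion: (2e-5 Pa)^2 * 1 s.
SPL_REF_PA2S = 4e-10


@dataclass
class SpectralProfile:
    """Band levels (dB SPL) for one vowel token."""

    b1: float
    b2: float
    b3: float
    b4: float
    window: VowelSegment
    window_length_ms: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.b1, self.b2, self.b3, self.b4)


def band_sos(band: tuple[float, float], fs: float, order: int = 4):
    """Zero-phase band filter coefficients; a 0 Hz lower edge gives a low-pass."""
    lo, hi = band
    nyq = fs / 2
    if hi >= nyq:
        raise ValueError(f"band {band} outside Nyquist ({nyq} Hz)")
    if lo <= 0:
        return butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")


def band_energy(
    wave: np.ndarray,
    fs: int,
    segment: VowelSegment | None,
    band: tuple[float, float],
    calibration_pa: float = FULL_SCALE_PA,
) -> float:
    """Band energy in Pa^2*s over ``segment`` (whole signal if ``None``).

    The waveform is band-filtered as a whole (forward-backward 4th-order
    Butterworth, zero phase) and the squared calibrated pressure is integrated
    over the segment.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.size == 0:
        raise ValueError("empty audio")
    sos = band_sos(band, fs)
    filtered = sosfiltfilt(sos, wave) * calibration_pa
    if segment is not None:
        filtered = filtered[segment.slice(fs)]
    if filtered.size == 0:
        raise ValueError("empty segment")
    return float(np.sum(filtered**2) / fs)


def spl_from_energy(energy: float, time_s: float, floor_db: float = -20.0) -> float:
    """Duration-normalized sound pressure level in dB.

    ``energy`` >= 0 in Pa^2*s, ``time_s`` > 0.  Zero energy returns the
    configured floor instead of -inf.
    """
    if energy < 0:
        raise ValueError("energy must be >= 0")
    if time_s <= 0:
        raise ValueError("time must be > 0")
    if energy == 0:
        return floor_db
    return 10.0 * np.log10(energy / (time_s * SPL_REF_PA2S))


def stable_window(
    track: F0Track,
    intensity: tuple[np.ndarray, np.ndarray],
    min_len_ms: float = 70.0,
) -> VowelSegment:
    """Most stable portion of a vowel: the ``min_len_ms`` window minimizing
    the combined variance of the (z-scored) F0 and intensity contours.

    ``intensity`` is a (times, dB) pair on a frame grid comparable to the
    track's.  Raises ``ValueError`` if the voiced vowel is shorter than
    ``min_len_ms``.
    """
    t_v = track.voiced_times()
    f_v = track.voiced_f0()
    if t_v.size < 2 or (t_v[-1] - t_v[0]) * 1000 < min_len_ms:
        raise ValueError("vowel shorter than the minimum stable-window length")
    it, idb = intensity
    # common uniform grid over the voiced span
    hop = track.hop
    grid = np.arange(t_v[0], t_v[-1] + hop / 2, hop)
    fz = np.interp(grid, t_v, f_v)
    iz = np.interp(grid, it, idb)

    def z(x):
        s = np.std(x)
        return (x - np.mean(x)) / s if s > 0 else np.zeros_like(x)

    fz, iz = z(fz), z(iz)
    w = max(2, int(round(min_len_ms / 1000 / hop)))
    if w > grid.size:
        raise ValueError("vowel shorter than the minimum stable-window length")
    best, best_score = 0, np.inf
    for i in range(grid.size - w + 1):
        score = float(np.var(fz[i:i + w]) + np.var(iz[i:i + w]))
        if score < best_score - 1e-12:
            best, best_score = i, score
    start = grid[best]
    return VowelSegment(start, start + w * hop)


def spectral_profile(
    wave: np.ndarray,
    fs: int,
    track: F0Track,
    min_len_ms: float = 70.0,
    calibration_pa: float = FULL_SCALE_PA,
) -> SpectralProfile:
    """B1-B4 dB SPL of a vowel over its automatically selected stable window."""
    intensity = intensity_contour(wave, fs)
    win = stable_window(track, intensity, min_len_ms)
    levels = [
        spl_from_energy(band_energy(wave, fs, win, band, calibration_pa), win.duration)
        for band in BANDS
    ]
    return SpectralProfile(*levels, window=win, window_length_ms=win.duration * 1000)
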