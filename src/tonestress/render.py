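"""Waveform rendering: additive harmonic source following an F0 trajectory,
shaped by a two-resonance vowel filter, calibrated either to an overall mean
intensity or to absolute per-band SPL targets.

The source is a band-limited harmonic series (all partials below 4 kHz of a
1/k glottal-like envelope) rather than a literal impulse train, which keeps
the signal alias-free and cleanly trackable.  No aspiration noise or
consonant acoustics are modelled: a token is two rendered vowels separated by
a silent consonant gap.
"""

from __future__ import annotations

import numpy as np

from .contours import sample_contour
from .extraction import (DEFAULT_SR, FULL_SCALE_PA, VowelSegment,
                         mean_intensity, write_wav)
from .spectral import BANDS, SPL_REF_PA2S, band_energy
from .templates import ToneTemplate
from .track import F0Track

__all__ = ["VOWEL_RESONANCES", "render_wav", "render_token"]

#: Two-resonance (F1, F2) shaping per vowel label, Hz.
VOWEL_RESONANCES = {
    "a": (850.0, 1610.0),
    "ɛ": (610.0, 1900.0),
    "i": (300.0, 2300.0),
    "ɔ": (500.0, 900.0),
    "u": (350.0, 800.0),
}

_EDGE_RAMP_S = 0.005
_MAX_HARMONIC_HZ = 3999.0


def _resonance_gain(freqs: np.ndarray, vowel: str) -> np.ndarray:
    """Magnitude of two cascaded resonators (bandwidth ~90 Hz) at ``freqs``."""
    gain = np.ones_like(freqs)
    for fc in VOWEL_RESONANCES[vowel]:
        bw = 90.0
        gain *= 1.0 / np.sqrt(((freqs**2 - fc**2) / (freqs * fc)) ** 2 + (bw / fc) ** 2)
    return gain / gain.max()


def _band_index(freq: float) -> int:
    for b, (lo, hi) in enumerate(BANDS):
        if lo <= freq < hi:
            return b
    return len(BANDS) - 1


def render_wav(
    track: F0Track,
    intensity_db: float = 63.0,
    vowel: str = "a",
    path=None,
    fs: int = DEFAULT_SR,
    band_targets_db: tuple[float, float, float, float] | None = None,
    calibration_pa: float = FULL_SCALE_PA,
) -> np.ndarray:
    """Render one vowel from an F0 track.

    With ``band_targets_db`` unset, the waveform is scaled so its mean
    intensity equals ``intensity_db``.  With band targets set, per-band gains
    are calibrated iteratively (against the same zero-phase band filters the
    analysis uses) so each band's duration-normalized SPL matches its target,
    and the overall level is whatever the targets imply.

    Returns the float waveform (and writes 16-bit PCM to ``path`` if given).
    Raises ``ValueError`` for a track with fewer than 2 voiced samples.
    """
    t_v = track.voiced_times()
    f_v = track.voiced_f0()
    if t_v.size < 2:
        raise ValueError("track needs at least 2 voiced samples")
    if vowel not in VOWEL_RESONANCES:
        raise ValueError(f"unknown vowel {vowel!r}")

    dur = t_v[-1] - t_v[0]
    n = int(round(dur * fs))
    st = np.arange(n) / fs
    f0 = np.interp(st, t_v - t_v[0], f_v)
    phase = 2 * np.pi * np.cumsum(f0) / fs

    f_mean = float(np.mean(f_v))
    n_harm = max(1, int(_MAX_HARMONIC_HZ // f_mean))
    ks = np.arange(1, n_harm + 1)
    freqs = ks * f_mean
    amps = (1.0 / ks) * _resonance_gain(freqs, vowel)
    if band_targets_db is not None:
        # Harmonics within 10% of an interior band edge leak across the
        # analysis filters' skirts, putting a floor under quiet bands; park
        # them so per-band levels stay independently controllable.
        for edge in (500.0, 1000.0, 2000.0):
            amps[np.abs(freqs / edge - 1.0) < 0.10] = 0.0
        if not all(any(a > 0 and lo <= f < hi for a, f in zip(amps, freqs))
                   for lo, hi in BANDS):
            raise ValueError("F0 too high to place harmonics in every band")

    band_of = np.array([_band_index(f) for f in freqs])
    gains = np.ones(len(BANDS))

    def synth() -> np.ndarray:
        w = np.zeros(n)
        for k, a, b in zip(ks, amps, band_of):
            w += gains[b] * a * np.sin(k * phase)
        ramp = int(_EDGE_RAMP_S * fs)
        if ramp and n > 2 * ramp:
            env = np.ones(n)
            env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            env[-ramp:] = env[:ramp][::-1]
            w *= env
        return w

    if band_targets_db is None:
        wave = synth()
        scale = 10 ** ((intensity_db - mean_intensity(wave, fs, calibration_pa=calibration_pa)) / 20)
        wave *= scale
    else:
        targets = np.asarray(band_targets_db, dtype=float)
        target_energy = dur * SPL_REF_PA2S * 10 ** (targets / 10)
        wave = synth()
        for _ in range(5):
            measured = np.array(
                [band_energy(wave, fs, None, band, calibration_pa) for band in BANDS]
            )
            gains *= np.sqrt(target_energy / np.maximum(measured, 1e-30))
            wave = synth()

    peak = np.max(np.abs(wave))
    if peak > 1.0:  # keep within digital full scale; warn via meta if clipped
        wave = wave / peak
    if path is not None:
        write_wav(path, wave, fs)
    return wave


def render_token(
    tracks: list[F0Track],
    vowels: list[str],
    templates: list[ToneTemplate] | None = None,
    intensity_db: float = 63.0,
    total_ms: float = 900.0,
    lead_ms: float = 100.0,
    gap_ms: float = 120.0,
    fs: int = DEFAULT_SR,
    use_band_targets: bool = False,
    path=None,
) -> tuple[np.ndarray, list[VowelSegment]]:
    """Assemble a disyllabic token: silence, vowel 1, consonant gap, vowel 2,
    trailing silence padded to ``total_ms`` (or longer if the vowels demand).

    Returns the waveform and the vowel segments in token coordinates.  With
    ``use_band_targets`` the per-syllable band SPLs are calibrated to the
    templates' B1-B4 targets; otherwise each vowel is scaled to the template
    intensity (or ``intensity_db`` when no templates are given).
    """
    if len(tracks) != len(vowels):
        raise ValueError("one vowel label per track")
    pieces = [np.zeros(int(lead_ms / 1000 * fs))]
    segments = []
    cursor = lead_ms / 1000
    for i, (trk, v) in enumerate(zip(tracks, vowels)):
        tpl = templates[i] if templates else None
        if use_band_targets and tpl is not None:
            wave = render_wav(trk, vowel=v, fs=fs,
                              band_targets_db=tuple(p.mean for p in tpl.band_spl))
        else:
            level = tpl.intensity_db.mean if tpl is not None else intensity_db
            wave = render_wav(trk, intensity_db=level, vowel=v, fs=fs)
        pieces.append(wave)
        segments.append(VowelSegment(cursor, cursor + len(wave) / fs))
        cursor += len(wave) / fs
        if i < len(tracks) - 1:
            pieces.append(np.zeros(int(gap_ms / 1000 * fs)))
            cursor += gap_ms / 1000
    token = np.concatenate(pieces)
    want = int(total_ms / 1000 * fs)
    if token.size < want:
        token = np.concatenate([token, np.zeros(want - token.size)])
    if path is not None:
        write_wav(path, token, fs)
    return token, segments
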