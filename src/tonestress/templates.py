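"""Per-category acoustic templates for the six Cantonese tones and the four
English stress conditions.

Each template stores the mean and standard deviation of the production
parameters of one category, measured over the recorded stimulus corpus these
defaults emulate: vowel duration, F0 onset/offset (and F0 minimum plus
fall/rise times for the contour tones), mean intensity, and the four
spectral-balance band levels B1-B4 (0-0.5, 0.5-1, 1-2, 2-4 kHz, dB SPL).

Tone notation follows the Chao numerals: T1 high level (55), T2 high rising
(25), T3 mid level (33), T4 low falling (21), T5 low rising (23), T6 low
level (22).  Stress conditions cross stress pattern with syllable position:
TS1/TS2 = first/second syllable of a trochaic (strong-weak) word, IS1/IS2 =
first/second syllable of an iambic (weak-strong) word.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Param",
    "ToneTemplate",
    "TONES",
    "TONE_CLASS",
    "TONE_TEMPLATES",
    "STRESS_CONDITIONS",
    "STRESS_TEMPLATES",
    "TONE_CONTRASTS",
    "TONE_PARAMETER_MEANS",
    "STRESS_PARAMETER_MEANS",
    "F0_RANGE_HZ",
]

TONES = ("T1", "T2", "T3", "T4", "T5", "T6")
STRESS_CONDITIONS = ("TS1", "TS2", "IS1", "IS2")

#: Contour class of each tone: {T1, T3, T6} level, {T2, T5} rising, {T4} falling.
TONE_CLASS = {
    "T1": "level",
    "T2": "rising",
    "T3": "level",
    "T4": "falling",
    "T5": "rising",
    "T6": "level",
}

#: The 15 unordered tone contrasts, in canonical order.
TONE_CONTRASTS = tuple(
    f"{TONES[i]}-{TONES[j]}" for i in range(6) for j in range(i + 1, 6)
)

#: Plausible F0 range for the (female) voice the templates describe.
F0_RANGE_HZ = (75.0, 500.0)


@dataclass(frozen=True)
class Param:
    """Mean and standard deviation of one acoustic parameter."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")


@dataclass(frozen=True)
class ToneTemplate:
    """Production parameters of one tone or stress category.

    ``f0_min``, ``fall_time_ms`` and ``rise_time_ms`` are only meaningful for
    the contour (rising/falling) classes and are ``None`` for level
    categories.  Band levels are dB SPL over the four spectral-balance bands.
    """

    label: str
    contour_class: str  # "level" | "rising" | "falling"
    duration_ms: Param
    f0_onset: Param
    f0_offset: Param
    intensity_db: Param
    band_spl: tuple[Param, Param, Param, Param]
    f0_min: Param | None = None
    fall_time_ms: Param | None = None
    rise_time_ms: Param | None = None

    def __post_init__(self) -> None:
        if self.contour_class not in ("level", "rising", "falling"):
            raise ValueError(f"unknown contour class {self.contour_class!r}")
        if self.duration_ms.mean <= 0:
            raise ValueError("duration must be positive")
        lo, hi = F0_RANGE_HZ
        for p in (self.f0_onset, self.f0_offset, self.f0_min):
            if p is not None and not (lo <= p.mean <= hi):
                raise ValueError(f"F0 mean {p.mean} outside plausible range {F0_RANGE_HZ}")
        if self.contour_class != "level":
            if self.f0_min is None or self.fall_time_ms is None or self.rise_time_ms is None:
                raise ValueError("contour templates need f0_min, fall_time_ms, rise_time_ms")

    @property
    def is_contour(self) -> bool:
        return self.contour_class != "level"


def _bands(b1, b2, b3, b4):
    return tuple(Param(m, s) for m, s in (b1, b2, b3, b4))


# F0 minima of the contour tones are onset + fall displacement; the fall
# displacement SD doubles as the minimum's SD since the two are measured on
# the same leg of the contour.
TONE_TEMPLATES: dict[str, ToneTemplate] = {
    "T1": ToneTemplate(
        "T1", "level",
        duration_ms=Param(230.64, 30.09),
        f0_onset=Param(315.99, 10.89), f0_offset=Param(290.45, 7.21),
        intensity_db=Param(65.71, 1.78),
        band_spl=_bands((57.03, 2.35), (56.11, 6.31), (42.78, 11.07), (42.05, 8.05)),
    ),
    "T2": ToneTemplate(
        "T2", "rising",
        duration_ms=Param(311.62, 41.34),
        f0_onset=Param(217.20, 14.33), f0_offset=Param(256.73, 11.91),
        f0_min=Param(217.20 - 36.50, 13.29),
        fall_time_ms=Param(108.34, 25.74), rise_time_ms=Param(205.01, 39.52),
        intensity_db=Param(62.72, 1.74),
        band_spl=_bands((53.51, 3.38), (48.96, 8.48), (35.21, 12.85), (36.61, 9.57)),
    ),
    "T3": ToneTemplate(
        "T3", "level",
        duration_ms=Param(250.68, 29.45),
        f0_onset=Param(273.40, 9.05), f0_offset=Param(254.19, 4.79),
        intensity_db=Param(65.12, 1.35),
        band_spl=_bands((57.46, 1.42), (55.99, 3.74), (42.94, 11.37), (40.51, 9.20)),
    ),
    "T4": ToneTemplate(
        "T4", "falling",
        duration_ms=Param(228.23, 29.93),
        f0_onset=Param(211.79, 14.88), f0_offset=Param(182.01, 7.66),
        f0_min=Param(211.79 - 36.30, 15.71),
        fall_time_ms=Param(166.86, 49.32), rise_time_ms=Param(61.37, 40.76),
        intensity_db=Param(62.61, 2.62),
        band_spl=_bands((53.51, 3.44), (50.34, 8.78), (30.67, 13.19), (34.12, 11.08)),
    ),
    "T5": ToneTemplate(
        "T5", "rising",
        duration_ms=Param(288.05, 34.02),
        f0_onset=Param(220.84, 16.43), f0_offset=Param(239.90, 8.10),
        f0_min=Param(220.84 - 33.75, 15.28),
        fall_time_ms=Param(103.61, 22.16), rise_time_ms=Param(184.43, 30.00),
        intensity_db=Param(64.17, 2.11),
        band_spl=_bands((55.05, 3.31), (52.16, 8.91), (37.64, 12.62), (38.69, 10.11)),
    ),
    "T6": ToneTemplate(
        "T6", "level",
        duration_ms=Param(229.16, 28.52),
        f0_onset=Param(247.93, 12.32), f0_offset=Param(224.13, 6.90),
        intensity_db=Param(62.42, 1.61),
        band_spl=_bands((55.88, 1.50), (47.70, 9.39), (39.46, 11.76), (38.65, 9.43)),
    ),
}

# Stress syllables carry no rise/fall decomposition; their F0 movement is a
# single (falling) glide, so they reuse the "level" linear contour model.
# Band cells B1(TS1), B1(TS2) and B4(TS2) are not directly documented for the
# source corpus; they are reconstructed from its marginal means (per-condition
# overall spectral level and per-band grand means), a reconstruction that
# reproduces the documented IS2 overall mean of 48.71 dB exactly.  Band SDs
# for stress are likewise undocumented and borrow the tone-table scale.
_STRESS_BAND_SD = (3.0, 8.0, 12.0, 10.0)


def _stress_bands(b1, b2, b3, b4):
    return tuple(Param(m, s) for m, s in zip((b1, b2, b3, b4), _STRESS_BAND_SD))


STRESS_TEMPLATES: dict[str, ToneTemplate] = {
    "TS1": ToneTemplate(
        "TS1", "level",
        duration_ms=Param(228.34, 28.27),
        f0_onset=Param(329.45, 13.50), f0_offset=Param(309.69, 14.02),
        intensity_db=Param(66.60, 1.53),
        band_spl=_stress_bands(58.42, 56.70, 41.85, 40.95),
    ),
    "TS2": ToneTemplate(
        "TS2", "level",
        duration_ms=Param(168.21, 34.05),
        f0_onset=Param(239.84, 17.53), f0_offset=Param(149.87, 16.13),
        intensity_db=Param(59.69, 2.13),
        band_spl=_stress_bands(50.70, 47.41, 32.87, 32.73),
    ),
    "IS1": ToneTemplate(
        "IS1", "level",
        duration_ms=Param(207.99, 29.31),
        f0_onset=Param(257.49, 12.69), f0_offset=Param(222.81, 7.03),
        intensity_db=Param(62.57, 2.06),
        band_spl=_stress_bands(55.25, 48.91, 38.04, 38.44),
    ),
    "IS2": ToneTemplate(
        "IS2", "level",
        duration_ms=Param(280.57, 28.74),
        f0_onset=Param(287.10, 15.30), f0_offset=Param(182.15, 16.30),
        intensity_db=Param(64.12, 1.73),
        band_spl=_stress_bands(54.71, 55.07, 42.00, 43.04),
    ),
}


# ---------------------------------------------------------------------------
# Reference per-category mean batteries (T1..T6 / TS1..IS2 order).  These are
# the documented category means of the corpus the templates emulate — the
# canonical inputs for the cue-saliency statistic and for category-level
# acoustic-perceptual correlations.  Slopes in Hz/s, durations ms, F0 Hz,
# intensity and bands dB.
# ---------------------------------------------------------------------------

TONE_PARAMETER_MEANS: dict[str, tuple[float, ...]] = {
    "duration": (230.64, 311.62, 250.68, 228.23, 288.05, 229.16),
    "f0_avg": (303.48, 206.06, 258.13, 184.59, 207.08, 225.79),
    "f0_onset": (315.99, 217.20, 273.40, 211.79, 220.84, 247.93),
    "f0_offset": (290.45, 256.73, 254.19, 182.01, 239.90, 224.13),
    "general_slope": (-111.48, 131.30, -77.90, -132.76, 65.49, -105.63),
    "displacement": (-25.54, 39.52, -19.21, -29.77, 19.05, -23.80),
    "major_slope": (-111.48, 379.72, -77.90, -233.21, 286.24, -105.63),
    "intensity": (65.71, 62.72, 65.12, 62.61, 64.17, 62.42),
    "b1": (57.03, 53.51, 57.46, 53.51, 55.05, 55.88),
    "b2": (56.11, 48.96, 55.99, 50.34, 52.16, 47.70),
    "b3": (42.78, 35.21, 42.94, 30.67, 37.64, 39.46),
    "b4": (42.05, 36.61, 40.51, 34.12, 38.69, 38.65),
}

STRESS_PARAMETER_MEANS: dict[str, tuple[float, ...]] = {
    "duration": (228.34, 168.21, 207.99, 280.57),
    "f0_avg": (317.96, 187.25, 232.90, 245.53),
    "f0_onset": (329.45, 239.84, 257.49, 287.10),
    "f0_offset": (309.69, 149.87, 222.81, 182.15),
    "general_slope": (-86.43, -548.96, -169.37, -377.66),
    "intensity": (66.60, 59.69, 62.57, 64.12),
    "b1": (58.42, 50.70, 55.25, 54.71),
    "b2": (56.70, 47.41, 48.91, 55.07),
    "b3": (41.85, 32.87, 38.04, 42.00),
    "b4": (40.95, 32.73, 38.44, 43.04),
}
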