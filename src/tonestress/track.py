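"""Fundamental-frequency track container shared by synthesis and extraction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["F0Track", "UNVOICED"]

#: Sentinel written to two-column text files for unvoiced frames.
UNVOICED = "--"


@dataclass
class F0Track:
    """Time-stamped F0 samples for one vowel.

    times
        Frame times in seconds, strictly increasing.  Interior frames lie on a
        uniform grid of spacing ``hop``; edge frames may sit off-grid (the
        pitch tracker reports the temporal centroid of the valid analysis
        window there).
    f0
        F0 in Hz per frame; ``nan`` marks unvoiced frames.
    hop
        Nominal frame spacing in seconds.
    """

    times: np.ndarray
    f0: np.ndarray
    hop: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.times.shape != self.f0.shape:
            raise ValueError("times and f0 must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def voiced(self) -> np.ndarray:
        """Boolean mask of voiced frames."""
        return np.isfinite(self.f0)

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())

    def voiced_times(self) -> np.ndarray:
        return self.times[self.voiced]

    def voiced_f0(self) -> np.ndarray:
        return self.f0[self.voiced]

    def shifted(self, dt: float) -> "F0Track":
        """Return a copy translated in time by ``dt`` seconds."""
        return F0Track(self.times + dt, self.f0.copy(), self.hop, dict(self.meta))

    # -- plain-text round trip (time s, F0 Hz; unvoiced as sentinel) --------
    def to_text(self) -> str:
        lines = []
        for t, f in zip(self.times, self.f0):
            val = UNVOICED if not np.isfinite(f) else f"{f:.6f}"
            lines.append(f"{t:.6f}\t{val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, hop: float | None = None) -> "F0Track":
        times, f0 = [], []
        for line in text.strip().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            t_s, f_s = line.split()
            times.append(float(t_s))
            f0.append(np.nan if f_s == UNVOICED else float(f_s))
        times_arr = np.asarray(times)
        if hop is None:
            hop = float(np.median(np.diff(times_arr))) if len(times) > 1 else 0.01
        return cls(times_arr, np.asarray(f0), hop)
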