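"""Parametric F0 contour synthesis from category templates.

Level categories are a straight line from onset to offset.  Contour
categories (rising T2/T5, falling T4) are two linear legs through the F0
minimum — onset falls to the minimum over the fall time, then rises to the
offset — blended with a short cosine ramp at the joint so the turning point
is a smooth concave-up curve rather than a corner.  The blend is anchored at
the minimum, so the curve passes through (t_min, f0_min) exactly and the
residual dip below f0_min is O(0.01 Hz) for template-scale slope asymmetries.
"""

from __future__ import annotations

import numpy as np

from .templates import ToneTemplate
from .track import F0Track

__all__ = ["sample_contour", "template_track"]

#: Half-width of the cosine blend at the fall/rise joint (seconds).
JOINT_RAMP_S = 0.010


def _contour_values(times: np.ndarray, onset: float, offset: float,
                    f0_min: float | None, t_min: float | None) -> np.ndarray:
    dur = times[-1]
    if f0_min is None:  # level: linear onset -> offset
        return onset + (offset - onset) * times / dur
    fall = onset + (f0_min - onset) * times / t_min
    rise = f0_min + (offset - f0_min) * (times - t_min) / (dur - t_min)
    r = min(JOINT_RAMP_S, t_min / 2, (dur - t_min) / 2)
    u = np.clip((times - t_min) / (2 * r), -0.5, 0.5)
    alpha = 0.5 * (1.0 + np.sin(np.pi * u))  # 0 before the joint, 1 after
    return (1.0 - alpha) * fall + alpha * rise


def sample_contour(
    template: ToneTemplate,
    contour_class: str | None = None,
    duration_ms: float | None = None,
    seed: int | np.random.Generator = 0,
    hop_s: float = 0.010,
    sd_scale: float = 1.0,
) -> F0Track:
    """Draw one F0 track from a category template.

    Parameters are sampled as independent Gaussians around the template means
    with the template SDs scaled by ``sd_scale`` (0 gives the deterministic
    template contour).  ``duration_ms`` overrides the sampled duration.  The
    returned track has exact endpoint samples at t = 0 and t = duration, on a
    uniform grid of spacing ~``hop_s``.

    Raises ``ValueError`` for an invalid template/class combination or a
    non-positive duration.
    """
    if contour_class is None:
        contour_class = template.contour_class
    if contour_class != template.contour_class:
        raise ValueError(
            f"class {contour_class!r} does not match template {template.label} "
            f"({template.contour_class})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draw(p):
        return p.mean + sd_scale * p.sd * rng.standard_normal()

    if duration_ms is None:
        duration_ms = draw(template.duration_ms)
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    dur = duration_ms / 1000.0

    onset = draw(template.f0_onset)
    offset = draw(template.f0_offset)
    f0_min = t_min = None
    if template.is_contour:
        f0_min = draw(template.f0_min)
        # keep the turning point below both endpoints
        f0_min = min(f0_min, min(onset, offset) - 1.0)
        fall = max(draw(template.fall_time_ms), 1.0)
        rise = max(draw(template.rise_time_ms), 1.0)
        # rescale the two legs so they tile the sampled duration exactly
        t_min = dur * fall / (fall + rise)

    n = max(2, round(dur / hop_s))
    times = np.linspace(0.0, dur, n + 1)
    f0 = _contour_values(times, onset, offset, f0_min, t_min)
    return F0Track(
        times, f0, hop=dur / n,
        meta={
            "label": template.label, "contour_class": contour_class,
            "onset": onset, "offset": offset, "f0_min": f0_min,
            "t_min": t_min, "duration_ms": duration_ms, "sd_scale": sd_scale,
        },
    )


def template_track(template: ToneTemplate, hop_s: float = 0.010) -> F0Track:
    """The deterministic (zero-jitter) contour at the template means."""
    return sample_contour(template, seed=0, hop_s=hop_s, sd_scale=0.0)
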