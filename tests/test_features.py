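"""Contour feature battery: hand-computed examples, invariants, and a
brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tonestress as ts
from tonestress.features import InsufficientDataError
from tonestress.track import F0Track


def make_track(times_ms, f0):
    t = np.asarray(times_ms, dtype=float) / 1000.0
    hop = float(np.median(np.diff(t))) if len(t) > 1 else 0.01
    return F0Track(t, np.asarray(f0, dtype=float), hop)


# ---------------------------------------------------------------------------
# basic measures / general slope
# ---------------------------------------------------------------------------

def test_linear_two_point_track():
    trk = make_track([0, 100], [300, 250])
    dur, avg, onset, offset = ts.basic_measures(trk)
    assert (dur, onset, offset) == (100.0, 300.0, 250.0)
    assert avg == 275.0
    assert ts.general_slope(onset, offset, dur) == pytest.approx(-500.0)


def test_constant_track_has_zero_slopes():
    trk = make_track(np.arange(0, 110, 10), [220.0] * 11)
    f = ts.features_from_track(trk, "level")
    assert f.f0_onset == f.f0_offset == f.f0_avg == 220.0
    assert f.general_slope == 0.0 and f.major_slope == 0.0
    assert ts.classify_contour(f.major_slope) == "unclassified"


def test_general_slope_hand_values():
    assert ts.general_slope(300.0, 250.0, 250.0) == pytest.approx(-200.0)
    # the corpus's T1 cell: -25.54 Hz over 230.64 ms, within 1% of -111.48
    assert ts.general_slope(315.99, 315.99 - 25.54, 230.64) == pytest.approx(
        -111.48, rel=0.01
    )


def test_time_scaling_halves_the_slope():
    trk = make_track([0, 50, 100], [300, 280, 250])
    slow = make_track([0, 100, 200], [300, 280, 250])
    f, g = ts.features_from_track(trk, "level"), ts.features_from_track(slow, "level")
    assert g.general_slope == pytest.approx(f.general_slope / 2)


def test_insufficient_voiced_frames_raise():
    with pytest.raises(InsufficientDataError):
        ts.basic_measures(make_track([0, 10], [200.0, np.nan]))


# ---------------------------------------------------------------------------
# fall/rise decomposition and ratios
# ---------------------------------------------------------------------------

def test_piecewise_dip_decomposition():
    # 220 -> 184 over 100 ms, then 184 -> 260 over 200 ms
    times = np.arange(0, 310, 10)
    f0 = np.where(times <= 100, 220 - 36 * times / 100, 184 + 76 * (times - 100) / 200)
    f = ts.features_from_track(make_track(times, f0), "rising")
    assert f.fall_displacement == pytest.approx(-36.0)
    assert f.fall_slope == pytest.approx(-360.0)
    assert f.rise_displacement == pytest.approx(76.0)
    assert f.rise_slope == pytest.approx(380.0)
    assert f.rf_d_ratio == pytest.approx(76 / 36)
    assert f.rf_t_ratio == pytest.approx(2.0)
    assert f.major_slope == f.rise_slope


def test_strictly_rising_track_is_degenerate():
    f = ts.features_from_track(make_track([0, 50, 100], [200, 230, 260]), "rising")
    assert f.degenerate_decomposition
    assert f.fall_time_ms == 0.0 and f.fall_slope == 0.0
    assert np.isnan(f.rf_t_ratio)  # zero fall time -> undefined marker


def test_symmetric_dip_has_unit_ratios():
    times = np.arange(0, 210, 10)
    f0 = 250 - 50 * (1 - np.abs(times - 100) / 100)
    f = ts.features_from_track(make_track(times, f0), "rising")
    assert f.rf_d_ratio == pytest.approx(1.0)
    assert f.rf_t_ratio == pytest.approx(1.0)


def test_t2_template_time_ratio_matches_leg_means():
    trk = ts.sample_contour(ts.TONE_TEMPLATES["T2"], seed=0, sd_scale=0.0, hop_s=0.002)
    f = ts.features_from_track(trk)
    # ratio of the template leg durations: 205.01 / 108.34
    assert f.rf_t_ratio == pytest.approx(205.01 / 108.34, rel=0.02)


def test_t5_template_rise_slope():
    trk = ts.sample_contour(ts.TONE_TEMPLATES["T5"], seed=0, sd_scale=0.0, hop_s=0.002)
    f = ts.features_from_track(trk)
    assert f.rise_slope == pytest.approx(286.24, rel=0.02)


# ---------------------------------------------------------------------------
# major slope and classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "value,expected",
    [(379.72, "rising"), (286.24, "rising"), (-111.48, "level"),
     (-77.90, "level"), (-233.21, "falling"), (0.0, "unclassified"),
     (500.0, "unclassified")],
)
def test_classification_ranges(value, expected):
    assert ts.classify_contour(value) == expected


def test_every_zero_jitter_template_classifies_into_its_class():
    for tone in ts.TONES:
        trk = ts.template_track(ts.TONE_TEMPLATES[tone], hop_s=0.005)
        f = ts.features_from_track(trk)
        assert ts.classify_contour(f.major_slope) == ts.TONE_CLASS[tone], tone


# ---------------------------------------------------------------------------
# invariants (property tests)
# ---------------------------------------------------------------------------

@st.composite
def tracks(draw, min_frames=3, max_frames=20):
    n = draw(st.integers(min_frames, max_frames))
    f0 = draw(st.lists(st.floats(80, 490), min_size=n, max_size=n))
    hop = draw(st.sampled_from([5.0, 10.0, 20.0]))
    return make_track(np.arange(n) * hop, f0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tracks())
def test_decomposition_additivity_and_slope_consistency(trk):
    f = ts.features_from_track(trk, "rising")
    assert f.fall_displacement + f.rise_displacement == pytest.approx(
        f.displacement, abs=1e-9
    )
    assert f.fall_time_ms + f.rise_time_ms == pytest.approx(f.duration_ms, abs=1e-9)
    assert f.general_slope * f.duration_ms / 1000 == pytest.approx(
        f.displacement, abs=1e-9
    )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(tracks(), st.floats(-5, 5))
def test_time_shift_changes_no_feature(trk, dt):
    a = ts.features_from_track(trk, "rising").as_dict()
    b = ts.features_from_track(trk.shifted(dt), "rising").as_dict()
    for key, va in a.items():
        vb = b[key]
        if isinstance(va, float):
            assert va == pytest.approx(vb, abs=1e-6, nan_ok=True), key
        else:
            assert va == vb, key


def brute_force_features(times_s, f0):
    """Direct frame-enumeration oracle for the feature battery."""
    duration = (times_s[-1] - times_s[0]) * 1000
    onset, offset = f0[0], f0[-1]
    avg = sum(f0) / len(f0)
    # 3-point median smoothing by explicit enumeration
    sm = list(f0)
    for i in range(1, len(f0) - 1):
        sm[i] = sorted([f0[i - 1], f0[i], f0[i + 1]])[1]
    i_s, best = 0, sm[0]
    for i, v in enumerate(sm):
        if v < best:
            i_s, best = i, v
    i_min, best = max(0, i_s - 1), f0[max(0, i_s - 1)]
    for i in range(max(0, i_s - 1), min(len(f0), i_s + 2)):
        if f0[i] < best:
            i_min, best = i, f0[i]
    fall_d = f0[i_min] - onset
    rise_d = offset - f0[i_min]
    fall_t = (times_s[i_min] - times_s[0]) * 1000
    rise_t = (times_s[-1] - times_s[i_min]) * 1000
    return {
        "duration_ms": duration, "f0_avg": avg, "f0_onset": onset,
        "f0_offset": offset, "displacement": offset - onset,
        "general_slope": (offset - onset) / (duration / 1000),
        "fall_displacement": fall_d, "rise_displacement": rise_d,
        "fall_time_ms": fall_t, "rise_time_ms": rise_t,
        "fall_slope": fall_d / (fall_t / 1000) if fall_t > 0 else 0.0,
        "rise_slope": rise_d / (rise_t / 1000) if rise_t > 0 else 0.0,
    }


@settings(max_examples=200, deadline=None, derandomize=True)
@given(tracks())
def test_features_match_brute_force_oracle(trk):
    expected = brute_force_features(list(trk.times), list(trk.f0))
    f = ts.features_from_track(trk, "rising").as_dict()
    for key, val in expected.items():
        assert f[key] == pytest.approx(val, rel=1e-9, abs=1e-9), key
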