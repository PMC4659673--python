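"""AXB simulation and perception-data aggregation."""

import numpy as np
import pandas as pd
import pytest

import tonestress as ts
from tonestress.axb import GroupParams, _tone_accuracies
from tonestress.templates import TONE_PARAMETER_MEANS


def small_params(tone_acc, stress_acc=0.9, n=4, timeout=0.0):
    return {
        "bilingual_child": GroupParams(
            tone_accuracy={c: tone_acc for c in ts.TONE_CONTRASTS},
            stress_accuracy=stress_acc,
            tone_latency_ms=(446.0, 100.0),
            stress_latency_ms=(450.0, 100.0),
            n_subjects=n,
            timeout_prob=timeout,
        )
    }


# ---------------------------------------------------------------------------
# simulate_axb
# ---------------------------------------------------------------------------

def test_certain_accuracy_yields_all_correct(design):
    trials = ts.simulate_axb(design, small_params(1.0, 1.0), seed=0)
    assert trials["correct"].all()
    assert trials["latency_ms"].between(0, 3000, inclusive="right").all()


def test_bernoulli_rate_recovered(design):
    trials = ts.simulate_axb(design, small_params(0.75, n=30), seed=1)
    tone = trials[trials["test"] == "tone"]
    p = tone["correct"].mean()
    se = np.sqrt(0.75 * 0.25 / len(tone))
    assert abs(p - 0.75) < 3 * se


def test_timeouts_are_incorrect_without_latency(design):
    trials = ts.simulate_axb(design, small_params(0.9, timeout=1.0), seed=0)
    assert (trials["response"] == "timeout").all()
    assert (~trials["correct"]).all()
    assert trials["latency_ms"].isna().all()


def test_invalid_parameters_raise():
    with pytest.raises(ValueError):
        GroupParams(tone_accuracy={"T1-T2": 1.2}, stress_accuracy=0.9,
                    tone_latency_ms=(400, 100), stress_latency_ms=(400, 100))
    with pytest.raises(ValueError):
        GroupParams(tone_accuracy={"T1-T2": 0.9}, stress_accuracy=0.9,
                    tone_latency_ms=(3500, 100), stress_latency_ms=(400, 100))


def test_simulation_deterministic_in_seed(design):
    a = ts.simulate_axb(design, small_params(0.8), seed=9)
    b = ts.simulate_axb(design, small_params(0.8), seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_default_contrast_table_averages_to_group_mean():
    acc = _tone_accuracies(0.92, {"T2-T5": 0.75})
    assert np.mean(list(acc.values())) == pytest.approx(0.92)
    assert acc["T2-T5"] == 0.75


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def _trial_frame(latencies, correct=None):
    n = len(latencies)
    return pd.DataFrame({
        "subject": ["s1"] * n, "group": ["g"] * n, "test": ["tone"] * n,
        "contrast": ["T1-T2"] * n,
        "correct": correct if correct is not None else [True] * n,
        "latency_ms": latencies,
    })


def test_small_cell_outlier_survives_the_2sd_rule():
    # with {300, 310, 320, 2000} the cell SD is inflated by the outlier:
    # |2000 - 732.5| = 1267.5 < 2 * 845.0, so nothing is removed
    trials = _trial_frame([300.0, 310.0, 320.0, 2000.0])
    trimmed, frac = ts.trim_latencies(trials)
    assert len(trimmed) == 4 and frac == 0.0


def test_clear_outlier_is_removed():
    # ten 300s plus a 2000: |2000 - 454.5| = 1545.5 > 2 * 512.6
    trials = _trial_frame([300.0] * 10 + [2000.0])
    trimmed, frac = ts.trim_latencies(trials)
    assert len(trimmed) == 10
    assert 2000.0 not in trimmed["latency_ms"].to_numpy()
    assert frac == pytest.approx(1 / 11)
    # one-pass rule: re-trimming the survivors removes nothing further
    again, frac2 = ts.trim_latencies(trimmed)
    assert len(again) == 10 and frac2 == 0.0


def test_equal_latencies_remove_nothing():
    trimmed, frac = ts.trim_latencies(_trial_frame([400.0] * 8))
    assert len(trimmed) == 8 and frac == 0.0


def test_incorrect_trials_never_trimmed():
    trials = _trial_frame([300.0] * 10 + [2000.0], correct=[True] * 10 + [False])
    trimmed, frac = ts.trim_latencies(trials)
    assert len(trimmed) == 11 and frac == 0.0  # the outlier is an error trial


def test_trimmed_fraction_near_4_6_percent_for_normal_latencies():
    rng = np.random.default_rng(0)
    rows = []
    for s in range(20):
        for c in ts.TONE_CONTRASTS:
            for lat in rng.normal(450, 80, size=60):
                rows.append({"subject": f"s{s}", "group": "g", "test": "tone",
                             "contrast": c, "correct": True, "latency_ms": lat})
    _, frac = ts.trim_latencies(pd.DataFrame(rows))
    assert 0.03 < frac < 0.05  # the 2SD rule removes ~4.6% asymptotically


# ---------------------------------------------------------------------------
# summaries and correlations
# ---------------------------------------------------------------------------

def test_accuracy_counts_three_of_four():
    trials = _trial_frame([300.0] * 4, correct=[True, True, True, False])
    summary = ts.summarize(trials)
    assert summary["accuracy"].iloc[0] == pytest.approx(0.75)


def test_group_accuracy_is_trial_weighted_contrast_mean(design):
    trials = ts.simulate_axb(design, small_params(0.85, n=6), seed=2)
    tone = trials[trials["test"] == "tone"]
    overall = ts.summarize(trials).set_index("test").loc["tone", "accuracy"]
    by_contrast = tone.groupby("contrast")["correct"].agg(["mean", "size"])
    weighted = np.average(by_contrast["mean"], weights=by_contrast["size"])
    assert overall == pytest.approx(weighted)


def test_pearson_closed_forms():
    x = np.arange(10.0)
    assert ts.pearson(x, 2 * x + 1) == pytest.approx(1.0)
    assert ts.pearson(x, -x) == pytest.approx(-1.0)
    assert np.isnan(ts.pearson(x, np.ones(10)))
    with pytest.raises(ValueError):
        ts.pearson([1.0, 2.0], [3.0, 4.0])


def test_independent_vectors_have_near_zero_correlation():
    rng = np.random.default_rng(5)
    assert abs(ts.pearson(rng.normal(size=10_000), rng.normal(size=10_000))) < 0.05


def _template_feature_frame():
    rows = []
    for i, tone in enumerate(ts.TONES):
        rows.append({"category": tone,
                     "duration_ms": TONE_PARAMETER_MEANS["duration"][i],
                     "general_slope": TONE_PARAMETER_MEANS["general_slope"][i],
                     "flat": 1.0})
    return pd.DataFrame(rows)


def _contrast_accuracy_trials(acc_by_group):
    """Tiny deterministic trial table with exact per-contrast accuracies."""
    rows = []
    for group, acc in acc_by_group.items():
        for contrast in ts.TONE_CONTRASTS:
            p = acc[contrast]
            for i in range(20):
                rows.append({"subject": f"{group}-1", "group": group,
                             "test": "tone", "contrast": contrast,
                             "correct": i < round(20 * p), "latency_ms": 400.0})
    return pd.DataFrame(rows)


def test_acoustic_perceptual_table_tone_level():
    rng = np.random.default_rng(8)
    acc = {c: 0.7 + 0.25 * rng.random() for c in ts.TONE_CONTRASTS}
    trials = _contrast_accuracy_trials({"g1": acc, "g2": acc})
    table = ts.acoustic_perceptual_table(trials, _template_feature_frame(),
                                         unit="tone_level")
    assert table.n == 6 and table.unit == "tone_level"
    # duration and general slope co-vary strongly across the six tones
    assert table.corr.loc["duration_ms", "general_slope"] == pytest.approx(0.9925, abs=0.001)
    # identical accuracy vectors for two groups correlate perfectly
    assert table.corr.loc["g1_accuracy", "g2_accuracy"] == pytest.approx(1.0)
    # constant feature -> undefined correlation row
    assert np.isnan(table.corr.loc["flat", "duration_ms"])


def test_acoustic_perceptual_table_contrast_level():
    rng = np.random.default_rng(9)
    acc = {c: 0.7 + 0.25 * rng.random() for c in ts.TONE_CONTRASTS}
    trials = _contrast_accuracy_trials({"g1": acc})
    table = ts.acoustic_perceptual_table(trials, _template_feature_frame(),
                                         unit="contrast_level")
    assert table.n == 15 and table.unit == "contrast_level"
    assert (table.data["duration_ms"] >= 0).all()  # absolute mean differences


def test_tone_stress_correlation_shape(design):
    trials = ts.simulate_axb(design, small_params(0.9, n=5), seed=4)
    out = ts.tone_stress_correlation(trials)
    assert set(out.columns) == {"group", "n", "r"}
    assert out["n"].iloc[0] == 5
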