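"""AXB discrimination-trial simulator.

Each trial presents three stimuli; the middle one (X) matches either the
first or the third, and the listener answers with button 1 or 3 within a
3000 ms deadline.  Correctness is Bernoulli with the group x contrast
accuracy; response latency is drawn from a normal truncated to (0, 3000] ms.
Timeouts (off by default — the emulated study reports none) are incorrect
and carry no latency.

Default parameters reproduce the emulated study's group structure: 30
bilingual children (tone accuracy .92, stress .91), 30 bilingual adults
(.95/.98), 15 English monolingual adults (.90/.95), with the specifically
reported contrast cells (children T2-T5 .75; adults T2-T5 .88 and T3-T6 .89;
monolinguals T2-T5 .73 and T1-T3 .85) and all remaining contrasts set to the
common value that makes the 15-contrast mean equal the group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .design import AXB_ORDERS, StimulusDesign
from .templates import TONE_CONTRASTS

__all__ = ["GroupParams", "default_group_params", "simulate_axb",
           "GROUPS", "RESPONSE_DEADLINE_MS"]

GROUPS = ("bilingual_child", "bilingual_adult", "english_monolingual")
RESPONSE_DEADLINE_MS = 3000.0

#: Button that names the matching stimulus for each AXB order.
_CORRECT_BUTTON = {"AAB": "1", "ABB": "3", "BAA": "3", "BBA": "1"}


def _check_prob(p: float, what: str) -> float:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{what} must be in [0, 1], got {p}")
    return float(p)


@dataclass
class GroupParams:
    """Per-group accuracy and latency parameters."""

    tone_accuracy: dict  # contrast id -> P(correct)
    stress_accuracy: float
    tone_latency_ms: tuple[float, float]  # (mean, sd)
    stress_latency_ms: tuple[float, float]
    n_subjects: int = 30
    timeout_prob: float = 0.0

    def __post_init__(self) -> None:
        for c, p in self.tone_accuracy.items():
            _check_prob(p, f"accuracy[{c}]")
        _check_prob(self.stress_accuracy, "stress accuracy")
        _check_prob(self.timeout_prob, "timeout probability")
        for mean, _sd in (self.tone_latency_ms, self.stress_latency_ms):
            if not (0 < mean < RESPONSE_DEADLINE_MS):
                raise ValueError(f"latency mean {mean} outside (0, {RESPONSE_DEADLINE_MS})")


def _tone_accuracies(group_mean: float, specials: dict) -> dict:
    """Fill the 15 contrasts: printed cells as given, the rest at the common
    value that makes the contrast mean equal the group mean."""
    k = len(specials)
    base = (15 * group_mean - sum(specials.values())) / (15 - k)
    return {c: specials.get(c, base) for c in TONE_CONTRASTS}


def default_group_params() -> dict[str, GroupParams]:
    latency_sd = 100.0  # per-trial latency SD; not reported, scale choice
    return {
        "bilingual_child": GroupParams(
            tone_accuracy=_tone_accuracies(0.92, {"T2-T5": 0.75}),
            stress_accuracy=0.91,
            tone_latency_ms=(446.0, latency_sd),
            stress_latency_ms=(450.0, latency_sd),
            n_subjects=30,
        ),
        "bilingual_adult": GroupParams(
            tone_accuracy=_tone_accuracies(0.95, {"T2-T5": 0.88, "T3-T6": 0.89}),
            stress_accuracy=0.98,
            tone_latency_ms=(359.0, latency_sd),
            stress_latency_ms=(250.0, latency_sd),
            n_subjects=30,
        ),
        "english_monolingual": GroupParams(
            tone_accuracy=_tone_accuracies(0.90, {"T2-T5": 0.73, "T1-T3": 0.85}),
            stress_accuracy=0.95,
            tone_latency_ms=(466.0, latency_sd),
            stress_latency_ms=(396.0, latency_sd),
            n_subjects=15,
        ),
    }


def _draw_latency(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a = (0.0 - mean) / sd
    b = (RESPONSE_DEADLINE_MS - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_axb(
    design: StimulusDesign,
    group_params: dict[str, GroupParams] | None = None,
    seed: int = 0,
    stress_trials_per_subject: int = 55,
) -> pd.DataFrame:
    """Simulate the full two-test experiment over all groups.

    Subjects are assigned to the design's 10 versions round-robin.  The tone
    test runs the subject's 165-trial version; the stress test presents one
    trochaic-vs-iambic trial per word (single 'stress' contrast).  Returns a
    trial table with columns subject, group, test, contrast, word, order,
    response, correct, latency_ms, version.
    """
    if group_params is None:
        group_params = default_group_params()
    rng = np.random.default_rng(seed)
    words = [str(w) for w in design.words]
    rows = []
    for group, params in group_params.items():
        for s in range(params.n_subjects):
            subject = f"{group}-{s + 1:02d}"
            version_idx = s % len(design.versions)
            version = design.versions[version_idx]

            # ---- tone test ----
            for trial in version.itertuples(index=False):
                rows.append(_one_trial(
                    rng, subject, group, "tone", trial.contrast, trial.word,
                    trial.order, params.tone_accuracy[trial.contrast],
                    params.tone_latency_ms, params.timeout_prob, version_idx + 1,
                ))
            # ---- stress test ----
            stress_words = list(rng.permutation(words))[:stress_trials_per_subject]
            for word in stress_words:
                order = AXB_ORDERS[int(rng.integers(len(AXB_ORDERS)))]
                rows.append(_one_trial(
                    rng, subject, group, "stress", "stress", word, order,
                    params.stress_accuracy, params.stress_latency_ms,
                    params.timeout_prob, version_idx + 1,
                ))
    return pd.DataFrame(rows)


def _one_trial(rng, subject, group, test, contrast, word, order,
               p_correct, latency_params, timeout_prob, version) -> dict:
    timeout = rng.random() < timeout_prob
    if timeout:
        return {"subject": subject, "group": group, "test": test,
                "contrast": contrast, "word": word, "order": order,
                "response": "timeout", "correct": False,
                "latency_ms": np.nan, "version": version}
    correct = bool(rng.random() < p_correct)
    right = _CORRECT_BUTTON[order]
    response = right if correct else ("3" if right == "1" else "1")
    latency = float(_draw_latency(rng, *latency_params, size=1)[0])
    return {"subject": subject, "group": group, "test": test,
            "contrast": contrast, "word": word, "order": order,
            "response": response, "correct": correct,
            "latency_ms": latency, "version": version}
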