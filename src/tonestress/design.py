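"""Stimulus-design generator: CVCV pseudoword inventory, tone/stress token
lists, and the latin-square AXB test versions.

The design emulates a two-test discrimination study:

* 55 disyllabic CVCV pseudowords drawn from 11 consonants and 5 vowels, with
  no repeated consonant or vowel inside a word;
* a tone test in which one syllable carries a constant high-level tone (T1)
  while the other varies over T1-T6, in both orders (constant on syllable 1
  or syllable 2), every token recorded 3 times -> 55 x 2 x 6 x 3 = 1980
  recordings, of which one repetition per cell (660 tokens) enters the test;
* a stress test with trochaic vs iambic versions of every word, 3 repetitions
  -> 330 recordings, 110 test tokens;
* 10 latin-square test versions (5 block rotations x 2 constant-tone
  positions), each containing 165 AXB trials = 5 blocks x 11 words x 3 tone
  contrasts, with all 55 words and all 15 contrasts present in every version.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .templates import TONES, TONE_CONTRASTS

__all__ = [
    "CONSONANTS",
    "VOWELS",
    "AXB_ORDERS",
    "Pseudoword",
    "StimulusDesign",
    "build_design",
]

CONSONANTS = ("b", "p", "d", "t", "g", "k", "m", "h", "l", "s", "f")
VOWELS = ("a", "ɛ", "i", "ɔ", "u")
AXB_ORDERS = ("AAB", "ABB", "BAA", "BBA")

N_WORDS = 55
N_BLOCKS = 5
WORDS_PER_BLOCK = 11
CONTRASTS_PER_BLOCK = 3
N_REPETITIONS = 3


@dataclass(frozen=True)
class Pseudoword:
    """Disyllabic CVCV pseudoword; no repeated consonant or vowel."""

    c1: str
    v1: str
    c2: str
    v2: str

    def __post_init__(self) -> None:
        for c in (self.c1, self.c2):
            if c not in CONSONANTS:
                raise ValueError(f"consonant {c!r} outside inventory")
        for v in (self.v1, self.v2):
            if v not in VOWELS:
                raise ValueError(f"vowel {v!r} outside inventory")
        if self.c1 == self.c2 or self.v1 == self.v2:
            raise ValueError("repeated consonant or vowel within a word")

    def __str__(self) -> str:
        return self.c1 + self.v1 + self.c2 + self.v2


@dataclass
class StimulusDesign:
    """Full stimulus inventory plus the 10 latin-square AXB test versions."""

    words: list[Pseudoword]
    recording_inventory: pd.DataFrame  # every recorded token (3 reps each)
    tone_tokens: pd.DataFrame  # 660 selected tone test tokens
    stress_tokens: pd.DataFrame  # 110 selected stress test tokens
    versions: list[pd.DataFrame]  # 10 versions x 165 AXB trial specs
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_recordings(self) -> int:
        return len(self.recording_inventory)


def _sample_words(rng: np.random.Generator) -> list[Pseudoword]:
    """Draw 55 distinct legal CVCV pseudowords."""
    seen: set[str] = set()
    words: list[Pseudoword] = []
    while len(words) < N_WORDS:
        c1, c2 = rng.choice(len(CONSONANTS), size=2, replace=False)
        v1, v2 = rng.choice(len(VOWELS), size=2, replace=False)
        w = Pseudoword(CONSONANTS[c1], VOWELS[v1], CONSONANTS[c2], VOWELS[v2])
        if str(w) not in seen:
            seen.add(str(w))
            words.append(w)
    return words


def build_design(seed: int = 0) -> StimulusDesign:
    """Generate the complete stimulus design, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    words = _sample_words(rng)
    word_ids = [str(w) for w in words]

    # ---- recording inventory: every token recorded N_REPETITIONS times ----
    rec_rows = []
    for wid in word_ids:
        for cpos in ("syll1", "syll2"):
            for tone in TONES:
                for rep in range(1, N_REPETITIONS + 1):
                    rec_rows.append(
                        {"token_type": "tone", "word": wid, "constant_pos": cpos,
                         "category": tone, "repetition": rep}
                    )
        for pattern in ("trochaic", "iambic"):
            for rep in range(1, N_REPETITIONS + 1):
                rec_rows.append(
                    {"token_type": "stress", "word": wid, "constant_pos": "",
                     "category": pattern, "repetition": rep}
                )
    recording_inventory = pd.DataFrame(rec_rows)

    # ---- test token selection: one repetition per design cell ----
    tone_rows = []
    for wid in word_ids:
        for cpos in ("syll1", "syll2"):
            for tone in TONES:
                rep = int(rng.integers(1, N_REPETITIONS + 1))
                tone_rows.append(
                    {"word": wid, "constant_pos": cpos, "tone": tone, "repetition": rep}
                )
    tone_tokens = pd.DataFrame(tone_rows)

    stress_rows = []
    for wid in word_ids:
        for pattern in ("trochaic", "iambic"):
            rep = int(rng.integers(1, N_REPETITIONS + 1))
            stress_rows.append({"word": wid, "pattern": pattern, "repetition": rep})
    stress_tokens = pd.DataFrame(stress_rows)

    # ---- latin-square versions ----
    # Words and contrasts are each shuffled once and cut into 5 groups; version
    # v pairs word block b with contrast group (b + v) mod 5, so every version
    # contains all 55 words and all 15 contrasts.  The 5 rotations are crossed
    # with the 2 constant-tone positions, giving 10 versions.
    word_perm = list(rng.permutation(word_ids))
    contrast_perm = list(rng.permutation(TONE_CONTRASTS))
    word_groups = [word_perm[b * WORDS_PER_BLOCK:(b + 1) * WORDS_PER_BLOCK]
                   for b in range(N_BLOCKS)]
    contrast_groups = [contrast_perm[b * CONTRASTS_PER_BLOCK:(b + 1) * CONTRASTS_PER_BLOCK]
                       for b in range(N_BLOCKS)]

    versions: list[pd.DataFrame] = []
    for cpos, rotation in itertools.product(("syll1", "syll2"), range(N_BLOCKS)):
        rows = []
        for b in range(N_BLOCKS):
            contrasts = contrast_groups[(b + rotation) % N_BLOCKS]
            for wid in word_groups[b]:
                for contrast in contrasts:
                    order = AXB_ORDERS[int(rng.integers(len(AXB_ORDERS)))]
                    rows.append(
                        {"block": b + 1, "word": wid, "contrast": contrast,
                         "order": order, "constant_pos": cpos}
                    )
        df = pd.DataFrame(rows)
        df.insert(0, "trial", np.arange(1, len(df) + 1))
        versions.append(df)

    return StimulusDesign(
        words=words,
        recording_inventory=recording_inventory,
        tone_tokens=tone_tokens,
        stress_tokens=stress_tokens,
        versions=versions,
        seed=seed,
        meta={"word_groups": word_groups, "contrast_groups": contrast_groups},
    )
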