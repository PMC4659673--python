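"""Build the stimulus design and render one disyllabic tone token.

The design comprises 55 CVCV pseudowords crossed with six Cantonese tones,
two constant-tone positions and two stress patterns, plus ten latin-square
AXB test versions of 165 trials each.  One T2 (high rising) token is rendered
to WAV to show the synthesis path.
"""

from pathlib import Path

import tonestress as ts

design = ts.build_design(seed=1)
print(f"pseudowords:          {len(design.words)}  (e.g. {design.words[0]}, {design.words[1]})")
print(f"tone test tokens:     {len(design.tone_tokens)}")
print(f"stress test tokens:   {len(design.stress_tokens)}")
print(f"recording inventory:  {design.n_recordings}")
print(f"test versions:        {len(design.versions)} x {len(design.versions[0])} trials")

word = str(design.words[0])
tracks = [ts.sample_contour(ts.TONE_TEMPLATES["T2"], seed=1),
          ts.sample_contour(ts.TONE_TEMPLATES["T1"], seed=2)]
out = Path("scratch")
out.mkdir(exist_ok=True)
wav = out / f"{word}_T2.wav"
token, segments = ts.render_token(tracks, vowels=[word[1], word[3]],
                                  templates=[ts.TONE_TEMPLATES["T2"],
                                             ts.TONE_TEMPLATES["T1"]],
                                  path=wav)
print(f"\nrendered {wav}: {len(token) / 44100 * 1000:.0f} ms total,")
for i, seg in enumerate(segments, 1):
    print(f"  syllable {i} vowel: {seg.start * 1000:.0f}-{seg.end * 1000:.0f} ms")
print("The token is a rising-tone first syllable followed by the constant "
      "high-level tone; total duration sits in the 800-1000 ms acceptance window.")
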