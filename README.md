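# tonestress

Acoustic-phonetic analysis of **Cantonese lexical tone** and **English
lexical stress**, packaged as a tested Python pipeline for speech-perception
research.  It is aimed at phoneticians and psycholinguists who study
suprasegmental cues — the pitch, duration, intensity and spectral-balance
differences that distinguish the six Cantonese tones (T1 high level 55, T2
high rising 25, T3 mid level 33, T4 low falling 21, T5 low rising 23, T6 low
level 22) and trochaic vs iambic stress — and who need every stage of such a
study reproducible without access to the original recordings.

The package covers:

* **Stimulus synthesis** (`design`, `contours`, `render`): 55 CVCV
  pseudowords from 11 consonants × 5 vowels (no repeated segment within a
  word); 660 tone and 110 stress test tokens out of a 2310-token recording
  inventory; ten latin-square AXB test versions of 165 trials; parametric F0
  contours drawn from per-category templates (level tones linear, contour
  tones two legs through the F0 minimum with a smoothed joint); and a
  harmonic-source renderer producing 44.1 kHz 16-bit mono WAV calibrated
  either to a mean intensity or to absolute per-band SPL targets.
* **Extraction** (`extraction`): a normalized-autocorrelation pitch tracker
  (default search range 75–500 Hz, 30 ms window, 10 ms hop, octave cost,
  parabolic peak refinement), mean intensity re 2×10⁻⁵ Pa, and the token
  acceptance screens (800–1000 ms duration, 50–66 dB intensity).
* **Contour features** (`features`): duration, F0 average/onset/offset,
  general slope = (F0_offset − F0_onset)/duration, displacement, the
  fall/rise decomposition around the F0 minimum with rise-to-fall
  displacement and time ratios, the **major slope** (rise slope for rising
  tones, fall slope for the falling tone, general slope for level tones),
  and classification of contours by the major-slope ranges +270…+410 (rising),
  −70…−130 (level), −200…−260 (falling) Hz/s.
* **Spectral balance** (`spectral`): band energies in B1 0–0.5, B2 0.5–1,
  B3 1–2, B4 2–4 kHz over an automatically selected stable vowel portion
  (≥ 70 ms), converted to duration-normalized SPL via
  `10·log10(energy / (time · 4×10⁻¹⁰))`.
* **Cue saliency** (`saliency`): the *estimated overall variation* statistic
  — for category means x₁…x_K, the sum of |xᵢ − xⱼ| over all K(K−1)/2
  contrasts divided by Σ|xₖ| — used to rank acoustic parameters by how much
  they separate the 15 tone contrasts.
* **Perception analysis** (`axb`, `perception`): an AXB trial simulator
  (Bernoulli accuracy per group × contrast, truncated-normal latencies on
  (0, 3000] ms), 2-SD latency trimming per subject × condition, accuracy and
  latency summaries, and Pearson correlation tables between group accuracies
  and acoustic parameters at the per-tone (n = 6) or per-contrast (n = 15)
  unit of analysis.

## Worked example

Ranking the acoustic correlates of tone by estimated overall variation
(`python examples/03_cue_saliency.py`):

```
    parameter  variation  percent  rank
  major_slope   3.588688      359     1
 displacement   3.090127      309     2
general_slope   3.008422      301     3
       f0_avg   0.555450       56     4
     f0_onset   0.481922       48     5
    f0_offset   0.452042       45     6
     duration   0.398900       40     7
           b3   0.375514       38     8
           b4   0.222824       22     9
           b2   0.208700       21    10
           b1   0.093671        9    11
    intensity   0.066440        7    12
```

Read the `percent` column as "the pairwise spread across the 15 tone
contrasts amounts to this fraction of the summed category magnitudes":
average F0 separates the tones most among the height/duration/spectral cues
(56%), followed by F0 onset (48%), F0 offset (45%) and duration (40%); the
spectral bands and intensity contribute much less.  Signed slope measures
(major slope, general slope, displacement) straddle zero, which shrinks the
absolute-mean denominator and inflates the statistic onto a different scale —
see `docs/methods.md` for why those rows are reported as computed rather than
rescaled.

The other examples synthesize and render stimuli (`01`), demonstrate the
synthesis → extraction round trip per tone (`02`), and run the full AXB
simulation and perception analysis (`04`).  A thin CLI mirrors the batch
workflows: `tonestress simulate-stimuli`, `simulate-axb`, `extract`,
`features`, `spectral`, `saliency`, `perception` (see `--help`).

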