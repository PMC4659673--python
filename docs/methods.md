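# Methods

This note documents the models, parameters and numerical choices behind
`tonestress`, and what the synthetic stimuli do and do not establish about
real speech.

## Contour model and category templates

Each tone or stress category is described by a template of production
parameters (mean, SD): vowel duration (ms), F0 onset and offset (Hz), mean
intensity (dB), band levels B1–B4 (dB SPL), and — for the contour tones T2,
T4, T5 — the F0 minimum (Hz) plus fall and rise times (ms).  Default values
are the per-category means and SDs of the recorded corpus the package
emulates; the F0 minimum is derived as onset + fall displacement, and its SD
reuses the fall-displacement SD since both describe the same contour leg.

A sampled contour is:

* **level classes** — a straight line from a sampled onset to a sampled
  offset.  The four stress conditions also use this model: their
  documented general slopes are numerically consistent with a single linear
  glide (e.g. TS1: (309.69 − 329.45)/0.22834 s = −86.5 Hz/s against a
  documented −86.43), so no fall/rise structure is imposed.
* **contour classes** — two linear legs, onset → minimum over the fall time
  and minimum → offset over the rise time, blended over ±10 ms at the joint
  by a half-sine crossfade anchored at the minimum.  The blend renders the
  turning point as the concave-up curve seen in natural productions while
  leaving the curve within ~0.01 Hz of the sampled minimum (the residual dip
  scales with the squared sum of the leg slopes, which nearly cancels for
  template-scale asymmetries).

All template parameters are jittered as independent Gaussians; a global
`sd_scale` factor scales every SD (0 gives the deterministic template
contour).  Because the documented fall/rise-time means are per-token means
and do not sum exactly to the documented durations, the sampled legs are
rescaled to tile the sampled duration: t_min = duration · fall/(fall + rise).
This keeps the decomposition identities (fall + rise time = duration,
fall + rise displacement = displacement) exact on synthetic tracks.

Tracks carry exact endpoint samples at t = 0 and t = duration on a uniform
grid of ~10 ms (configurable), so the zero-jitter onset and offset equal the
template values identically.

### What the generator emulates — and what it does not

The generator reproduces the *category structure* of the stimulus corpus:
per-category parameter means and SDs, the stimulus counts (55 words, 660
tone / 110 stress test tokens, 2310 recordings, 10 test versions × 165
trials), and trackable harmonic voicing.  It does not emulate consonant
acoustics (consonants are silent gaps), aspiration noise, coarticulation,
within-token F0 microprosody, vowel-quality variation (F1/F2 are fixed
two-resonance settings per vowel), or correlations *between* parameters
within a token (all jitters are independent).  Passing round-trip tests
therefore demonstrates that the extraction and feature code is faithful on
clean voiced material with known truth — not that the pitch tracker is
robust to breathy or irregular phonation, nor that the saliency ranking
would survive a different speaker's parameter covariance.

## Rendering and calibration

The voice source is an additive band-limited harmonic series (all partials
of a 1/k envelope below 4 kHz) following the interpolated F0 trajectory,
shaped by two cascaded resonators per vowel (bandwidth 90 Hz) and given 5 ms
cosine edge ramps.  Digital full scale maps to √2 Pa, putting a full-scale
sine at 94 dB SPL — the conventional calibration-tone level; absolute dB
values in a corpus presuppose some such recording calibration, and this one
is the package's fixed choice.

Two calibration modes exist because the documented per-tone intensities and
band SPLs are mutually inconsistent under any single calibration (the power
sum of T1's four band levels is ≈ 59.8 dB against a documented mean
intensity of 65.71 dB — the two were evidently measured over different
windows/settings):

* **intensity mode** (default): the waveform is scaled so its mean intensity
  matches the requested level; round trips hold to ±1 dB.
* **band-target mode**: per-band gains are iterated (5 rounds) against the
  same zero-phase Butterworth band filters the analysis uses until each
  band's duration-normalized SPL matches its template target (±1 dB in
  practice); the overall intensity is then emergent (56–60 dB for the tone
  templates, inside the 50–66 dB acceptance screen).  Harmonics within 10%
  of an interior band edge (500, 1000, 2000 Hz) are omitted in this mode:
  they leak across the 4th-order filter skirts and would otherwise floor a
  quiet band (T4's B3 sits 23 dB below its B2) beyond the reach of any
  per-band gain.

## Pitch tracking

Normalized autocorrelation per frame, with the correlation at lag τ
normalized by the energies of the two overlapping stretches (this makes the
tracker exactly amplitude-invariant); candidate lags cover the 75–500 Hz
default search range, an octave cost of 0.03 per octave penalizes longer
lags, the peak is refined parabolically, and frames with peak correlation
below 0.45 are unvoiced.  Unvoiced gaps of ≤ 2 frames are linearly
interpolated; the longest voiced run is analyzed.

Window and hop: 30 ms window, 10 ms hop by default.  A longer (40 ms) window
would be the textbook choice for a 75 Hz floor, but the first and last
frames then reflect F0 ~10 ms inside the vowel, which biases onset/offset by
more than 3 Hz on fast contours (T2's falling leg moves at ≈ −340 Hz/s); 30
ms supports the search floor (≥ 2 periods at 75 Hz) while halving that
bias.  Edge frames use the valid (asymmetric) part of the window with the
frame time reported at the temporal centroid of the samples actually used,
and the finished track is linearly extrapolated to the segment edges from
the two adjacent voiced frames.  With these choices the zero-jitter
synthesis → extraction round trip recovers onset, offset and mean F0 within
2 Hz for every tone.  For contour decomposition (fall/rise legs, major
slope) a 5 ms hop is recommended — the leg boundary is otherwise quantized
to the frame grid; the feature functions take whatever grid the track has.

## Feature battery

Onset/offset are the first/last voiced frame values (the track is already
edge-extrapolated), average F0 the mean over voiced frames, duration the
voiced span.  Slopes are reported in **Hz/s**: the corpus tables label their
slopes "Hz/ms", but every printed magnitude is consistent with Hz per
second (−25.54 Hz over 230.64 ms ≈ −111 as printed), so the label is treated
as a misprint and the package documents Hz/s throughout.

The F0 minimum is located on a 3-frame median-smoothed copy of the voiced
track (earliest frame on ties), then refined to the raw minimum among that
frame's immediate neighbors — the median otherwise flattens a sharp corner
by one frame.  Displacements and times use raw values at the located frame,
so the additivity identities hold exactly.  Monotonic tracks yield a
zero-time leg (slope 0) and a degenerate flag rather than an error;
rise-to-fall ratios with a zero fall leg are NaN markers.  For level-class
tokens the decomposition is computed but diagnostic only.

Category aggregation averages per-token features arithmetically — ratios are
means of per-token ratios, which is why a corpus's mean time ratio (e.g.
2.01 for T2) need not equal the ratio of its mean leg times
(205.01/108.34 = 1.89).

## Spectral balance

Band filtering is zero-phase forward–backward 4th-order Butterworth with
edges at the printed frequencies; B1 is implemented as a 500 Hz low-pass
(its nominal lower edge is 0 Hz).  In-band tones at 0.6 of a cutoff lose
~3% of their energy to the filter skirts; the four bands jointly capture
0–4 kHz energy to within ~1% for components away from the edges.  The
"stable portion" (≥ 70 ms) is operationalized as the window minimizing the
summed variance of the z-scored F0 and intensity contours — the selection
rule is the package's own, recorded in the profile output, since only the
length constraint is documented.  Note that on strongly moving contours the
stable-window band levels can differ by 1–2 dB from whole-vowel levels (the
harmonics move across band edges); the band-target calibration is defined
over the whole vowel.

## Cue saliency

`estimated_overall_variation` is computed exactly as defined — absolute
values appear only where the definition writes them, i.e. around the
pairwise differences and around the category means in the denominator.  Two
consequences are reported rather than corrected:

* signed parameters that straddle zero (major slope, general slope,
  displacement) get a small denominator and values far above 1 (major slope
  computes to ≈ 359% where the source battery reports 38%; no reading of the
  printed equation reproduces 38% from the printed means, and the package
  does not guess at the unstated normalization);
* intensity computes to 6.6% from the printed means where 6% is reported
  (plausibly a raw-token computation or truncation; also left as computed).

The statistic is scale-invariant but *not* translation-invariant (tested),
so it is only meaningful for parameters with a natural zero.  It generalizes
to any K ≥ 2 categories (K(K−1)/2 pairs), e.g. the four stress conditions —
an extension beyond its original six-tone use.

## AXB simulation and perception analysis

Correctness is Bernoulli per trial with the group × contrast accuracy;
latencies are normal truncated to (0, 3000] ms and drawn for answered
trials.  Defaults follow the emulated study: group sizes 30/30/15, group
mean accuracies (tone/stress) .92/.91, .95/.98, .90/.95, the specifically
reported contrast cells (children T2–T5 .75; adults T2–T5 .88, T3–T6 .89;
monolinguals T2–T5 .73, T1–T3 .85) with the remaining contrasts at the
common value that preserves the group mean, and group latency means 446/450,
359/250, 466/396 ms.  Latency SDs (100 ms) and the zero timeout rate are the
package's defaults — neither is documented.  Versions are assigned to
subjects round-robin (the original assignment scheme is unstated).  Because
subjects share their group's parameters, per-subject tone and stress
accuracies are independent by construction: the simulator reproduces group
means and contrast orderings, not between-subject correlation structure
(tone–stress correlations computed on simulated data hover near zero).

Latency trimming removes correct-trial latencies more than 2 SD from their
subject × test × contrast cell mean, in a single pass, using the sample SD
of the full cell; cells with fewer than 3 correct trials or zero SD are left
intact.  Note the rule's small-sample behaviour: in a 4-point cell a single
extreme value inflates the SD enough to protect itself (e.g. {300, 310, 320,
2000} removes nothing), which is a property of the rule, not a bug;
asymptotically it removes ≈ 4.6% of normal latencies.  Timeouts count as
errors for accuracy and never enter latency analysis.

Acoustic-perceptual correlation tables are provided at two units of
analysis, both labelled, neither privileged: per tone (n = 6; a tone's
accuracy is the mean over the 5 contrasts containing it) and per contrast
(n = 15; features enter as absolute differences of category means).  The
unit behind published tables of this kind is often unstated, and the two
units can give visibly different r values.  No inferential machinery
(ANOVA, post-hoc tests, effect sizes) is attached; the summaries are the
descriptive inputs such tests would consume.

## Stress templates: reconstructed cells

Three stress band-SPL cells (B1 of TS1, B1 of TS2, B4 of TS2) are not
directly documented.  They were reconstructed from documented marginals —
per-condition overall spectral means and per-band grand means — which pins
them uniquely; the reconstruction reproduces the documented IS2 overall mean
(48.71 dB) exactly, supporting its consistency.  Stress band SDs are
undocumented and borrow the tone-table scale (3/8/12/10 dB).  These values
are synthetic-fill, flagged here, and only affect stress-token synthesis.

## Problem sizes

The test suite runs end-to-end at desk scale: 20 tokens per tone (jitter
halved) for synthesis → extraction parameter recovery, 30 subjects per group
for AXB recovery, 10,000 draws for parameter-jitter Monte-Carlo checks.
These sizes put Monte-Carlo standard errors well below the effects being
checked while keeping the full suite under a minute.

## Known limitations

* The renderer is a stimulus generator, not a speech synthesizer: no noise
  source, no consonants, fixed resonances.
* The pitch tracker assumes clean periodic voicing; it has no octave-jump
  repair beyond the octave cost and no voicing hysteresis.
* Intensity and band-SPL targets cannot be satisfied simultaneously (see
  calibration above); users must pick the mode matching their question.
* The saliency statistic has no sampling theory attached (no standard
  errors); treat rankings, not differences between adjacent values, as the
  output.
* Perceptual tone normalization (semitone or z-scored F0 scales) and
  tonal-context modelling are out of scope; contours are analyzed in raw Hz.
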