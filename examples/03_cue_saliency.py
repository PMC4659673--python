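"""Rank the acoustic correlates of Cantonese tone by estimated overall
variation: the sum of absolute pairwise differences of the six per-tone means
(the 15 tone contrasts) divided by the sum of absolute per-tone means.
"""

import pandas as pd

import tonestress as ts
from tonestress.templates import TONE_PARAMETER_MEANS, TONES

table = pd.DataFrame({"category": TONES,
                      **{p: list(v) for p, v in TONE_PARAMETER_MEANS.items()}})
saliency = ts.saliency_table(table)
print(saliency.to_string(index=False))
print(
    "\nHeight cues dominate: average F0 (56%), F0 onset (48%) and F0 offset"
    "\n(45%) vary most across the 15 contrasts, ahead of duration (40%) and the"
    "\nspectral bands.  The major-slope row is on another scale entirely (~359%)"
    "\nbecause signed slopes straddle zero, so the absolute-mean denominator is"
    "\nsmall relative to the pairwise spread — a known quirk of this statistic"
    "\nfor signed parameters."
)
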