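"""Published letter identification rates for eight P300 decoding approaches.

Benchmark table of letter identification rates (%) at 10 intensifications for
eight ALS subjects spelling 20 test letters on the standard 6x6 row/column
speller, as reported for a public 8-channel / 256 Hz dataset.  The methods
span classical decoders (stepwise LDA, SVM), CNN baselines (EEGNET, BCINET),
a keypoint-descriptor method (SIFT) and the three waveform-plot CNN variants
implemented here.  Subjects are the natural blocks for a nonparametric
method comparison such as :func:`p300wave.stats.quade_test`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

METHODS = ("SWLDA", "SVM", "EEGNET", "BCINET", "SIFT", "VGG16", "SV16", "MSV16")

#: Rows: subjects 1-8; columns: the methods above. Values are percentages.
LETTER_RATE_TABLE = np.array(
    [
        [45, 40, 50, 45, 35, 15, 10, 0],
        [30, 50, 30, 55, 85, 70, 50, 75],
        [65, 55, 70, 65, 25, 30, 30, 40],
        [40, 50, 60, 55, 55, 30, 40, 30],
        [35, 45, 40, 45, 40, 35, 50, 50],
        [35, 70, 60, 75, 60, 45, 40, 50],
        [60, 35, 90, 80, 80, 70, 65, 80],
        [90, 95, 100, 95, 95, 90, 95, 100],
    ],
    dtype=float,
)


def letter_rate_table() -> pd.DataFrame:
    """The benchmark table as a subjects x methods DataFrame."""
    return pd.DataFrame(
        LETTER_RATE_TABLE,
        index=pd.RangeIndex(1, 9, name="subject"),
        columns=list(METHODS),
    )
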