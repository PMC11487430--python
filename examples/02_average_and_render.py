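"""Average target epochs, z-score, and rasterize the waveform plot.

Shows the signal-averaging chain on one letter of a synthetic session: the
per-channel SD of the running average falls roughly as 1/sqrt(N), the
z-scored average has unit variance, and the rendered plot is a binary
trace with ~25% blank margin for a symmetric signal.
"""

import numpy as np

from p300wave import (
    SyntheticConfig,
    average_epochs,
    averaging_sd_curve,
    extract_epochs,
    generate_session,
    group_by_code,
    render_plot,
    rescale_image,
    zscore_normalize,
)

rec = generate_session(SyntheticConfig(n_letters=3, seed=4))
es = extract_epochs(rec)
grouped = group_by_code(es, letter_index=0, n_intensifications=10)

# the attended letter's row code: its epochs carry the P300
target_code = next(c for c in range(1, 7) if grouped[c][0].is_target)
epochs = grouped[target_code]

curve = averaging_sd_curve(epochs)  # (N, channels) SD of the running average
print("SD of running average on Cz (uV):")
for n in (1, 2, 4, 10):
    print(f"  N={n:2d}: {curve[n - 1, 1]:6.2f}"
          + ("   <- single epoch" if n == 1 else ""))
print("averaging suppresses noise ~1/sqrt(N) while the P300 persists\n")

erp = zscore_normalize(average_epochs(epochs))
print(f"z-scored average : per-channel mean {erp.data.mean(axis=1).max():.1e}, "
      f"SD {erp.data.std(axis=1).mean():.3f}")

img = render_plot(erp.data[1])  # Cz
white_rows = np.flatnonzero(img.pixels.any(axis=1))
print(f"binary plot      : {img.height}x{img.width} px, values "
      f"{sorted(np.unique(img.pixels))}")
print(f"blank margins    : {white_rows[0]} rows above, "
      f"{img.height - 1 - white_rows[-1]} below "
      "(asymmetric here: the P300 bump pulls the trace one way; a "
      "symmetric signal gets 25% on each side)")
print(f"rescaled         : {rescale_image(img).pixels.shape} grayscale for the CNN")
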