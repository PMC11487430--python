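# Methods

## The problem

A row/column P300 speller presents a 6×6 character matrix whose six rows
and six columns flash in random order. Attending one cell makes its two
flashes (one row, one column) rare, task-relevant events, which evoke a
P300: a positive event-related potential (ERP) peaking roughly 300 ms
after stimulus onset. Decoding which row and which column evoked a P300
identifies the attended character. `p300wave` implements a decoder that
makes this decision on *images of the signal plot* — the same waveform a
clinician would inspect — classified by small VGG-style convolutional
networks, together with the offline BCI simulation needed to evaluate it
and a synthetic session generator that makes every stage testable without
recordings.

## Signal model and averaging

Each stimulus-locked segment is modelled as `x_i(t) = n_i(t) + s_i(t)`,
`t = 1..L`: zero-mean noise plus a time-locked response present only on
target flashes. Epochs are half-open windows `[onset, onset + L)` with
`L = floor(0.8 s · Fs)` (204 samples at 256 Hz), rescaled to zero mean per
channel. No spectral filtering or artifact rejection is applied anywhere;
epochs of neighbouring flashes overlap freely because the 0.25 s flash
period is shorter than the window.

Averaging N epochs leaves the time-locked response and shrinks the noise
variance to `σ²/N`. Because N itself therefore changes the plotted
waveform's amplitude, the averaged segment is z-scored per channel
(population SD over the L samples) before plotting, so both classes reach
the rasterizer with unit variance and a classifier cannot shortcut on
variance instead of waveform shape. Population rather than sample SD is a
free choice here: the difference is a constant factor absorbed by the
amplitude scale γh.

`variance_reduction_report` and `averaging_sd_curve` expose the built-in
control that the SD of the average is indeed below the single-epoch SD and
falls as more segments enter the average; they warn rather than fail on
noise-free (identical-epoch) input, where no reduction is possible.

## Plot rasterization

A z-scored channel `X(t)` becomes a binary image via

    I(z1, z2) = 255  at  (z1, z2) = (⌊γw·t⌋, ⌊γh·X(t) + Z⌋),   0 elsewhere

with height `Hy = ⌊2·γh·(max X − min X)⌋`, width `Wx = γw·L`, zero line
`Z = Hy/2`, origin top-left, z2 growing downward. Defaults γh = 30,
γw = 2. Consecutive sample points are joined with Bresenham's line
algorithm so the trace is a single 8-connected stroke covering every
sample column. For a signal symmetric about zero the construction leaves
blank margins of 25% of the image height above and below the trace.

Numerical conventions worth stating:

- `Z` is kept exact (`Hy/2`, possibly half-integer) and the floor is taken
  of the complete vertical coordinate `γh·X(t) + Z`. Flooring `Z` first
  biases the trace upward by up to one row when `Hy` is odd and breaks the
  25% margin symmetry.
- Row coordinates are clamped to `[0, Hy−1]`; only values at the floor
  boundary can clamp, heavy-tailed signals stay inside the canvas.
- Positive deflections are drawn toward the image bottom (z2 downward, no
  sign flip). This is a visual, not informational, convention.
- A flat channel (max = min) is a validation error: it has no plottable
  height, and z-scoring upstream already rejects constant channels.
- The hot rendering path draws segments with a vectorized closed-form
  Bresenham (`(2·i·d_minor + d_major) // (2·d_major)` along the major
  axis) that reproduces the incremental error recurrence pixel-for-pixel;
  the equivalence is asserted exhaustively over all octants in the tests.

The binary plot is rescaled to 150×150 with bilinear interpolation
(scikit-image, `order=1`, no anti-aliasing). Interpolation introduces
intermediate gray values and no re-thresholding is applied; images are
stored as grayscale in [0, 255] and divided by 255 at the CNN input. The
multichannel pipeline stacks the eight per-channel 150×150 plots in
montage order (Fz, Cz, Pz, Oz, P3, P4, PO7, PO8) as an 8-deep image.

## Classifiers

Three feed-forward variants, all 3×3 convolutions (stride 1, same
padding), each conv block followed by a 2×2 stride-2 max-pool in ceil
mode, dropout 0.5 between the last pool and the flatten, ReLU activations
and a single sigmoid output unit:

| variant | input | conv depths | spatial trace | flatten | dense head |
|---|---|---|---|---|---|
| `vgg16` | 150×150×1 | 32, 64, 128, 128, 256 | 150→75→38→19→10→5 | 6400 | 1024, 512, 256, 1 |
| `sv16` | 150×150×1 | 32, 64, 128 | 150→75→38→19 | 46208 | 512, 256, 1 |
| `msv16` | 150×150×8 | 32, 64, 128 | 150→75→38→19 | 46208 | 512, 256, 1 |

Training minimizes mean squared error between the sigmoid output and
{0, 1} labels with Adam: learning rate 5×10⁻⁴ and batch 20 for `vgg16`
and `sv16`; 3×10⁻³ and batch 6 for `msv16`; early stopping with patience
7 epochs for `sv16`/`msv16`, monitoring validation loss on a held-out
slice of the training letters, with best-weight restoration.

The oddball design yields a 1:5 class imbalance (2 target codes of 12).
Every training batch is therefore class-balanced: the minority class is
consumed without replacement within an epoch, the majority subsampled to
match, and the remainder discarded for that pass.

The layer stack, loss and optimizer are implemented directly on NumPy
arrays. Convolution runs as nine shifted matrix products (one per kernel
tap) with the input gradient as the transposed convolution of the
spatially flipped kernels; gradients are verified against central finite
differences in the tests. `ArchitectureSpec.preset(variant, width_factor)`
narrows every conv depth and hidden dense width by a common factor while
preserving layer count, input depth and the spatial trace — desk-scale
runs use `width_factor = 0.125`; the full-width presets are what the
shape audit asserts against. The printed trainable-parameter totals of the
original architectures are not reproduced or asserted: they are mutually
inconsistent with the printed layer sizes, and the spatial trace plus
flatten widths are taken as binding instead.

## BCI simulation

The simulation replays the online protocol: the classifier sees only the
first 15 spelled letters (12 for calibration, the last 3 as the validation
slice for early stopping and channel ranking), then decodes the remaining
20 letters in temporal order. For a test letter at intensification level
n, the *first* n epochs of each stimulus code are averaged — a temporal
prefix, never a shuffle — z-scored, rendered and scored; the decoded
character sits at the intersection of the best-scoring row code (1–6) and
column code (7–12), ties breaking toward the lower code. The letter
identification rate is the percentage of the 20 test letters decoded
correctly, so rates are multiples of 5%.

Training images are built from *disjoint* groups of `train_averaging`
epochs per code, default 1: a 10-repetition letter contributes 120
single-trial images, 20 of the hit class and 100 not. This choice, rather
than one fully averaged image per code, matters twice over: it matches
the per-letter class counts of the oddball protocol, and it is what makes
the randomized-label control behave (below). One model, trained at that
depth, is evaluated at every intensification level;
`retrain_per_level=True` instead retrains per level with
`min(n, train_averaging)`-deep training images.

For the single-channel variants, channel selection trains one model per
channel on the calibration slice and ranks channels by letter rate on the
validation slice of the training block — never on test letters; ties
break toward montage order.

### Controls

*Chance level.* Decoding with independent uniform scores hits each of the
36 cells with equal probability; `simulate_chance_level` measures this
(1/36 ≈ 2.8%) over any number of simulated letters.

*Randomized labels.* `randomized_label_control` permutes the labels of
the entire 15-letter training block — including the validation slice, so
early stopping cannot select against true labels — retrains the identical
pipeline, and re-runs it with true labels for comparison. With
single-trial training images (300 positives) the residual association
between the shuffled labels and the "contains a P300 bump" feature is
small enough that the shuffled model decodes at chance; with only 30
fully-averaged positives, the hypergeometric fluctuation of a single
permutation (±2 bumps around the expected 5) is reliably exploited by the
network in a high-SNR synthetic world, driving the control to 0% or 100%
instead of chance. That failure mode motivated the default
`train_averaging = 1`.

### Statistics

The Quade test compares k decoders over b subjects: within-subject
mid-ranks `R_ij`, subject weights `Q_i` = ranks of the within-subject
sample ranges, `S_ij = Q_i (R_ij − (k+1)/2)`, `A = ΣS_ij²`,
`B = Σ_j S_j²/b`, `F = (b−1)B/(A−B)` on `F(k−1, (b−1)(k−1))` with the
asymptotic p-value. The implementation matches R's `stats::quade.test` to
at least 1e-9 on reference tables frozen into the tests. An all-tied
table is reported as a degenerate no-variance result (NaN, p = 1), not an
exception. On the bundled benchmark table of eight published decoders ×
eight subjects the statistic is F(7, 49) = 1.797, p = 0.109.

The information transfer rate uses the Wolpaw definition
`B = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))` bits per selection, with
the P ∈ {0, 1} limits handled analytically, divided by the selection
time. The default timing basis is `n · 12 · 0.25 s` (flashes plus pauses
only); the inter-trial pause is excluded unless passed explicitly, and
any published bits-per-second figure depends on exactly this convention.

## Synthetic sessions

`generate_session` emulates the copy-spelling protocol: per letter, 10
repetition blocks each flashing the 12 codes in seeded random order, one
flash every 0.25 s (0.125 s flash + 0.125 s pause), a 2 s inter-trial
pause (not printed in the protocol description; 2 s is a typical value
and configurable), 1 s lead-in and tail. The continuous 8-channel signal
is zero-mean Gaussian noise (default SD 10 µV, white by default; an AR(1)
coefficient adds temporal coloring when wanted). Every target flash adds
a Gaussian-shaped deflection (peak at 300 ms, σ = 60 ms, peak height
`p300_amplitude` × noise SD, default 3) scaled per channel by a gain
vector that emphasizes Cz/Pz, mimicking centro-parietal P300 topography.
Because the noise is drawn continuously, overlapping epochs share samples
and overlapping target templates superpose exactly as real overlapping
windows would — which also means target templates bleed into neighbouring
non-target windows, a real feature of the protocol that the recovery
tests account for.

What the generator does *not* emulate: ocular/muscle artifacts, background
rhythms, drifts, non-stationarity across the session, latency jitter, and
subject-to-subject variability. Tests passing on these sessions therefore
demonstrate the correctness of the machinery — epoching, averaging,
rendering, training, decoding, and the statistical controls — not
performance on clinical EEG.

## Problem sizes and defaults used in the checks

The end-to-end recovery check runs the full 35-letter session (15
training / 20 test letters) with `msv16` at `width_factor = 0.125`, 15
epoch cap, seed-fixed; at the default 3-SD amplitude it decodes ≥ 90% of
test letters at 10 intensifications with a non-decreasing rate trend,
while the randomized-label control stays within the exact-binomial chance
region (≤ 3/20). The chance-level check uses 10,000 simulated letters;
the variance-law check 1,000 draws at N ∈ {2, 4, 16}. Model widths,
epoch caps and session counts are package defaults chosen for desk-scale
reproducibility; the architecture presets themselves are always audited
at full width.

## Known limitations

- EDF writing pads the last data record to a whole second and quantizes
  to 16 bits; round trips are exact only to the per-channel quantization
  step (~amplitude/3×10⁴).
- The native container of the public benchmark dataset is not read
  directly; recordings must be provided as EDF plus a CSV event sidecar.
- Training the full-width networks on one CPU is possible but slow; the
  narrowed presets are the intended desk-scale configuration.
- The Quade p-value is asymptotic (F distribution), as in common
  statistical practice; no permutation variant is provided.
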