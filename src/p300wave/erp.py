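"""Signal averaging and z-score normalization of event-related potentials.

A single stimulus-locked segment is modelled as ``x_i(t) = n_i(t) + s_i(t)``:
zero-mean noise plus a time-locked response.  Averaging N repetitions leaves
the response while shrinking the noise variance to sigma^2 / N, which is the
whole reason the speller repeats its flashes.  Because the number of averaged
segments itself changes the variance (and hence the apparent size of the
plotted waveform), the averaged segment is z-scored per channel before being
rasterized, so a classifier must rely on waveform *shape* rather than on
amplitude differences induced by N.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .recording import Epoch, ValidationError


@dataclass
class AveragedERP:
    """Per-channel average of N stimulus-locked epochs."""

    data: np.ndarray  # (n_channels, L); microvolts, unitless once z-scored
    n_averaged: int
    zscored: bool = False
    channel_labels: Sequence[str] | None = None
    code: int | None = None
    letter_index: int | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def average_epochs(epochs: Sequence[Epoch]) -> AveragedERP:
    """Element-wise arithmetic mean of epochs, per channel."""
    if not epochs:
        raise ValidationError("cannot average an empty list of epochs")
    shapes = {e.data.shape for e in epochs}
    if len(shapes) != 1:
        raise ValidationError(f"epochs have mismatched shapes: {sorted(shapes)}")
    stack = np.stack([e.data for e in epochs])
    codes = {e.code for e in epochs}
    letters = {e.letter_index for e in epochs}
    return AveragedERP(
        data=stack.mean(axis=0),
        n_averaged=len(epochs),
        zscored=False,
        code=codes.pop() if len(codes) == 1 else None,
        letter_index=letters.pop() if len(letters) == 1 else None,
    )


def zscore_normalize(erp: AveragedERP) -> AveragedERP:
    """Transform each channel to zero mean, unit population SD."""
    mean = erp.data.mean(axis=1, keepdims=True)
    sd = erp.data.std(axis=1, keepdims=True)  # population (1/L) SD
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        labels = (
            [erp.channel_labels[i] for i in flat]
            if erp.channel_labels is not None
            else flat.tolist()
        )
        raise ValidationError(f"constant channel(s) cannot be z-scored: {labels}")
    return replace(erp, data=(erp.data - mean) / sd, zscored=True)


@dataclass
class VarianceReport:
    """Per-channel SDs of an average versus its constituent epochs.

    ``reduced`` flags, per channel, whether averaging actually lowered the
    SD below the mean single-epoch SD — the expected ordering whenever the
    epochs carry independent noise.  Identical (noise-free) epochs do not
    reduce and are flagged false.
    """

    sd_average: np.ndarray  # (n_channels,)
    sd_epochs: np.ndarray  # (n_epochs, n_channels)
    n_averaged: int
    reduced: np.ndarray = field(init=False)  # (n_channels,) bool

    def __post_init__(self) -> None:
        mean_sd = self.sd_epochs.mean(axis=0)
        # strict reduction beyond float noise; identical epochs stay flagged
        self.reduced = (mean_sd - self.sd_average) > 1e-9 * np.maximum(mean_sd, 1e-30)


def variance_reduction_report(
    epochs: Sequence[Epoch], erp: AveragedERP
) -> VarianceReport:
    """Check that averaging reduced per-channel SD, as sigma^2/N predicts.

    ``erp`` must be the pre-z-score average of ``epochs`` (z-scoring forces
    SD to 1 and would make the comparison meaningless).
    """
    if erp.zscored:
        raise ValidationError("variance report requires the pre-z-score average")
    if erp.n_averaged != len(epochs):
        raise ValidationError(
            f"average was built from {erp.n_averaged} epochs, got {len(epochs)}"
        )
    sd_avg = erp.data.std(axis=1)
    sd_eps = np.stack([e.data.std(axis=1) for e in epochs])
    return VarianceReport(sd_average=sd_avg, sd_epochs=sd_eps, n_averaged=len(epochs))


def averaging_sd_curve(epochs: Sequence[Epoch]) -> np.ndarray:
    """SD of the running average over nested prefixes of the epoch list.

    Returns an (n_epochs, n_channels) array whose row N-1 holds the
    per-channel SD of the average of the first N epochs.  On noisy data the
    trend is decreasing, approaching the SD of the time-locked response.
    """
    if not epochs:
        raise ValidationError("cannot build an SD curve from no epochs")
    stack = np.stack([e.data for e in epochs])  # (N, C, L)
    running = np.cumsum(stack, axis=0) / np.arange(1, len(epochs) + 1)[:, None, None]
    return running.std(axis=2)
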