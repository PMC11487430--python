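"""Recordings, stimulus events and stimulus-locked epoch extraction.

The data model mirrors an 8-channel oddball-speller acquisition: a continuous
multichannel signal in microvolts at a fixed sampling rate, plus a stream of
flash events.  Every flash is described by its onset sample, its stimulus
code (1-6 rows, 7-12 columns), whether it intensified the attended character
(known in copy-spelling) and the index of the letter being spelled.

Epochs are half-open windows ``[onset, onset + L)`` cut from the continuous
signal, one per retained event, rescaled to zero mean per channel.  With the
default 800 ms window at 256 Hz each epoch holds L = 204 samples.  Epochs of
neighbouring flashes overlap freely (the 0.25 s flash period is shorter than
the window); no artifact rejection is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .speller import ALL_CODES

logger = logging.getLogger(__name__)

#: Montage of the 8-channel recordings this package models.
DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "Oz", "P3", "P4", "PO7", "PO8")

DEFAULT_SAMPLING_RATE_HZ = 256.0
DEFAULT_WINDOW_MS = 800.0


class ValidationError(ValueError):
    """Raised when recordings, events or epochs violate the data contract."""


@dataclass(frozen=True)
class StimulusEvent:
    """One row/column flash, time-locked to the continuous recording."""

    onset_sample: int
    code: int
    is_target: bool
    letter_index: int

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValidationError(f"event onset must be >= 0, got {self.onset_sample}")
        if self.code not in ALL_CODES:
            raise ValidationError(f"stimulus code must be 1-12, got {self.code}")
        if self.letter_index < 0:
            raise ValidationError("letter_index must be >= 0")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG (microvolts) with its stimulus events."""

    signal: np.ndarray  # (n_channels, n_samples), microvolts
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    events: list[StimulusEvent] = field(default_factory=list)
    spelled_text: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a (channels, samples) array")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling rate must be positive")
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("event onsets must be strictly increasing")
        for i, e in enumerate(self.events):
            if e.onset_sample >= self.n_samples:
                raise ValidationError(
                    f"event {i} (code {e.code}, letter {e.letter_index}) has onset "
                    f"{e.onset_sample} beyond the recording ({self.n_samples} samples)"
                )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_letters(self) -> int:
        return 1 + max((e.letter_index for e in self.events), default=-1)


@dataclass(frozen=True)
class Epoch:
    """A stimulus-locked segment, zero-mean per channel."""

    data: np.ndarray  # (n_channels, L), microvolts, zero-mean per channel
    is_target: bool
    code: int
    letter_index: int
    onset_sample: int

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """All epochs of a recording, in temporal order."""

    epochs: list[Epoch]
    sampling_rate_hz: float
    channel_labels: Sequence[str]
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def letter_indices(self) -> list[int]:
        return sorted({e.letter_index for e in self.epochs})

    def for_letter(self, letter_index: int) -> list[Epoch]:
        return [e for e in self.epochs if e.letter_index == letter_index]

    def class_counts(self, letter_index: int | None = None) -> tuple[int, int]:
        """(target, non-target) epoch counts, optionally for one letter."""
        pool = self.epochs if letter_index is None else self.for_letter(letter_index)
        n_t = sum(e.is_target for e in pool)
        return n_t, len(pool) - n_t


def window_length_samples(
    sampling_rate_hz: float, window_ms: float = DEFAULT_WINDOW_MS
) -> int:
    """Epoch length L = floor(window * Fs); 800 ms at 256 Hz gives 204."""
    return math.floor(window_ms / 1000.0 * sampling_rate_hz)


def extract_epochs(
    rec: EEGRecording, window_ms: float = DEFAULT_WINDOW_MS
) -> EpochSet:
    """Cut one zero-mean epoch per stimulus event.

    Events whose window would run past the end of the recording are dropped
    (their count is logged and recorded on the returned set).
    """
    if not rec.events:
        raise ValidationError("recording has no stimulus events")
    L = window_length_samples(rec.sampling_rate_hz, window_ms)
    if L < 1:
        raise ValidationError("epoch window is shorter than one sample")
    epochs: list[Epoch] = []
    n_dropped = 0
    for ev in rec.events:
        stop = ev.onset_sample + L
        if stop > rec.n_samples:
            n_dropped += 1
            continue
        seg = rec.signal[:, ev.onset_sample : stop]
        seg = seg - seg.mean(axis=1, keepdims=True)
        epochs.append(
            Epoch(
                data=seg,
                is_target=ev.is_target,
                code=ev.code,
                letter_index=ev.letter_index,
                onset_sample=ev.onset_sample,
            )
        )
    if n_dropped:
        logger.info("dropped %d events too close to the end of the recording", n_dropped)
    return EpochSet(
        epochs=epochs,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_labels=tuple(rec.channel_labels),
        n_dropped=n_dropped,
    )


def group_by_code(
    es: EpochSet, letter_index: int, n_intensifications: int
) -> dict[int, list[Epoch]]:
    """First ``n_intensifications`` epochs of each code for one letter.

    Selection is a temporal prefix — the simulation replays the online
    protocol, so only flashes already seen at intensification level n may be
    averaged; no shuffling across time.
    """
    letter = es.for_letter(letter_index)
    if not letter:
        raise ValidationError(f"no epochs for letter {letter_index}")
    grouped: dict[int, list[Epoch]] = {code: [] for code in ALL_CODES}
    for ep in letter:  # EpochSet is in temporal order
        grouped[ep.code].append(ep)
    available = min(len(v) for v in grouped.values())
    if not 1 <= n_intensifications <= available:
        raise ValidationError(
            f"requested {n_intensifications} intensifications but letter "
            f"{letter_index} has {available} complete repetitions"
        )
    return {code: eps[:n_intensifications] for code, eps in grouped.items()}
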