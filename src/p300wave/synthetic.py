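"""Synthetic P300 speller sessions with the statistical structure the
decoder assumes.

A session emulates the oddball copy-spelling protocol: for every letter of a
35-character text, each of the 12 row/column codes flashes once per
repetition block in random order, 10 blocks per letter, with a 0.125 s flash
followed by a 0.125 s pause (one flash every 64 samples at 256 Hz) and an
inter-trial pause between letters.  The continuous 8-channel signal is
zero-mean Gaussian background noise; every *target* flash adds a smooth
positive deflection peaking ~300 ms after onset, scaled per channel by a
gain vector that mimics the centro-parietal topography of the P300.

This is a statistical emulation, not a physiological one: no ocular
artifacts, rhythms or drifts, and the noise is white by default (an AR(1)
coloring flag adds temporal correlation when wanted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .recording import (
    DEFAULT_CHANNELS,
    EEGRecording,
    StimulusEvent,
    ValidationError,
    window_length_samples,
)
from .speller import SpellerMatrix

#: Seven five-letter words: 35 characters, the standard session length.
DEFAULT_TEXT = "WATERBRAINMOUSELIGHTSOUNDPLANECHAIR"

#: Relative P300 gain per channel (Fz, Cz, Pz, Oz, P3, P4, PO7, PO8):
#: strongest over the centro-parietal midline.
DEFAULT_CHANNEL_GAINS = (0.6, 1.0, 1.0, 0.5, 0.8, 0.8, 0.7, 0.7)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults match the emulated protocol."""

    n_letters: int = 35
    n_repetitions: int = 10
    flash_s: float = 0.125
    pause_s: float = 0.125
    inter_trial_s: float = 2.0
    sampling_rate_hz: float = 256.0
    noise_sd: float = 10.0  # microvolts
    p300_amplitude: float = 3.0  # peak height, in units of noise_sd
    p300_latency_ms: float = 300.0
    p300_width_ms: float = 60.0  # Gaussian sigma of the deflection
    window_ms: float = 800.0
    channel_gains: tuple[float, ...] = DEFAULT_CHANNEL_GAINS
    spelled_text: str = DEFAULT_TEXT
    ar_coefficient: float = 0.0  # optional AR(1) noise coloring, 0 = white
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.flash_s, self.pause_s, self.inter_trial_s) < 0 or (
            self.flash_s + self.pause_s
        ) <= 0:
            raise ValidationError("flash/pause durations must be positive")
        if self.sampling_rate_hz <= 0 or self.noise_sd <= 0:
            raise ValidationError("sampling rate and noise SD must be positive")
        if self.p300_amplitude < 0:
            raise ValidationError("p300_amplitude must be >= 0")
        if len(self.channel_gains) != len(DEFAULT_CHANNELS):
            raise ValidationError("channel_gains must have 8 entries")
        if len(self.spelled_text) < self.n_letters:
            raise ValidationError(
                f"spelled_text has {len(self.spelled_text)} characters, "
                f"need {self.n_letters}"
            )
        if not 0 <= self.ar_coefficient < 1:
            raise ValidationError("ar_coefficient must be in [0, 1)")

    @property
    def flash_period_samples(self) -> int:
        return round((self.flash_s + self.pause_s) * self.sampling_rate_hz)

    @property
    def text(self) -> str:
        return self.spelled_text[: self.n_letters]


def schedule_flashes(
    cfg: SyntheticConfig,
    matrix: SpellerMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> list[StimulusEvent]:
    """Flash onsets for a whole session, in temporal order.

    Per letter: ``n_repetitions`` blocks, each a random permutation of the 12
    codes, onsets one flash period apart, then an inter-trial pause before
    the next letter.  Target flags come from the spelled text via the matrix.
    """
    matrix = matrix or SpellerMatrix()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    period = cfg.flash_period_samples
    gap = round(cfg.inter_trial_s * cfg.sampling_rate_hz)
    lead_in = round(1.0 * cfg.sampling_rate_hz)
    events: list[StimulusEvent] = []
    onset = lead_in
    for letter_index, char in enumerate(cfg.text):
        row_code, col_code = matrix.char_to_codes(char)  # raises for bad chars
        for _rep in range(cfg.n_repetitions):
            for code in rng.permutation(np.arange(1, 13)):
                events.append(
                    StimulusEvent(
                        onset_sample=onset,
                        code=int(code),
                        is_target=code in (row_code, col_code),
                        letter_index=letter_index,
                    )
                )
                onset += period
        onset += gap
    return events


def p300_template(cfg: SyntheticConfig) -> np.ndarray:
    """The injected deflection over one epoch window, in microvolts.

    A Gaussian bump of SD ``p300_width_ms`` peaking at ``p300_latency_ms``
    with height ``p300_amplitude * noise_sd``.  All-zero when the amplitude
    is 0 (null-effect sessions).
    """
    fs = cfg.sampling_rate_hz
    L = window_length_samples(fs, cfg.window_ms)
    if not 0 <= cfg.p300_latency_ms <= cfg.window_ms:
        raise ValidationError("p300 latency must lie inside the epoch window")
    if cfg.p300_latency_ms + 3 * cfg.p300_width_ms > cfg.window_ms:
        raise ValidationError(
            "p300 template (latency + 3 sigma) exceeds the epoch window"
        )
    peak = round(cfg.p300_latency_ms / 1000.0 * fs)
    sigma = cfg.p300_width_ms / 1000.0 * fs
    t = np.arange(L, dtype=float)
    return (cfg.p300_amplitude * cfg.noise_sd) * np.exp(
        -0.5 * ((t - peak) / sigma) ** 2
    )


def generate_session(
    cfg: SyntheticConfig, matrix: SpellerMatrix | None = None
) -> EEGRecording:
    """A complete synthetic 8-channel recording with embedded events.

    Noise is drawn continuously for the whole session, so epochs that
    overlap in time share samples exactly as real overlapping windows do,
    and overlapping target templates add up naturally.
    """
    matrix = matrix or SpellerMatrix()
    rng = np.random.default_rng(cfg.seed)
    events = schedule_flashes(cfg, matrix, rng)
    fs = cfg.sampling_rate_hz
    L = window_length_samples(fs, cfg.window_ms)
    n_samples = events[-1].onset_sample + L + round(1.0 * fs)
    n_ch = len(DEFAULT_CHANNELS)
    signal = rng.standard_normal((n_ch, n_samples)) * cfg.noise_sd
    if cfg.ar_coefficient > 0:
        from scipy.signal import lfilter

        rho = cfg.ar_coefficient
        # AR(1) with unit marginal variance, then rescaled to noise_sd
        signal = lfilter([math.sqrt(1 - rho**2)], [1.0, -rho], signal, axis=1)
    template = p300_template(cfg)
    gains = np.asarray(cfg.channel_gains, dtype=float)
    for ev in events:
        if ev.is_target:
            sl = slice(ev.onset_sample, ev.onset_sample + L)
            signal[:, sl] += gains[:, None] * template[None, :]
    return EEGRecording(
        signal=signal,
        sampling_rate_hz=fs,
        channel_labels=DEFAULT_CHANNELS,
        events=events,
        spelled_text=cfg.text,
    )
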