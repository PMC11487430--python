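"""Offline BCI simulation of the P300 speller.

The simulation replays the online protocol on a recorded (or synthetic)
copy-spelling session: the classifier is calibrated on the first 15 spelled
letters (3 five-letter words) and then asked to decode the remaining 20
letters in temporal order, never touching their labels.  For every test
letter and every intensification level n = 1..10 the first n epochs of each
of the 12 stimulus codes are averaged, z-scored, rasterized and scored by
the trained CNN; the decoded character sits at the intersection of the
best-scoring row code and the best-scoring column code.  The letter
identification rate is the percentage of correctly decoded test letters.

Controls include decoding with uniformly random scores (chance level
1/36 ~ 3% on a 6x6 matrix) and retraining with randomized labels, which
must collapse performance to chance if the decoder generalizes rather than
memorizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .cnn import ArchitectureSpec, Model, TrainingConfig, build_model, predict_scores, train_classifier
from .erp import average_epochs, zscore_normalize
from .recording import EEGRecording, EpochSet, ValidationError, extract_epochs, group_by_code
from .rendering import (
    DEFAULT_GAMMA_H,
    DEFAULT_GAMMA_W,
    DEFAULT_IMAGE_SIZE,
    bundle_channels,
    render_channels,
    render_plot,
    rescale_image,
)
from .speller import ALL_CODES, COL_CODES, ROW_CODES, SpellerMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol and model settings for one simulated session."""

    n_train_letters: int = 15
    n_validation_letters: int = 3  # tail of the training block, never test letters
    intensification_levels: tuple[int, ...] = tuple(range(1, 11))
    train_averaging: int = 1  # intensifications averaged per training image
    gamma_w: int = DEFAULT_GAMMA_W
    gamma_h: int = DEFAULT_GAMMA_H
    width_factor: float = 1.0  # CNN width scale for desk-scale runs
    max_epochs: int = 30
    channel: str | None = None  # single-channel pipelines: None = select best
    retrain_per_level: bool = False
    seed: int = 0


@dataclass
class SimulationResult:
    """Decodings and letter identification rates of one simulated session."""

    rates: dict[int, float]  # intensification level -> rate in %
    predictions: dict[int, str]  # intensification level -> decoded text
    true_text: str
    variant: str
    channel: str | None = None
    per_channel_rates: dict[str, float] | None = None
    history: dict[str, list[float]] = field(default_factory=dict)
    seed: int = 0


def decode_letter(scores: Mapping[int, float], matrix: SpellerMatrix) -> str:
    """Character at the intersection of the best row and best column score.

    Ties break toward the lowest stimulus code, deterministically.
    """
    missing = [c for c in ALL_CODES if c not in scores]
    if missing:
        raise ValidationError(f"scores missing for codes {missing}")
    best_row = max(ROW_CODES, key=lambda c: (scores[c], -c))
    best_col = max(COL_CODES, key=lambda c: (scores[c], -c))
    return matrix.cell(best_row, best_col)


def simulate_chance_level(
    n_letters: int = 10000,
    seed: int = 0,
    matrix: SpellerMatrix | None = None,
) -> float:
    """Accuracy of decoding with uniformly random scores (expected 1/36)."""
    matrix = matrix or SpellerMatrix()
    rng = np.random.default_rng(seed)
    correct = 0
    chars = [c for row in matrix.grid for c in row]
    truth_idx = rng.integers(0, 36, size=n_letters)
    scores = rng.random((n_letters, 12))
    for i in range(n_letters):
        mapping = {code: scores[i, code - 1] for code in ALL_CODES}
        if decode_letter(mapping, matrix) == chars[truth_idx[i]]:
            correct += 1
    return correct / n_letters


# --------------------------------------------------------------------------
# image pipelines


class _ImagePipeline:
    """Turns grouped epochs into CNN-ready images for one session."""

    def __init__(
        self,
        epoch_set: EpochSet,
        matrix: SpellerMatrix,
        text: str,
        cfg: SimulationConfig,
        channel_index: int | None,  # None = multichannel bundle
    ) -> None:
        self.es = epoch_set
        self.matrix = matrix
        self.text = text
        self.cfg = cfg
        self.channel_index = channel_index

    def _render(self, epochs) -> np.ndarray:
        # uint8 keeps the materialized image sets small; the CNN rescales
        # to [0, 1] per batch
        erp = zscore_normalize(average_epochs(epochs))
        if self.channel_index is None:
            planes = render_channels(erp, self.cfg.gamma_w, self.cfg.gamma_h)
            pixels = bundle_channels(planes).pixels
        else:
            img = rescale_image(
                render_plot(erp.data[self.channel_index], self.cfg.gamma_w, self.cfg.gamma_h)
            )
            pixels = img.pixels[:, :, None]
        return np.round(pixels).astype(np.uint8)

    def images_for_letter(self, letter: int, n: int) -> np.ndarray:
        """(12, size, size, depth) array in stimulus-code order 1..12.

        Test-time images: the first n epochs of each code are averaged, as
        in the online protocol at intensification level n.
        """
        grouped = group_by_code(self.es, letter, n)
        return np.stack([self._render(grouped[code]) for code in ALL_CODES])

    def labels_for_letter(self, letter: int) -> np.ndarray:
        row, col = self.matrix.char_to_codes(self.text[letter])
        return np.array([1.0 if c in (row, col) else 0.0 for c in ALL_CODES])

    def training_set_for_letter(
        self, letter: int, n_avg: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """All training images a letter yields at averaging depth ``n_avg``.

        The letter's repetitions are split per code into disjoint groups of
        ``n_avg`` epochs, one image per group.  At the default depth 1 a
        10-repetition letter yields 120 single-trial images, 20 of the hit
        class and 100 not.
        """
        letter_epochs = self.es.for_letter(letter)
        by_code: dict[int, list] = {code: [] for code in ALL_CODES}
        for ep in letter_epochs:
            by_code[ep.code].append(ep)
        row, col = self.matrix.char_to_codes(self.text[letter])
        images, labels = [], []
        for code in ALL_CODES:
            eps = by_code[code]
            for k in range(len(eps) // n_avg):
                images.append(self._render(eps[k * n_avg : (k + 1) * n_avg]))
                labels.append(1.0 if code in (row, col) else 0.0)
        return np.stack(images), np.array(labels)

    def dataset(self, letters: Sequence[int], n_avg: int) -> tuple[np.ndarray, np.ndarray]:
        pairs = [self.training_set_for_letter(let, n_avg) for let in letters]
        return np.concatenate([p[0] for p in pairs]), np.concatenate([p[1] for p in pairs])


def _channel_index(labels: Sequence[str], channel: str) -> int:
    try:
        return list(labels).index(channel)
    except ValueError:
        raise ValidationError(f"unknown channel {channel!r}; montage is {list(labels)}")


def _train_model(
    pipeline: _ImagePipeline,
    variant: str,
    cfg: SimulationConfig,
    train_letters: Sequence[int],
    val_letters: Sequence[int],
    label_shuffle_seed: int | None = None,
) -> tuple[Model, dict[str, list[float]]]:
    """Train one model on the calibration letters.

    ``label_shuffle_seed``, when given, permutes the labels of the *entire*
    training block (calibration and validation letters alike) — the
    randomized-label control must not leave true labels anywhere model
    selection could see them.
    """
    spec = ArchitectureSpec.preset(variant, width_factor=cfg.width_factor)
    tc = TrainingConfig.for_variant(variant, max_epochs=cfg.max_epochs, seed=cfg.seed)
    x_train, y_train = pipeline.dataset(train_letters, cfg.train_averaging)
    validation = None
    if val_letters:
        x_val, y_val = pipeline.dataset(val_letters, cfg.train_averaging)
        if label_shuffle_seed is not None:
            y_all = np.concatenate([y_train, y_val])
            perm = np.random.default_rng(label_shuffle_seed).permutation(len(y_all))
            y_all = y_all[perm]
            y_train, y_val = y_all[: len(y_train)], y_all[len(y_train) :]
        validation = (x_val, y_val)
    elif label_shuffle_seed is not None:
        perm = np.random.default_rng(label_shuffle_seed).permutation(len(y_train))
        y_train = y_train[perm]
    model = build_model(spec, seed=cfg.seed)
    history = train_classifier(model, x_train, y_train, tc, validation=validation)
    return model, history


def _evaluate(
    pipeline: _ImagePipeline,
    model: Model,
    test_letters: Sequence[int],
    levels: Sequence[int],
) -> tuple[dict[int, float], dict[int, str]]:
    rates: dict[int, float] = {}
    predictions: dict[int, str] = {}
    for n in levels:
        decoded = []
        for letter in test_letters:
            scores = predict_scores(model, pipeline.images_for_letter(letter, n))
            mapping = {code: float(scores[code - 1]) for code in ALL_CODES}
            decoded.append(decode_letter(mapping, pipeline.matrix))
        predictions[n] = "".join(decoded)
        correct = sum(
            p == pipeline.text[letter] for p, letter in zip(decoded, test_letters)
        )
        rates[n] = 100.0 * correct / len(test_letters)
    return rates, predictions


def _prepare(
    rec: EEGRecording,
    variant: str,
    config: SimulationConfig,
    matrix: SpellerMatrix | None,
) -> tuple[EpochSet, SpellerMatrix]:
    matrix = matrix or SpellerMatrix()
    if not rec.spelled_text:
        raise ValidationError("recording has no spelled text (copy-spelling required)")
    es = extract_epochs(rec)
    n_letters = len(es.letter_indices)
    if n_letters < config.n_train_letters + 1:
        raise ValidationError(
            f"simulation needs more than {config.n_train_letters} spelled letters, "
            f"got {n_letters}"
        )
    return es, matrix


def select_best_channel(
    rec: EEGRecording,
    variant: str,
    config: SimulationConfig = SimulationConfig(),
    matrix: SpellerMatrix | None = None,
) -> tuple[str, dict[str, float]]:
    """Rank channels for a single-channel pipeline on training letters only.

    One model per channel is trained on the calibration slice of the
    training block and scored (letter rate at full averaging) on the
    held-out validation slice of the training block.  Ties break toward
    montage order.
    """
    if variant.lower() == "msv16":
        raise ValidationError("channel selection does not apply to the multichannel variant")
    es, matrix = _prepare(rec, variant, config, matrix)
    n_cal = config.n_train_letters - config.n_validation_letters
    cal = list(range(n_cal))
    val = list(range(n_cal, config.n_train_letters))
    rates: dict[str, float] = {}
    for ci, label in enumerate(rec.channel_labels):
        pipeline = _ImagePipeline(es, matrix, rec.spelled_text, config, ci)
        model, _ = _train_model(pipeline, variant, config, cal, [])
        r, _p = _evaluate(pipeline, model, val, [config.train_averaging])
        rates[label] = r[config.train_averaging]
    best = max(rec.channel_labels, key=lambda lab: rates[lab])  # max keeps first tie
    return best, rates


def run_simulation(
    rec: EEGRecording,
    variant: str = "msv16",
    config: SimulationConfig = SimulationConfig(),
    matrix: SpellerMatrix | None = None,
    _label_shuffle_seed: int | None = None,
) -> SimulationResult:
    """Calibrate on the first letters, decode the rest, report rates per level."""
    es, matrix = _prepare(rec, variant, config, matrix)
    single_channel = variant.lower() != "msv16"
    per_channel_rates = None
    channel = None
    if single_channel:
        if config.channel is None:
            channel, per_channel_rates = select_best_channel(rec, variant, config, matrix)
        else:
            channel = config.channel
        ci = _channel_index(rec.channel_labels, channel)
    else:
        ci = None
    pipeline = _ImagePipeline(es, matrix, rec.spelled_text, config, ci)
    n_cal = config.n_train_letters - config.n_validation_letters
    cal = list(range(n_cal))
    val = list(range(n_cal, config.n_train_letters))
    test = [i for i in es.letter_indices if i >= config.n_train_letters]
    rates: dict[int, float] = {}
    predictions: dict[int, str] = {}
    if config.retrain_per_level:
        history = {}
        for n in config.intensification_levels:
            cfg_n = replace(config, train_averaging=min(n, config.train_averaging))
            pl = _ImagePipeline(es, matrix, rec.spelled_text, cfg_n, ci)
            model, history = _train_model(pl, variant, cfg_n, cal, val, _label_shuffle_seed)
            r, p = _evaluate(pl, model, test, [n])
            rates.update(r)
            predictions.update(p)
    else:
        model, history = _train_model(pipeline, variant, config, cal, val, _label_shuffle_seed)
        rates, predictions = _evaluate(pipeline, model, test, config.intensification_levels)
    return SimulationResult(
        rates=rates,
        predictions=predictions,
        true_text="".join(rec.spelled_text[i] for i in test),
        variant=variant.lower(),
        channel=channel,
        per_channel_rates=per_channel_rates,
        history=history,
        seed=config.seed,
    )


@dataclass
class RandomizedLabelControl:
    """Paired runs with permuted and true training labels."""

    randomized: SimulationResult
    recovered: SimulationResult
    shuffle_seed: int


def randomized_label_control(
    rec: EEGRecording,
    variant: str = "msv16",
    config: SimulationConfig = SimulationConfig(),
    matrix: SpellerMatrix | None = None,
    seed: int = 0,
) -> RandomizedLabelControl:
    """Re-run the identical pipeline with training labels permuted at random.

    The randomized run should collapse to the 1/36 chance level; the paired
    true-label run shows recovery.  The permutation is seeded and covers the
    whole training block — calibration and validation letters — so early
    stopping cannot select against true labels.
    """
    randomized = run_simulation(rec, variant, config, matrix, _label_shuffle_seed=seed)
    recovered = run_simulation(rec, variant, config, matrix)
    return RandomizedLabelControl(randomized=randomized, recovered=recovered, shuffle_seed=seed)
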