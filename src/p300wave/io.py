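"""Reading and writing sessions: EDF signals, CSV event sidecars, JSON matrix.

Signals travel as European Data Format (EDF): a 16-bit format universally
readable by EEG tooling.  Reading goes through MNE; writing uses a minimal
EDF writer (1-second data records, per-channel physical scaling), which is
enough to round-trip the synthetic sessions this package generates.  EDF
quantizes to 16 bits, so a round trip reproduces the signal to within the
per-channel quantization step (~amplitude / 3e4), not bit-exactly.

The event sidecar is a CSV with columns ``onset_sample, code, is_target,
letter_index``; session metadata (speller grid, spelled text, montage) lives
in a small JSON manifest.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import EEGRecording, StimulusEvent, ValidationError
from .speller import ALL_CODES, SpellerMatrix

EVENT_COLUMNS = ("onset_sample", "code", "is_target", "letter_index")


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording) -> None:
    """Write a recording as EDF (16-bit, 1-second data records).

    The last record is zero-padded to a whole second; readers therefore see
    ``ceil(n_samples / Fs) * Fs`` samples.
    """
    fs = rec.sampling_rate_hz
    if fs != int(fs) or fs <= 0:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch = rec.n_channels
    n_records = -(-rec.n_samples // fs)  # ceil
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : rec.n_samples] = rec.signal
    # per-channel symmetric physical range, headroom so extremes stay in range
    pmax = np.maximum(np.abs(padded).max(axis=1) * 1.01, 1e-6)
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    dmin, dmax = -32768, 32767
    scale = (2 * pmax) / (dmax - dmin)
    digital = np.round(padded / scale[:, None]).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate 01-JAN-2000 X X X", 80),
            _ascii(now.strftime("%d.%m.%y"), 8),
            _ascii(now.strftime("%H.%M.%S"), 8),
            _ascii(256 * (n_ch + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii("1", 8),
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        b"".join(_ascii(lab, 16) for lab in rec.channel_labels),
        b"".join(_ascii("", 80) for _ in range(n_ch)),
        b"".join(_ascii("uV", 8) for _ in range(n_ch)),
        b"".join(_ascii(f"{-v:.6g}"[:8], 8) for v in pmax),
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_ascii(dmin, 8) for _ in range(n_ch)),
        b"".join(_ascii(dmax, 8) for _ in range(n_ch)),
        b"".join(_ascii("", 80) for _ in range(n_ch)),
        b"".join(_ascii(fs, 8) for _ in range(n_ch)),
        b"".join(_ascii("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def write_events_csv(path: str | Path, events: list[StimulusEvent]) -> None:
    pd.DataFrame(
        {
            "onset_sample": [e.onset_sample for e in events],
            "code": [e.code for e in events],
            "is_target": [int(e.is_target) for e in events],
            "letter_index": [e.letter_index for e in events],
        }
    ).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[StimulusEvent]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"event file {path} lacks columns {sorted(missing)}")
    events = []
    for i, row in enumerate(df.itertuples(index=False)):
        code = int(row.code)
        if code not in ALL_CODES:
            raise ValidationError(
                f"event {i} in {path} has out-of-range code {code} (must be 1-12)"
            )
        events.append(
            StimulusEvent(
                onset_sample=int(row.onset_sample),
                code=code,
                is_target=bool(row.is_target),
                letter_index=int(row.letter_index),
            )
        )
    return events


def load_recording(
    path: str | Path,
    events_path: str | Path,
    manifest_path: str | Path | None = None,
) -> EEGRecording:
    """Load an EDF recording plus its CSV event sidecar.

    ``manifest_path`` optionally supplies the spelled text (and speller
    grid) from a session manifest JSON.  Channel order is preserved as
    stored.  Events beyond the recording raise a validation error naming
    the event.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data(units="uV")
    events = read_events_csv(events_path)
    spelled_text = ""
    if manifest_path is not None:
        manifest = json.loads(Path(manifest_path).read_text())
        spelled_text = manifest.get("spelled_text", "")
    return EEGRecording(
        signal=signal,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
        spelled_text=spelled_text,
    )


def save_session(
    directory: str | Path,
    rec: EEGRecording,
    matrix: SpellerMatrix | None = None,
) -> dict[str, Path]:
    """Write signal.edf + events.csv + session.json into a directory."""
    matrix = matrix or SpellerMatrix()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": directory / "signal.edf",
        "events": directory / "events.csv",
        "manifest": directory / "session.json",
    }
    write_edf(paths["edf"], rec)
    write_events_csv(paths["events"], rec.events)
    paths["manifest"].write_text(
        json.dumps(
            {
                "spelled_text": rec.spelled_text,
                "grid": list(matrix.grid),
                "channel_labels": list(rec.channel_labels),
                "sampling_rate_hz": rec.sampling_rate_hz,
            },
            indent=1,
        )
    )
    return paths


def load_session(directory: str | Path) -> EEGRecording:
    """Load a session previously written by :func:`save_session`."""
    directory = Path(directory)
    return load_recording(
        directory / "signal.edf",
        directory / "events.csv",
        directory / "session.json",
    )
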