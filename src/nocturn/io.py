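"""Reading and writing recordings and hypnograms.

Signals travel as 16-bit EDF (one file per animal per day, channels
EEG1/EEG2/EMG) with a JSON sidecar carrying what the EDF header cannot:
zeitgeber start time, LD schedule, and day label.  A plain-CSV signal
dialect (one column per channel) is provided for small fixtures.
Hypnograms are CSV with columns ``epoch_index, zt_seconds, state[,
artifact]``.

EDF files are written by a minimal writer in :mod:`nocturn.edf` and
read back through :func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np

from .core import (Hypnogram, SignalRecording, State, STATE_LABELS,
                   parse_state_label)
from .edf import write_edf
from .errors import FormatError, TimingError

__all__ = [
    "write_recording",
    "read_recording",
    "write_hypnogram",
    "read_hypnogram",
]

_SIDECAR_FIELDS = ("start_zt_s", "lights_on_period_h", "lights_off_period_h",
                   "day_label", "epoch_length_s")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_sidecar(recording: SignalRecording, path: Path) -> None:
    meta = {k: getattr(recording, k) for k in _SIDECAR_FIELDS}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        warnings.warn(f"no sidecar {sc.name}; assuming recording starts at "
                      "ZT0 with a 12:12 LD schedule")
        return {}
    return json.loads(sc.read_text())


def write_recording(recording: SignalRecording, path, format: str = "edf"
                    ) -> Path:
    """Write a recording plus its JSON timing sidecar; returns the path."""
    path = Path(path)
    if format == "edf":
        write_edf(path, recording.channels, recording.sampling_rate_hz,
                  record_duration_s=recording.epoch_length_s)
    elif format == "csv":
        names = list(recording.channels)
        data = np.column_stack([recording.channels[n] for n in names])
        header = ",".join(names)
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.6f")
    else:
        raise FormatError(f"unknown recording format {format!r}")
    _write_sidecar(recording, path)
    return path


def _read_edf_channels(path: Path) -> tuple[dict[str, np.ndarray], float]:
    import mne

    with warnings.catch_warnings():
        # Physical-dimension quirks in third-party files are tolerable.
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    channels = {}
    for name in raw.ch_names:
        data = raw.get_data(picks=[name])[0]
        # mne rescales channels whose physical dimension it recognizes
        # (uV -> V); restore microvolt-scale numbers.
        if np.nanmax(np.abs(data), initial=0.0) < 1.0:
            data = data * 1e6
        channels[name] = data
    return channels, fs


def read_recording(path, format: str | None = None,
                   required_channels: tuple[str, ...] = ("EMG",)
                   ) -> SignalRecording:
    """Read an EDF or CSV recording written by :func:`write_recording`.

    The sampling rate comes from the file header (EDF) or sidecar (CSV);
    ZT start and LD schedule come from the sidecar when present.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    meta = _read_sidecar(path)
    if format == "edf":
        channels, fs = _read_edf_channels(path)
    elif format == "csv":
        with open(path) as fh:
            reader = csv.reader(fh)
            try:
                names = next(reader)
            except StopIteration:
                raise FormatError(f"{path} is empty") from None
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        channels = {n: data[:, i] for i, n in enumerate(names)}
        fs = meta.get("sampling_rate_hz", 64.0)
    else:
        raise FormatError(f"unknown recording format {format!r}")

    for name in required_channels:
        if name not in channels:
            raise FormatError(
                f"required channel {name!r} missing from {path.name} "
                f"(found {sorted(channels)})")

    rec = SignalRecording(
        channels=channels,
        sampling_rate_hz=fs,
        start_zt_s=float(meta.get("start_zt_s", 0.0)),
        lights_on_period_h=float(meta.get("lights_on_period_h", 12.0)),
        lights_off_period_h=float(meta.get("lights_off_period_h", 12.0)),
        day_label=meta.get("day_label", "baseline"),
        epoch_length_s=float(meta.get("epoch_length_s", 4.0)),
    )
    return rec


def write_hypnogram(hypnogram: Hypnogram, path) -> Path:
    """Write ``epoch_index, zt_seconds, state, artifact`` CSV."""
    path = Path(path)
    zt = hypnogram.zt_s()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "zt_seconds", "state", "artifact"])
        for i, (z, s, a) in enumerate(zip(zt, hypnogram.states,
                                          hypnogram.artifact)):
            w.writerow([i, f"{z:.1f}", STATE_LABELS[State(int(s))], int(a)])
    return path


def read_hypnogram(path, epoch_length_s: float = 4.0) -> Hypnogram:
    """Read a hypnogram CSV; rejects unknown state tokens and empty files.

    Accepts 3-column files (no artifact column); a bare ``ARTIFACT``
    state token sets the flag with WAKE as best-guess state.
    """
    path = Path(path)
    states: list[int] = []
    artifact: list[bool] = []
    first_zt: float | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path} contains no hypnogram rows")
    header = rows[0]
    if header[0].strip().lower() == "epoch_index":
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path} contains a header but no epochs")
    for row in rows:
        if len(row) < 3:
            raise FormatError(f"{path}: expected >= 3 columns, got {row}")
        state = parse_state_label(row[2])
        flagged = bool(int(row[3])) if len(row) > 3 else False
        if state == State.ARTIFACT:
            state, flagged = State.WAKE, True
        if first_zt is None:
            first_zt = float(row[1])
        states.append(int(state))
        artifact.append(flagged)
    return Hypnogram(states=np.array(states, dtype=np.int8),
                     epoch_length_s=epoch_length_s,
                     start_zt_s=first_zt or 0.0,
                     artifact=np.array(artifact, dtype=bool))
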