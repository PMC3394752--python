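"""Minimal 16-bit EDF writer.

Writes standard European Data Format files (ASCII header, little-endian
int16 samples) sufficient for single-session polysomnography exports:
equal sampling rate across channels, fixed record duration, physical
dimension µV.  Reading is delegated to :func:`mne.io.read_raw_edf`,
which doubles as an independent check that these files are well-formed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, TimingError

__all__ = ["write_edf"]

_DIGITAL_MAX = 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # Numeric fields must not silently lose precision beyond rounding.
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, channels: dict[str, np.ndarray], sampling_rate_hz: float,
              record_duration_s: float = 4.0,
              physical_dims: dict[str, str] | None = None) -> Path:
    """Write ``channels`` (equal-length float arrays) as an EDF file.

    Samples are quantized to int16 over a symmetric per-channel physical
    range, so round-tripped values agree within one quantization step.
    """
    path = Path(path)
    names = list(channels)
    data = [np.asarray(channels[n], dtype=np.float64) for n in names]
    n_samples = data[0].size
    if any(d.size != n_samples for d in data):
        raise FormatError("EDF channels must have equal length")
    spr = sampling_rate_hz * record_duration_s
    if abs(spr - round(spr)) > 1e-9:
        raise TimingError("samples per record must be an integer")
    spr = int(round(spr))
    if n_samples % spr:
        raise TimingError(
            f"signal length {n_samples} is not a multiple of the "
            f"{spr}-sample record")
    n_records = n_samples // spr
    ns = len(names)
    dims = physical_dims or {}

    phys_max = []
    digital = []
    for d in data:
        pmax = float(np.max(np.abs(d), initial=0.0))
        pmax = pmax * 1.000001 + 1e-9  # keep extremes inside the range
        # EDF numeric fields are 8 ASCII chars; keep a friendly precision.
        pmax = float(f"{pmax:.6g}")
        scale = _DIGITAL_MAX / pmax
        digital.append(np.clip(np.rint(d * scale), -_DIGITAL_MAX,
                               _DIGITAL_MAX).astype("<i2"))
        phys_max.append(pmax)

    header = b"".join([
        _field(0, 8),                      # version
        _field("X X X X", 80),             # patient id (anonymous)
        _field("Startdate X X X X", 80),   # recording id
        _field("01.01.00", 8),             # start date (synthetic data)
        _field("07.00.00", 8),             # start time = lights-on
        _field(256 * (ns + 1), 8),         # header length
        _field("", 44),
        _field(n_records, 8),
        _field(f"{record_duration_s:g}", 8),
        _field(ns, 4),
    ])
    per_signal = [
        b"".join(_field(n, 16) for n in names),
        b"".join(_field("", 80) for _ in names),                 # transducer
        b"".join(_field(dims.get(n, "uV"), 8) for n in names),
        b"".join(_field(f"{-m:.6g}", 8) for m in phys_max),      # phys min
        b"".join(_field(f"{m:.6g}", 8) for m in phys_max),       # phys max
        b"".join(_field(-_DIGITAL_MAX, 8) for _ in names),
        b"".join(_field(_DIGITAL_MAX, 8) for _ in names),
        b"".join(_field("", 80) for _ in names),                 # prefilter
        b"".join(_field(spr, 8) for _ in names),
        b"".join(_field("", 32) for _ in names),
    ]
    # Data records: per record, each signal's block of int16 samples.
    blocks = np.empty((n_records, ns, spr), dtype="<i2")
    for j, d in enumerate(digital):
        blocks[:, j, :] = d.reshape(n_records, spr)

    with open(path, "wb") as fh:
        fh.write(header)
        for chunk in per_signal:
            fh.write(chunk)
        fh.write(blocks.tobytes())
    return path
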