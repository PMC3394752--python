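"""Core domain objects: vigilance states, hypnograms, signal recordings,
and zeitgeber-time arithmetic.

Conventions used throughout the package:

* The scoring epoch is 4 s by default; epoch ``i`` covers the half-open
  span ``[i * epoch_length_s, (i + 1) * epoch_length_s)`` relative to the
  recording start.
* Zeitgeber time (ZT) is measured in seconds since lights-on; ZT0 is
  lights-on and, with the default 12:12 schedule, the light phase is
  ``zt mod 86400 < 43200``.
* An epoch carries a best-guess vigilance state *and* an independent
  artifact flag.  Artifact-flagged epochs are excluded from spectral
  averages but, by default, contribute their best-guess state to
  hypnogram architecture metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterator

import numpy as np

from .errors import FormatError, TimingError

__all__ = [
    "State",
    "STATE_LABELS",
    "Hypnogram",
    "SignalRecording",
    "epoch_zt_s",
    "is_light",
    "epoch_view",
    "SECONDS_PER_DAY",
    "LIGHT_SECONDS_DEFAULT",
]

SECONDS_PER_DAY = 86_400
LIGHT_SECONDS_DEFAULT = 43_200


class State(IntEnum):
    """Vigilance state of a scoring epoch."""

    WAKE = 0
    NREM = 1
    REM = 2
    ARTIFACT = 3


STATE_LABELS = {State.WAKE: "WAKE", State.NREM: "NREM", State.REM: "REM",
                State.ARTIFACT: "ARTIFACT"}
_LABEL_TO_STATE = {v: k for k, v in STATE_LABELS.items()}

#: The three scorable states (ARTIFACT is a flag, not a dwell state).
SCORABLE = (State.WAKE, State.NREM, State.REM)


def is_light(zt_s, light_period_h: float = 12.0, dark_period_h: float = 12.0):
    """True where the zeitgeber time (seconds) falls in the light phase.

    The LD cycle repeats every ``light + dark`` hours with lights on at
    ZT0.  Vectorized over ``zt_s``.
    """
    cycle = (light_period_h + dark_period_h) * 3600.0
    return np.asarray(zt_s) % cycle < light_period_h * 3600.0


def epoch_zt_s(epoch_index, start_zt_s: float, epoch_length_s: float = 4.0):
    """Zeitgeber time (s) of the start of each epoch."""
    return start_zt_s + np.asarray(epoch_index) * float(epoch_length_s)


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state sequence aligned to a recording.

    Parameters
    ----------
    states
        Integer codes from :class:`State`; the *best-guess* state of each
        epoch (never ``ARTIFACT`` — artifacts live in ``artifact``).
    epoch_length_s
        Scoring epoch length, seconds.
    start_zt_s
        Zeitgeber time of epoch 0.
    artifact
        Boolean mask of artifact-contaminated epochs.  Defaults to all
        clean.
    """

    states: np.ndarray
    epoch_length_s: float = 4.0
    start_zt_s: float = 0.0
    artifact: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise FormatError("hypnogram states must be one-dimensional")
        bad = ~np.isin(self.states, [int(s) for s in SCORABLE])
        if bad.any():
            raise FormatError(
                f"hypnogram contains invalid state codes: "
                f"{sorted(set(self.states[bad].tolist()))}"
            )
        if self.artifact is None:
            self.artifact = np.zeros(self.states.size, dtype=bool)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
            if self.artifact.shape != self.states.shape:
                raise FormatError("artifact mask length mismatch")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_length_s

    def zt_s(self) -> np.ndarray:
        """ZT (s) of the start of every epoch."""
        return epoch_zt_s(np.arange(self.n_epochs), self.start_zt_s,
                          self.epoch_length_s)

    def light_mask(self, light_period_h: float = 12.0,
                   dark_period_h: float = 12.0) -> np.ndarray:
        return is_light(self.zt_s(), light_period_h, dark_period_h)

    def labels(self) -> list[str]:
        """String labels with ``ARTIFACT`` substituted on flagged epochs."""
        out = [STATE_LABELS[State(s)] for s in self.states]
        for i in np.flatnonzero(self.artifact):
            out[i] = "ARTIFACT"
        return out

    def slice(self, start_epoch: int, stop_epoch: int) -> "Hypnogram":
        """Sub-hypnogram covering ``[start_epoch, stop_epoch)``."""
        return Hypnogram(
            states=self.states[start_epoch:stop_epoch].copy(),
            epoch_length_s=self.epoch_length_s,
            start_zt_s=self.start_zt_s + start_epoch * self.epoch_length_s,
            artifact=self.artifact[start_epoch:stop_epoch].copy(),
        )

    def copy(self) -> "Hypnogram":
        return Hypnogram(self.states.copy(), self.epoch_length_s,
                         self.start_zt_s, self.artifact.copy())


def parse_state_label(token: str) -> State:
    """Map a CSV state token to a :class:`State`; raise on unknown labels."""
    try:
        return _LABEL_TO_STATE[token.strip().upper()]
    except KeyError:
        raise FormatError(f"unknown vigilance-state label: {token!r}") from None


@dataclass
class SignalRecording:
    """Multichannel EEG/EMG trace with timing and LD-schedule metadata.

    ``channels`` maps channel name to a 1-D float array; EEG channels are
    in microvolts, the EMG channel in arbitrary units.  All channels must
    have equal length, divisible by the samples-per-epoch implied by the
    4-s scoring grid.
    """

    channels: dict[str, np.ndarray]
    sampling_rate_hz: float = 64.0
    start_zt_s: float = 0.0
    lights_on_period_h: float = 12.0
    lights_off_period_h: float = 12.0
    day_label: str = "baseline"
    epoch_length_s: float = 4.0

    # Spectral analysis runs up to 29 Hz; Nyquist must clear it.
    MIN_SAMPLING_RATE_HZ = 58.0

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=np.float64)
                         for k, v in self.channels.items()}
        if not self.channels:
            raise FormatError("recording has no channels")
        lengths = {k: v.size for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise TimingError(f"channel lengths differ: {lengths}")
        if self.sampling_rate_hz < self.MIN_SAMPLING_RATE_HZ:
            raise TimingError(
                f"sampling rate {self.sampling_rate_hz} Hz is below the "
                f"{self.MIN_SAMPLING_RATE_HZ} Hz minimum for 0.5-29 Hz analysis"
            )
        spe = self.sampling_rate_hz * self.epoch_length_s
        if abs(spe - round(spe)) > 1e-9:
            raise TimingError(
                f"sampling_rate_hz x epoch_length_s = {spe} is not an integer"
            )
        residue = self.n_samples % self.samples_per_epoch
        if residue:
            raise TimingError(
                f"recording length {self.n_samples} is not a multiple of "
                f"{self.samples_per_epoch} samples/epoch "
                f"(residue {residue} samples)"
            )

    @property
    def n_samples(self) -> int:
        return int(next(iter(self.channels.values())).size)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sampling_rate_hz * self.epoch_length_s))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // self.samples_per_epoch

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(
                f"channel {name!r} not in recording "
                f"(have {sorted(self.channels)})"
            ) from None

    def epochs_of(self, name: str) -> np.ndarray:
        """Channel reshaped to ``(n_epochs, samples_per_epoch)`` (a view)."""
        return self.channel(name).reshape(self.n_epochs, self.samples_per_epoch)

    def slice_epochs(self, start_epoch: int, stop_epoch: int,
                     day_label: str | None = None) -> "SignalRecording":
        spe = self.samples_per_epoch
        return replace(
            self,
            channels={k: v[start_epoch * spe:stop_epoch * spe].copy()
                      for k, v in self.channels.items()},
            start_zt_s=self.start_zt_s + start_epoch * self.epoch_length_s,
            day_label=day_label if day_label is not None else self.day_label,
        )


def epoch_view(recording: SignalRecording
               ) -> Iterator[tuple[int, dict[str, np.ndarray]]]:
    """Iterate non-overlapping 4-s blocks as ``(epoch_index, {ch: block})``.

    The blocks partition every channel: concatenating them restores the
    original sample sequence.
    """
    per_channel = {k: recording.epochs_of(k) for k in recording.channels}
    for i in range(recording.n_epochs):
        yield i, {k: v[i] for k, v in per_channel.items()}
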