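"""Per-epoch EEG power spectra and the normalization conventions of
rodent sleep analysis.

Each 4-s epoch (256 samples at 64 Hz) is Fourier-transformed to a power
density on an exact 0.25-Hz grid.  Two normalizations are provided:

* **NREM delta time course** — delta-band (0.5–5 Hz by default) power of
  NREM epochs, expressed as a percentage of a per-animal scalar: the
  total 0.5–29 Hz power averaged over *all* NREM epochs of the 24-h
  reference day.  This is the standard way slow-wave activity is made
  comparable across animals.
* **State spectral profiles / band tables** — per-bin (or per-band)
  power of a state's epochs as a percentage of the mean total power of
  all epochs over 24 h (0.25 Hz up to the last full bin below Nyquist).

Both are ratios, hence invariant to global amplitude scaling of the EEG.
Artifact-flagged epochs carry no weight in any average; empty bins are
reported as missing (NaN), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .core import Hypnogram, SignalRecording, State
from .errors import AlignmentError, FormatError

__all__ = [
    "BandDefinition",
    "BANDS",
    "DELTA_FIG1",
    "EpochSpectra",
    "compute_epoch_spectra",
    "flag_artifacts",
    "nrem_total_power_normalizer",
    "nrem_delta_timecourse",
    "state_spectral_profile",
    "band_power_by_state",
    "theta_peak_frequency",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not 0 < self.lo_hz < self.hi_hz:
            raise FormatError(f"invalid band {self.name}: "
                              f"[{self.lo_hz}, {self.hi_hz}]")


#: Default frequency bands.  Note delta–theta leaves a 5–6 Hz gap by design.
BANDS = {
    "delta": BandDefinition("delta", 0.5, 5.0),
    "theta": BandDefinition("theta", 6.0, 9.0),
    "sigma": BandDefinition("sigma", 10.0, 15.0),
    "beta": BandDefinition("beta", 16.0, 23.0),
}

#: Narrower delta variant (0.5–4 Hz) used by some time-course figures.
DELTA_FIG1 = BandDefinition("delta", 0.5, 4.0)

#: Total-power integration range for the NREM normalizer.
ANALYSIS_BAND = (0.5, 29.0)


@dataclass
class EpochSpectra:
    """Per-epoch one-sided power on a uniform frequency grid.

    ``power[i, k]`` is the power (µV²) of epoch ``i`` in the bin centered
    at ``freqs[k]``; a bin-centered tone of amplitude ``A`` contributes
    ``A²/2`` to its bin.  ``artifact_mask`` marks epochs excluded from
    every average.
    """

    power: np.ndarray
    freqs: np.ndarray
    artifact_mask: np.ndarray
    bin_width_hz: float = 0.25
    #: True when the last grid bin is the Nyquist bin (real-FFT grids);
    #: total power then stops at the last full bin below Nyquist.
    includes_nyquist: bool = False

    def __post_init__(self):
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]

    def band_mask(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """Bins whose center lies in the closed interval [lo, hi]."""
        return (self.freqs >= lo_hz - 1e-9) & (self.freqs <= hi_hz + 1e-9)

    def band_power(self, lo_hz: float, hi_hz: float) -> np.ndarray:
        """Per-epoch power summed over a band (inclusive bin centers)."""
        return self.power[:, self.band_mask(lo_hz, hi_hz)].sum(axis=1)

    def total_power(self) -> np.ndarray:
        """Per-epoch power over the full analysis grid, excluding the
        Nyquist bin (0.25 Hz up to the last full bin below Nyquist)."""
        if self.includes_nyquist:
            return self.power[:, :-1].sum(axis=1)
        return self.power.sum(axis=1)


def compute_epoch_spectra(recording: SignalRecording, channel: str = "EEG2",
                          taper: str = "hann") -> EpochSpectra:
    """FFT power per 4-s epoch on the 0.25-Hz grid.

    The default taper is a Hann window renormalized to unit mean-square,
    so broadband power is preserved; ``taper="rectangular"`` gives the
    bare periodogram (exact for bin-centered tones).  The DC bin is
    dropped; the grid runs 0.25 Hz … Nyquist.
    """
    x = recording.epochs_of(channel).astype(np.float64)
    n = x.shape[1]
    if taper == "hann":
        w = sps.windows.hann(n, sym=False)
        w = w / np.sqrt(np.mean(w ** 2))
    elif taper == "rectangular":
        w = np.ones(n)
    else:
        raise FormatError(f"unknown taper {taper!r}")
    X = np.fft.rfft(x * w[None, :], axis=1)
    power = 2.0 * np.abs(X) ** 2 / n ** 2
    power[:, 0] /= 2.0   # DC (dropped below)
    power[:, -1] /= 2.0  # Nyquist is not mirrored
    power = power[:, 1:]
    freqs = np.fft.rfftfreq(n, d=1.0 / recording.sampling_rate_hz)[1:]
    return EpochSpectra(power=power, freqs=freqs,
                        artifact_mask=np.zeros(x.shape[0], dtype=bool),
                        bin_width_hz=float(freqs[0]),
                        includes_nyquist=True)


def flag_artifacts(spectra: EpochSpectra, k: float = 8.0,
                   window_epochs: int = 450,
                   hypnogram: Hypnogram | None = None) -> np.ndarray:
    """Artifact mask: epochs whose total 0.5–29 Hz power exceeds ``k``
    times a centered rolling median (±``window_epochs``), plus any epochs
    already flagged in the hypnogram.

    Returns the mask and stores it on ``spectra.artifact_mask``.
    """
    total = spectra.band_power(*ANALYSIS_BAND)
    size = 2 * window_epochs + 1
    if np.isfinite(k):
        med = ndimage.median_filter(total, size=min(size, total.size),
                                    mode="nearest")
        mask = total > k * med
    else:
        mask = np.zeros(total.size, dtype=bool)
    if hypnogram is not None:
        if len(hypnogram) != spectra.n_epochs:
            raise AlignmentError("hypnogram/spectra length mismatch")
        mask = mask | hypnogram.artifact
    spectra.artifact_mask = mask
    return mask


def _check_aligned(spectra: EpochSpectra, hypnogram: Hypnogram) -> None:
    if len(hypnogram) != spectra.n_epochs:
        raise AlignmentError(
            f"hypnogram has {len(hypnogram)} epochs, spectra "
            f"{spectra.n_epochs}")


def _unmasked(spectra: EpochSpectra, hypnogram: Hypnogram,
              state: State | None = None) -> np.ndarray:
    keep = ~spectra.artifact_mask & ~hypnogram.artifact
    if state is not None:
        keep &= hypnogram.states == int(state)
    return keep


def nrem_total_power_normalizer(spectra: EpochSpectra, hypnogram: Hypnogram
                                ) -> float:
    """Per-animal scalar: mean total 0.5–29 Hz power over all unmasked
    NREM epochs of the (reference) day."""
    _check_aligned(spectra, hypnogram)
    keep = _unmasked(spectra, hypnogram, State.NREM)
    if not keep.any():
        raise AlignmentError("no unmasked NREM epochs in the reference day")
    return float(spectra.band_power(*ANALYSIS_BAND)[keep].mean())


def nrem_delta_timecourse(spectra: EpochSpectra, hypnogram: Hypnogram,
                          bin_h: float = 2.0,
                          band: BandDefinition = BANDS["delta"],
                          normalizer: float | None = None) -> pd.Series:
    """Normalized NREM delta-power time course (%).

    Per time bin: mean delta-band power over the bin's unmasked NREM
    epochs, divided by the 24-h NREM total-power normalizer, ×100.
    ``normalizer=None`` computes it from this day (which must then cover
    the reference day); pass the baseline day's value when analyzing a
    recovery day.  Bins without NREM epochs are NaN.
    """
    _check_aligned(spectra, hypnogram)
    if normalizer is None:
        normalizer = nrem_total_power_normalizer(spectra, hypnogram)
    keep = _unmasked(spectra, hypnogram, State.NREM)
    delta = spectra.band_power(band.lo_hz, band.hi_hz)
    zt_h = hypnogram.zt_s() / 3600.0
    bins = np.floor((zt_h - zt_h[0]) / bin_h).astype(int)
    n_bins = int(bins.max()) + 1
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = keep & (bins == b)
        if m.any():
            out[b] = delta[m].mean() / normalizer * 100.0
    index = zt_h[0] + np.arange(n_bins) * bin_h
    return pd.Series(out, index=index, name=f"nrem_{band.name}_pct")


def _grand_mean_total(spectra: EpochSpectra, hypnogram: Hypnogram) -> float:
    keep = _unmasked(spectra, hypnogram)
    if not keep.any():
        raise AlignmentError("all epochs are artifact-masked")
    return float(spectra.total_power()[keep].mean())


def state_spectral_profile(spectra: EpochSpectra, hypnogram: Hypnogram,
                           state: State) -> pd.Series:
    """Per-bin spectral profile of a state (%).

    Bin power averaged over the state's unmasked epochs, divided by the
    mean total power of *all* unmasked epochs over the day (0.25 Hz to
    the last full bin below Nyquist), ×100.  Consequently
    ``profile.sum() == 100 · state-mean-total / grand-mean-total``, and
    exactly 100% for a single-state recording.
    """
    _check_aligned(spectra, hypnogram)
    keep = _unmasked(spectra, hypnogram, state)
    if not keep.any():
        raise AlignmentError(f"no unmasked {State(state).name} epochs")
    grand = _grand_mean_total(spectra, hypnogram)
    prof = spectra.power[keep].mean(axis=0) / grand * 100.0
    return pd.Series(prof, index=spectra.freqs, name=State(state).name)


def band_power_by_state(spectra: EpochSpectra, hypnogram: Hypnogram,
                        bands: dict[str, BandDefinition] = BANDS,
                        interval: str | None = None,
                        light_period_h: float = 12.0) -> pd.DataFrame:
    """State × band table of normalized power (%) in an LD interval.

    Numerator: mean band power over the state's unmasked epochs in the
    interval (``"light"``, ``"dark"``, or ``None`` for 24 h); denominator:
    mean total power over all unmasked epochs of the full day.  Empty
    state×interval cells are NaN.
    """
    _check_aligned(spectra, hypnogram)
    grand = _grand_mean_total(spectra, hypnogram)
    in_interval = np.ones(len(hypnogram), dtype=bool)
    if interval is not None:
        light = hypnogram.light_mask(light_period_h)
        in_interval = light if interval == "light" else ~light
    rows = {}
    for state in (State.WAKE, State.NREM, State.REM):
        keep = _unmasked(spectra, hypnogram, state) & in_interval
        rows[state.name] = {
            name: (spectra.band_power(b.lo_hz, b.hi_hz)[keep].mean()
                   / grand * 100.0) if keep.any() else np.nan
            for name, b in bands.items()
        }
    return pd.DataFrame(rows).T


def theta_peak_frequency(profile: pd.Series, lo_hz: float = 6.0,
                         hi_hz: float = 9.0) -> float:
    """Frequency (Hz) of the maximum profile bin within [lo, hi];
    ties resolve to the lower frequency."""
    window = profile.loc[(profile.index >= lo_hz - 1e-9)
                         & (profile.index <= hi_hz + 1e-9)]
    if window.empty:
        raise FormatError("profile does not cover the theta range")
    return float(window.index[np.argmax(window.to_numpy())])
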