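"""Semi-automatic vigilance-state scoring from EMG tone and EEG spectra.

Each 4-s epoch is described by five features — EMG RMS, delta / theta /
total EEG band power, and the derived delta:theta and theta:total
ratios — and classified by an explicit decision rule:

1. **WAKE** when EMG RMS is at or above the wake cut (muscle tone wins
   regardless of the EEG);
2. otherwise **REM** when the EMG shows atonia *and* the theta:total
   ratio is high;
3. otherwise **NREM** when the delta:theta ratio is high;
4. otherwise the nearest class by normalized log-distance to the cuts.

Thresholds are calibrated per recording, either from quantiles and
antimodes of the recording's own feature distributions (self-calibrating,
so globally rescaling EEG or EMG leaves the labels unchanged) or by
fitting cuts against a partial manually scored hypnogram.  A single
majority-smoothing pass removes isolated one-epoch states, standing in
for the visual confirm-and-correct step of conventional scoring;
:func:`apply_corrections` provides the manual-override hook.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import Hypnogram, SignalRecording, State
from .errors import AlignmentError, ConfigurationError
from .spectral import ANALYSIS_BAND, BANDS, EpochSpectra

__all__ = [
    "EpochFeatures",
    "ScoringThresholds",
    "extract_features",
    "calibrate_thresholds",
    "classify",
    "smooth",
    "apply_corrections",
    "score_recording",
]


@dataclass
class EpochFeatures:
    """Per-epoch scoring features; ratios are NaN where the denominator
    vanishes."""

    emg_rms: np.ndarray
    delta_power: np.ndarray
    theta_power: np.ndarray
    total_power: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.emg_rms.size

    @property
    def delta_theta_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.theta_power > 0,
                            self.delta_power / self.theta_power, np.nan)

    @property
    def theta_total_ratio(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.total_power > 0,
                            self.theta_power / self.total_power, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "emg_rms": self.emg_rms,
            "delta_power": self.delta_power,
            "theta_power": self.theta_power,
            "total_power": self.total_power,
            "delta_theta_ratio": self.delta_theta_ratio,
            "theta_total_ratio": self.theta_total_ratio,
        })


@dataclass(frozen=True)
class ScoringThresholds:
    emg_wake_cut: float
    emg_atonia_cut: float
    delta_ratio_cut: float
    theta_ratio_cut: float

    def __post_init__(self):
        if not self.emg_atonia_cut < self.emg_wake_cut:
            raise ConfigurationError(
                "emg_atonia_cut must be below emg_wake_cut")


def extract_features(spectra: EpochSpectra, recording: SignalRecording,
                     emg_channel: str = "EMG") -> EpochFeatures:
    """EMG RMS per 4-s epoch plus EEG band powers from the spectra."""
    if recording.n_epochs != spectra.n_epochs:
        raise AlignmentError(
            f"recording has {recording.n_epochs} epochs, spectra "
            f"{spectra.n_epochs}")
    emg = recording.epochs_of(emg_channel)
    emg_rms = np.sqrt(np.mean(emg.astype(np.float64) ** 2, axis=1))
    delta = BANDS["delta"]
    theta = BANDS["theta"]
    return EpochFeatures(
        emg_rms=emg_rms,
        delta_power=spectra.band_power(delta.lo_hz, delta.hi_hz),
        theta_power=spectra.band_power(theta.lo_hz, theta.hi_hz),
        total_power=spectra.band_power(*ANALYSIS_BAND),
    )


def _antimode(values: np.ndarray, fallback_quantile: float) -> float:
    """Deepest valley between the two tallest KDE modes of log(values);
    falls back to the given quantile when the distribution is unimodal."""
    v = np.log(values[np.isfinite(values) & (values > 0)])
    fallback = float(np.exp(np.quantile(v, fallback_quantile)))
    if v.size < 10 or np.ptp(v) < 1e-12:
        return fallback
    grid = np.linspace(v.min(), v.max(), 256)
    try:
        dens = sstats.gaussian_kde(v)(grid)
    except np.linalg.LinAlgError:
        return fallback
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size < 2:
        return fallback
    top2 = np.sort(peaks[np.argsort(dens[peaks])[-2:]])
    valley = top2[0] + int(np.argmin(dens[top2[0]:top2[1] + 1]))
    return float(np.exp(grid[valley]))


def calibrate_thresholds(features: EpochFeatures, method: str = "quantile",
                         labels: np.ndarray | None = None
                         ) -> ScoringThresholds:
    """Derive scoring cuts from a recording's own feature distributions.

    ``method="quantile"``: EMG cuts at the 60th/20th percentiles of log
    EMG RMS (falling between the high-tone wake cluster and the sleep
    clusters for typical occupancies); ratio cuts at the antimode of each
    ratio's distribution, with fixed-quantile fallbacks.
    ``method="labeled"``: starts from the quantile cuts, then greedily
    refines each cut to maximize epoch accuracy against the provided
    (possibly partial) reference labels — use -1 for unscored epochs.
    """
    if features.n_epochs < 100:
        raise ConfigurationError(
            f"calibration needs >= 100 epochs, got {features.n_epochs}")
    log_emg = np.log(np.maximum(features.emg_rms, 1e-300))
    if np.ptp(log_emg) < 1e-9:
        raise ConfigurationError(
            "degenerate EMG distribution: all epochs identical")
    thr = ScoringThresholds(
        emg_wake_cut=float(np.exp(np.quantile(log_emg, 0.60))),
        emg_atonia_cut=float(np.exp(np.quantile(log_emg, 0.20))),
        delta_ratio_cut=_antimode(features.delta_theta_ratio, 0.50),
        theta_ratio_cut=_antimode(features.theta_total_ratio, 0.80),
    )
    if method == "quantile":
        return thr
    if method != "labeled":
        raise ConfigurationError(f"unknown calibration method {method!r}")
    if labels is None:
        raise ConfigurationError("labeled calibration requires labels")
    labels = np.asarray(labels)
    scored = labels >= 0
    if not scored.any():
        raise ConfigurationError("labeled calibration: no scored epochs")

    def accuracy(t: ScoringThresholds) -> float:
        pred = classify(features, t).states
        return float(np.mean(pred[scored] == labels[scored]))

    # Greedy coordinate refinement over candidate quantiles of the
    # relevant feature distribution for each cut.
    qgrid = np.linspace(0.02, 0.98, 25)
    fields = [
        ("emg_wake_cut", features.emg_rms),
        ("emg_atonia_cut", features.emg_rms),
        ("delta_ratio_cut", features.delta_theta_ratio),
        ("theta_ratio_cut", features.theta_total_ratio),
    ]
    for _ in range(2):
        for name, feat in fields:
            v = feat[np.isfinite(feat)]
            best, best_acc = getattr(thr, name), accuracy(thr)
            for cand in np.quantile(v, qgrid):
                try:
                    trial = replace(thr, **{name: float(cand)})
                except ConfigurationError:
                    continue
                acc = accuracy(trial)
                if acc > best_acc:
                    best, best_acc = float(cand), acc
            thr = replace(thr, **{name: best})
    return thr


def classify(features: EpochFeatures, thresholds: ScoringThresholds
             ) -> Hypnogram:
    """Pointwise decision-rule classification (no smoothing).

    Epochs with undefined EEG ratios (zero power) are scored by EMG
    alone: WAKE above the wake cut, NREM otherwise.
    """
    t = thresholds
    emg = features.emg_rms
    dt = features.delta_theta_ratio
    tt = features.theta_total_ratio

    out = np.empty(features.n_epochs, dtype=np.int8)
    wake = emg >= t.emg_wake_cut
    valid = np.isfinite(dt) & np.isfinite(tt)
    rem = ~wake & valid & (emg <= t.emg_atonia_cut) & (tt >= t.theta_ratio_cut)
    nrem = ~wake & ~rem & valid & (dt >= t.delta_ratio_cut)
    undecided = ~wake & ~rem & ~nrem & valid

    out[wake] = int(State.WAKE)
    out[rem] = int(State.REM)
    out[nrem] = int(State.NREM)
    out[~valid & ~wake] = int(State.NREM)

    if undecided.any():
        # Nearest class by signed log-distance to each rule's cut,
        # normalized by the spread of the corresponding feature.
        def zmargin(x, cut):
            lx = np.log(np.maximum(x, 1e-300))
            spread = np.nanstd(lx)
            return (lx - np.log(max(cut, 1e-300))) / max(spread, 1e-12)

        m_wake = zmargin(emg, t.emg_wake_cut)
        m_rem = np.minimum(-zmargin(emg, t.emg_atonia_cut),
                           zmargin(tt, t.theta_ratio_cut))
        m_nrem = zmargin(dt, t.delta_ratio_cut)
        stacked = np.vstack([m_wake, m_nrem, m_rem])  # rows: W, N, R codes
        out[undecided] = np.argmax(stacked[:, undecided], axis=0).astype(
            np.int8)
    return Hypnogram(states=out)


def smooth(hypnogram: Hypnogram, enabled: bool = True) -> Hypnogram:
    """One left-to-right pass relabeling isolated single-epoch states
    flanked by an identical pair to the flanking state."""
    if not enabled:
        return hypnogram.copy()
    s = hypnogram.states.copy()
    for i in range(1, s.size - 1):
        if s[i - 1] == s[i + 1] != s[i]:
            s[i] = s[i - 1]
    return Hypnogram(states=s, epoch_length_s=hypnogram.epoch_length_s,
                     start_zt_s=hypnogram.start_zt_s,
                     artifact=hypnogram.artifact.copy())


def apply_corrections(hypnogram: Hypnogram,
                      edits: list[tuple[int, State]]) -> Hypnogram:
    """Pointwise manual overrides; the audit trail of
    ``(epoch, old, new)`` is attached as ``corrected.audit_log``."""
    out = hypnogram.copy()
    log = []
    for idx, state in edits:
        if not 0 <= idx < len(out):
            raise AlignmentError(
                f"edit index {idx} outside hypnogram of {len(out)} epochs")
        log.append((int(idx), State(int(out.states[idx])), State(state)))
        out.states[idx] = int(State(state))
    out.audit_log = log
    return out


def score_recording(recording: SignalRecording, channel: str = "EEG2",
                    smoothing: bool = True,
                    thresholds: ScoringThresholds | None = None
                    ) -> tuple[Hypnogram, EpochFeatures, ScoringThresholds]:
    """End-to-end convenience: spectra → artifact mask → features →
    calibrated classification → smoothing."""
    from .spectral import compute_epoch_spectra, flag_artifacts

    spectra = compute_epoch_spectra(recording, channel=channel)
    flag_artifacts(spectra)
    features = extract_features(spectra, recording)
    thr = thresholds or calibrate_thresholds(features)
    hyp = classify(features, thr)
    hyp = smooth(hyp, enabled=smoothing)
    hyp.start_zt_s = recording.start_zt_s
    hyp.epoch_length_s = recording.epoch_length_s
    hyp.artifact = spectra.artifact_mask.copy()
    return hyp, features, thr
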