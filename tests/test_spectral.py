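"""Spectral estimation and the two normalization conventions."""

import numpy as np
import pandas as pd
import pytest

import nocturn as nc
from nocturn.core import Hypnogram, SignalRecording, State
from nocturn.errors import AlignmentError
from nocturn.spectral import (BANDS, EpochSpectra, band_power_by_state,
                              compute_epoch_spectra, flag_artifacts,
                              nrem_delta_timecourse,
                              nrem_total_power_normalizer,
                              state_spectral_profile, theta_peak_frequency)
from conftest import tone_recording


def _spectra_of_tone(freq, amplitude=50.0, taper="rectangular", n_epochs=4):
    rec = tone_recording(freq, amplitude, n_epochs=n_epochs)
    return compute_epoch_spectra(rec, taper=taper)


def test_grid_is_exactly_quarter_hz():
    spec = _spectra_of_tone(2.0)
    assert spec.bin_width_hz == 0.25
    np.testing.assert_allclose(np.diff(spec.freqs), 0.25)
    assert spec.freqs[0] == 0.25
    assert spec.freqs[-1] == 32.0  # Nyquist at 64 Hz


@pytest.mark.parametrize("taper", ["rectangular", "hann"])
@pytest.mark.parametrize("freq", [2.0, 7.0, 15.25, 28.75])
def test_parseval_on_bin_centered_tones(freq, taper):
    A = 37.0
    spec = _spectra_of_tone(freq, A, taper=taper)
    total = spec.power.sum(axis=1)
    np.testing.assert_allclose(total, A ** 2 / 2, rtol=1e-9)


def test_tone_power_concentrates_in_its_bin():
    A = 50.0
    spec = _spectra_of_tone(2.0, A, taper="rectangular")
    k = np.argmax(spec.power[0])
    assert spec.freqs[k] == 2.0
    np.testing.assert_allclose(spec.power[:, k], A ** 2 / 2, rtol=1e-9)
    spec7 = _spectra_of_tone(7.0, A, taper="hann")
    assert spec7.freqs[np.argmax(spec7.power[0])] == 7.0


def test_white_noise_spectrum_is_flat(rng):
    # 10,000 epochs of white noise; 1-Hz band averages of the mean
    # spectrum flat within 2% over 1-25 Hz.
    n_epochs = 10_000
    x = rng.standard_normal(n_epochs * 256)
    rec = SignalRecording(channels={"EEG2": x, "EMG": np.zeros(x.size)})
    spec = compute_epoch_spectra(rec)
    mean = spec.power.mean(axis=0)
    sel = (spec.freqs >= 1.0) & (spec.freqs < 25.0)
    bands = mean[sel].reshape(-1, 4).mean(axis=1)  # 1-Hz averages
    assert np.max(np.abs(bands / bands.mean() - 1)) < 0.02


def test_artifact_flagging_sensitivity_and_false_positives():
    cfg = nc.archetype("NAB").apply().replace(n_hours=12.0, seed=19,
                                              artifact_rate=0.005)
    hyp = nc.simulate_hypnogram(cfg)
    rec = nc.simulate_signals(hyp, cfg)
    spec = compute_epoch_spectra(rec)
    mask = flag_artifacts(spec)  # spectra-only, no ground-truth flags
    truth = hyp.artifact
    assert truth.sum() > 20
    sensitivity = (mask & truth).sum() / truth.sum()
    fpr = (mask & ~truth).sum() / (~truth).sum()
    assert sensitivity >= 0.95
    assert fpr <= 0.01


def test_identical_epochs_and_infinite_k_produce_no_flags():
    power = np.ones((200, 4))
    spec = EpochSpectra(power=power, freqs=np.array([0.25, 0.5, 0.75, 1.0]),
                        artifact_mask=np.zeros(200, bool))
    assert not flag_artifacts(spec).any()
    spec2 = EpochSpectra(power=np.abs(np.random.default_rng(0)
                                      .standard_normal((200, 4))) + 29.0,
                         freqs=np.array([10.0, 11.0, 12.0, 13.0]),
                         artifact_mask=np.zeros(200, bool))
    assert not flag_artifacts(spec2, k=np.inf).any()


def _toy_spectra(power_rows, freqs=None, states=None):
    power = np.asarray(power_rows, float)
    if freqs is None:
        freqs = 0.25 * np.arange(1, power.shape[1] + 1)
    spec = EpochSpectra(power=power, freqs=np.asarray(freqs),
                        artifact_mask=np.zeros(power.shape[0], bool))
    hyp = Hypnogram(states=np.asarray(states, dtype=np.int8))
    return spec, hyp


def test_delta_timecourse_matches_hand_computation():
    # 3 NREM epochs; grid 0.25..29 Hz. Hand-computed below.
    n_bins = 116  # 0.25..29.0
    freqs = 0.25 * np.arange(1, n_bins + 1)
    power = np.zeros((3, n_bins))
    delta_sel = (freqs >= 0.5) & (freqs <= 5.0)
    total_sel = (freqs >= 0.5) & (freqs <= 29.0)
    power[0, delta_sel] = 2.0
    power[0, ~delta_sel] = 1.0
    power[1, delta_sel] = 4.0
    power[2, total_sel] = 0.5
    spec, hyp = _toy_spectra(power, freqs, states=[1, 1, 1])
    delta_each = power[:, delta_sel].sum(axis=1)
    total_each = power[:, total_sel].sum(axis=1)
    expected = delta_each.mean() / total_each.mean() * 100.0
    tc = nrem_delta_timecourse(spec, hyp, bin_h=24.0)
    assert tc.iloc[0] == pytest.approx(expected, rel=1e-12)


def test_delta_timecourse_constant_spectrum_and_scale_invariance():
    n_bins = 116
    freqs = 0.25 * np.arange(1, n_bins + 1)
    row = np.ones(n_bins)
    power = np.tile(row, (900, 1))
    spec, hyp = _toy_spectra(power, freqs, states=[1] * 900)
    tc = nrem_delta_timecourse(spec, hyp, bin_h=0.5)
    delta_frac = ((freqs >= 0.5) & (freqs <= 5.0)).sum() / \
        ((freqs >= 0.5) & (freqs <= 29.0)).sum()
    np.testing.assert_allclose(tc.to_numpy(), 100 * delta_frac, rtol=1e-12)
    # x4 power (2x amplitude) changes nothing.
    spec4, _ = _toy_spectra(4 * power, freqs, states=[1] * 900)
    tc4 = nrem_delta_timecourse(spec4, hyp, bin_h=0.5)
    np.testing.assert_allclose(tc4.to_numpy(), tc.to_numpy(), rtol=1e-12)


def test_delta_timecourse_weighted_mean_equals_pooled_ratio(rng):
    # Weighted (by NREM epochs per bin) mean of the time course equals
    # the pooled delta/normalizer ratio to 1e-10.
    n_ep = 2000
    states = rng.choice([0, 1, 2], size=n_ep, p=[0.4, 0.5, 0.1])
    power = rng.gamma(2.0, 1.0, size=(n_ep, 128))
    freqs = 0.25 * np.arange(1, 129)
    spec, hyp = _toy_spectra(power, freqs, states=states)
    tc = nrem_delta_timecourse(spec, hyp, bin_h=0.5)
    zt_bins = np.floor(hyp.zt_s() / 3600.0 / 0.5).astype(int)
    nrem = states == 1
    weights = np.bincount(zt_bins[nrem], minlength=len(tc)).astype(float)
    pooled = np.nansum(tc.to_numpy() * weights) / weights.sum()
    norm = nrem_total_power_normalizer(spec, hyp)
    direct = spec.band_power(0.5, 5.0)[nrem].mean() / norm * 100
    assert pooled == pytest.approx(direct, abs=1e-10)


def test_delta_timecourse_empty_bins_are_missing_and_no_nrem_errors():
    n_bins = 116
    power = np.ones((1800, n_bins))
    states = np.zeros(1800, dtype=np.int8)
    states[:900] = 1  # NREM only in the first hour
    spec, hyp = _toy_spectra(power, states=states)
    tc = nrem_delta_timecourse(spec, hyp, bin_h=1.0)
    assert np.isfinite(tc.iloc[0]) and np.isnan(tc.iloc[1])
    spec2, hyp2 = _toy_spectra(power, states=np.zeros(1800, np.int8))
    with pytest.raises(AlignmentError):
        nrem_delta_timecourse(spec2, hyp2)


def test_state_profile_sums_follow_total_power_identity(rng):
    power = rng.gamma(2.0, 1.0, size=(600, 128))
    freqs = 0.25 * np.arange(1, 129)
    states = rng.choice([0, 1, 2], size=600, p=[0.5, 0.4, 0.1])
    spec, hyp = _toy_spectra(power, freqs, states=states)
    grand = spec.total_power().mean()
    for s in (State.WAKE, State.NREM, State.REM):
        prof = state_spectral_profile(spec, hyp, s)
        state_mean = spec.total_power()[states == int(s)].mean()
        assert prof.sum() == pytest.approx(100 * state_mean / grand,
                                           rel=1e-10)
    #

    # Single-state recording: profile sums to exactly 100%.
    spec1, hyp1 = _toy_spectra(power, freqs, states=np.ones(600, np.int8))
    prof = state_spectral_profile(spec1, hyp1, State.NREM)
    assert prof.sum() == pytest.approx(100.0, rel=1e-12)


def test_nrem_profile_delta_exceeds_beta_under_default_archetype(
        short_recording):
    rec, hyp = short_recording
    spec = compute_epoch_spectra(rec)
    flag_artifacts(spec, hypnogram=hyp)
    prof = state_spectral_profile(spec, hyp, State.NREM)
    delta = prof[(prof.index >= 0.5) & (prof.index <= 5)].mean()
    beta = prof[(prof.index >= 16) & (prof.index <= 23)].mean()
    assert delta > 5 * beta


def test_band_table_hand_fixture_and_flat_spectrum_proportionality():
    freqs = 0.25 * np.arange(1, 129)
    power = np.tile(np.ones(128), (4, 1))
    power[2:] *= 3.0
    spec, hyp = _toy_spectra(power, freqs, states=[0, 0, 1, 1])
    table = band_power_by_state(spec, hyp)
    grand = spec.total_power().mean()  # excludes the 32 Hz Nyquist bin
    widths = {name: ((freqs >= b.lo_hz) & (freqs <= b.hi_hz)).sum()
              for name, b in BANDS.items()}
    for name in BANDS:
        assert table.loc["WAKE", name] == pytest.approx(
            widths[name] / grand * 100, rel=1e-12)
        assert table.loc["NREM", name] == pytest.approx(
            3 * widths[name] / grand * 100, rel=1e-12)
        assert np.isnan(table.loc["REM", name])
    # Flat spectrum: band values proportional to band widths.
    ratio = table.loc["WAKE", "delta"] / table.loc["WAKE", "beta"]
    assert ratio == pytest.approx(widths["delta"] / widths["beta"],
                                  rel=1e-12)
    # Scale invariance.
    spec2, _ = _toy_spectra(7.0 * power, freqs, states=[0, 0, 1, 1])
    table2 = band_power_by_state(spec2, hyp)
    pd.testing.assert_frame_equal(table, table2)


def test_theta_peak_frequency_cases():
    rec = tone_recording(7.25, 40.0)
    spec = compute_epoch_spectra(rec, taper="rectangular")
    prof = pd.Series(spec.power.mean(axis=0), index=spec.freqs)
    assert theta_peak_frequency(prof) == 7.25
    flat = pd.Series(np.ones(128), index=0.25 * np.arange(1, 129))
    assert theta_peak_frequency(flat) == 6.0  # tie -> lower edge


def test_simulated_rem_theta_peak_shift_is_recovered():
    # REM signature centered at 7.0 Hz (NAB) vs 6.2 Hz (LAB): the
    # recovered peaks differ by ~0.8 Hz.
    peaks = {}
    for line in ("NAB", "LAB"):
        cfg = nc.archetype(line).apply().replace(n_hours=4.0, seed=23,
                                                 artifact_rate=0.0)
        hyp = nc.simulate_hypnogram(cfg)
        assert (hyp.states == int(State.REM)).sum() > 50
        rec = nc.simulate_signals(hyp, cfg)
        spec = compute_epoch_spectra(rec)
        prof = state_spectral_profile(spec, hyp, State.REM)
        peaks[line] = theta_peak_frequency(prof)
    assert peaks["NAB"] - peaks["LAB"] == pytest.approx(0.8, abs=0.3)
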