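"""Generator: Markov dynamics, homeostasis, protocol, archetypes."""

import numpy as np
import pytest

import nocturn as nc
from nocturn.core import State
from nocturn.errors import ConfigurationError
from nocturn.simulate import (ARCHETYPE_NAMES, HomeostasisParams,
                              homeostatic_process, simulate_hypnogram_batch)


def test_absorbing_wake_state_yields_all_wake():
    rates = {k: np.array([[1.0, 0, 0], [0.04, 0.94, 0.02], [0.1, 0.02, 0.88]])
             for k in ("light", "dark")}
    cfg = nc.SimConfig(transition_rates=rates, n_hours=1.0, seed=3)
    hyp = nc.simulate_hypnogram(cfg)
    assert (hyp.states == int(State.WAKE)).all()


def test_same_seed_reproduces_hypnogram_and_signals():
    cfg = nc.archetype("HAB").apply().replace(n_hours=1.0, seed=11)
    h1, h2 = (nc.simulate_hypnogram(cfg) for _ in range(2))
    np.testing.assert_array_equal(h1.states, h2.states)
    np.testing.assert_array_equal(h1.artifact, h2.artifact)
    r1, r2 = (nc.simulate_signals(h1, cfg) for _ in range(2))
    for ch in r1.channels:
        np.testing.assert_array_equal(r1.channels[ch], r2.channels[ch])


def test_invalid_transition_matrix_rejected():
    rates = {k: np.array([[0.9, 0.2, 0], [0.04, 0.94, 0.02],
                          [0.1, 0.02, 0.88]]) for k in ("light", "dark")}
    cfg = nc.SimConfig(transition_rates=rates)
    with pytest.raises(ConfigurationError):
        nc.simulate_hypnogram(cfg)


def test_geometric_mean_bout_length_matches_exit_probability():
    # Exit probability p from NREM -> mean bout length 1/p epochs.
    p = 0.1
    rates = {k: np.array([[0.80, 0.20, 0.00],
                          [p, 1 - p, 0.00],
                          [0.10, 0.02, 0.88]]) for k in ("light", "dark")}
    cfg = nc.SimConfig(transition_rates=rates, n_hours=96.0, seed=5,
                       artifact_rate=0.0)
    hyp = nc.simulate_hypnogram(cfg)
    bouts = [b.length_epochs for b in nc.detect_bouts(hyp)
             if b.state == State.NREM]
    bouts = bouts[1:-1]  # interior bouts only (no boundary censoring)
    assert len(bouts) >= 2000
    assert np.mean(bouts) == pytest.approx(1 / p, rel=0.05)


def test_sd_protocol_forces_exactly_5400_wake_epochs_on_day_two():
    cfg = nc.archetype("NAB").apply().replace(n_hours=48.0, seed=9)
    hyp = nc.simulate_hypnogram(cfg, protocol="sd_recovery")
    day2_zt0, day2_zt6 = 21600, 27000
    window = hyp.states[day2_zt0:day2_zt6]
    assert window.size == 5400
    assert (window == int(State.WAKE)).all()
    # Free sleep resumes afterwards.
    assert (hyp.states[day2_zt6:] != int(State.WAKE)).any()


def test_sd_protocol_requires_at_least_24_hours():
    cfg = nc.archetype("NAB").apply().replace(n_hours=12.0)
    with pytest.raises(ConfigurationError):
        nc.simulate_hypnogram(cfg, protocol="sd_recovery")


def test_empirical_transition_frequencies_converge_to_configured():
    # ~1e5 epochs per phase; conditional frequencies within TV 0.02.
    cfg = nc.archetype("NAB").apply().replace(n_hours=240.0, seed=21,
                                              artifact_rate=0.0)
    hyp = nc.simulate_hypnogram(cfg)
    light = hyp.light_mask()
    for phase, mask in (("light", light), ("dark", ~light)):
        target = cfg.transition_rates[phase]
        frm, to = hyp.states[:-1], hyp.states[1:]
        inphase = mask[:-1] & mask[1:]
        assert inphase.sum() >= 100_000
        for i in range(3):
            sel = inphase & (frm == i)
            emp = np.array([np.mean(to[sel] == j) for j in range(3)])
            tv = 0.5 * np.abs(emp - target[i]).sum()
            assert tv < 0.02, (phase, i, tv)


def test_homeostatic_process_bounded_and_rises_during_forced_wake():
    params = HomeostasisParams()
    wake6h = np.zeros(5400, dtype=np.int8)
    s = homeostatic_process(wake6h, params)
    assert s[-1] > s[0]
    assert np.all((s >= params.floor) & (s <= params.ceiling))
    nrem6h = np.full(5400, int(State.NREM), dtype=np.int8)
    s = homeostatic_process(nrem6h, params)
    assert s[-1] < s[0]
    assert np.all((s >= params.floor) & (s <= params.ceiling))


def test_stationary_delta_power_when_homeostasis_disabled():
    # All-NREM hypnogram, gain fixed at 1: per-epoch delta power is
    # stationary (CoV bounded by sampling noise of ~12 effective bins).
    cfg = nc.archetype("NAB").apply().replace(
        n_hours=2.0, seed=13, artifact_rate=0.0,
        homeostasis=HomeostasisParams(enabled=False))
    hyp = nc.Hypnogram(np.full(cfg.n_epochs, int(State.NREM), dtype=np.int8))
    rec = nc.simulate_signals(hyp, cfg)
    spec = nc.compute_epoch_spectra(rec)
    delta = spec.band_power(0.5, 5.0)
    cov = delta.std() / delta.mean()
    assert cov < 0.45
    # And with homeostasis enabled from s0 = ceiling, power decays.
    cfg2 = cfg.replace(homeostasis=HomeostasisParams(s0=1.8))
    rec2 = nc.simulate_signals(hyp, cfg2)
    d2 = nc.compute_epoch_spectra(rec2).band_power(0.5, 5.0)
    first, last = d2[:200].mean(), d2[-200:].mean()
    assert first > 1.5 * last


def test_emg_levels_order_wake_above_nrem_above_rem(short_recording):
    rec, hyp = short_recording
    emg = rec.epochs_of("EMG")
    rms = np.sqrt((emg ** 2).mean(axis=1))
    means = {s: rms[hyp.states == int(s)].mean()
             for s in (State.WAKE, State.NREM, State.REM)
             if (hyp.states == int(s)).any()}
    assert means[State.WAKE] > means[State.NREM] > means[State.REM]


def test_archetype_presets_encode_reported_directions():
    nab = nc.archetype("NAB").apply()
    lab = nc.archetype("LAB").apply()
    hab = nc.archetype("HAB").apply()
    for phase in ("light", "dark"):
        n, l, h = (c.transition_rates[phase] for c in (nab, lab, hab))
        # HAB: shorter NREM/REM bouts (higher exit rates), more frequent
        # NREM->REM entries than NAB.
        assert 1 - h[1, 1] > 1 - n[1, 1]
        assert 1 - h[2, 2] >= 1 - n[2, 2]
        assert h[1, 2] > n[1, 2]
    # LAB: lower wake-exit probability at light onset than NAB.
    assert lab.transition_rates["light"][0, 1] < \
        nab.transition_rates["light"][0, 1]
    # Homeostatic buildup: HAB fast, LAB sluggish.
    assert hab.homeostasis.tau_rise_h < nab.homeostasis.tau_rise_h \
        < lab.homeostasis.tau_rise_h
    # EMG ordering invariant for every shipped archetype.
    for name in ARCHETYPE_NAMES:
        cfg = nc.archetype(name).apply()
        emg = cfg.emg_amplitude
        assert emg[State.WAKE] > emg[State.NREM] >= emg[State.REM]


def test_make_study_gives_distinct_animals_and_rejects_empty_cohort():
    study = nc.make_study("HAB", 5, seed=2, signals=False)
    seqs = [tuple(a.baseline_hypnogram.states[:500]) for a in study]
    assert len(set(seqs)) == 5
    assert all(len(a.baseline_hypnogram) == 21600 for a in study)
    assert all(len(a.recovery_hypnogram) == 21600 for a in study)
    with pytest.raises(ConfigurationError):
        nc.make_study("NAB", 0, seed=1)


def test_batch_simulation_matches_marginal_statistics():
    cfg = nc.archetype("NAB").apply().replace(n_hours=2.0, seed=31)
    batch = simulate_hypnogram_batch(cfg, 50)
    assert batch.shape == (50, cfg.n_epochs)
    # All chains start in the configured initial state.
    assert (batch[:, 0] == int(cfg.initial_state)).all()


def test_simconfig_yaml_round_trip(tmp_path):
    cfg = nc.archetype("LAB").apply().replace(seed=77, n_hours=6.0)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = nc.SimConfig.from_yaml(path)
    assert back.seed == 77 and back.n_hours == 6.0
    for phase in ("light", "dark"):
        np.testing.assert_allclose(back.transition_rates[phase],
                                   cfg.transition_rates[phase])
    assert back.spectral_signature == cfg.spectral_signature
    assert back.homeostasis == cfg.homeostasis
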