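"""Synthetic sleep-study generator.

Emulates a standard rodent sleep-phenotyping design: 24-h baseline
EEG/EMG recordings (64 Hz, 4-s scoring epochs, 12:12 LD with lights on
at 7:00) followed by a day on which the animal is kept awake for the
first 6 h of the light phase and then records freely for 18 h.

The generative model, stage by stage:

1. **State dynamics** — a first-order Markov chain over
   {WAKE, NREM, REM} at epoch resolution, with separate transition
   matrices for the light and the dark phase.  This is the simplest
   mechanism that produces geometric-like bout durations and a
   light/dark rhythm in state occupancy.
2. **Homeostatic process** — a dimensionless scalar ``S`` that rises
   exponentially toward a ceiling during WAKE and REM and decays
   exponentially toward a floor during NREM, in the spirit of the
   two-process model of sleep regulation.  ``S`` multiplies the
   amplitude of the NREM delta spectral component, so slow-wave
   activity tracks accumulated time awake.
3. **Signals** — per 4-s epoch, the EEG is synthesized in the frequency
   domain as a 1/f background plus state-specific Gaussian spectral
   components (NREM: delta + sigma; REM: a sharp theta peak; wake:
   mixed), realized with random phases; the EMG is white noise at a
   state-specific RMS level (wake > NREM > REM).  Artifact epochs get a
   large broadband transient added.

Three line archetypes ship with the package.  They encode the
*directions* of the phenotypes reported for mice selectively bred for
high (HAB), normal (NAB) and low (LAB) anxiety-related behavior —
HAB: fragmented sleep, frequent NREM→REM entries, elevated delta and
fast homeostatic buildup; LAB: long wake bouts, long sleep latency,
sluggish delta accumulation; NAB: consolidated, intermediate.  The
magnitudes are free parameters of this package, not fitted values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import Hypnogram, SignalRecording, State, is_light
from .errors import ConfigurationError

__all__ = [
    "SpectralComponent",
    "StateSignature",
    "HomeostasisParams",
    "SimConfig",
    "LineArchetype",
    "archetype",
    "ARCHETYPE_NAMES",
    "simulate_hypnogram",
    "simulate_hypnogram_batch",
    "homeostatic_process",
    "simulate_signals",
    "make_study",
    "iter_study",
    "AnimalRecordings",
]

_STATE_ORDER = (State.WAKE, State.NREM, State.REM)


@dataclass(frozen=True)
class SpectralComponent:
    """One Gaussian bump in a state's EEG amplitude spectrum.

    ``amplitude`` is the per-bin tone-equivalent amplitude (µV) at the
    component's center frequency; ``bandwidth_hz`` is its full width at
    half maximum.
    """

    center_hz: float
    bandwidth_hz: float
    amplitude: float


@dataclass(frozen=True)
class StateSignature:
    """EEG spectral signature of one vigilance state: a 1/f background
    weight (µV at 1 Hz) plus narrowband components."""

    background: float
    components: tuple[SpectralComponent, ...] = ()


@dataclass(frozen=True)
class HomeostasisParams:
    """Saturating-exponential slow-wave pressure process.

    ``S`` relaxes toward ``ceiling`` with time constant ``tau_rise_h``
    while the animal is awake or in REM, and toward ``floor`` with
    ``tau_decay_h`` during NREM.  ``S`` multiplies the NREM delta
    component amplitude (components centered at or below ``delta_hi_hz``).
    Dimensionless; ``s0`` is the value at recording start.
    """

    tau_rise_h: float = 10.0
    tau_decay_h: float = 3.0
    floor: float = 0.7
    ceiling: float = 1.8
    s0: float = 1.0
    enabled: bool = True
    delta_hi_hz: float = 5.0

    def validate(self) -> None:
        if self.tau_rise_h <= 0 or self.tau_decay_h <= 0:
            raise ConfigurationError("homeostasis time constants must be > 0")
        if not (self.ceiling > self.floor >= 0):
            raise ConfigurationError(
                "homeostasis requires ceiling > floor >= 0"
            )
        if not (self.floor <= self.s0 <= self.ceiling):
            raise ConfigurationError("s0 must lie in [floor, ceiling]")


def _default_signatures() -> dict[State, StateSignature]:
    return {
        State.WAKE: StateSignature(
            background=7.0,
            components=(
                SpectralComponent(1.5, 2.0, 5.0),
                SpectralComponent(7.5, 2.0, 8.0),
            ),
        ),
        State.NREM: StateSignature(
            background=6.0,
            components=(
                SpectralComponent(2.0, 2.0, 18.0),   # delta, scaled by S
                SpectralComponent(12.0, 3.0, 6.0),   # sigma / spindle range
            ),
        ),
        State.REM: StateSignature(
            background=5.0,
            components=(
                SpectralComponent(1.5, 1.5, 3.0),
                SpectralComponent(7.0, 1.2, 14.0),   # theta peak
            ),
        ),
    }


def _default_rates() -> dict[str, np.ndarray]:
    # Rows/cols ordered WAKE, NREM, REM; per-4-s-epoch probabilities.
    # Calibrated so the light phase runs ~55% NREM / ~8% REM and the
    # dark phase ~78% wake, with wake bouts ~2 min (light) / ~8 min (dark).
    light = np.array([
        [0.9780, 0.0220, 0.0000],
        [0.0040, 0.9778, 0.0182],
        [0.1000, 0.0250, 0.8750],
    ])
    dark = np.array([
        [0.9900, 0.0100, 0.0000],
        [0.0300, 0.9580, 0.0120],
        [0.1000, 0.0200, 0.8800],
    ])
    return {"light": light, "dark": dark}


@dataclass
class SimConfig:
    """Generative parameters for one simulated animal.

    ``transition_rates`` maps ``"light"``/``"dark"`` to 3x3 row-stochastic
    matrices over (WAKE, NREM, REM).  ``emg_amplitude`` gives per-state
    EMG RMS levels in arbitrary units; the shipped archetypes satisfy
    wake > NREM >= REM.
    """

    epoch_length_s: float = 4.0
    sampling_rate_hz: float = 64.0
    lights_on_clock: float = 7.0
    n_hours: float = 24.0
    transition_rates: dict[str, np.ndarray] = field(
        default_factory=_default_rates)
    spectral_signature: dict[State, StateSignature] = field(
        default_factory=_default_signatures)
    emg_amplitude: dict[State, float] = field(default_factory=lambda: {
        State.WAKE: 3.0, State.NREM: 1.0, State.REM: 0.45})
    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)
    artifact_rate: float = 0.005
    artifact_amplitude: float = 60.0
    initial_state: State = State.WAKE
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_rates = {
            k: np.asarray(v, dtype=float)
            for k, v in self.transition_rates.items()
        }

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        spe = self.sampling_rate_hz * self.epoch_length_s
        if abs(spe - round(spe)) > 1e-9:
            raise ConfigurationError(
                "sampling_rate_hz x epoch_length_s must be an integer")
        if self.n_hours <= 0:
            raise ConfigurationError("n_hours must be positive")
        for phase in ("light", "dark"):
            if phase not in self.transition_rates:
                raise ConfigurationError(f"missing {phase!r} transition matrix")
            m = self.transition_rates[phase]
            if m.shape != (3, 3):
                raise ConfigurationError(
                    f"{phase} transition matrix must be 3x3, got {m.shape}")
            if (m < -1e-12).any() or (m > 1 + 1e-12).any():
                raise ConfigurationError(
                    f"{phase} transition probabilities outside [0, 1]")
            rowsum = m.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-8):
                raise ConfigurationError(
                    f"{phase} transition-matrix rows must sum to 1 "
                    f"(got {rowsum})")
        if not 0 <= self.artifact_rate <= 1:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        self.homeostasis.validate()

    @property
    def n_epochs(self) -> int:
        return int(round(self.n_hours * 3600.0 / self.epoch_length_s))

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sampling_rate_hz * self.epoch_length_s))

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    # -- YAML round trip ----------------------------------------------
    def to_yaml(self, path) -> None:
        d = {
            "epoch_length_s": self.epoch_length_s,
            "sampling_rate_hz": self.sampling_rate_hz,
            "lights_on_clock": self.lights_on_clock,
            "n_hours": self.n_hours,
            "transition_rates": {k: v.tolist()
                                 for k, v in self.transition_rates.items()},
            "spectral_signature": {
                s.name: {
                    "background": sig.background,
                    "components": [[c.center_hz, c.bandwidth_hz, c.amplitude]
                                   for c in sig.components],
                }
                for s, sig in self.spectral_signature.items()
            },
            "emg_amplitude": {s.name: v
                              for s, v in self.emg_amplitude.items()},
            "homeostasis": dataclasses.asdict(self.homeostasis),
            "artifact_rate": self.artifact_rate,
            "artifact_amplitude": self.artifact_amplitude,
            "initial_state": State(self.initial_state).name,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sig = {
            State[name]: StateSignature(
                background=entry["background"],
                components=tuple(SpectralComponent(*c)
                                 for c in entry["components"]),
            )
            for name, entry in d.pop("spectral_signature").items()
        }
        emg = {State[name]: v for name, v in d.pop("emg_amplitude").items()}
        homeo = HomeostasisParams(**d.pop("homeostasis"))
        init = State[d.pop("initial_state")]
        rates = {k: np.asarray(v) for k, v in d.pop("transition_rates").items()}
        return cls(transition_rates=rates, spectral_signature=sig,
                   emg_amplitude=emg, homeostasis=homeo,
                   initial_state=init, **d)


# ---------------------------------------------------------------------
# Line archetypes
# ---------------------------------------------------------------------

ARCHETYPE_NAMES = ("NAB", "LAB", "HAB")


@dataclass(frozen=True)
class LineArchetype:
    """Named preset: a partial override of the default (NAB) SimConfig."""

    name: str
    overrides: dict = field(default_factory=dict)

    def apply(self, base: SimConfig | None = None) -> SimConfig:
        cfg = base if base is not None else SimConfig()
        return cfg.replace(**self.overrides)


def _hab_overrides() -> dict:
    # Fragmented sleep, frequent NREM<->REM shuttling, blunted LD rhythm,
    # elevated delta with fast homeostatic buildup.
    rates = {
        "light": np.array([
            [0.880, 0.120, 0.000],
            [0.040, 0.930, 0.030],
            [0.150, 0.100, 0.750],
        ]),
        "dark": np.array([
            [0.960, 0.040, 0.000],
            [0.040, 0.925, 0.035],
            [0.150, 0.100, 0.750],
        ]),
    }
    sig = _default_signatures()
    sig[State.NREM] = StateSignature(
        background=6.0,
        components=(
            SpectralComponent(2.0, 2.0, 22.0),
            SpectralComponent(12.0, 3.0, 6.0),
        ),
    )
    sig[State.REM] = StateSignature(
        background=5.0,
        components=(
            SpectralComponent(1.5, 1.5, 3.5),
            SpectralComponent(6.1, 1.2, 14.0),   # theta peak ~0.9 Hz slower
        ),
    )
    return {
        "transition_rates": rates,
        "spectral_signature": sig,
        "homeostasis": HomeostasisParams(tau_rise_h=6.0, tau_decay_h=3.0,
                                         floor=0.7, ceiling=1.8, s0=1.0),
    }


def _lab_overrides() -> dict:
    # Long wake bouts (especially at light onset), long sleep latency,
    # sluggish homeostatic buildup, extra NREM beta power.
    rates = {
        "light": np.array([
            [0.993, 0.007, 0.000],
            [0.003, 0.985, 0.012],
            [0.080, 0.020, 0.900],
        ]),
        "dark": np.array([
            [0.995, 0.005, 0.000],
            [0.030, 0.960, 0.010],
            [0.100, 0.020, 0.880],
        ]),
    }
    sig = _default_signatures()
    sig[State.NREM] = StateSignature(
        background=6.0,
        components=(
            SpectralComponent(2.0, 2.0, 18.0),
            SpectralComponent(12.0, 3.0, 6.0),
            SpectralComponent(17.0, 2.0, 3.0),   # beta excess
        ),
    )
    sig[State.REM] = StateSignature(
        background=5.0,
        components=(
            SpectralComponent(1.5, 1.5, 3.5),
            SpectralComponent(6.2, 1.2, 14.0),   # theta peak ~0.8 Hz slower
        ),
    )
    return {
        "transition_rates": rates,
        "spectral_signature": sig,
        "homeostasis": HomeostasisParams(tau_rise_h=16.0, tau_decay_h=3.0,
                                         floor=0.7, ceiling=1.8, s0=1.0),
    }


_ARCHETYPES = {
    "NAB": LineArchetype("NAB", {}),
    "LAB": LineArchetype("LAB", _lab_overrides()),
    "HAB": LineArchetype("HAB", _hab_overrides()),
}


def archetype(name: str) -> LineArchetype:
    """Return the shipped preset for line ``name`` (NAB, LAB, or HAB)."""
    try:
        return _ARCHETYPES[name.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown line archetype {name!r}; choose from {ARCHETYPE_NAMES}"
        ) from None


# ---------------------------------------------------------------------
# Hypnogram simulation
# ---------------------------------------------------------------------

def _forced_wake_mask(config: SimConfig, protocol: str) -> np.ndarray | None:
    """Epochs forced to WAKE under the sleep-deprivation protocol.

    Day 1 is baseline; on day 2 the 6 h from ZT0 (epoch 21,600 at 4-s
    epochs) are enforced wakefulness, emulating gentle handling.
    """
    if protocol == "baseline":
        return None
    if protocol != "sd_recovery":
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    if config.n_hours < 24:
        raise ConfigurationError("sd_recovery requires n_hours >= 24")
    epochs_per_hour = 3600.0 / config.epoch_length_s
    start = int(round(24 * epochs_per_hour))
    stop = int(round(30 * epochs_per_hour))
    mask = np.zeros(config.n_epochs, dtype=bool)
    mask[start:min(stop, config.n_epochs)] = True
    return mask


def _simulate_states(config: SimConfig, n_chains: int,
                     rng: np.random.Generator,
                     forced_wake: np.ndarray | None) -> np.ndarray:
    """Batched inhomogeneous Markov chain; returns (n_chains, n_epochs)."""
    n_epochs = config.n_epochs
    zt = np.arange(n_epochs) * config.epoch_length_s
    light = is_light(zt)
    cum = {
        True: np.cumsum(config.transition_rates["light"], axis=1),
        False: np.cumsum(config.transition_rates["dark"], axis=1),
    }
    states = np.empty((n_chains, n_epochs), dtype=np.int8)
    s = np.full(n_chains, int(config.initial_state), dtype=np.int64)
    for t in range(n_epochs):
        if forced_wake is not None and forced_wake[t]:
            s[:] = int(State.WAKE)
        states[:, t] = s
        # Draw the next state even for the final epoch so RNG consumption
        # is uniform; the draw after the last epoch is discarded.
        u = rng.random(n_chains)
        c = cum[bool(light[t])]
        s = (u[:, None] > c[s]).sum(axis=1)
    return states


def simulate_hypnogram(config: SimConfig,
                       protocol: str = "baseline") -> Hypnogram:
    """Simulate one animal's hypnogram.

    ``protocol`` is ``"baseline"`` (free sleep throughout) or
    ``"sd_recovery"`` (free day 1, forced WAKE during [ZT0, ZT6) of day
    2, free thereafter).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    forced = _forced_wake_mask(config, protocol)
    states = _simulate_states(config, 1, rng, forced)[0]
    artifact = rng.random(config.n_epochs) < config.artifact_rate
    return Hypnogram(states=states, epoch_length_s=config.epoch_length_s,
                     start_zt_s=0.0, artifact=artifact)


def simulate_hypnogram_batch(config: SimConfig, n: int,
                             protocol: str = "baseline") -> np.ndarray:
    """State sequences for ``n`` independent animals sharing one RNG
    stream, as an ``(n, n_epochs)`` int8 array (no artifact injection).

    Intended for large null simulations where constructing per-animal
    :class:`Hypnogram` objects would dominate the cost.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    forced = _forced_wake_mask(config, protocol)
    return _simulate_states(config, n, rng, forced)


# ---------------------------------------------------------------------
# Homeostatic process and signal synthesis
# ---------------------------------------------------------------------

def homeostatic_process(states: np.ndarray, params: HomeostasisParams,
                        epoch_length_s: float = 4.0) -> np.ndarray:
    """Per-epoch value of the slow-wave pressure process ``S``.

    ``S[t]`` is the value in force during epoch ``t`` (so ``S[0] == s0``);
    the state of epoch ``t`` drives the update to ``S[t+1]``.  Stays in
    ``[floor, ceiling]`` for ``s0`` in that interval.
    """
    if not params.enabled:
        return np.ones(len(states))
    dt_h = epoch_length_s / 3600.0
    a_rise = np.exp(-dt_h / params.tau_rise_h)
    a_decay = np.exp(-dt_h / params.tau_decay_h)
    s = np.empty(len(states))
    val = params.s0
    nrem = int(State.NREM)
    for t, st in enumerate(states):
        s[t] = val
        if st == nrem:
            val = params.floor + (val - params.floor) * a_decay
        else:
            val = params.ceiling + (val - params.ceiling) * a_rise
    return s


def _amplitude_spectra(config: SimConfig, freqs: np.ndarray
                       ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per state: (non-delta amplitude spectrum, delta-component spectrum).

    The delta part (components centered at or below ``delta_hi_hz``)
    of the NREM signature is returned separately so the homeostatic
    process can scale it per epoch.
    """
    out = {}
    delta_hi = config.homeostasis.delta_hi_hz
    with np.errstate(divide="ignore"):
        one_over_sqrt_f = np.where(freqs > 0, 1.0 / np.sqrt(
            np.maximum(freqs, 0.25)), 0.0)
    for state, sig in config.spectral_signature.items():
        base = sig.background * one_over_sqrt_f
        base[freqs == 0] = 0.0
        delta_part = np.zeros_like(freqs)
        for comp in sig.components:
            sigma = comp.bandwidth_hz / 2.355  # FWHM -> std
            bump = comp.amplitude * np.exp(
                -0.5 * ((freqs - comp.center_hz) / sigma) ** 2)
            if state == State.NREM and comp.center_hz <= delta_hi:
                delta_part = delta_part + bump
            else:
                base = base + bump
        out[int(state)] = (base, delta_part)
    return out


def simulate_signals(hypnogram: Hypnogram, config: SimConfig
                     ) -> SignalRecording:
    """Synthesize EEG (two derivations) and EMG for a hypnogram.

    Each 4-s epoch of EEG is an independent Gaussian realization of the
    state's amplitude spectrum (random phases in the frequency domain),
    with the NREM delta component scaled by the homeostatic process.
    The two EEG channels share spectra but are independent realizations,
    standing in for the frontal/parietal derivations.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    n_epochs = len(hypnogram)
    n = config.samples_per_epoch
    n_rfft = n // 2 + 1
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sampling_rate_hz)
    spectra = _amplitude_spectra(config, freqs)

    s_proc = homeostatic_process(hypnogram.states, config.homeostasis,
                                 config.epoch_length_s)

    # Per-epoch target amplitude spectrum, (n_epochs, n_rfft).
    amp = np.empty((n_epochs, n_rfft))
    states = hypnogram.states
    for code, (base, delta_part) in spectra.items():
        m = states == code
        if not m.any():
            continue
        amp[m] = base[None, :] + s_proc[m, None] * delta_part[None, :]

    rng = np.random.default_rng(config.seed + 1)

    def _realize(target_amp: np.ndarray) -> np.ndarray:
        zr = rng.standard_normal((n_epochs, n_rfft))
        zi = rng.standard_normal((n_epochs, n_rfft))
        coefs = (target_amp * (n / 2.0)) * (zr + 1j * zi) / np.sqrt(2.0)
        coefs[:, 0] = 0.0
        coefs[:, -1] = coefs[:, -1].real * np.sqrt(2.0)
        return np.fft.irfft(coefs, n=n, axis=1).reshape(-1)

    # Artifact epochs: broadband high-amplitude transient added on top.
    art_amp = np.zeros((n_epochs, 1))
    art_amp[hypnogram.artifact, 0] = config.artifact_amplitude
    eeg1 = _realize(amp + art_amp)
    eeg2 = _realize(amp + art_amp)

    emg_level = np.empty(n_epochs)
    for state, level in config.emg_amplitude.items():
        emg_level[states == int(state)] = level
    emg = (rng.standard_normal((n_epochs, n)) * emg_level[:, None]
           ).reshape(-1)

    return SignalRecording(
        channels={"EEG1": eeg1, "EEG2": eeg2, "EMG": emg},
        sampling_rate_hz=config.sampling_rate_hz,
        start_zt_s=hypnogram.start_zt_s,
        epoch_length_s=config.epoch_length_s,
    )


# ---------------------------------------------------------------------
# Study builder
# ---------------------------------------------------------------------

@dataclass
class AnimalRecordings:
    """Paired baseline/recovery data for one simulated animal."""

    animal_id: str
    line: str
    seed: int
    baseline_hypnogram: Hypnogram
    recovery_hypnogram: Hypnogram
    baseline_recording: SignalRecording | None = None
    recovery_recording: SignalRecording | None = None


def iter_study(line: LineArchetype | str, n_animals: int, seed: int,
               signals: bool = True,
               base_config: SimConfig | None = None):
    """Lazily simulate a cohort: per animal, a 48-h session (free day 1,
    6-h forced wake + 18-h recovery on day 2) split into paired 24-h
    baseline and recovery halves with ground-truth hypnograms.

    Yields one :class:`AnimalRecordings` at a time so a full study with
    signals never needs to reside in memory at once (a single animal's
    two days of 3-channel 64-Hz signal is ~0.25 GB).  ``signals=False``
    skips EEG/EMG synthesis when only hypnograms are needed.  Each
    animal gets an independent seed derived from ``seed``.
    """
    if n_animals < 1:
        raise ConfigurationError("n_animals must be >= 1")
    arch = archetype(line) if isinstance(line, str) else line
    cfg = arch.apply(base_config)
    seeder = np.random.default_rng(seed)
    animal_seeds = seeder.integers(0, 2**31 - 1, size=n_animals)

    epochs_per_day = int(round(24 * 3600 / cfg.epoch_length_s))
    for i, aseed in enumerate(animal_seeds):
        acfg = cfg.replace(n_hours=48.0, seed=int(aseed))
        hyp = simulate_hypnogram(acfg, protocol="sd_recovery")
        base_h = hyp.slice(0, epochs_per_day)
        rec_h = hyp.slice(epochs_per_day, 2 * epochs_per_day)
        rec_h.start_zt_s = 0.0  # day 2 restarts at ZT0 (lights-on)
        base_r = rec_r = None
        if signals:
            full = simulate_signals(hyp, acfg)
            base_r = full.slice_epochs(0, epochs_per_day,
                                       day_label="baseline")
            rec_r = full.slice_epochs(epochs_per_day, 2 * epochs_per_day,
                                      day_label="recovery")
            rec_r.start_zt_s = 0.0
            del full
        yield AnimalRecordings(
            animal_id=f"{arch.name.lower()}{i:02d}",
            line=arch.name, seed=int(aseed),
            baseline_hypnogram=base_h, recovery_hypnogram=rec_h,
            baseline_recording=base_r, recovery_recording=rec_r,
        )


def make_study(line: LineArchetype | str, n_animals: int, seed: int,
               signals: bool = True,
               base_config: SimConfig | None = None
               ) -> list[AnimalRecordings]:
    """Materialized :func:`iter_study`.  With ``signals=True`` this holds
    every animal's signals in memory at once; prefer :func:`iter_study`
    for cohorts larger than a few animals."""
    return list(iter_study(line, n_animals, seed, signals=signals,
                           base_config=base_config))
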