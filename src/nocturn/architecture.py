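"""Hypnogram architecture: bouts, transitions, state amounts, light/dark
amplitudes, and consolidated-sleep latency.

Conventions (fixed and documented rather than configurable where the
field's usage varies):

* A *bout* is a maximal run of identical state.  Metrics are computed
  per 12-h light/dark interval; a run spanning the LD boundary
  contributes a clipped bout to each side.
* Transitions are counted over adjacent epoch pairs with differing
  states; a pair straddling an interval boundary is credited to the
  interval containing the second epoch.
* Latency to NREM (or REM) sleep is the time from a reference — lights
  on, or the end of sleep deprivation — to the start of the first
  consolidated episode: a window that starts and ends with the target
  state, spans at least 15 epochs, and contains at most 6 non-target
  epochs.  The span reading of "lasting at least 15 epochs" is the
  default; ``rule="net"`` instead requires 15 target epochs net of
  interruptions.
* Artifact-flagged epochs count as their best-guess state by default
  (``artifact_policy="as_state"``); ``"exclude"`` removes them, breaking
  runs and contributing no transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Hypnogram, State, SCORABLE
from .errors import AlignmentError

__all__ = [
    "Bout",
    "ArchitectureSummary",
    "detect_bouts",
    "count_transitions",
    "state_amounts",
    "ld_amplitude",
    "sleep_latency",
    "summarize_architecture",
    "TRANSITION_PAIRS",
]

#: The six ordered state pairs counted as transitions.
TRANSITION_PAIRS = tuple((a, b) for a in SCORABLE for b in SCORABLE if a != b)

_EXCLUDED = -1  # sentinel for artifact-excluded epochs


@dataclass(frozen=True)
class Bout:
    state: State
    start_epoch: int
    length_epochs: int
    zt_start_s: float


def _effective_states(hypnogram: Hypnogram, artifact_policy: str
                      ) -> np.ndarray:
    s = hypnogram.states.astype(np.int64)
    if artifact_policy == "as_state":
        return s
    if artifact_policy == "exclude":
        s = s.copy()
        s[hypnogram.artifact] = _EXCLUDED
        return s
    raise ValueError(f"unknown artifact_policy {artifact_policy!r}")


def _interval_segments(hypnogram: Hypnogram, interval: str | None
                       ) -> list[tuple[int, int]]:
    """Contiguous epoch ranges [start, stop) belonging to the interval."""
    n = len(hypnogram)
    if interval is None:
        return [(0, n)]
    if interval not in ("light", "dark"):
        raise ValueError(f"interval must be 'light', 'dark', or None")
    want = hypnogram.light_mask() if interval == "light" \
        else ~hypnogram.light_mask()
    if not want.any():
        return []
    edges = np.flatnonzero(np.diff(want.astype(np.int8)) != 0) + 1
    bounds = np.concatenate([[0], edges, [n]])
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])
            if want[a]]


def detect_bouts(hypnogram: Hypnogram, interval: str | None = None,
                 artifact_policy: str = "as_state") -> list[Bout]:
    """Maximal runs of identical state, clipped to the interval."""
    s = _effective_states(hypnogram, artifact_policy)
    out: list[Bout] = []
    for a, b in _interval_segments(hypnogram, interval):
        seg = s[a:b]
        if seg.size == 0:
            continue
        changes = np.flatnonzero(np.diff(seg) != 0) + 1
        starts = np.concatenate([[0], changes])
        stops = np.concatenate([changes, [seg.size]])
        for st, sp in zip(starts, stops):
            if seg[st] == _EXCLUDED:
                continue
            out.append(Bout(
                state=State(int(seg[st])),
                start_epoch=int(a + st),
                length_epochs=int(sp - st),
                zt_start_s=float(hypnogram.start_zt_s
                                 + (a + st) * hypnogram.epoch_length_s),
            ))
    return out


def count_transitions(hypnogram: Hypnogram, interval: str | None = None,
                      artifact_policy: str = "as_state"
                      ) -> dict[tuple[State, State], int]:
    """Counts of the six ordered transitions within the interval.

    A pair ``(i, i+1)`` belongs to the interval containing epoch
    ``i + 1``.
    """
    s = _effective_states(hypnogram, artifact_policy)
    n = s.size
    counts = {pair: 0 for pair in TRANSITION_PAIRS}
    if n < 2:
        return counts
    frm, to = s[:-1], s[1:]
    keep = (frm != to) & (frm != _EXCLUDED) & (to != _EXCLUDED)
    if interval is not None:
        want = hypnogram.light_mask() if interval == "light" \
            else ~hypnogram.light_mask()
        keep &= want[1:]
    codes = frm[keep] * 4 + to[keep]
    binned = np.bincount(codes, minlength=16)
    for a, b in TRANSITION_PAIRS:
        counts[(a, b)] = int(binned[int(a) * 4 + int(b)])
    return counts


def state_amounts(hypnogram: Hypnogram, bin_h: float = 2.0,
                  artifact_policy: str = "as_state") -> pd.DataFrame:
    """Percent time per state per ZT bin (columns WAKE/NREM/REM, plus
    ``excluded`` when artifacts are excluded).

    Denominator is all epochs in the bin, so per bin the state
    percentages (plus the excluded fraction) sum to 100.
    """
    s = _effective_states(hypnogram, artifact_policy)
    zt_h = hypnogram.zt_s() / 3600.0
    bins = np.floor((zt_h - zt_h[0]) / bin_h).astype(int)
    n_bins = int(bins.max()) + 1
    denom = np.bincount(bins, minlength=n_bins).astype(float)
    data = {}
    for state in SCORABLE:
        cnt = np.bincount(bins[s == int(state)], minlength=n_bins)
        data[state.name] = 100.0 * cnt / denom
    cnt = np.bincount(bins[s == _EXCLUDED], minlength=n_bins)
    data["excluded"] = 100.0 * cnt / denom
    index = zt_h[0] + np.arange(n_bins) * bin_h
    return pd.DataFrame(data, index=pd.Index(index, name="zt_h"))


def _interval_percentages(hypnogram: Hypnogram, artifact_policy: str
                          ) -> pd.DataFrame:
    s = _effective_states(hypnogram, artifact_policy)
    light = hypnogram.light_mask()
    rows = {}
    for name, mask in (("light", light), ("dark", ~light)):
        denom = float(mask.sum())
        rows[name] = {
            st.name: (100.0 * np.count_nonzero(s[mask] == int(st)) / denom
                      if denom else np.nan)
            for st in SCORABLE
        }
        rows[name]["excluded"] = (
            100.0 * np.count_nonzero(s[mask] == _EXCLUDED) / denom
            if denom else np.nan)
    return pd.DataFrame(rows).T


def ld_amplitude(percent_time: pd.DataFrame) -> pd.Series:
    """Light-minus-dark difference in percent time, per state — the
    circadian-amplitude index.  Input is the light/dark × state table
    from :func:`summarize_architecture` (or equivalent)."""
    return percent_time.loc["light"] - percent_time.loc["dark"]


def sleep_latency(hypnogram: Hypnogram, reference_zt_s: float,
                  target: State = State.NREM, min_span_epochs: int = 15,
                  allowance_epochs: int = 6, rule: str = "span",
                  artifact_policy: str = "as_state") -> float:
    """Minutes from the reference to the first consolidated episode of
    the target state, or NaN when none occurs.

    An episode qualifies when it starts and ends with a target epoch and
    either spans ≥ ``min_span_epochs`` with ≤ ``allowance_epochs``
    non-target epochs inside (``rule="span"``, default) or contains
    ≥ ``min_span_epochs`` target epochs with the same allowance
    (``rule="net"``).
    """
    if rule not in ("span", "net"):
        raise ValueError(f"unknown latency rule {rule!r}")
    offset = (reference_zt_s - hypnogram.start_zt_s) / hypnogram.epoch_length_s
    ref_epoch = int(round(offset))
    if not 0 <= ref_epoch <= len(hypnogram):
        raise AlignmentError(
            f"reference ZT {reference_zt_s} s lies outside the hypnogram")
    s = _effective_states(hypnogram, artifact_policy)[ref_epoch:]
    is_t = s == int(target)
    for start in np.flatnonzero(is_t):
        bad = 0
        for j in range(start, s.size):
            if not is_t[j]:
                bad += 1
                if bad > allowance_epochs:
                    break
                continue
            span_ok = (j - start + 1 >= min_span_epochs if rule == "span"
                       else j - start + 1 - bad >= min_span_epochs)
            if span_ok:
                return start * hypnogram.epoch_length_s / 60.0
    return float("nan")


@dataclass
class ArchitectureSummary:
    """Per-animal architecture metrics, organized per 12-h interval."""

    bout_counts: pd.DataFrame        # interval × state, bouts / 12 h
    bout_durations: pd.DataFrame     # interval × state, min / bout
    percent_time: pd.DataFrame       # interval × state (+ excluded), %
    transitions: pd.DataFrame        # interval × ordered-pair counts
    latency_nrem_min: float
    latency_rem_min: float
    ld_amplitude: pd.Series          # per state, light − dark, %


def summarize_architecture(hypnogram: Hypnogram,
                           artifact_policy: str = "as_state",
                           latency_reference_zt_s: float = 0.0
                           ) -> ArchitectureSummary:
    """Compute the full per-animal architecture table for one 24-h day."""
    counts, durations, trans = {}, {}, {}
    for interval in ("light", "dark"):
        bouts = detect_bouts(hypnogram, interval, artifact_policy)
        tcounts = count_transitions(hypnogram, interval, artifact_policy)
        counts[interval] = {
            st.name: sum(1 for b in bouts if b.state == st)
            for st in SCORABLE}
        durations[interval] = {
            st.name: (np.mean([b.length_epochs for b in bouts
                               if b.state == st])
                      * hypnogram.epoch_length_s / 60.0
                      if any(b.state == st for b in bouts) else np.nan)
            for st in SCORABLE}
        trans[interval] = {f"{a.name}->{b.name}": c
                           for (a, b), c in tcounts.items()}
    pct = _interval_percentages(hypnogram, artifact_policy)
    return ArchitectureSummary(
        bout_counts=pd.DataFrame(counts).T,
        bout_durations=pd.DataFrame(durations).T,
        percent_time=pct,
        transitions=pd.DataFrame(trans).T,
        latency_nrem_min=sleep_latency(hypnogram, latency_reference_zt_s,
                                       State.NREM,
                                       artifact_policy=artifact_policy),
        latency_rem_min=sleep_latency(hypnogram, latency_reference_zt_s,
                                      State.REM,
                                      artifact_policy=artifact_policy),
        ld_amplitude=ld_amplitude(pct[[s.name for s in SCORABLE]]),
    )
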