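"""Independent brute-force oracles for hypnogram analytics.

Deliberately written with different primitives than the package
(itertools.groupby, pair Counters, exhaustive window scans vs the
numpy run-length / histogram implementations) so the two routes share
no code.
"""

import itertools
from collections import Counter

import numpy as np

from nocturn.architecture import TRANSITION_PAIRS
from nocturn.core import State


def random_hypnogram(rng, n, p_stay=None):
    """Random state sequence with realistic bout structure: per-draw
    persistence between 0.60 and 0.98."""
    if p_stay is None:
        p_stay = rng.uniform(0.60, 0.98)
    states = np.empty(n, dtype=np.int8)
    states[0] = rng.integers(0, 3)
    stay = rng.random(n - 1) < p_stay
    jumps = rng.integers(1, 3, size=n - 1)  # +1 or +2 mod 3
    for i in range(1, n):
        states[i] = states[i - 1] if stay[i - 1] else \
            (states[i - 1] + jumps[i - 1]) % 3
    return states


def rle_oracle(states):
    """Run-length encoding via itertools.groupby:
    [(state, start, length), ...]."""
    out = []
    pos = 0
    for key, grp in itertools.groupby(states.tolist()):
        length = sum(1 for _ in grp)
        out.append((int(key), pos, length))
        pos += length
    return out


def transition_oracle(states):
    """Ordered-pair counts via a Counter over adjacent pairs."""
    c = Counter(zip(states.tolist(), states.tolist()[1:]))
    return {(a, b): c.get((int(a), int(b)), 0) for a, b in TRANSITION_PAIRS}


def latency_oracle(states, target, min_span=15, allow=6, rule="span",
                   epoch_length_s=4.0):
    """Exhaustive scan over all windows [s, e]: earliest start of a
    window bounded by target epochs with at most ``allow`` non-target
    epochs and span (or net target count) >= ``min_span``.  Minutes."""
    n = len(states)
    is_t = states == target
    for s in range(n):
        if not is_t[s]:
            continue
        for e in range(s, n):
            span = e - s + 1
            bad = span - int(is_t[s:e + 1].sum())
            if bad > allow:
                break
            if not is_t[e]:
                continue
            size = span if rule == "span" else span - bad
            if size >= min_span:
                return s * epoch_length_s / 60.0
    return float("nan")
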