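"""Brute-force reference implementations used only for testing.

Every function here is written as a naive, sample-by-sample loop that is
easy to verify by eye, independent of the vectorized package code paths.
"""

from __future__ import annotations

import math
from collections import Counter


def turns_oracle(x, threshold):
    """Greedy Willison-turn acceptance, naive per-sample state machine.

    Tracks the running extremum since the last accepted turn; accepts it
    when the trace reverses away by at least the threshold. The first
    turn must lie at least one threshold from the first sample.
    """
    x = [float(v) for v in x]
    x0 = x[0]
    turns = []
    direction = 0  # +1 seeking a maximum, -1 seeking a minimum
    mx = mn = x[0]
    mx_i = mn_i = 0
    for i in range(1, len(x)):
        v = x[i]
        if v > mx:
            mx, mx_i = v, i
        if v < mn:
            mn, mn_i = v, i
        if direction >= 0 and mx - v >= threshold and (direction == 1 or mx - x0 >= threshold):
            turns.append((mx_i, mx))
            direction = -1
            mn, mn_i = v, i
        elif direction <= 0 and v - mn >= threshold and (direction == -1 or x0 - mn >= threshold):
            turns.append((mn_i, mn))
            direction = 1
            mx, mx_i = v, i
    return turns


def willison_rate_oracle(x, threshold, fs):
    count = 0
    for k in range(len(x) - 1):
        if abs(x[k + 1] - x[k]) > threshold:
            count += 1
    return count * fs / len(x)


def energy_oracle(x, fs):
    total_uv = 0.0
    for v in x:
        total_uv += abs(v)
    duration = len(x) / fs
    return (total_uv / 1000.0) / duration


def permutation_entropy_oracle(x, order_n, lag_tau):
    """Exhaustive window enumeration and rank-pattern tally.

    Ranks are assigned by sorting (value, position) pairs, so tied values
    rank in temporal order.
    """
    x = [float(v) for v in x]
    span = lag_tau * (order_n - 1)
    patterns = Counter()
    for t in range(len(x) - span):
        window = [x[t + j * lag_tau] for j in range(order_n)]
        order = tuple(sorted(range(order_n), key=lambda j: (window[j], j)))
        patterns[order] += 1
    total = sum(patterns.values())
    h = 0.0
    for c in patterns.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def confusion_oracle(pairs):
    tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for true, pred in pairs:
        if true == "neuropathic" and pred == "neuropathic":
            tally["tp"] += 1
        elif true == "neuropathic":
            tally["fn"] += 1
        elif pred == "neuropathic":
            tally["fp"] += 1
        else:
            tally["tn"] += 1
    return tally
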