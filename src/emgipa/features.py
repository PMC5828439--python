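"""Quantitative features of the needle-EMG interference pattern.

The classical turns-amplitude (Willison) measures, the Willison rate,
the peak-ratio, signal energy, and permutation entropy. All amplitudes
are µV internally; energy is reported in mV/s as is conventional for
interference-pattern summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .recording import EMGRecording

#: Classical turn-detection threshold (µV).
DEFAULT_TURN_THRESHOLD_UV = 100.0


@dataclass(frozen=True)
class TurnSequence:
    """Accepted turns of one recording at a given threshold.

    A turn is a direction reversal of the trace that differs by at least
    ``threshold`` µV from the adjacent accepted turns, so consecutive turn
    amplitudes alternate between local maxima and minima and differ by at
    least the threshold.
    """

    threshold: float
    indices: np.ndarray = field(repr=False)
    amplitudes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        amp = np.asarray(self.amplitudes, dtype=float)
        if idx.shape != amp.shape:
            raise ValueError("indices and amplitudes must have equal length")
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("turn indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class PEConfig:
    """Permutation-entropy parameters.

    order_n
        Length of the ordinal pattern (number of lagged samples per
        window); the entropy is bounded by log2(order_n!) bits.
    lag_tau
        Lag between the samples of one window; the window start still
        advances by one sample.
    normalize
        Divide the entropy by (order_n - 1) to make orders comparable.
    """

    order_n: int = 3
    lag_tau: int = 2
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.order_n < 2:
            raise ValueError("order_n must be >= 2")
        if self.lag_tau < 1:
            raise ValueError("lag_tau must be >= 1")
        if self.order_n > 12:
            raise ValueError("order_n > 12 makes n! patterns impractical")


#: Field order doubles as the canonical feature-column order in tables.
FEATURE_NAMES = (
    "turns_per_s",
    "mean_interspike_amplitude",
    "energy",
    "permutation_entropy",
    "willison_rate",
    "peak_ratio",
)


@dataclass(frozen=True)
class FeatureVector:
    """Per-subject scalar features of the interference pattern.

    Units: turns_per_s in 1/s; mean_interspike_amplitude in µV; energy in
    mV/s; permutation_entropy in bits (or bits per symbol transition when
    normalized); willison_rate in 1/s; peak_ratio in 1/(s·µV). Features
    that are undefined for a recording (fewer than two turns) are NaN and
    flagged, never silently zero.
    """

    turns_per_s: float
    mean_interspike_amplitude: float
    energy: float
    permutation_entropy: float
    willison_rate: float
    peak_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def is_complete(self) -> bool:
        """True when every feature is defined (no NaN)."""
        return all(math.isfinite(v) for v in self.as_dict().values())


# ---------------------------------------------------------------------------
# turns-amplitude analysis
# ---------------------------------------------------------------------------

def _candidate_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices/values of local extrema of ``x`` plus both endpoints.

    Plateaus contribute their first sample. The turn detector's hysteresis
    pass depends only on this reduced sequence, because running extrema and
    threshold crossings are attained at local extrema of the trace.
    """
    d = np.diff(x)
    nz = np.flatnonzero(d != 0)
    if nz.size == 0:
        return np.array([0, x.size - 1]), x[[0, -1]]
    s = np.sign(d[nz])
    rev = np.flatnonzero(s[1:] != s[:-1])
    # extremum sits at the end of the run that precedes the sign change
    idx = nz[rev] + 1
    idx = np.concatenate(([0], idx, [x.size - 1]))
    return idx, x[idx]


def detect_turns(
    rec: EMGRecording, threshold: float = DEFAULT_TURN_THRESHOLD_UV
) -> TurnSequence:
    """Detect turns with the Willison criterion.

    Greedy single-pass hysteresis: track the running extremum since the
    last accepted turn; when the trace reverses away from it by at least
    ``threshold`` µV, accept that extremum as a turn. The first turn must
    additionally lie at least ``threshold`` µV from the first sample.
    Because acceptance already requires a full threshold excursion, the
    accepted turns alternate max/min and consecutive turn amplitudes
    differ by at least the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive (µV)")
    x = rec.samples
    idx, val = _candidate_extrema(x)
    x0 = x[0]

    turn_i: list[int] = []
    turn_v: list[float] = []
    direction = 0  # +1: seeking a maximum, -1: seeking a minimum
    mx_i = mn_i = int(idx[0])
    mx = mn = float(val[0])
    for i, v in zip(idx[1:], val[1:]):
        if v > mx:
            mx, mx_i = v, int(i)
        if v < mn:
            mn, mn_i = v, int(i)
        if direction >= 0 and mx - v >= threshold and (direction == 1 or mx - x0 >= threshold):
            turn_i.append(mx_i)
            turn_v.append(mx)
            direction = -1
            mn, mn_i = v, int(i)
        elif direction <= 0 and v - mn >= threshold and (direction == -1 or x0 - mn >= threshold):
            turn_i.append(mn_i)
            turn_v.append(mn)
            direction = 1
            mx, mx_i = v, int(i)
    return TurnSequence(
        threshold=float(threshold),
        indices=np.asarray(turn_i, dtype=np.int64),
        amplitudes=np.asarray(turn_v, dtype=float),
    )


def turns_per_second(ts: TurnSequence, duration_s: float) -> float:
    """Number of accepted turns divided by the record duration."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return len(ts) / duration_s


def mean_interspike_amplitude(ts: TurnSequence) -> float:
    """Mean absolute amplitude between successive turns (µV).

    Undefined (NaN) when fewer than two turns were accepted; callers must
    treat NaN as a flagged missing feature.
    """
    if len(ts) < 2:
        return math.nan
    return float(np.mean(np.abs(np.diff(ts.amplitudes))))


def peak_ratio(turns_per_s: float, mean_amplitude_uv: float) -> float:
    """Turns per second divided by mean inter-turn amplitude (peak-ratio).

    Zero turns give 0; an undefined amplitude propagates NaN.
    """
    if turns_per_s == 0:
        return 0.0
    if not math.isfinite(mean_amplitude_uv):
        return math.nan
    if mean_amplitude_uv <= 0:
        raise ValueError("mean_amplitude_uv must be positive")
    return turns_per_s / mean_amplitude_uv


def willison_rate(
    rec: EMGRecording, threshold: float = DEFAULT_TURN_THRESHOLD_UV
) -> float:
    """Per-second count of successive-sample differences exceeding threshold.

    W = count{ |x(k+1) - x(k)| > threshold } / (Ts * N), with a strict
    comparison, distinct from the >= used by turn acceptance.
    """
    x = rec.samples
    count = int(np.count_nonzero(np.abs(np.diff(x)) > threshold))
    return count * rec.fs / x.size


def signal_energy(rec: EMGRecording) -> float:
    """Sum of absolute sample values per second, in mV/s.

    Samples are µV internally; the sum is converted to mV before dividing
    by the record duration.
    """
    return float(np.sum(np.abs(rec.samples))) / 1000.0 / rec.duration_s


# ---------------------------------------------------------------------------
# permutation entropy
# ---------------------------------------------------------------------------

def _ordinal_pattern_counts(x: np.ndarray, order_n: int, lag_tau: int) -> np.ndarray:
    """Counts of observed ordinal patterns over all sliding windows.

    Each window (x[t], x[t+τ], ..., x[t+(n-1)τ]) is mapped to the
    permutation that sorts it; ties rank by temporal order (stable sort),
    so equal values keep their original succession.
    """
    n, tau = order_n, lag_tau
    span = tau * (n - 1)
    m = x.size - span
    if m < 1:
        raise ValueError(
            f"signal of length {x.size} too short for one window of order {n} at lag {tau}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, span + 1)[:, ::tau]
    patterns = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation as an integer in a mixed-radix (factorial-free) code
    code = np.zeros(m, dtype=np.int64)
    for j in range(n):
        code = code * n + patterns[:, j]
    _, counts = np.unique(code, return_counts=True)
    return counts


def permutation_entropy(rec: EMGRecording, cfg: PEConfig = PEConfig()) -> float:
    """Permutation entropy of the trace, in bits.

    Shannon entropy of the distribution of rank-order patterns of lagged
    sample windows: H = -Σ p(π) log2 p(π). Rank-based, hence invariant
    under strictly monotone amplitude transforms; 0 <= H <= log2(n!).
    With ``cfg.normalize`` the value is H / (n - 1).
    """
    counts = _ordinal_pattern_counts(rec.samples, cfg.order_n, cfg.lag_tau)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log2(p)))
    if cfg.normalize:
        h /= cfg.order_n - 1
    return h


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def extract_features(
    rec: EMGRecording,
    threshold: float = DEFAULT_TURN_THRESHOLD_UV,
    cfg: PEConfig = PEConfig(),
) -> FeatureVector:
    """Compute the full feature vector of one recording.

    Deterministic; composes the individual feature functions. An
    undefined mean interspike amplitude (fewer than two turns) yields NaN
    for that feature and for the peak ratio.
    """
    ts = detect_turns(rec, threshold)
    tps = turns_per_second(ts, rec.duration_s)
    mia = mean_interspike_amplitude(ts)
    return FeatureVector(
        turns_per_s=tps,
        mean_interspike_amplitude=mia,
        energy=signal_energy(rec),
        permutation_entropy=permutation_entropy(rec, cfg),
        willison_rate=willison_rate(rec, threshold),
        peak_ratio=peak_ratio(tps, mia),
    )


def extract_cohort(
    recordings,
    threshold: float = DEFAULT_TURN_THRESHOLD_UV,
    cfg: PEConfig = PEConfig(),
):
    """Feature table (one row per recording) for a sequence of recordings."""
    import pandas as pd

    rows = []
    for rec in recordings:
        fv = extract_features(rec, threshold=threshold, cfg=cfg)
        rows.append({"subject_id": rec.subject_id, "label": rec.label, **fv.as_dict()})
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])
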