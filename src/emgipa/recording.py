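"""The in-memory representation of a single-channel intramuscular EMG trace."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default sampling frequency (Hz) used when a container carries none.
DEFAULT_FS = 12_500.0

#: Allowed class labels for a subject.
LABELS = ("normal", "neuropathic", "unknown")


@dataclass(frozen=True)
class EMGRecording:
    """One subject's sampled EMG trace.

    Parameters
    ----------
    subject_id
        Unique identifier of the subject/recording.
    samples
        Sampled amplitudes in microvolts (µV). At least two samples,
        all finite.
    fs
        Sampling frequency in Hz (> 0).
    label
        Diagnostic class: ``"normal"``, ``"neuropathic"`` or ``"unknown"``.
    """

    subject_id: str
    samples: np.ndarray = field(repr=False)
    fs: float = DEFAULT_FS
    label: str = "unknown"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError(
                f"recording {self.subject_id!r} has {samples.size} samples; need at least 2"
            )
        if not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(
                f"recording {self.subject_id!r} contains a non-finite sample at index {bad}"
            )
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError(f"sampling frequency must be positive and finite, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs
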