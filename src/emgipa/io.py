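"""Readers and writers for EMG signals and tabular feature artifacts.

Raw signals travel as one-sample-per-line CSV (µV), WAV, or EDF.  The
canonical amplitude unit is µV everywhere inside the package; WAV and EDF
sample values are mapped to µV on load.  Cohort feature tables are plain
RFC-4180 CSV with a header row.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .recording import DEFAULT_FS, EMGRecording

#: Columns every cohort table must carry in addition to the feature columns.
ID_COLUMNS = ("subject_id", "label")


# ---------------------------------------------------------------------------
# raw signal I/O
# ---------------------------------------------------------------------------

def read_recording_csv(
    path: str | os.PathLike,
    fs: float = DEFAULT_FS,
    label: str = "unknown",
    subject_id: str | None = None,
) -> EMGRecording:
    """Load a recording from a one-numeric-value-per-line CSV file.

    Values are interpreted as amplitudes in µV. A malformed line raises a
    ``ValueError`` naming its (1-based) line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such signal file: {path}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric sample {text!r} on line {lineno}"
                ) from None
    if len(values) < 2:
        raise ValueError(f"{path}: found {len(values)} samples; need at least 2")
    return EMGRecording(
        subject_id=subject_id or path.stem,
        samples=np.asarray(values, dtype=float),
        fs=fs,
        label=label,
    )


def write_recording_csv(rec: EMGRecording, path: str | os.PathLike) -> None:
    """Write a recording as one µV value per line (full double precision)."""
    np.savetxt(path, rec.samples, fmt="%.17g")


def read_recording_wav(
    path: str | os.PathLike,
    label: str = "unknown",
    scale_uv_per_count: float = 1.0,
    subject_id: str | None = None,
) -> EMGRecording:
    """Load a recording from a WAV file.

    The sampling frequency comes from the WAV header. WAV carries no
    physical units: sample values (integer PCM counts, or float values)
    are multiplied by ``scale_uv_per_count`` to obtain µV; the default
    treats one count as 1 µV.
    """
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected a single-channel WAV, got shape {data.shape}")
    samples = np.asarray(data, dtype=float) * float(scale_uv_per_count)
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path}: WAV contains non-finite samples")
    return EMGRecording(
        subject_id=subject_id or path.stem,
        samples=samples,
        fs=float(fs),
        label=label,
    )


def write_recording_wav(rec: EMGRecording, path: str | os.PathLike) -> None:
    """Write a recording as a 64-bit float WAV (1 unit = 1 µV, lossless)."""
    wavfile.write(path, int(round(rec.fs)), rec.samples.astype(np.float64))


def read_recording_edf(
    path: str | os.PathLike,
    channel: str,
    label: str = "unknown",
    subject_id: str | None = None,
) -> EMGRecording:
    """Load one channel of an EDF file as an EMG recording.

    EDF stores physical units per channel; values are converted to µV
    assuming the channel's physical dimension is volts-based (MNE returns
    volts internally). A missing channel raises a ``ValueError`` listing
    the channels present.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    if channel not in raw.ch_names:
        raise ValueError(
            f"{path}: channel {channel!r} not found; available channels: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0]
    samples = np.asarray(data, dtype=float) * 1e6  # V -> µV
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path}: EDF channel {channel!r} contains non-finite samples")
    return EMGRecording(
        subject_id=subject_id or path.stem,
        samples=samples,
        fs=float(raw.info["sfreq"]),
        label=label,
    )


# ---------------------------------------------------------------------------
# cohort feature tables
# ---------------------------------------------------------------------------

def write_cohort_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cohort feature table as CSV with a header row.

    The table must carry ``subject_id`` and ``label`` columns plus one
    column per feature; the round-trip through :func:`read_cohort_table`
    is lossless to double precision.
    """
    _validate_cohort_table(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort feature table written by :func:`write_cohort_table`."""
    table = pd.read_csv(path)
    _validate_cohort_table(table)
    return table


def _validate_cohort_table(table: pd.DataFrame) -> None:
    if len(table) == 0:
        raise ValueError("cohort table is empty")
    for col in ID_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id values in cohort table: {sorted(set(dup))}")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a cohort table (everything non-ID)."""
    return [c for c in table.columns if c not in ID_COLUMNS]


def write_manifest(rows: Sequence[dict], path: str | os.PathLike) -> None:
    """Write a simulation manifest (subject_id, label, seed, file) as CSV."""
    pd.DataFrame(list(rows)).to_csv(path, index=False)
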