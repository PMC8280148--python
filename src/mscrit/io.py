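"""Reading and writing recordings and result tables.

Two input routes: delimited text matrices (rows = channels, optional header
row of channel labels; the sampling rate must be supplied) and EDF biosignal
files (rate and labels from the header, via :mod:`mne`, which is an optional
dependency).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import Recording

__all__ = [
    "load_text_recording",
    "save_text_recording",
    "load_edf_recording",
    "load_recording",
]


def load_text_recording(
    path: str | Path,
    sampling_rate: float,
    delimiter: str | None = None,
) -> Recording:
    """Read a channels-x-samples delimited text matrix.

    A first row that fails numeric parsing is taken as channel labels.
    """
    path = Path(path)
    delimiter = delimiter or ("," if path.suffix.lower() == ".csv" else None)
    with open(path) as fh:
        first = fh.readline()
    tokens = first.split(delimiter)
    labels: tuple[str, ...] = ()
    skip = 0
    try:
        [float(t) for t in tokens]
    except ValueError:
        labels = tuple(t.strip() for t in tokens if t.strip())
        skip = 1
    data = np.loadtxt(path, delimiter=delimiter, skiprows=skip, ndmin=2)
    if labels and len(labels) == data.shape[1] and len(labels) != data.shape[0]:
        # labels ran along columns: the matrix was written samples-major
        data = data.T
    return Recording(data, sampling_rate, labels)


def save_text_recording(rec: Recording, path: str | Path, delimiter: str = "\t") -> None:
    """Write a recording as a labeled channels-x-samples text matrix."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data.T, delimiter=delimiter, fmt="%.6g")


def load_edf_recording(path: str | Path) -> Recording:
    """Read an EDF file; sampling rate and channel names from its header."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), float(raw.info["sfreq"]), tuple(raw.ch_names))


def load_recording(
    path: str | Path, sampling_rate: float | None = None
) -> Recording:
    """Dispatch on file extension: .edf to the EDF reader, else text."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return load_edf_recording(path)
    if sampling_rate is None:
        raise ValueError("text input requires an explicit sampling_rate")
    return load_text_recording(path, sampling_rate)
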