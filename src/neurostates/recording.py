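"""Multichannel recording container, delimited-text I/O, and preprocessing steps.

A :class:`Recording` stores a channels x time matrix together with its
sampling rate, ordered channel labels and subject metadata.  The two
preprocessing operations offered here are the ones applied before state
segmentation: non-overlapping block averaging in time (e.g. 512 Hz recordings
averaged over every 100 samples, giving one sample every ~195 ms) and
restriction to a named channel subset (e.g. a frontal electrode cluster).

Filtering, re-referencing, ICA and artifact handling are upstream concerns
and are deliberately not implemented.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, RecordingFormatError

GROUPS = ("younger", "older", "unknown")


@dataclass
class ChannelRoster:
    """A named, ordered set of channel labels (e.g. ``frontal``)."""

    name: str
    labels: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if not self.labels:
            raise ValueError("roster labels must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"roster {self.name!r} contains duplicate labels")


@dataclass
class Recording:
    """Channels x time numeric matrix with sampling-rate and subject metadata.

    Parameters
    ----------
    data
        Real matrix of shape (n_channels, n_samples), arbitrary units.
    sampling_rate_hz
        Positive sampling rate.
    channel_labels
        One label per matrix row, in row order.
    subject_id, group
        Subject metadata; ``group`` is one of ``younger``/``older``/``unknown``
        (any other value is coerced to ``unknown`` and excluded from group
        contrasts downstream).
    """

    data: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    subject_id: str = "unknown"
    group: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x time matrix")
        if self.data.shape[0] < 2 or self.data.shape[1] < 2:
            raise ValueError(
                f"need >=2 channels and >=2 samples, got shape {self.data.shape}"
            )
        self.channel_labels = [str(x) for x in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise RecordingFormatError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} matrix rows"
            )
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise RecordingFormatError(
                f"non-finite value at channel {bad[0]}, sample {bad[1]}"
            )
        self.sampling_rate_hz = float(self.sampling_rate_hz)
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.group not in GROUPS:
            self.group = "unknown"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based grid)."""
        return np.arange(self.n_samples) / self.sampling_rate_hz


def write_recording(rec: Recording, matrix_path, sidecar_path=None) -> None:
    """Write a recording as a CSV matrix (rows = channels) plus JSON sidecar."""
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    np.savetxt(matrix_path, rec.data, delimiter=",", fmt="%.17g")
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
        "group": rec.group,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_recording(matrix_path, sidecar_path=None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    The matrix file is a delimited numeric table with one row per channel;
    the JSON sidecar declares sampling rate, channel labels and subject
    metadata.  Raises :class:`RecordingFormatError` on a row/label count
    mismatch and a parse error naming the offending cell for non-numeric
    content.
    """
    matrix_path = Path(matrix_path)
    if sidecar_path is None:
        sidecar_path = matrix_path.with_suffix(".json")
    try:
        sidecar = json.loads(Path(sidecar_path).read_text())
    except json.JSONDecodeError as exc:
        raise RecordingFormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}")
    sep = "\t" if matrix_path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(matrix_path, header=None, sep=sep, dtype=str, comment=None)
    try:
        data = raw.to_numpy(dtype=float)
    except ValueError:
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    float(raw.iat[i, j])
                except (TypeError, ValueError):
                    raise RecordingFormatError(
                        f"non-numeric cell at row {i}, column {j}: {raw.iat[i, j]!r}"
                    )
        raise
    labels = sidecar.get("channel_labels", [])
    if len(labels) != data.shape[0]:
        raise RecordingFormatError(
            f"sidecar declares {len(labels)} channels but matrix has "
            f"{data.shape[0]} rows"
        )
    return Recording(
        data=data,
        sampling_rate_hz=sidecar["sampling_rate_hz"],
        channel_labels=labels,
        subject_id=str(sidecar.get("subject_id", "unknown")),
        group=str(sidecar.get("group", "unknown")),
    )


def block_downsample(rec: Recording, block: int) -> Recording:
    """Average every ``block`` consecutive samples (non-overlapping).

    Each output sample is the arithmetic mean of one block of ``block``
    consecutive input samples per channel; the output sampling rate is the
    input rate divided by ``block``.  A trailing partial block is dropped so
    that every output sample is an equal-weight mean.
    """
    block = int(block)
    if block < 1:
        raise ValueError("block must be >= 1")
    if block > rec.n_samples:
        raise ValueError(
            f"block ({block}) exceeds sample count ({rec.n_samples})"
        )
    n_out = rec.n_samples // block
    trimmed = rec.data[:, : n_out * block]
    down = trimmed.reshape(rec.n_channels, n_out, block).mean(axis=2)
    return replace(
        rec, data=down, sampling_rate_hz=rec.sampling_rate_hz / block,
        channel_labels=list(rec.channel_labels),
    )


def select_channels(rec: Recording, roster: ChannelRoster) -> Recording:
    """Restrict a recording to the roster's channels, in roster order."""
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    for lab in roster.labels:
        if lab not in index:
            raise KeyError(f"channel {lab!r} not present in recording")
        rows.append(index[lab])
    return replace(
        rec, data=rec.data[rows, :], channel_labels=list(roster.labels),
    )


def roster_for(name: str, rec: Recording | None = None) -> ChannelRoster:
    """Resolve a builtin roster name, or load one from a JSON file path.

    ``"all"`` selects every channel of ``rec``.  ``"frontal"`` and
    ``"parietal"`` are example 10-10 system clusters for standard caps.  Any
    other value is treated as a path to a JSON file ``{"name":..,
    "labels": [..]}``.
    """
    if name == "all":
        if rec is None:
            raise ValueError("roster 'all' needs a recording to resolve against")
        return ChannelRoster("all", list(rec.channel_labels))
    if name in BUILTIN_ROSTERS:
        return ChannelRoster(name, list(BUILTIN_ROSTERS[name]))
    path = Path(name)
    if path.exists():
        spec = json.loads(path.read_text())
        return ChannelRoster(spec.get("name", path.stem), spec["labels"])
    raise ValueError(f"unknown roster {name!r}")


# Example anterior / posterior clusters in 10-10 nomenclature, for use with
# standard caps.  Synthetic cohorts use roster "all".
BUILTIN_ROSTERS: dict[str, list[str]] = {
    "frontal": [
        "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
        "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
        "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    ],
    "parietal": [
        "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
        "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
        "PO7", "PO3", "POz", "PO4", "PO8",
    ],
}


def recording_from_mne(raw, subject_id: str = "unknown", group: str = "unknown") -> Recording:
    """Adapt an ``mne.io.Raw`` object (e.g. BioSemi BDF/EDF) to a Recording.

    ``mne`` is an optional dependency; this function only touches the public
    Raw API (``get_data``, ``info``, ``ch_names``).
    """
    data = np.asarray(raw.get_data())
    return Recording(
        data=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        group=group,
    )


def read_raw_recording(path, subject_id: str = "unknown", group: str = "unknown") -> Recording:
    """Read a BioSemi BDF or EDF file via ``mne`` and emit a Recording."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading BDF/EDF requires the optional 'mne' extra") from exc
    path = Path(path)
    if path.suffix.lower() == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise RecordingFormatError(f"unsupported raw format: {path.suffix}")
    return recording_from_mne(raw, subject_id=subject_id, group=group)
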