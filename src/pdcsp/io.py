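"""Recordings, dataset manifests, and file readers/writers.

A :class:`Recording` is one subject/session: a ``ch x samples`` matrix of
channel time series plus its sampling rate and clinical metadata (group,
eyes state).  Datasets are described by a CSV manifest with columns
``file,subject_id,group,eyes,fs`` so that synthetic and real data flow
through the same entry point.

Amplitude units are carried through untouched: no microvolt conversion is
applied anywhere.  Everything downstream of the covariance normalisation is
scale-invariant except the amplitude-thresholded entropies, which operate on
whatever scale the input uses.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "Eyes",
    "Recording",
    "DatasetManifest",
    "read_matrix_recording",
    "write_matrix_recording",
    "read_standard_eeg",
    "load_dataset",
    "write_dataset",
]


class Group(str, enum.Enum):
    """Clinical group label."""

    PD_OFF = "PD_OFF"  # Parkinson's, off dopaminergic medication
    PD_ON = "PD_ON"    # Parkinson's, on medication
    HC = "HC"          # healthy control

    @classmethod
    def parse(cls, token: str) -> "Group":
        try:
            return cls(str(token).strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown group token {token!r}; expected one of "
                f"{[g.value for g in cls]}"
            ) from None


class Eyes(str, enum.Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, token: str) -> "Eyes":
        token = str(token).strip().upper()
        if token in ("", "NA", "NONE"):
            return cls.UNKNOWN
        try:
            return cls(token)
        except ValueError:
            raise ValueError(
                f"unknown eyes token {token!r}; expected OPEN/CLOSED/UNKNOWN"
            ) from None


@dataclass
class Recording:
    """One multichannel recording: ``data`` is channels x samples."""

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str = ""
    group: Group = Group.HC
    eyes: Eyes = Eyes.UNKNOWN

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be a 2-D channels x samples array")
        ch, n = self.data.shape
        if ch < 2:
            raise ValueError(f"need at least 2 channels for spatial filtering, got {ch}")
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(ch)]
        if len(self.channel_names) != ch:
            raise ValueError("channel_names length must equal channel count")
        if len(set(self.channel_names)) != ch:
            raise ValueError("channel_names must be unique")
        if not isinstance(self.group, Group):
            self.group = Group.parse(self.group)
        if not isinstance(self.eyes, Eyes):
            self.eyes = Eyes.parse(self.eyes)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class DatasetManifest:
    """Ordered list of (file, subject, group, eyes, fs) entries."""

    entries: list[dict]
    name: str = ""

    def groups(self) -> set[Group]:
        return {e["group"] for e in self.entries}


def read_matrix_recording(
    path: str | Path,
    fs: float,
    group: Group | str = Group.HC,
    eyes: Eyes | str = Eyes.UNKNOWN,
    subject_id: str = "",
) -> Recording:
    """Read a delimited text (or ``.npy``) matrix file, rows = channels.

    Values are taken exactly as stored; no scaling is applied.
    """
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        try:
            data = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric content in matrix file {path}: {exc}") from exc
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError(
            f"matrix file {path} must have >= 2 rows (channels), got shape {data.shape}"
        )
    return Recording(data=data, fs=float(fs), group=group, eyes=eyes, subject_id=subject_id)


def write_matrix_recording(path: str | Path, recording: Recording) -> None:
    """Write ``recording.data`` so a round-trip read is bitwise equal.

    ``.npy`` preserves the float64 bit pattern natively; text files use
    ``%.17g`` which round-trips IEEE doubles exactly.
    """
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, recording.data)
    else:
        np.savetxt(path, recording.data, fmt="%.17g")


def read_standard_eeg(
    path: str | Path,
    group: Group | str = Group.HC,
    eyes: Eyes | str = Eyes.UNKNOWN,
    drop_channels: Sequence[str] = (),
    subject_id: str = "",
) -> Recording:
    """Read an EDF or BDF file into a :class:`Recording`.

    ``drop_channels`` removes named channels (e.g. the EXG auxiliary
    channels of BioSemi amplifiers) without reordering the survivors; the
    sampling rate is taken from the file header.
    """
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if suffix == ".bdf":
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="ERROR")
        elif suffix == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
        else:
            raise ValueError(f"unsupported EEG file extension {suffix!r} (need .edf/.bdf)")
    keep = [name for name in raw.ch_names if name not in set(drop_channels)]
    if len(keep) < 2:
        raise ValueError(
            f"dropping {list(drop_channels)} leaves {len(keep)} channel(s); need >= 2"
        )
    raw.pick(keep)
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        group=group,
        eyes=eyes,
        subject_id=subject_id or path.stem,
    )


MANIFEST_COLUMNS = ["file", "subject_id", "group", "eyes", "fs"]


def read_manifest(manifest_path: str | Path, name: str = "") -> DatasetManifest:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns {missing}")
    entries = []
    for i, row in df.iterrows():
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = manifest_path.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(
                f"manifest entry {i} ({row['subject_id']}): file {fpath} does not exist"
            )
        entries.append(
            {
                "file": fpath,
                "subject_id": str(row["subject_id"]),
                "group": Group.parse(row["group"]),
                "eyes": Eyes.parse(row["eyes"]),
                "fs": float(row["fs"]),
            }
        )
    return DatasetManifest(entries=entries, name=name or manifest_path.stem)


def load_dataset(manifest_path: str | Path) -> list[Recording]:
    """Load every entry of a CSV manifest, order preserved."""
    manifest = read_manifest(manifest_path)
    recordings = []
    for entry in manifest.entries:
        fpath: Path = entry["file"]
        if fpath.suffix.lower() in (".edf", ".bdf"):
            rec = read_standard_eeg(
                fpath, group=entry["group"], eyes=entry["eyes"],
                subject_id=entry["subject_id"],
            )
        else:
            rec = read_matrix_recording(
                fpath, fs=entry["fs"], group=entry["group"], eyes=entry["eyes"],
                subject_id=entry["subject_id"],
            )
        recordings.append(rec)
    return recordings


def write_dataset(directory: str | Path, recordings: Sequence[Recording],
                  name: str = "dataset") -> Path:
    """Write recordings as matrix files plus a manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        fname = f"{name}_{i:03d}.npy"
        write_matrix_recording(directory / fname, rec)
        rows.append(
            {
                "file": fname,
                "subject_id": rec.subject_id or f"S{i:03d}",
                "group": rec.group.value,
                "eyes": rec.eyes.value,
                "fs": rec.fs,
            }
        )
    manifest_path = directory / f"{name}_manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    return manifest_path
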