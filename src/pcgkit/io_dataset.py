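"""WAV input/output and dataset manifests for heart-sound recordings.

A dataset is a folder tree with one subdirectory per diagnostic class —
normal (N) and the four valvular disorders: aortic stenosis (AS), mitral
regurgitation (MR), mitral stenosis (MS), and mitral valve prolapse (MVP).
Recordings are mono 16-bit PCM WAV files, nominally sampled at 8 kHz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

log = logging.getLogger(__name__)

CLASSES: tuple[str, ...] = ("N", "AS", "MR", "MS", "MVP")

#: case-insensitive folder-name aliases -> canonical class label
FOLDER_ALIASES: dict[str, str] = {
    "n": "N",
    "normal": "N",
    "as": "AS",
    "aortic_stenosis": "AS",
    "aortic stenosis": "AS",
    "mr": "MR",
    "mitral_regurgitation": "MR",
    "mitral regurgitation": "MR",
    "ms": "MS",
    "mitral_stenosis": "MS",
    "mitral stenosis": "MS",
    "mvp": "MVP",
    "mitral_valve_prolapse": "MVP",
    "mitral valve prolapse": "MVP",
}


class FormatError(ValueError):
    """Raised for files that are not mono PCM WAV."""


@dataclass
class PCGRecording:
    """A sampled phonocardiogram with optional class label.

    Attributes
    ----------
    id : str
        Identity of the recording (usually the file stem).
    samples : np.ndarray
        1-D float amplitude sequence scaled to [-1, 1].
    fs : int
        Sampling rate in Hz.
    label : str or None
        One of N/AS/MR/MS/MVP, or None for unlabeled audio.
    """

    id: str
    samples: np.ndarray
    fs: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN/Inf")
        if not (isinstance(self.fs, (int, np.integer)) and self.fs > 0):
            raise ValueError(f"fs must be a positive integer, got {self.fs!r}")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DatasetManifest:
    """Listing of recordings under a dataset root with labels and durations."""

    entries: pd.DataFrame = field(default_factory=pd.DataFrame)
    root: str = ""
    fs_expected: int = 8000

    def __post_init__(self) -> None:
        required = {"id", "path", "label", "fs", "duration_s"}
        if len(self.entries) and not required.issubset(self.entries.columns):
            raise ValueError(f"manifest requires columns {sorted(required)}")
        if len(self.entries):
            if self.entries["path"].duplicated().any():
                raise ValueError("manifest paths must be unique")
            bad = set(self.entries["label"]) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown labels in manifest: {sorted(bad)}")

    def class_counts(self) -> dict[str, int]:
        counts = self.entries["label"].value_counts().to_dict() if len(self.entries) else {}
        return {c: int(counts.get(c, 0)) for c in CLASSES}

    def __len__(self) -> int:
        return len(self.entries)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.entries.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, root: str = "", fs_expected: int = 8000):
        df = pd.read_csv(path)
        return cls(entries=df, root=root, fs_expected=fs_expected)


def read_wav(path: str | Path) -> PCGRecording:
    """Read a mono PCM WAV file into a [-1, 1]-scaled recording.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        If the file is not WAV or not single-channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        fs, data = wavfile.read(path)
    except ValueError as exc:
        raise FormatError(f"{path} is not a readable WAV file: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(
            f"{path} has {data.shape[1]} channels; only mono recordings are supported"
        )
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path}: unsupported WAV sample format {data.dtype}")
    return PCGRecording(id=path.stem, samples=samples, fs=int(fs))


def write_wav(rec: PCGRecording, path: str | Path) -> Path:
    """Write a recording as mono 16-bit PCM WAV; clips out-of-range samples."""
    path = Path(path)
    samples = rec.samples
    peak = np.max(np.abs(samples)) if samples.size else 0.0
    if peak > 1.0:
        warnings.warn(
            f"recording {rec.id}: peak amplitude {peak:.3f} > 1, clipping", stacklevel=2
        )
        samples = np.clip(samples, -1.0, 1.0)
    # scale by 2^15 and clip the single value that would overflow so the
    # round-trip error stays within half an LSB (1/32768 worst case)
    pcm = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(rec.fs), pcm)
    return path


def _resolve_class(folder_name: str) -> str | None:
    return FOLDER_ALIASES.get(folder_name.strip().lower())


def scan_dataset(root: str | Path, fs_expected: int = 8000) -> DatasetManifest:
    """Walk a class-folder tree and build a labeled manifest.

    Subdirectories whose names are not recognized class aliases are skipped
    with a warning. Raises ``ValueError`` if no recordings are found at all.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    rows = []
    for sub in sorted(root.iterdir()):
        if not sub.is_dir():
            continue
        label = _resolve_class(sub.name)
        if label is None:
            log.warning("skipping unrecognized class folder %s", sub)
            continue
        wavs = sorted(sub.glob("*.wav")) + sorted(sub.glob("*.WAV"))
        if not wavs:
            log.warning("class folder %s contains no WAV files", sub)
        for p in wavs:
            rec = read_wav(p)
            rows.append(
                {
                    "id": f"{label}/{p.stem}",
                    "path": str(p),
                    "label": label,
                    "fs": rec.fs,
                    "duration_s": rec.duration_s,
                }
            )
    if not rows:
        raise ValueError(f"no recordings found under {root}")
    df = pd.DataFrame(rows)
    return DatasetManifest(entries=df, root=str(root), fs_expected=fs_expected)
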