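"""Delta-controlled background-deformation augmentation.

A training copy of a recording is ``x + delta * background`` where
``delta`` is drawn from the open interval (0, 1) and the background is an
equal-length stochastic signal — by default unit-RMS Gaussian noise
band-limited to the 15-150 Hz heart-sound band; alternatively a different
same-class recording ("recording-mix"). Augmentation is applied to
training rosters only; test folds never contain augmented records.

Two roster modes are provided. ``leakage_free`` (default) augments only
the originals inside the training split. ``paper_faithful`` additionally
augments the held-out originals into the training roster, reproducing the
published roster arithmetic (10-fold over 2000 originals: 1800 originals +
2000 augmented = 3800 training records) at the cost of information leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .io_dataset import DatasetManifest, PCGRecording

log = logging.getLogger(__name__)

BACKGROUND_BAND = (15.0, 150.0)


@dataclass
class AugmentConfig:
    delta: float | None = None  # None -> per-copy Uniform(0,1) excluding endpoints
    background_mode: str = "bandlimited-noise"  # or "recording-mix"
    copies_per_original: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta is not None and not (0.0 < self.delta < 1.0):
            raise ValueError("fixed delta must lie strictly inside (0, 1)")
        if self.copies_per_original < 1:
            raise ValueError("copies_per_original must be >= 1")
        if self.background_mode not in ("bandlimited-noise", "recording-mix"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


def background_deform(
    x: PCGRecording, delta: float, background: np.ndarray
) -> PCGRecording:
    """Return ``x + delta * background`` with label/fs inherited, id suffixed."""
    if not (0.0 < delta < 1.0):
        raise ValueError(f"delta must lie strictly inside (0, 1), got {delta}")
    background = np.asarray(background, dtype=np.float64)
    if background.shape != x.samples.shape:
        raise ValueError(
            f"background length {background.size} != signal length {x.samples.size}"
        )
    y = x.samples + delta * background
    return PCGRecording(id=f"{x.id}-aug", samples=y, fs=x.fs, label=x.label)


def make_background(
    template: PCGRecording,
    mode: str = "bandlimited-noise",
    rng: np.random.Generator | int = 0,
    class_pool: list[PCGRecording] | None = None,
) -> np.ndarray:
    """Produce a unit-RMS background sequence the same length as ``template``.

    ``bandlimited-noise``: Gaussian noise zero-phase filtered to 15-150 Hz.
    ``recording-mix``: a randomly chosen *different* same-class recording
    from ``class_pool``, length-matched; falls back to noise with a warning
    when fewer than two recordings of the class are available.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = template.samples.size
    if mode == "recording-mix":
        pool = [
            r
            for r in (class_pool or [])
            if r.label == template.label and r.id != template.id
        ]
        if not pool:
            log.warning(
                "recording-mix needs >= 2 recordings of class %s; "
                "falling back to band-limited noise",
                template.label,
            )
            mode = "bandlimited-noise"
        else:
            other = pool[int(rng.integers(len(pool)))]
            y = other.samples
            if y.size >= n:
                y = y[:n].astype(np.float64)
            else:
                reps = int(np.ceil(n / y.size))
                y = np.tile(y, reps)[:n].astype(np.float64)
            rms = np.sqrt(np.mean(y**2))
            return y / rms if rms > 0 else y
    if mode != "bandlimited-noise":
        raise ValueError(f"unknown background mode {mode!r}")
    x = rng.standard_normal(n)
    sos = _signal.butter(3, BACKGROUND_BAND, btype="bandpass", fs=template.fs, output="sos")
    y = _signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def _draw_delta(rng: np.random.Generator) -> float:
    """Uniform(0,1) excluding the endpoints by re-draw."""
    while True:
        d = float(rng.uniform())
        if 0.0 < d < 1.0:
            return d


def augment_recording(
    x: PCGRecording,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    class_pool: list[PCGRecording] | None = None,
) -> tuple[PCGRecording, float]:
    """One augmented copy of ``x``; returns (copy, delta used)."""
    delta = cfg.delta if cfg.delta is not None else _draw_delta(rng)
    bg = make_background(x, cfg.background_mode, rng, class_pool)
    return background_deform(x, delta, bg), delta


def build_training_roster(
    manifest: DatasetManifest,
    fold_assignments: dict[str, int],
    test_fold: int,
    cfg: AugmentConfig,
    mode: str = "leakage_free",
) -> list[dict]:
    """Assemble the training roster for one cross-validation fold.

    Returns a list of record references ``{"id", "parent_id", "kind"}``
    with ``kind`` in {"original", "augmented"}.

    ``leakage_free``: training originals + augmented copies of training
    originals only. ``paper_faithful``: training originals + augmented
    copies of *every* original including the held-out fold's.
    """
    if mode not in ("leakage_free", "paper_faithful"):
        raise ValueError(f"unknown roster mode {mode!r}")
    ids = list(manifest.entries["id"])
    if set(fold_assignments) != set(ids):
        raise ValueError("fold assignments do not partition the manifest")
    train_ids = [i for i in ids if fold_assignments[i] != test_fold]
    roster: list[dict] = [
        {"id": i, "parent_id": i, "kind": "original"} for i in train_ids
    ]
    aug_parents = ids if mode == "paper_faithful" else train_ids
    for parent in aug_parents:
        for c in range(cfg.copies_per_original):
            roster.append(
                {"id": f"{parent}-aug{c}", "parent_id": parent, "kind": "augmented"}
            )
    return roster
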