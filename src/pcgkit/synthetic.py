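"""Parametric five-class heart-sound simulator.

Each recording is one or more cardiac cycles of S1 and S2 transients
(exponentially damped tone bursts in the 50-150 Hz band) with systole fixed
at 35% of the cycle, plus a class-specific murmur built from band-limited
noise shaped by a textbook auscultation envelope:

* N    — no murmur;
* AS   — mid-systolic crescendo-decrescendo (triangular envelope peaking at
         mid-systole) in the 150-400 Hz murmur band;
* MR   — uniform holosystolic envelope in the murmur band;
* MS   — low-frequency (40-100 Hz) mid-diastolic rumble;
* MVP  — a short (~5 ms) mid-systolic click plus a late-systolic ramp.

White sensor noise is added at a configurable SNR and the waveform is
peak-normalized. The simulator targets spectral/temporal class
separability, not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .io_dataset import CLASSES, DatasetManifest, PCGRecording, write_wav
import pandas as pd


@dataclass
class SynthConfig:
    fs: int = 2000
    duration_s: float = 1.2
    heart_rate_bpm: tuple[float, float] = (60.0, 100.0)
    s1_band: tuple[float, float] = (50.0, 120.0)
    s2_band: tuple[float, float] = (60.0, 150.0)
    murmur_band: tuple[float, float] = (150.0, 400.0)
    ms_rumble_band: tuple[float, float] = (40.0, 100.0)
    murmur_gain: float = 0.5
    noise_snr_db: float = 20.0
    systole_frac: float = 0.35

    def __post_init__(self) -> None:
        nyq = self.fs / 2
        for band in (self.s1_band, self.s2_band, self.murmur_band, self.ms_rumble_band):
            if not (0 < band[0] < band[1] < nyq):
                raise ValueError(f"band {band} must lie inside (0, {nyq})")
        if self.duration_s * self.heart_rate_bpm[0] / 60.0 < 1.0:
            raise ValueError("duration must cover at least one cycle at the slowest rate")


def _damped_burst(
    n: int, fs: int, t0: float, freq: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Exponentially damped sinusoid burst starting at time ``t0`` seconds."""
    t = np.arange(n) / fs
    rel = t - t0
    env = np.where(rel >= 0, np.exp(-np.maximum(rel, 0.0) / tau), 0.0)
    phase = rng.uniform(0, 2 * np.pi)
    return env * np.sin(2 * np.pi * freq * rel + phase)


def _bandnoise(n: int, fs: int, band: tuple[float, float], rng) -> np.ndarray:
    """Unit-RMS Gaussian noise zero-phase band-limited to ``band``."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def generate_recording(
    label: str, cfg: SynthConfig | None = None, rng: np.random.Generator | int = 0
) -> PCGRecording:
    """Simulate one labeled heart-sound recording (deterministic per rng state)."""
    cfg = cfg or SynthConfig()
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}; expected one of {CLASSES}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs
    hr = rng.uniform(*cfg.heart_rate_bpm)
    cycle = 60.0 / hr
    sys_len = cfg.systole_frac * cycle

    x = np.zeros(n)
    t = np.arange(n) / fs
    # S1/S2 transients for every cycle that starts within the recording
    n_cycles = int(np.ceil(cfg.duration_s / cycle)) + 1
    starts = [k * cycle for k in range(n_cycles)]
    for t0 in starts:
        f1 = rng.uniform(*cfg.s1_band)
        f2 = rng.uniform(*cfg.s2_band)
        x += 1.0 * _damped_burst(n, fs, t0, f1, tau=0.022, rng=rng)
        x += 0.8 * _damped_burst(n, fs, t0 + sys_len, f2, tau=0.016, rng=rng)

    # class-specific murmur, built per cycle from band noise and an envelope
    phase = (t / cycle) % 1.0  # 0 at S1, systole_frac at S2
    sf = cfg.systole_frac
    if label == "AS":
        noise = _bandnoise(n, fs, cfg.murmur_band, rng)
        env = np.clip(1.0 - np.abs(phase - sf / 2) / (sf / 2), 0.0, 1.0)
        env[phase > sf] = 0.0
        x += cfg.murmur_gain * env * noise
    elif label == "MR":
        noise = _bandnoise(n, fs, cfg.murmur_band, rng)
        env = (phase <= sf).astype(float)
        x += cfg.murmur_gain * env * noise
    elif label == "MS":
        noise = _bandnoise(n, fs, cfg.ms_rumble_band, rng)
        dia_mid = sf + (1.0 - sf) / 2
        width = (1.0 - sf) / 4
        env = np.exp(-0.5 * ((phase - dia_mid) / width) ** 2)
        env[phase < sf] = 0.0
        x += cfg.murmur_gain * env * noise
    elif label == "MVP":
        # mid-systolic click: a very short high-frequency burst each cycle
        for t0 in starts:
            click_t = t0 + 0.5 * sys_len
            click = _damped_burst(n, fs, click_t, rng.uniform(250, 400), tau=0.0025, rng=rng)
            x += 0.9 * click
        noise = _bandnoise(n, fs, cfg.murmur_band, rng)
        ramp = np.clip((phase - 0.5 * sf) / (0.5 * sf), 0.0, 1.0)
        ramp[phase > sf] = 0.0
        x += cfg.murmur_gain * ramp * noise
    # label == "N": heart tones only

    # additive white sensor noise at the configured SNR
    sig_pow = np.mean(x**2)
    noise_pow = sig_pow / (10.0 ** (cfg.noise_snr_db / 10.0))
    x = x + rng.standard_normal(n) * np.sqrt(noise_pow)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    rec_id = f"{label}-synth-{rng.integers(0, 2**31):08x}"
    return PCGRecording(id=rec_id, samples=x, fs=fs, label=label)


def generate_dataset(
    n_per_class: int,
    cfg: SynthConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[DatasetManifest, list[PCGRecording]]:
    """Generate ``5 * n_per_class`` recordings; optionally write WAVs to disk.

    Per-recording seeds are spawned from the master seed, so any recording
    is reproducible independently of generation order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(5 * n_per_class)
    recs: list[PCGRecording] = []
    rows = []
    k = 0
    for label in CLASSES:
        for i in range(n_per_class):
            rng = np.random.default_rng(children[k])
            rec = generate_recording(label, cfg, rng)
            rec.id = f"{label}/{label.lower()}_{i:04d}"
            recs.append(rec)
            row = {
                "id": rec.id,
                "path": "",
                "label": label,
                "fs": rec.fs,
                "duration_s": rec.duration_s,
            }
            if out_dir is not None:
                d = Path(out_dir) / label
                d.mkdir(parents=True, exist_ok=True)
                p = d / f"{label.lower()}_{i:04d}.wav"
                write_wav(rec, p)
                row["path"] = str(p)
            rows.append(row)
            k += 1
    if out_dir is None:
        # keep paths unique even when nothing is on disk
        for row in rows:
            row["path"] = row["id"]
    manifest = DatasetManifest(
        entries=pd.DataFrame(rows),
        root=str(out_dir) if out_dir else "",
        fs_expected=cfg.fs,
    )
    return manifest, recs


def band_energy(
    rec: PCGRecording, band: tuple[float, float], t0: float, t1: float
) -> float:
    """Energy of ``rec`` within a frequency band and a time window (seconds)."""
    i0, i1 = int(t0 * rec.fs), int(t1 * rec.fs)
    seg = rec.samples[i0:i1]
    if seg.size < 8:
        return 0.0
    freqs, psd = signal.periodogram(seg, fs=rec.fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))
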