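"""Time-frequency imaging of heart sounds.

Two representations are provided:

* the STFT power spectrogram ``|STFT(t, w)|^2`` (Hann window, 256 samples,
  hop 64, 512-point FFT at the 2 kHz analysis rate — a 128 ms window that
  resolves both the S1/S2 transients and murmur bands), and
* the CWT scalogram ``|CWT(s, t)|`` on log-spaced scales (analytic Morlet,
  center frequency parameter 6, 12 voices per octave), the constant-Q
  representation whose log-frequency axis matches auditory resolution.

Either matrix is rendered to a fixed-size RGB image: dB scale with a floor,
per-image min-max normalization, a pinned 256-entry colormap lookup table
(shipped with the package so rendering is bit-reproducible), and bilinear
resizing with low frequencies at the bottom row.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy.signal import get_window

from .io_dataset import PCGRecording

#: Morlet angular center frequency (omega0); fc = omega0 / (2 pi) cycles
MORLET_OMEGA0 = 6.0
_MORLET_FC = MORLET_OMEGA0 / (2.0 * np.pi)


@dataclass
class TFRConfig:
    stft_window: str = "hann"
    window_len: int = 256
    hop: int = 64
    fft_size: int = 512
    voices_per_octave: int = 12
    freq_range: tuple[float, float] = (10.0, 500.0)
    db_floor: float = -80.0
    image_size: int = 224

    def __post_init__(self) -> None:
        if self.hop > self.window_len:
            raise ValueError("hop must not exceed the window length")
        if self.fft_size < self.window_len:
            raise ValueError("fft_size must be >= window length")
        if self.freq_range[0] <= 0 or self.freq_range[0] >= self.freq_range[1]:
            raise ValueError("freq_range must be increasing and positive")


@dataclass
class TFMatrix:
    """A nonnegative frequency-by-time matrix with physical axes."""

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    kind: str  # "stft-power" | "cwt-magnitude"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freq_axis = np.asarray(self.freq_axis, dtype=np.float64)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frequency x time)")
        if self.values.shape != (self.freq_axis.size, self.time_axis.size):
            raise ValueError("axis lengths must match the value matrix")
        if np.any(self.values < 0):
            raise ValueError("time-frequency values must be nonnegative")
        for ax in (self.freq_axis, self.time_axis):
            if ax.size > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise ValueError("axes must be strictly monotone")


@dataclass
class SpectroImage:
    """An H x W x 3 float image in [0, 1] rendered from a TFMatrix."""

    pixels: np.ndarray
    source_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be non-empty")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def stft_spectrogram(rec: PCGRecording, cfg: TFRConfig | None = None) -> TFMatrix:
    """Power spectrogram: squared magnitude of the windowed short-time DFT.

    Frames start at multiples of ``hop``; each frame is multiplied by a
    periodic Hann window and zero-padded to ``fft_size`` before the DFT.
    No window-gain scaling is applied, so ``values[f, t]`` is exactly
    ``|sum_n w[n] x[t*hop + n] e^{-2 pi i f n / fft_size}|^2``.
    """
    cfg = cfg or TFRConfig()
    x = rec.samples
    if x.size < cfg.window_len:
        raise ValueError(
            f"signal of {x.size} samples is shorter than the {cfg.window_len}-sample window"
        )
    win = get_window(cfg.stft_window, cfg.window_len, fftbins=True)
    n_frames = 1 + (x.size - cfg.window_len) // cfg.hop
    idx = np.arange(cfg.window_len)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    spec = np.abs(np.fft.rfft(frames, n=cfg.fft_size, axis=1)) ** 2  # (T, F)
    freq = np.fft.rfftfreq(cfg.fft_size, d=1.0 / rec.fs)
    times = (cfg.hop * np.arange(n_frames) + cfg.window_len / 2) / rec.fs
    return TFMatrix(values=spec.T, freq_axis=freq, time_axis=times, kind="stft-power")


def cwt_frequencies(cfg: TFRConfig) -> np.ndarray:
    """Log-spaced pseudo-frequency grid, descending from the top of freq_range."""
    lo, hi = cfg.freq_range
    n = int(np.floor(cfg.voices_per_octave * np.log2(hi / lo))) + 1
    return hi / 2.0 ** (np.arange(n) / cfg.voices_per_octave)


def cwt_scalogram(rec: PCGRecording, cfg: TFRConfig | None = None) -> TFMatrix:
    """Constant-Q scalogram: |CWT| with an analytic Morlet wavelet.

    Scales are chosen so the wavelet pseudo-frequencies form a log-spaced
    grid over ``freq_range`` with ``voices_per_octave`` voices.
    """
    cfg = cfg or TFRConfig()
    if rec.samples.size < 2:
        raise ValueError("signal must contain at least 2 samples")
    if cfg.freq_range[1] >= rec.fs / 2:
        raise ValueError(
            f"freq_range upper edge {cfg.freq_range[1]} must be below Nyquist {rec.fs / 2}"
        )
    freqs = cwt_frequencies(cfg)  # descending
    wavelet = f"cmor1.5-{_MORLET_FC:.10f}"
    dt = 1.0 / rec.fs
    scales = _MORLET_FC / (freqs * dt)
    coeffs, _ = pywt.cwt(rec.samples, scales, wavelet, sampling_period=dt)
    mag = np.abs(coeffs)  # (scales, time), freq descending
    # store with ascending frequency axis
    times = np.arange(rec.samples.size) * dt
    return TFMatrix(
        values=mag[::-1], freq_axis=freqs[::-1], time_axis=times, kind="cwt-magnitude"
    )


@lru_cache(maxsize=1)
def _colormap_lut() -> np.ndarray:
    """The pinned 256 x 3 RGB lookup table shipped with the package."""
    ref = importlib.resources.files("pcgkit") / "data" / "colormap256.csv"
    lut = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    assert lut.shape == (256, 3)
    return lut


def bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Align-corners bilinear resize of an H x W (x C) array.

    Resizing to the input size is exactly the identity.
    """
    h, w = img.shape[:2]
    if (h, w) == (out_h, out_w):
        return img.copy()
    ys = np.linspace(0.0, h - 1, out_h) if out_h > 1 else np.zeros(1)
    xs = np.linspace(0.0, w - 1, out_w) if out_w > 1 else np.zeros(1)
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0).reshape(-1, 1)
    fx = (xs - x0).reshape(1, -1)
    if img.ndim == 3:
        fy = fy[..., None]
        fx = fx[..., None]
    top = img[y0][:, x0] * (1 - fx) + img[y0][:, x1] * fx
    bot = img[y1][:, x0] * (1 - fx) + img[y1][:, x1] * fx
    return top * (1 - fy) + bot * fy


def to_decibel(values: np.ndarray, db_floor: float = -80.0) -> np.ndarray:
    """10*log10 relative to the matrix peak, floored at ``db_floor`` dB."""
    peak = values.max()
    if peak <= 0:
        return np.full_like(values, db_floor, dtype=np.float64)
    db = 10.0 * np.log10(np.maximum(values / peak, 10.0 ** (db_floor / 10.0)))
    return db


def render_rgb(tf: TFMatrix, cfg: TFRConfig | None = None) -> SpectroImage:
    """Render a TFMatrix as an image_size^2 RGB image in [0, 1].

    dB scale -> per-image min-max -> 256-entry colormap -> bilinear resize.
    Row 0 of the rendered image is the *highest* frequency, so low
    frequencies sit at the bottom as in conventional spectrogram plots.
    """
    cfg = cfg or TFRConfig()
    if tf.values.size == 0:
        raise ValueError("cannot render an empty matrix")
    db = to_decibel(tf.values, cfg.db_floor)
    lo, hi = db.min(), db.max()
    gray = np.zeros_like(db) if hi == lo else (db - lo) / (hi - lo)
    lut = _colormap_lut()
    rgb = lut[np.clip(np.round(gray * 255).astype(int), 0, 255)]
    rgb = rgb[::-1]  # put low frequencies at the bottom row
    out = bilinear_resize(rgb, cfg.image_size, cfg.image_size)
    out = np.clip(out, 0.0, 1.0)
    return SpectroImage(pixels=out)


def recording_to_image(
    rec: PCGRecording, cfg: TFRConfig | None = None, kind: str = "cwt"
) -> SpectroImage:
    """Full 1-D -> image stage: CWT scalogram by default, STFT on request."""
    cfg = cfg or TFRConfig()
    if kind == "cwt":
        tf = cwt_scalogram(rec, cfg)
    elif kind == "stft":
        tf = stft_spectrogram(rec, cfg)
    else:
        raise ValueError(f"unknown representation kind {kind!r}")
    img = render_rgb(tf, cfg)
    img.source_id = rec.id
    img.label = rec.label
    return img
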