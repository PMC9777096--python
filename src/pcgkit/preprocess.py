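"""Signal conditioning for phonocardiograms.

The pipeline applied before time-frequency imaging is:

1. band-pass 25-900 Hz (3rd-order Butterworth) at the acquisition rate to
   strip out-of-band sensor noise,
2. anti-aliased decimation to 2000 Hz,
3. zero-phase 3rd-order 15-150 Hz band-pass (forward-backward filtering, so
   S1/S2 timing is not shifted) — heartbeat energy lies mainly in 50-150 Hz,
4. optional wavelet denoise (off by default),
5. peak normalization,
6. length fixed to 2312 samples (ceil(1.1556 s x 2000 Hz), the shortest
   recording in the source database).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal

from .io_dataset import PCGRecording

#: default fixed segment length in samples at 2000 Hz
SEGMENT_LEN = 2312
TARGET_FS = 2000


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth band-pass specification."""

    order: int
    low_hz: float
    high_hz: float
    fs: float
    family: str = "butterworth-bandpass"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not (0 < self.low_hz < self.high_hz < self.fs / 2):
            raise ValueError(
                f"need 0 < low ({self.low_hz}) < high ({self.high_hz}) "
                f"< fs/2 ({self.fs / 2})"
            )


#: acquisition-stage band (applied at the native 8 kHz rate)
ACQUISITION_BAND = FilterSpec(order=3, low_hz=25.0, high_hz=900.0, fs=8000.0)
#: analysis-stage band (applied zero-phase after decimation to 2 kHz)
ANALYSIS_BAND = FilterSpec(order=3, low_hz=15.0, high_hz=150.0, fs=2000.0)


@dataclass
class PreprocConfig:
    acquisition_band: FilterSpec = ACQUISITION_BAND
    analysis_band: FilterSpec = ANALYSIS_BAND
    target_fs: int = TARGET_FS
    segment_len: int = SEGMENT_LEN
    denoise_enabled: bool = False

    def __post_init__(self) -> None:
        if self.segment_len < 1:
            raise ValueError("segment_len must be >= 1")


def design_bandpass(spec: FilterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Design a digital Butterworth band-pass; returns (b, a).

    The returned filter has its half-power (-3 dB) points at ``low_hz``
    and ``high_hz`` by the Butterworth defining property.
    """
    return signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=spec.fs
    )


def frequency_response(
    spec: FilterSpec, freqs: np.ndarray
) -> np.ndarray:
    """|H(f)| of the band-pass evaluated at ``freqs`` (Hz)."""
    b, a = design_bandpass(spec)
    _, h = signal.freqz(b, a, worN=np.asarray(freqs, dtype=float), fs=spec.fs)
    return np.abs(h)


def half_power_points(spec: FilterSpec, n_grid: int = 2_000_001) -> tuple[float, float]:
    """Locate the lower/upper -3 dB crossings from a dense frequency grid.

    The crossing is refined by linear interpolation between grid points,
    so the result is accurate to well under the grid step.
    """
    freqs = np.linspace(0.0, spec.fs / 2, n_grid)[1:-1]
    mag = frequency_response(spec, freqs)
    target = 1.0 / math.sqrt(2.0)
    above = mag >= target
    if not above.any():
        raise ValueError("response never reaches the half-power level")
    lo_i = int(np.argmax(above))
    hi_i = len(above) - 1 - int(np.argmax(above[::-1]))

    def interp(i0: int, i1: int) -> float:
        f0, f1 = freqs[i0], freqs[i1]
        m0, m1 = mag[i0], mag[i1]
        if m1 == m0:
            return float(f0)
        return float(f0 + (target - m0) * (f1 - f0) / (m1 - m0))

    low = interp(lo_i - 1, lo_i) if lo_i > 0 else float(freqs[0])
    high = interp(hi_i, hi_i + 1) if hi_i < len(freqs) - 1 else float(freqs[-1])
    return low, high


def zero_phase_filter(rec: PCGRecording, spec: FilterSpec) -> PCGRecording:
    """Forward-backward (zero net phase) band-pass filtering.

    The effective magnitude response is the square of the single-pass
    response; transient timing is preserved exactly.
    """
    if rec.fs != spec.fs:
        raise ValueError(f"recording fs {rec.fs} != filter fs {spec.fs}")
    b, a = design_bandpass(spec)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if rec.samples.size <= padlen:
        raise ValueError(
            f"signal of {rec.samples.size} samples is too short for zero-phase "
            f"filtering (needs > {padlen})"
        )
    y = signal.filtfilt(b, a, rec.samples)
    return PCGRecording(id=rec.id, samples=y, fs=rec.fs, label=rec.label)


def bandpass_filter(rec: PCGRecording, spec: FilterSpec) -> PCGRecording:
    """Single-pass (causal) band-pass filtering."""
    if rec.fs != spec.fs:
        raise ValueError(f"recording fs {rec.fs} != filter fs {spec.fs}")
    b, a = design_bandpass(spec)
    y = signal.lfilter(b, a, rec.samples)
    return PCGRecording(id=rec.id, samples=y, fs=rec.fs, label=rec.label)


def resample(rec: PCGRecording, target_fs: int) -> PCGRecording:
    """Anti-aliased polyphase resampling to ``target_fs`` (downsampling only).

    Output length is ``ceil(N * target_fs / fs)``.
    """
    if target_fs > rec.fs:
        raise ValueError(
            f"upsampling ({rec.fs} -> {target_fs} Hz) is not supported"
        )
    if target_fs == rec.fs:
        return PCGRecording(rec.id, rec.samples.copy(), rec.fs, rec.label)
    frac = Fraction(int(target_fs), int(rec.fs))
    y = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return PCGRecording(id=rec.id, samples=y, fs=int(target_fs), label=rec.label)


def normalize(rec: PCGRecording) -> PCGRecording:
    """Scale so the peak absolute amplitude is 1 (zero input unchanged)."""
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("cannot normalize a signal containing NaN/Inf")
    peak = np.max(np.abs(rec.samples))
    if peak == 0.0:
        warnings.warn(f"recording {rec.id} is all zeros; not normalized", stacklevel=2)
        return PCGRecording(rec.id, rec.samples.copy(), rec.fs, rec.label)
    return PCGRecording(rec.id, rec.samples / peak, rec.fs, rec.label)


def fix_length(rec: PCGRecording, segment_len: int = SEGMENT_LEN) -> PCGRecording:
    """Truncate (from the head) or zero-pad (at the tail) to ``segment_len``."""
    if segment_len < 1:
        raise ValueError("segment_len must be >= 1")
    x = rec.samples
    if x.size >= segment_len:
        y = x[:segment_len].copy()
    else:
        y = np.concatenate([x, np.zeros(segment_len - x.size)])
    return PCGRecording(rec.id, y, rec.fs, rec.label)


def wavelet_denoise(
    rec: PCGRecording,
    wavelet: str = "db4",
    levels: int = 5,
    threshold: float | None = None,
) -> PCGRecording:
    """Dyadic wavelet shrinkage denoising.

    Decompose ``levels`` deep, soft-threshold the detail coefficients with
    the universal threshold sigma*sqrt(2*log N) (sigma estimated from the
    median absolute deviation of the finest details), reconstruct.
    ``threshold`` overrides the universal threshold when given.
    """
    n = rec.samples.size
    if n < 2**levels:
        raise ValueError(f"signal of {n} samples too short for {levels} levels")
    coeffs = pywt.wavedec(rec.samples, wavelet, level=levels)
    if threshold is None:
        sigma = np.median(np.abs(coeffs[-1])) / 0.6744897501960817
        threshold = sigma * math.sqrt(2.0 * math.log(max(n, 2)))
    if threshold > 0:
        out = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    else:
        out = coeffs
    y = pywt.waverec(out, wavelet)[:n]
    return PCGRecording(rec.id, y, rec.fs, rec.label)


def preprocess(rec: PCGRecording, cfg: PreprocConfig | None = None) -> PCGRecording:
    """Run the full conditioning pipeline on one recording."""
    cfg = cfg or PreprocConfig()
    out = rec
    if out.fs != cfg.target_fs:
        acq = cfg.acquisition_band
        if acq.fs != out.fs:
            acq = FilterSpec(acq.order, acq.low_hz, acq.high_hz, float(out.fs))
        out = bandpass_filter(out, acq)
        out = resample(out, cfg.target_fs)
    out = zero_phase_filter(out, cfg.analysis_band)
    if cfg.denoise_enabled:
        out = wavelet_denoise(out)
    out = normalize(out)
    out = fix_length(out, cfg.segment_len)
    return out
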