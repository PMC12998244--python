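"""Fundamental-frequency (F0) contour extraction.

A lion call's F0 — the lowest frequency of its periodic waveform — is the
observation sequence every downstream model consumes. The extraction
pipeline mirrors the classical bioacoustics recipe: bandpass the call to
the species' fundamental band (30-375 Hz for lions), then slide a short
window over the signal and take, per window, the lag that maximises the
normalized autocorrelation. Quiet frames (below an amplitude gate set at
the top percentile of the clip's absolute amplitude) yield no estimate and
are dropped from the contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .audio import AudioClip

__all__ = ["F0Config", "F0Contour", "bandpass", "extract_f0", "call_to_contour"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class F0Config:
    """Parameters of the bandpass + autocorrelation F0 extractor.

    Defaults target lion roaring bouts recorded at 16 kHz: the fundamental
    sits between 30 and 375 Hz, the bandpass uses either a zero-phase
    Butterworth (``filter_mode="butterworth"``) or a Hann-windowed FFT
    mask with 68% overlap (``filter_mode="fft_hann"``), and the
    autocorrelation window is 128 samples (8 ms) with half-window hop.
    """

    band_low_hz: float = 30.0
    band_high_hz: float = 375.0
    filter_mode: str = "butterworth"
    filter_order: int = 4
    filter_window: int = 2048
    filter_overlap_fraction: float = 0.68
    ac_window: int = 128
    amplitude_top_fraction: float = 0.01
    peak_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigError("need 0 < band_low_hz < band_high_hz")
        if not 0 < self.filter_overlap_fraction < 1:
            raise ConfigError("filter_overlap_fraction must be in (0, 1)")
        if self.ac_window < 8:
            raise ConfigError("ac_window must be >= 8 samples")
        if self.filter_mode not in ("butterworth", "fft_hann"):
            raise ConfigError(f"unknown filter_mode {self.filter_mode!r}")

    @property
    def hop(self) -> int:
        return self.ac_window // 2

    def lag_range(self, rate: float) -> tuple[int, int]:
        """Inclusive (min, max) lag in samples for the configured band."""
        return int(round(rate / self.band_high_hz)), int(round(rate / self.band_low_hz))


@dataclass(frozen=True)
class F0Contour:
    """An ordered sequence of F0 estimates (Hz) with their frame times.

    Quiet (gated) frames have already been dropped, so ``frame_times_s``
    is strictly increasing but not necessarily uniformly spaced.
    """

    values_hz: np.ndarray
    frame_times_s: np.ndarray
    call_ref: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values_hz, dtype=np.float64)
        times = np.asarray(self.frame_times_s, dtype=np.float64)
        if values.shape != times.shape or values.ndim != 1:
            raise ValueError("values_hz and frame_times_s must be equal-length 1-D")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame_times_s must be strictly increasing")
        object.__setattr__(self, "values_hz", values)
        object.__setattr__(self, "frame_times_s", times)

    def __len__(self) -> int:
        return len(self.values_hz)


def bandpass(clip: AudioClip, cfg: F0Config = F0Config()) -> AudioClip:
    """Bandpass a mono clip to [band_low_hz, band_high_hz].

    ``butterworth`` mode applies a 4th-order Butterworth forward-backward
    (zero phase); ``fft_hann`` masks an STFT computed with the configured
    Hann window and overlap. Both attenuate by well over 40 dB one octave
    beyond each band edge. Output has the input's length and rate.
    """
    x = clip.mono
    nyquist = clip.rate / 2
    if cfg.band_high_hz >= nyquist:
        raise ConfigError(f"band_high_hz {cfg.band_high_hz} must lie below Nyquist {nyquist}")
    if cfg.filter_mode == "butterworth":
        sos = signal.butter(
            cfg.filter_order,
            [cfg.band_low_hz, cfg.band_high_hz],
            btype="bandpass",
            fs=clip.rate,
            output="sos",
        )
        y = signal.sosfiltfilt(sos, x)
    else:
        nperseg = min(cfg.filter_window, len(x))
        noverlap = int(round(cfg.filter_overlap_fraction * nperseg))
        f, _, z = signal.stft(x, fs=clip.rate, window="hann", nperseg=nperseg, noverlap=noverlap)
        z[(f < cfg.band_low_hz) | (f > cfg.band_high_hz), :] = 0.0
        _, y = signal.istft(z, fs=clip.rate, window="hann", nperseg=nperseg, noverlap=noverlap)
        y = np.resize(y, len(x)) if len(y) < len(x) else y[: len(x)]
    return AudioClip(y, clip.rate)


def _best_lag(
    frame: np.ndarray, tail: np.ndarray, lag_min: int, lag_max: int, peak_tolerance: float
) -> int | None:
    """Lag in [lag_min, lag_max] maximising the normalized cross-correlation
    of ``frame`` with the signal shifted by that lag.

    ``tail`` holds the signal from the frame start onward. Among lags whose
    correlation comes within ``peak_tolerance`` of the maximum, the shortest
    is returned: every integer multiple of a true period scores near the
    maximum, and without this rule noise would select a subharmonic. Exact
    float ties break toward the longer lag (the lower frequency).
    """
    w = len(frame)
    lag_max = min(lag_max, len(tail) - w)
    if lag_max < lag_min:
        return None
    e0 = float(np.dot(frame, frame))
    if e0 <= 0:
        return None
    lags = np.arange(lag_min, lag_max + 1)
    # Correlations for all lags at once via FFT cross-correlation.
    corr = signal.fftconvolve(tail, frame[::-1], mode="valid")  # corr[l] = sum frame * tail[l:l+w]
    sq = np.concatenate(([0.0], np.cumsum(tail * tail)))
    energies = sq[lags + w] - sq[lags]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = corr[lags] / np.sqrt(e0 * energies)
    r[~np.isfinite(r)] = -np.inf
    if not np.any(r > -np.inf):
        return None
    r_max = float(np.max(r))
    # Local maxima of r (flat ends count); every integer multiple of the
    # true period is a near-maximum peak, so among peaks within tolerance
    # of the global maximum the shortest lag is the fundamental period's.
    interior = np.ones(len(r), dtype=bool)
    if len(r) > 1:
        interior[1:] = r[1:] >= r[:-1]
        interior[:-1] &= r[:-1] >= r[1:]
    peaks = np.flatnonzero(interior & (r >= r_max - peak_tolerance))
    if len(peaks) == 0:
        peaks = np.flatnonzero(r == r_max)
    best = int(peaks[0])
    # exact ties -> longer lag (the lower frequency)
    exact = peaks[r[peaks] == r[best]]
    if len(exact) > 1 and np.all(np.diff(exact) == 1):
        best = int(exact[-1])
    return int(lags[best])


def extract_f0(clip: AudioClip, cfg: F0Config = F0Config(), call_ref: object = None) -> F0Contour:
    """Extract the F0 contour of a (bandpassed) mono clip.

    Frames of ``ac_window`` samples advance by half a window. A frame
    contributes an estimate only if its peak absolute amplitude reaches the
    clip's ``1 - amplitude_top_fraction`` amplitude quantile; gated frames
    are dropped. Per retained frame, F0 = rate / lag* where lag* maximises
    the normalized autocorrelation over lags spanning the configured band.
    """
    x = clip.mono
    w, hop = cfg.ac_window, cfg.hop
    if len(x) < w:
        raise ValueError(f"clip of {len(x)} samples is shorter than one {w}-sample window")
    lag_min, lag_max = cfg.lag_range(clip.rate)
    threshold = float(np.quantile(np.abs(x), 1.0 - cfg.amplitude_top_fraction))
    n_frames = (len(x) - w) // hop + 1

    values, times = [], []
    for i in range(n_frames):
        start = i * hop
        frame = x[start : start + w]
        peak = float(np.max(np.abs(frame)))
        if peak < threshold or peak <= 0.0:
            continue
        lag = _best_lag(frame, x[start:], lag_min, lag_max, cfg.peak_tolerance)
        if lag is None:
            continue
        values.append(clip.rate / lag)
        times.append((start + w / 2) / clip.rate)
    return F0Contour(
        np.array(values), np.array(times), call_ref=call_ref,
        meta={"filter_mode": cfg.filter_mode, "rate": clip.rate},
    )


def call_to_contour(clip: AudioClip, cfg: F0Config = F0Config(), call_ref: object = None) -> F0Contour:
    """Bandpass then extract: the standard one-call pipeline."""
    return extract_f0(bandpass(clip, cfg), cfg, call_ref=call_ref)
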