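"""Threshold spike detection on band-pass-filtered extracellular traces.

The noise level of each channel is estimated robustly as
``sigma = median(|x|) / 0.6745`` (the median of |N(0, sigma)| is
0.6745 sigma), and spikes are local extrema of the filtered signal whose
magnitude exceeds ``T = N_S * sigma`` with ``N_S = 8`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import SpikeTrainSet, StimulationLog
from .synthetic import RawRecording

__all__ = ["DetectionParams", "NoiseEstimate", "estimate_noise_sigma", "band_pass", "detect_spikes"]

#: median of the absolute value of a standard normal variable
_MAD_SCALE = 0.6745


@dataclass(frozen=True)
class DetectionParams:
    band_low: float = 300.0
    band_high: float = 8000.0
    n_s: float = 8.0
    refractory_ms: float = 1.0
    blanking_ms: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")
        if self.n_s <= 0:
            raise ValueError("spike-detection coefficient must be positive")
        if self.refractory_ms < 0 or self.blanking_ms < 0:
            raise ValueError("refractory and blanking must be non-negative")


@dataclass(frozen=True)
class NoiseEstimate:
    sigma: float
    n_s: float

    @property
    def threshold(self) -> float:
        return self.n_s * self.sigma


def estimate_noise_sigma(x: np.ndarray) -> float:
    """Robust noise SD of a filtered trace: ``median(|x|) / 0.6745``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot estimate noise from an empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return float(np.median(np.abs(x)) / _MAD_SCALE)


def band_pass(x: np.ndarray, sampling_rate: float, params: DetectionParams) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward)."""
    nyq = sampling_rate / 2.0
    if params.band_high >= nyq:
        raise ValueError(
            f"band edge {params.band_high} Hz incompatible with sampling rate {sampling_rate} Hz"
        )
    sos = signal.butter(
        4, [params.band_low, params.band_high], btype="bandpass", fs=sampling_rate, output="sos"
    )
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def detect_spikes(
    raw: RawRecording,
    params: DetectionParams | None = None,
    stims: StimulationLog | None = None,
) -> SpikeTrainSet:
    """Detect spikes on every channel of a raw recording.

    Per channel: band-pass filter, estimate sigma on the filtered trace,
    record a spike at each local extremum of |x| exceeding ``n_s * sigma``,
    keep at most one detection per refractory window, and discard detections
    within ``blanking_ms`` after any stimulus (artifact blanking).
    Both polarities are detected; the timestamp is the extremum sample.
    """
    params = params or DetectionParams()
    fs = raw.sampling_rate
    dist = max(1, int(round(params.refractory_ms * 1e-3 * fs)))
    trains: dict[int, np.ndarray] = {}
    for ch in range(raw.n_channels):
        xf = band_pass(raw.data[ch], fs, params)
        sigma = estimate_noise_sigma(xf)
        thresh = params.n_s * sigma
        if sigma == 0:
            trains[ch + 1] = np.empty(0)
            continue
        peaks, _ = signal.find_peaks(np.abs(xf), height=thresh, distance=dist)
        times = peaks / fs
        if stims is not None and len(stims) and params.blanking_ms > 0:
            blank = params.blanking_ms * 1e-3
            keep = np.ones(times.size, dtype=bool)
            starts = np.searchsorted(times, stims.times, side="left")
            stops = np.searchsorted(times, stims.times + blank, side="right")
            for a, b in zip(starts, stops):
                keep[a:b] = False
            times = times[keep]
        trains[ch + 1] = times
    return SpikeTrainSet(trains, n_electrodes=raw.n_channels, duration=raw.duration)
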