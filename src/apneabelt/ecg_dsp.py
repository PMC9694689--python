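"""ECG denoising and Pan-Tompkins R-peak detection.

The downstream shallow features (RR intervals, R amplitudes, kurtosis-based
EDR) are computed exclusively from the denoised ECG (``stage="denoised"``)
and the detected R-peak sample indices, so this module defines both the
record container and the fiducial-point detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = ["ECGRecord", "RPeakIndex", "denoise", "detect_rpeaks", "refine_rpeaks"]

#: physiological RR guard band (s): intervals outside are treated as detector
#: artefacts, not beats
RR_MIN_S = 0.2
RR_MAX_S = 3.0


@dataclass(frozen=True)
class ECGRecord:
    """Uniformly sampled single-lead ECG in millivolts.

    Parameters
    ----------
    samples : ndarray
        Signal values in mV.
    fs : float
        Sampling rate in Hz.
    stage : {"raw", "denoised"}
        Processing stage; R-peak detection requires ``"denoised"``.
    """

    samples: np.ndarray
    fs: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.stage not in ("raw", "denoised"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.samples.ndim != 1:
            raise ValueError("ECG must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RPeakIndex:
    """Ordered 0-based sample positions of detected R peaks."""

    indices: np.ndarray
    fs: float = field(default=0.0)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def count(self) -> int:
        return len(self)

    def times(self, fs: float | None = None) -> np.ndarray:
        fs = fs or self.fs
        return self.indices / fs


def denoise(record: ECGRecord, band: tuple[float, float] = (0.5, 40.0),
            order: int = 4, notch_hz: float = 50.0) -> ECGRecord:
    """Remove baseline wander and high-frequency/powerline noise.

    Zero-phase (forward-backward) Butterworth band-pass, default 0.5-40 Hz,
    plus a powerline notch when the sampling rate allows one. Zero phase
    keeps R-peak positions within a sample or two of the raw signal.
    """
    if record.stage != "raw":
        raise ValueError("denoise expects a raw-stage record")
    lo, hi = band
    nyq = record.fs / 2.0
    if hi >= nyq:
        raise ValueError(
            f"fs={record.fs} Hz too low for denoising band {band}: "
            f"upper edge {hi} Hz >= Nyquist {nyq} Hz")
    if record.samples.size < int(2 * record.fs):
        raise ValueError("need at least 2 s of signal to denoise")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=record.fs, output="sos")
    y = sps.sosfiltfilt(sos, record.samples)
    if notch_hz is not None and notch_hz < 0.9 * nyq:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=record.fs)
        y = sps.filtfilt(b, a, y)
    return ECGRecord(samples=y, fs=record.fs, stage="denoised")


def refine_rpeaks(samples: np.ndarray, indices: np.ndarray, fs: float,
                  window_s: float = 0.05) -> np.ndarray:
    """Snap each candidate index to the local maximum of ``samples``
    within +-``window_s``. Idempotent: refining a refined set is a no-op."""
    half = max(1, int(round(window_s * fs)))
    n = samples.size
    out = np.empty(indices.size, dtype=np.int64)
    for k, i in enumerate(indices):
        a, b = max(0, i - half), min(n, i + half + 1)
        out[k] = a + int(np.argmax(samples[a:b]))
    out = np.unique(out)
    return out


def _enforce_refractory(samples: np.ndarray, indices: np.ndarray, fs: float,
                        min_rr_s: float = RR_MIN_S) -> np.ndarray:
    """Drop the smaller of any pair of peaks closer than ``min_rr_s``."""
    if indices.size < 2:
        return indices
    keep: list[int] = [int(indices[0])]
    for i in indices[1:]:
        if (i - keep[-1]) / fs < min_rr_s:
            if samples[i] > samples[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    return np.asarray(keep, dtype=np.int64)


def detect_rpeaks(record: ECGRecord) -> RPeakIndex:
    """Pan-Tompkins QRS detection on a denoised record.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, dual adaptive thresholds with 200 ms
    refractory period and RR-based search-back. Every threshold is relative
    to running signal/noise peak estimates, so detection is invariant to
    positive rescaling of the input. Detected fiducials are refined to the
    local maximum of the denoised ECG within +-50 ms.
    """
    if record.stage != "denoised":
        raise ValueError("detect_rpeaks expects a denoised record")
    fs = record.fs
    if fs < 100:
        raise ValueError("detect_rpeaks requires fs >= 100 Hz")
    x = record.samples
    if x.size < int(2 * fs):
        raise ValueError("record shorter than 2 s")
    if np.std(x) == 0:
        warnings.warn("zero-variance ECG: no beats detectable", stacklevel=2)
        return RPeakIndex(indices=np.empty(0, dtype=np.int64), fs=fs)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # five-point derivative, antisymmetric => no phase shift with mode="same"
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel[::-1], mode="same")
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        warnings.warn("no candidate peaks found", stacklevel=2)
        return RPeakIndex(indices=np.empty(0, dtype=np.int64), fs=fs)

    # threshold initialization from the first 2 s of the integrated signal
    head = mwi[: int(2 * fs)]
    spki = float(np.max(head))
    npki = float(np.mean(head)) * 0.5
    thr1 = npki + 0.25 * (spki - npki)

    detections: list[int] = []
    rr_hist: list[float] = []
    last_unchecked = 0  # candidate pointer for search-back
    for ci, c in enumerate(cand):
        p = mwi[c]
        if p > thr1:
            if detections:
                rr_hist.append((c - detections[-1]) / fs)
                rr_hist = rr_hist[-8:]
            detections.append(int(c))
            spki = 0.125 * p + 0.875 * spki
            last_unchecked = ci + 1
        else:
            npki = 0.125 * p + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)

        # search-back: expected beat missed?
        if detections and rr_hist:
            rr_avg = float(np.mean(rr_hist))
            if (c - detections[-1]) / fs > 1.66 * rr_avg:
                thr2 = 0.5 * thr1
                best, best_p = -1, -np.inf
                for cj in cand[last_unchecked:ci + 1]:
                    if cj <= detections[-1] + refractory:
                        continue
                    pj = mwi[cj]
                    # ties resolved to the earlier candidate (strict >)
                    if pj > thr2 and pj > best_p:
                        best, best_p = int(cj), pj
                if best >= 0:
                    detections.append(best)
                    detections.sort()
                    spki = 0.25 * best_p + 0.75 * spki
                    thr1 = npki + 0.25 * (spki - npki)
                last_unchecked = ci + 1

    idx = np.asarray(sorted(set(detections)), dtype=np.int64)
    idx = refine_rpeaks(x, idx, fs)
    idx = _enforce_refractory(x, idx, fs)
    return RPeakIndex(indices=idx, fs=fs)
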