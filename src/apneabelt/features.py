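"""Shallow ECG feature signals: RR intervals, R amplitudes, kurtosis EDR.

Three per-beat streams are derived from the denoised ECG (ECGF) and the
R-peak index sequence (RP_idx, length L):

* ``RRI[i]  = (RP_idx[i+1] - RP_idx[i]) / fs``            (L-1 values, s)
* ``RAMP[i] = ECGF[RP_idx[i]]``                           (L values, mV)
* ``EDR[i]`` from the excess kurtosis ``K_i`` and standard deviation
  ``sigma_i`` of the inter-peak segment ``ECGFS_i`` (L-1 values):

      EDR_i = sqrt( (sqrt(sigma^4 + (gamma4 - 3 sigma^4) K) - sigma^2)
                    / (gamma4 - 3 sigma^4) )

  Because ``gamma4``, ``sigma`` and ``K`` come from the same segment, the
  moment identity ``gamma4 = sigma^4 (K + 3)`` reduces this to the closed
  form ``EDR_i = sqrt((sqrt(1 + K^2) - 1) / (sigma^2 K))``; the removable
  singularity at K -> 0 has limit 0 (a Gaussian segment carries no
  respiratory modulation), and K < 0 (expression negative under the outer
  root) is defined as 0 with a warning.

The EDR stream tracks beat-morphology modulation by breathing and acts as a
pseudo-respiration signal. Per-beat streams are cubic-spline interpolated to
a common uniform grid (default 3 Hz) and cut into per-minute, per-record
z-scored 3-channel segments for the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle

from .ecg_dsp import ECGRecord, RPeakIndex

__all__ = [
    "EDRComponents", "BeatSeries", "MinuteSegment",
    "compute_rri", "compute_ramp", "beat_segments", "excess_kurtosis",
    "segment_moments", "edr_sample", "edr_sample_printed", "edr_series",
    "compute_beat_series", "hrv_summary", "segment_minutes",
]

EPS_KURTOSIS = 1e-8  # |K| below this is treated as the Gaussian limit


@dataclass(frozen=True)
class EDRComponents:
    """Per-segment moments feeding one EDR sample."""

    kurtosis: float   # excess kurtosis K_i (dimensionless)
    sigma: float      # standard deviation of the segment (mV)
    gamma4: float     # fourth central moment (mV^4)


@dataclass(frozen=True)
class BeatSeries:
    """Per-beat feature streams plus their uniformly resampled versions."""

    beat_times: np.ndarray    # R-peak times (s), length L
    rri: np.ndarray           # length L-1, seconds
    ramp: np.ndarray          # length L, mV
    edr: np.ndarray           # length L-1, dimensionless
    uniform_fs: float
    grid_times: np.ndarray
    rri_u: np.ndarray
    ramp_u: np.ndarray
    edr_u: np.ndarray


@dataclass(frozen=True)
class MinuteSegment:
    """One 60-s window: (N, 3) feature sequence + binary apnea label."""

    features: np.ndarray      # shape (N, 3), channels (RRI, RAMP, EDR)
    label: int
    minute_index: int


def compute_rri(rpeaks: RPeakIndex, fs: float) -> np.ndarray:
    """RR intervals in seconds: successive R-index differences over fs."""
    if len(rpeaks) < 2:
        raise ValueError("need at least two R peaks for RR intervals")
    return np.diff(rpeaks.indices) / fs


def compute_ramp(ecgf: ECGRecord, rpeaks: RPeakIndex) -> np.ndarray:
    """R amplitudes: the denoised ECG sampled at each R index."""
    idx = rpeaks.indices
    if idx.size and (idx[0] < 0 or idx[-1] >= ecgf.samples.size):
        raise IndexError("R-peak index outside the record")
    return ecgf.samples[idx]


def beat_segments(ecgf: ECGRecord, rpeaks: RPeakIndex):
    """Inter-peak segments ECGFS_i, inclusive of both endpoint samples,
    so each has length J_i = RP_idx[i+1] - RP_idx[i] + 1."""
    idx = rpeaks.indices
    if idx.size and (idx[0] < 0 or idx[-1] >= ecgf.samples.size):
        raise IndexError("R-peak index outside the record")
    return [ecgf.samples[idx[i]: idx[i + 1] + 1] for i in range(idx.size - 1)]


def excess_kurtosis(segment: np.ndarray) -> float:
    """Excess kurtosis m4/m2^2 - 3 with biased central moments (1/n sums)."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least two samples")
    if np.ptp(x) == 0:
        raise ValueError("degenerate flat segment: zero variance")
    d = x - x.mean()
    m2 = np.mean(d ** 2)
    if m2 == 0:
        raise ValueError("degenerate flat segment: zero variance")
    m4 = np.mean(d ** 4)
    return float(m4 / m2 ** 2 - 3.0)


def segment_moments(segment: np.ndarray) -> EDRComponents:
    x = np.asarray(segment, dtype=float)
    d = x - x.mean()
    sigma = float(np.sqrt(np.mean(d ** 2)))
    gamma4 = float(np.mean(d ** 4))
    return EDRComponents(kurtosis=excess_kurtosis(x), sigma=sigma, gamma4=gamma4)


def edr_sample(kurtosis: float, sigma: float) -> float:
    """One EDR sample from a segment's excess kurtosis and std deviation.

    Closed form sqrt((sqrt(1+K^2)-1)/(sigma^2 K)); K -> 0 resolves to the
    limit 0, K < 0 is defined as 0 with a warning (the printed expression
    is negative under the outer root there).
    """
    if sigma == 0:
        raise ValueError("sigma must be positive")
    if abs(kurtosis) < EPS_KURTOSIS:
        return 0.0
    if kurtosis < 0:
        warnings.warn(f"platykurtic segment (K={kurtosis:.3g}): EDR set to 0",
                      stacklevel=2)
        return 0.0
    return float(np.sqrt((np.sqrt(1.0 + kurtosis ** 2) - 1.0)
                         / (sigma ** 2 * kurtosis)))


def edr_sample_printed(components: EDRComponents) -> float:
    """EDR evaluated exactly as printed, from sigma, gamma4 and K:
    sqrt((sqrt(sigma^4+(gamma4-3 sigma^4)K) - sigma^2)/(gamma4-3 sigma^4)).
    Used as the cross-check oracle for the simplified closed form."""
    k, s, g4 = components.kurtosis, components.sigma, components.gamma4
    denom = g4 - 3.0 * s ** 4
    inner = np.sqrt(s ** 4 + denom * k)
    return float(np.sqrt((inner - s ** 2) / denom))


def edr_series(ecgf: ECGRecord, rpeaks: RPeakIndex,
               uniform_fs: float = 3.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-beat EDR samples plus a cubic-spline uniform stream.

    Each EDR knot sits at the starting R peak of its inter-peak interval;
    outside the first/last knot the edge values are held (no extrapolation).
    Returns ``(edr_per_beat, grid_times, edr_uniform)``.
    """
    if len(rpeaks) < 4:
        raise ValueError("cubic-spline EDR needs at least 4 beats")
    edr = np.empty(len(rpeaks) - 1)
    for i, seg in enumerate(beat_segments(ecgf, rpeaks)):
        c = segment_moments(seg)
        edr[i] = edr_sample(c.kurtosis, c.sigma)
    knots = rpeaks.indices[:-1] / ecgf.fs
    grid = _uniform_grid(ecgf, uniform_fs)
    return edr, grid, _spline_hold(knots, edr, grid)


def _uniform_grid(ecgf: ECGRecord, uniform_fs: float) -> np.ndarray:
    n_u = int(np.floor(ecgf.duration_s * uniform_fs))
    return np.arange(n_u) / uniform_fs


def _spline_hold(knots: np.ndarray, values: np.ndarray,
                 grid: np.ndarray) -> np.ndarray:
    spl = CubicSpline(knots, values, bc_type="natural")
    return spl(np.clip(grid, knots[0], knots[-1]))


def compute_beat_series(ecgf: ECGRecord, rpeaks: RPeakIndex,
                        uniform_fs: float = 3.0) -> BeatSeries:
    """All three per-beat streams resampled onto one uniform grid.

    RRI and EDR knots sit at the left R peak of their interval; RAMP knots
    at each R peak.
    """
    rri = compute_rri(rpeaks, ecgf.fs)
    ramp = compute_ramp(ecgf, rpeaks)
    edr, grid, edr_u = edr_series(ecgf, rpeaks, uniform_fs)
    beat_times = rpeaks.indices / ecgf.fs
    rri_u = _spline_hold(beat_times[:-1], rri, grid)
    ramp_u = _spline_hold(beat_times, ramp, grid)
    return BeatSeries(beat_times=beat_times, rri=rri, ramp=ramp, edr=edr,
                      uniform_fs=uniform_fs, grid_times=grid,
                      rri_u=rri_u, ramp_u=ramp_u, edr_u=edr_u)


def hrv_summary(rri: np.ndarray) -> dict[str, float]:
    """Standard HRV statistics of an RR-interval series.

    Time domain: mean RR, SDNN, RMSSD, pNN50. Frequency domain: LF
    (0.04-0.15 Hz) and HF (0.15-0.4 Hz) band powers of the detrended RRI
    tachogram via Lomb-Scargle at the (irregular) beat times, plus LF/HF.
    """
    rri = np.asarray(rri, dtype=float)
    if rri.size < 2:
        raise ValueError("need at least two RR intervals")
    diffs = np.diff(rri)
    out = {
        "mean_rr_s": float(np.mean(rri)),
        "sdnn_s": float(np.std(rri, ddof=1)),
        "rmssd_s": float(np.sqrt(np.mean(diffs ** 2))),
        "pnn50": float(np.mean(np.abs(diffs) > 0.05)),
    }
    t = np.cumsum(rri) - rri[0]
    y = rri - rri.mean()
    freqs = np.linspace(0.04, 0.4, 200)
    if np.allclose(y, 0):
        power = np.zeros_like(freqs)
    else:
        power = lombscargle(t, y, 2 * np.pi * freqs, normalize=False)
    lf = float(np.trapezoid(power[freqs <= 0.15], freqs[freqs <= 0.15]))
    hf = float(np.trapezoid(power[freqs > 0.15], freqs[freqs > 0.15]))
    out["lf_power"] = lf
    out["hf_power"] = hf
    out["lf_hf"] = lf / hf if hf > 0 else float("nan")
    return out


def segment_minutes(series: BeatSeries, labels: np.ndarray) -> list[MinuteSegment]:
    """Cut the uniform streams into non-overlapping 60-s, 3-channel windows.

    Channels are ordered (RRI, RAMP, EDR) and z-scored per record (over the
    whole uniform stream) before windowing; a trailing partial minute is
    discarded. The number of labels must not exceed the number of full
    minutes covered by the streams.
    """
    labels = np.asarray(labels)
    n_per_min = int(round(60 * series.uniform_fs))
    n_full = series.rri_u.size // n_per_min
    if labels.size > n_full:
        raise ValueError(
            f"{labels.size} minute labels but streams cover only {n_full} "
            "full minutes")
    stack = np.column_stack([series.rri_u, series.ramp_u, series.edr_u])
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (stack - mu) / sd
    segments = []
    for k in range(labels.size):
        win = z[k * n_per_min:(k + 1) * n_per_min]
        segments.append(MinuteSegment(features=win, label=int(labels[k]),
                                      minute_index=k))
    return segments
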