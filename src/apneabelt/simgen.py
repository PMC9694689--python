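"""Synthetic cardiorespiratory signal generator.

Produces labelled single-lead ECG, piezoelectric-belt style respiration and
tri-axial motion traces carrying the apnea/normal signatures used by the
screening pipeline:

* normal minutes: RR intervals mainly 0.8-1.0 s, R amplitude fluctuating
  between 0.6 and 0.8 mV with the respiratory cycle;
* apneic minutes: RR intervals mainly 1.1-1.2 s, R amplitude around 0.6 mV,
  respiration envelope collapsed (breath hold of 10 s or more);
* motion: low-level accelerometer noise with occasional movement bursts.

The ECG is a train of Gaussian PQRST templates placed at cumulative RR
intervals. Each beat is area-balanced (a wide shallow restoration lobe
cancels the beat's net area) so that the band-pass denoiser downstream
preserves the configured R deflection; R peaks are snapped to the sample
grid so the emitted ``true_rpeaks`` are exact.

Everything is driven by one integer seed; per-channel substreams are spawned
deterministically, so identical configs give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .ecg_dsp import ECGRecord, RPeakIndex

__all__ = [
    "SimConfig", "SimOutput", "RespirationTrace", "MotionTrace", "SimEvent",
    "simulate_subject", "write_simulation",
]

# PQRST template: (offset from R [s], Gaussian sigma [s], amplitude rel. R)
_WAVES = (
    (-0.200, 0.045, 0.12),   # P
    (-0.030, 0.010, -0.10),  # Q
    (0.000, 0.015, 1.00),    # R
    (0.030, 0.010, -0.15),   # S
    (0.280, 0.070, 0.30),    # T
)
_RESTORE_CENTER_S = 0.46   # baseline-restoration lobe position
_RESTORE_SIGMA_S = 0.12
_APNEA_RESIDUAL = 0.05     # respiration envelope residual during apnea (>=90% collapse)


@dataclass(frozen=True)
class RespirationTrace:
    """Belt respiration signal in arbitrary voltage-equivalent units."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("respiration samples must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")


@dataclass(frozen=True)
class MotionTrace:
    """Tri-axial acceleration in g."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.x.size == self.y.size == self.z.size):
            raise ValueError("motion channels must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.x ** 2 + self.y ** 2 + self.z ** 2)


@dataclass(frozen=True)
class SimEvent:
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated subject.

    Defaults encode the target signatures: normal RR 0.8-1.0 s at R amplitude
    0.6-0.8 mV, apneic RR 1.1-1.2 s at ~0.6 mV, respiration in the 0.1-1 Hz
    band with breath holds of at least 10 s.
    """

    duration_s: float = 3600.0
    fs_ecg: float = 100.0
    fs_resp: float = 25.0
    fs_motion: float = 25.0
    rr_normal_range: tuple[float, float] = (0.8, 1.0)
    rr_apnea_range: tuple[float, float] = (1.1, 1.2)
    ramp_normal_range: tuple[float, float] = (0.6, 0.8)
    ramp_apnea_mV: float = 0.6
    resp_freq_range: tuple[float, float] = (0.1, 1.0)
    apnea_min_duration_s: float = 8.0
    apnea_rate_per_hour: float = 6.0
    noise_sd_mV: float = 0.02
    baseline_wander_amp_mV: float = 0.1
    motion_event_rate_per_hour: float = 4.0
    seed: int = 0
    # explicit apnea placement ((start_s, duration_s), ...); overrides the
    # Poisson event draw when given
    forced_events: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("rr_normal_range", "rr_apnea_range", "ramp_normal_range",
                     "resp_freq_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        for name in ("duration_s", "apnea_rate_per_hour", "noise_sd_mV",
                     "baseline_wander_amp_mV", "motion_event_rate_per_hour",
                     "apnea_min_duration_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fs_ecg < 100:
            raise ValueError("fs_ecg must be >= 100 Hz")
        lo, hi = self.resp_freq_range
        if not (0.05 <= lo and hi <= 2.0):
            raise ValueError("resp_freq_range must lie within [0.05, 2] Hz")
        if self.fs_resp <= 2 * hi:
            raise ValueError("fs_resp must exceed twice the top respiration frequency")


@dataclass(frozen=True)
class SimOutput:
    ecg: ECGRecord
    respiration: RespirationTrace
    motion: MotionTrace
    true_rpeaks: RPeakIndex
    minute_labels: np.ndarray
    event_log: tuple[SimEvent, ...]
    motion_events: tuple[SimEvent, ...]
    config: SimConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "minute_labels",
                           np.asarray(self.minute_labels, dtype=np.int8))


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _place_events(cfg: SimConfig, rng: np.random.Generator) -> tuple[SimEvent, ...]:
    if cfg.forced_events is not None:
        events = sorted((SimEvent(float(s), float(d)) for s, d in cfg.forced_events),
                        key=lambda e: e.start_s)
        for ev in events:
            if ev.duration_s < cfg.apnea_min_duration_s:
                raise ValueError("forced event shorter than apnea_min_duration_s")
            if ev.start_s < 0 or ev.end_s > cfg.duration_s:
                raise ValueError("forced event does not fit the record")
        for a, b in zip(events, events[1:]):
            if b.start_s < a.end_s:
                raise ValueError("forced events overlap")
        return tuple(events)

    n = rng.poisson(cfg.apnea_rate_per_hour * cfg.duration_s / 3600.0)
    if n == 0:
        return ()
    dur_lo = max(10.0, cfg.apnea_min_duration_s)
    durations = rng.uniform(dur_lo, 30.0, size=n)
    if durations.sum() + 15.0 * n > cfg.duration_s - 10.0:
        raise ValueError("apnea events cannot fit the record duration")
    events: list[SimEvent] = []
    for d in durations:
        for _ in range(1000):
            start = rng.uniform(5.0, cfg.duration_s - d - 5.0)
            cand = SimEvent(float(start), float(d))
            if all(cand.end_s + 10.0 < e.start_s or cand.start_s > e.end_s + 10.0
                   for e in events):
                events.append(cand)
                break
        else:
            raise ValueError("could not place apnea events without overlap")
    return tuple(sorted(events, key=lambda e: e.start_s))


def _in_event(t: float, events: tuple[SimEvent, ...]) -> bool:
    return any(e.start_s <= t < e.end_s for e in events)


def _smooth_track(rng: np.random.Generator, n: int, fs: float,
                  lo: float, hi: float, knot_spacing_s: float = 20.0) -> np.ndarray:
    """Slowly varying random trajectory in [lo, hi] via interpolated knots."""
    if hi == lo:
        return np.full(n, lo)
    n_knots = max(2, int(np.ceil(n / fs / knot_spacing_s)) + 1)
    kt = np.linspace(0, n / fs, n_knots)
    kv = rng.uniform(lo, hi, size=n_knots)
    return np.interp(np.arange(n) / fs, kt, kv)


def _respiration(cfg: SimConfig, rng: np.random.Generator,
                 events: tuple[SimEvent, ...]) -> tuple[RespirationTrace, np.ndarray]:
    n = int(round(cfg.duration_s * cfg.fs_resp))
    f = _smooth_track(rng, n, cfg.fs_resp, *cfg.resp_freq_range)
    phase = 2 * np.pi * np.cumsum(f) / cfg.fs_resp
    amp = 1.0 + 0.2 * (_smooth_track(rng, n, cfg.fs_resp, -1, 1, 30.0))
    hold = np.zeros(n)
    t = np.arange(n) / cfg.fs_resp
    for ev in events:
        hold[(t >= ev.start_s) & (t < ev.end_s)] = 1.0
    # ~0.5 s smooth transition into/out of the breath hold
    k = max(1, int(round(0.5 * cfg.fs_resp)))
    kernel = np.hanning(2 * k + 1)
    hold = np.convolve(hold, kernel / kernel.sum(), mode="same")
    envelope = 1.0 - (1.0 - _APNEA_RESIDUAL) * hold
    x = amp * envelope * np.sin(phase) + 0.02 * rng.standard_normal(n)
    return RespirationTrace(samples=x, fs=cfg.fs_resp), phase


def _motion(cfg: SimConfig, rng: np.random.Generator) -> tuple[MotionTrace, tuple[SimEvent, ...]]:
    n = int(round(cfg.duration_s * cfg.fs_motion))
    chans = [0.005 * rng.standard_normal(n) for _ in range(3)]
    n_ev = rng.poisson(cfg.motion_event_rate_per_hour * cfg.duration_s / 3600.0)
    bursts: list[SimEvent] = []
    for _ in range(n_ev):
        d = rng.uniform(2.0, 5.0)
        start = rng.uniform(0.0, max(cfg.duration_s - d, 0.0))
        a = rng.uniform(0.2, 0.5)
        i0, i1 = int(start * cfg.fs_motion), int((start + d) * cfg.fs_motion)
        for c in chans:
            c[i0:i1] += a * rng.standard_normal(i1 - i0)
        bursts.append(SimEvent(float(start), float(d)))
    return (MotionTrace(x=chans[0], y=chans[1], z=chans[2], fs=cfg.fs_motion),
            tuple(sorted(bursts, key=lambda e: e.start_s)))


def _ecg(cfg: SimConfig, rng: np.random.Generator, events: tuple[SimEvent, ...],
         resp_phase: np.ndarray) -> tuple[ECGRecord, RPeakIndex]:
    fs = cfg.fs_ecg
    n = int(round(cfg.duration_s * fs))
    x = np.zeros(n)
    mid = 0.5 * (cfg.ramp_normal_range[0] + cfg.ramp_normal_range[1])
    half = 0.5 * (cfg.ramp_normal_range[1] - cfg.ramp_normal_range[0])

    t = 1.5  # clear of the denoiser's edge transient
    rpeaks: list[int] = []
    amps: list[float] = []
    while t < cfg.duration_s - 0.6:
        idx = int(round(t * fs))
        apneic = _in_event(t, events)
        if apneic:
            a = cfg.ramp_apnea_mV + 0.002 * rng.standard_normal()
            rr = rng.uniform(*cfg.rr_apnea_range)
        else:
            ph = resp_phase[min(int(t * cfg.fs_resp), resp_phase.size - 1)]
            a = mid + half * np.sin(ph) + 0.002 * rng.standard_normal()
            rr = rng.uniform(*cfg.rr_normal_range)
        rpeaks.append(idx)
        amps.append(float(a))
        t += rr

    # superpose area-balanced PQRST templates; two restoration lobes at
    # +-_RESTORE_CENTER_S cancel both the net area and the first moment of
    # the waves, so the band-pass denoiser sees essentially no sub-band
    # content even at the train edges and R deflections survive intact
    net_area = sum(amp * sig for _, sig, amp in _WAVES)      # / sqrt(2*pi)
    net_m1 = sum(amp * sig * off for off, sig, amp in _WAVES)
    area_right = 0.5 * (-net_area - net_m1 / _RESTORE_CENTER_S)
    area_left = -net_area - area_right
    waves = _WAVES + (
        (_RESTORE_CENTER_S, _RESTORE_SIGMA_S, area_right / _RESTORE_SIGMA_S),
        (-_RESTORE_CENTER_S, _RESTORE_SIGMA_S, area_left / _RESTORE_SIGMA_S),
    )
    span = int(round(0.9 * fs))
    rel = np.arange(-span, span + 1) / fs
    for idx, a in zip(rpeaks, amps):
        beat = np.zeros(rel.size)
        for off, sig, amp in waves:
            beat += amp * np.exp(-0.5 * ((rel - off) / sig) ** 2)
        # scale so the R deflection equals the configured amplitude exactly
        beat *= a / beat[span]
        lo, hi = idx - span, idx + span + 1
        blo, bhi = max(0, lo), min(n, hi)
        x[blo:bhi] += beat[blo - lo: beat.size - (hi - bhi)]

    if cfg.baseline_wander_amp_mV > 0:
        tt = np.arange(n) / fs
        for frac, f0 in ((0.7, rng.uniform(0.15, 0.25)), (0.3, rng.uniform(0.25, 0.33))):
            x += frac * cfg.baseline_wander_amp_mV * np.sin(
                2 * np.pi * f0 * tt + rng.uniform(0, 2 * np.pi))
    if cfg.noise_sd_mV > 0:
        x += cfg.noise_sd_mV * rng.standard_normal(n)

    return (ECGRecord(samples=x, fs=fs, stage="raw"),
            RPeakIndex(indices=np.asarray(rpeaks, dtype=np.int64), fs=fs))


def minute_labels_from_events(events: tuple[SimEvent, ...], n_minutes: int,
                              min_overlap_s: float) -> np.ndarray:
    """A minute is apneic iff its overlap with any single event reaches
    ``min_overlap_s`` (default rule threshold: 8 s)."""
    labels = np.zeros(n_minutes, dtype=np.int8)
    for k in range(n_minutes):
        w0, w1 = 60.0 * k, 60.0 * (k + 1)
        for ev in events:
            overlap = min(w1, ev.end_s) - max(w0, ev.start_s)
            if overlap >= min_overlap_s:
                labels[k] = 1
                break
    return labels


def simulate_subject(config: SimConfig) -> SimOutput:
    """Generate one subject's ECG, respiration and motion with ground truth.

    Fully reproducible: identical configs (including seed) give bit-identical
    output.
    """
    if config.duration_s < 60:
        raise ValueError("duration_s must cover at least one minute")
    ev_rng, resp_rng, ecg_rng, mot_rng = _spawn(config.seed, 4)
    events = _place_events(config, ev_rng)
    respiration, resp_phase = _respiration(config, resp_rng, events)
    ecg, rpeaks = _ecg(config, ecg_rng, events, resp_phase)
    motion, bursts = _motion(config, mot_rng)
    n_minutes = int(config.duration_s // 60)
    labels = minute_labels_from_events(events, n_minutes, config.apnea_min_duration_s)
    return SimOutput(ecg=ecg, respiration=respiration, motion=motion,
                     true_rpeaks=rpeaks, minute_labels=labels,
                     event_log=events, motion_events=bursts, config=config)


def write_simulation(sim: SimOutput, directory: str | Path) -> dict:
    """Write CSV per channel plus a JSON manifest; returns the manifest.

    Round-trips through the package's CSV readers, and re-simulating from
    ``manifest["config"]`` reproduces the samples bit-identically.
    """
    from . import io as abio  # deferred: io imports our types

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    abio.write_signal_csv(directory / "ecg.csv", {"ecg_mV": sim.ecg.samples}, sim.ecg.fs)
    abio.write_signal_csv(directory / "respiration.csv",
                          {"resp_au": sim.respiration.samples}, sim.respiration.fs)
    abio.write_signal_csv(directory / "motion.csv",
                          {"x_g": sim.motion.x, "y_g": sim.motion.y, "z_g": sim.motion.z},
                          sim.motion.fs)
    cfg = asdict(sim.config)
    manifest = {
        "config": cfg,
        "seed": sim.config.seed,
        "minute_labels": [int(v) for v in sim.minute_labels],
        "event_log": [{"start_s": e.start_s, "duration_s": e.duration_s}
                      for e in sim.event_log],
        "motion_events": [{"start_s": e.start_s, "duration_s": e.duration_s}
                          for e in sim.motion_events],
        "true_rpeaks": [int(i) for i in sim.true_rpeaks.indices],
        "files": {"ecg": "ecg.csv", "respiration": "respiration.csv",
                  "motion": "motion.csv"},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def config_from_manifest(manifest: dict) -> SimConfig:
    cfg = dict(manifest["config"])
    for key in ("rr_normal_range", "rr_apnea_range", "ramp_normal_range",
                "resp_freq_range"):
        cfg[key] = tuple(cfg[key])
    if cfg.get("forced_events") is not None:
        cfg["forced_events"] = tuple(tuple(e) for e in cfg["forced_events"])
    return SimConfig(**cfg)
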