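"""Readers, writers, configuration and the end-to-end screening pipeline.

CSV signal files carry their sampling rate in a ``# fs_hz=...`` comment line
followed by a normal header row, so a file is self-describing. A small WFDB
subset (format-16 signals, MIT-format annotations restricted to the per-
minute apnea convention 'A'/'N') supports the optional Apnea-ECG loader and
round-trips records written by this package.

:func:`run_pipeline` chains denoise -> R peaks -> features -> minute
segmentation -> classifier (plus breathing rule and motion gating when those
channels are present) into a :class:`ScreeningReport`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
import time
import urllib.request
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .conditioning import apply_chain, ecg_chain, respiration_chain
from .detect import (ApneaEvent, LSTMSpec, breathing_rule, compute_ahi,
                     evaluate, motion_gate, predict_minutes)
from .ecg_dsp import ECGRecord, RPeakIndex, denoise, detect_rpeaks
from .features import compute_beat_series, segment_minutes
from .simgen import MotionTrace, RespirationTrace, SimConfig, simulate_subject

logger = logging.getLogger("apneabelt")

__all__ = [
    "PipelineConfig", "ScreeningReport", "load_config", "config_hash",
    "read_csv_signals", "write_signal_csv",
    "read_wfdb_record", "write_wfdb_record",
    "read_wfdb_annotations", "write_wfdb_annotations",
    "run_pipeline", "synthesize_training_minutes", "fetch_apnea_ecg",
]


# ---------------------------------------------------------------------------
# configuration


class SimgenSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
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


class DspSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    band_low_hz: float = 0.5
    band_high_hz: float = 40.0
    order: int = 4
    notch_hz: float = 50.0


class FeaturesSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    uniform_fs: float = 3.0


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    num_lstm_layers: int = 3
    lstm_hidden: int = 64
    dense_sizes: tuple[int, ...] = (128, 64, 32, 1)
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32

    def to_spec(self) -> LSTMSpec:
        return LSTMSpec(num_lstm_layers=self.num_lstm_layers,
                        lstm_hidden=self.lstm_hidden,
                        dense_sizes=tuple(self.dense_sizes),
                        epochs=self.epochs,
                        learning_rate=self.learning_rate,
                        batch_size=self.batch_size)


class DetectSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    breathing_threshold_s: float = 8.0
    breathing_window_s: float = 2.0
    breathing_floor_frac: float = 0.2
    motion_threshold_g: float = 0.02


class ConditioningSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    emulate_adc: bool = True


class PipelineConfig(BaseModel):
    """Validated, fully materialized pipeline configuration."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    simgen: SimgenSection = SimgenSection()
    conditioning: ConditioningSection = ConditioningSection()
    dsp: DspSection = DspSection()
    features: FeaturesSection = FeaturesSection()
    model: ModelSection = ModelSection()
    detect: DetectSection = DetectSection()

    def sim_config(self, **overrides) -> SimConfig:
        kw = self.simgen.model_dump()
        kw["seed"] = self.seed
        kw.update(overrides)
        return SimConfig(**kw)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML pipeline config (all defaults when ``path`` is None).
    Unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the semantic config content: changes iff a field changes."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# CSV signals


def write_signal_csv(path: str | Path, channels: dict[str, np.ndarray],
                     fs: float) -> None:
    """One column per channel plus a time column; fs recorded in a comment
    header so files are self-describing."""
    n = len(next(iter(channels.values())))
    df = pd.DataFrame({"time_s": np.arange(n) / fs, **channels})
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={fs!r}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv_with_fs(path: str | Path) -> tuple[pd.DataFrame, float]:
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "fs_hz=" not in first:
        raise ValueError(f"{path}: missing '# fs_hz=...' metadata line")
    fs = float(first.split("fs_hz=")[1])
    df = pd.read_csv(path, comment="#")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: NaN values at rows {rows[:20]}")
    if "time_s" in df and np.any(np.diff(df["time_s"].to_numpy()) <= 0):
        raise ValueError(f"{path}: non-monotonic time column")
    return df, fs


def read_csv_signals(path: str | Path):
    """Read a signal CSV into the appropriate typed trace.

    Column conventions: ``ecg_mV`` -> :class:`ECGRecord` (raw stage),
    ``resp_au`` -> :class:`RespirationTrace`, ``x_g,y_g,z_g`` ->
    :class:`MotionTrace`.
    """
    df, fs = _read_csv_with_fs(path)
    cols = set(df.columns)
    if "ecg_mV" in cols:
        return ECGRecord(samples=df["ecg_mV"].to_numpy(), fs=fs, stage="raw")
    if "resp_au" in cols:
        return RespirationTrace(samples=df["resp_au"].to_numpy(), fs=fs)
    if {"x_g", "y_g", "z_g"} <= cols:
        return MotionTrace(x=df["x_g"].to_numpy(), y=df["y_g"].to_numpy(),
                           z=df["z_g"].to_numpy(), fs=fs)
    raise ValueError(f"{path}: unrecognized channel columns {sorted(cols)}")


# ---------------------------------------------------------------------------
# minimal WFDB subset (format 16)

_ANN_CODES = {"N": 1, "A": 8}
_ANN_SYMBOLS = {v: k for k, v in _ANN_CODES.items()}
_SKIP = 59


def write_wfdb_record(directory: str | Path, name: str, record: ECGRecord,
                      adc_gain: float = 200.0,
                      minute_labels: np.ndarray | None = None) -> Path:
    """Write ``name.hea``/``name.dat`` (format 16, one channel, mV) and an
    optional ``name.apn`` per-minute apnea annotation file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.round(record.samples * adc_gain).astype("<i2")
    header = (f"{name} 1 {record.fs:g} {adc.size}\n"
              f"{name}.dat 16 {adc_gain:g}(0)/mV 16 0 {int(adc[0]) if adc.size else 0} 0 0 ECG\n")
    (directory / f"{name}.hea").write_text(header)
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    if minute_labels is not None:
        write_wfdb_annotations(directory / f"{name}.apn", minute_labels,
                               record.fs)
    return directory / f"{name}.hea"


def read_wfdb_record(path: str | Path, channel: int = 0
                     ) -> tuple[ECGRecord, np.ndarray | None]:
    """Read a WFDB record (format 16) back into mV; returns the record and,
    when a ``.apn`` annotation file is present, its per-minute 0/1 labels."""
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    lines = [ln for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    name, nsig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    if channel >= nsig:
        raise ValueError(f"channel {channel} but record has {nsig} signals")
    sig_fields = lines[1 + channel].split()
    dat_file, fmt = sig_fields[0], sig_fields[1]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB signal format {fmt!r} (only 16)")
    gain_spec = sig_fields[2] if len(sig_fields) > 2 else "200"
    gain_part = gain_spec.split("/")[0]
    units = gain_spec.split("/")[1] if "/" in gain_spec else "mV"
    if units.lower() not in ("mv", "millivolts"):
        raise ValueError(f"unknown units {units!r}")
    if "(" in gain_part:
        gain = float(gain_part[: gain_part.index("(")])
        baseline = int(gain_part[gain_part.index("(") + 1: -1])
    else:
        gain, baseline = float(gain_part), 0
    if gain == 0:
        gain = 200.0
    raw = np.frombuffer((hea.parent / dat_file).read_bytes(), dtype="<i2")
    if nsig > 1:
        raw = raw[: raw.size // nsig * nsig].reshape(-1, nsig)[:, channel]
    samples = (raw.astype(float) - baseline) / gain
    record = ECGRecord(samples=samples, fs=fs, stage="raw")
    apn = hea.parent / f"{name}.apn"
    labels = None
    if apn.exists():
        ann = read_wfdb_annotations(apn)
        labels = np.array([1 if sym == "A" else 0 for _, sym in ann],
                          dtype=np.int8)
    return record, labels


def write_wfdb_annotations(path: str | Path, minute_labels: np.ndarray,
                           fs: float) -> None:
    """MIT-format annotation stream: one 'A'/'N' annotation at the start of
    each labelled minute (times in samples at ``fs``)."""
    out = bytearray()
    prev = 0
    for k, lab in enumerate(np.asarray(minute_labels)):
        t = int(round(k * 60 * fs))
        delta = t - prev
        prev = t
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        code = _ANN_CODES["A" if lab else "N"]
        out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)  # EOF
    Path(path).write_bytes(bytes(out))


def read_wfdb_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read the supported MIT annotation subset; returns (sample, symbol)."""
    data = Path(path).read_bytes()
    anns: list[tuple[int, str]] = []
    t = 0
    pending_skip = 0
    i = 0
    while i + 1 < len(data):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        if code in (60, 61):  # NUM / SUB: modifier, no time
            continue
        if code == 63:  # AUX: length + padded payload
            i += delta + (delta & 1)
            continue
        t += delta + pending_skip
        pending_skip = 0
        anns.append((t, _ANN_SYMBOLS.get(code, "?")))
    return anns


def fetch_apnea_ecg(dest: str | Path, records: list[str] | None = None,
                    base_url: str = "https://physionet.org/files/apnea-ecg/1.0.0"
                    ) -> list[Path]:
    """Download Apnea-ECG records (explicit opt-in; requires network)."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    records = records or ["a01"]
    fetched = []
    for rec in records:
        for ext in ("hea", "dat", "apn"):
            url = f"{base_url}/{rec}.{ext}"
            target = dest / f"{rec}.{ext}"
            logger.info("fetching %s", url)
            urllib.request.urlretrieve(url, target)
            fetched.append(target)
    return fetched


# ---------------------------------------------------------------------------
# screening report and pipeline


@dataclass(frozen=True)
class ScreeningReport:
    """Per-minute screening outcome plus rule/gating context and provenance."""

    n_minutes: int
    probabilities: list | None
    pred_labels: list | None
    usable: list
    breathing_events: list
    ahi: float | None
    metrics: dict | None
    absent: list
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScreeningReport":
        return cls(**json.loads(text))


def run_pipeline(config: PipelineConfig, ecg: ECGRecord,
                 resp: RespirationTrace | None = None,
                 motion: MotionTrace | None = None,
                 model=None,
                 truth_labels: np.ndarray | None = None) -> ScreeningReport:
    """Execute the full screening chain on one record.

    ECG is mandatory; respiration, motion, a trained classifier and truth
    labels are optional, and the report states which are absent.
    Deterministic given the config (no randomness at inference time).
    """
    t0 = time.perf_counter()
    absent = []
    dsp = config.dsp
    ecgf = denoise(ecg, band=(dsp.band_low_hz, dsp.band_high_hz),
                   order=dsp.order, notch_hz=dsp.notch_hz)
    rpeaks = detect_rpeaks(ecgf)
    logger.info("denoise+rpeaks: %d beats in %.1f s of ECG (%.2fs)",
                len(rpeaks), ecg.duration_s, time.perf_counter() - t0)
    series = compute_beat_series(ecgf, rpeaks, config.features.uniform_fs)
    n_minutes = int(ecg.duration_s // 60)
    seg_labels = (np.asarray(truth_labels)[:n_minutes]
                  if truth_labels is not None else np.zeros(n_minutes, dtype=int))
    segments = segment_minutes(series, seg_labels)

    probabilities = pred_labels = None
    if model is not None:
        p, lab = predict_minutes(model, segments)
        probabilities = [float(v) for v in p]
        pred_labels = [int(v) for v in lab]
    else:
        absent.append("classifier")

    if motion is not None:
        usable = motion_gate(motion, n_minutes, config.detect.motion_threshold_g)
    else:
        usable = np.ones(n_minutes, dtype=bool)
        absent.append("motion")

    events = []
    if resp is not None:
        events = breathing_rule(resp,
                                threshold_s=config.detect.breathing_threshold_s,
                                window_s=config.detect.breathing_window_s,
                                floor_frac=config.detect.breathing_floor_frac)
    else:
        absent.append("respiration")

    ahi = None
    if pred_labels is not None and usable.any():
        gated = np.asarray(pred_labels) * usable.astype(int)
        ahi = compute_ahi(gated, usable_hours=float(usable.sum()) / 60.0)

    metrics = None
    if pred_labels is not None and truth_labels is not None:
        metrics = evaluate(pred_labels, seg_labels).as_dict()

    report = ScreeningReport(
        n_minutes=n_minutes,
        probabilities=probabilities,
        pred_labels=pred_labels,
        usable=[bool(v) for v in usable],
        breathing_events=[{"start_s": e.start_s, "duration_s": e.duration_s,
                           "source": e.source} for e in events],
        ahi=ahi,
        metrics=metrics,
        absent=absent,
        provenance={"config_hash": config_hash(config), "seed": config.seed,
                    "apneabelt": __version__, "numpy": np.__version__},
    )
    logger.info("pipeline done: %d minutes, %d events, %.2fs total",
                n_minutes, len(events), time.perf_counter() - t0)
    return report


def synthesize_training_minutes(n_minutes: int = 240, seed: int = 0,
                                apnea_fraction: float = 0.5,
                                uniform_fs: float = 3.0,
                                config: PipelineConfig | None = None):
    """Balanced labelled minute dataset from one long simulated record.

    Apneic minutes are induced by forcing a full-minute apnea event in a
    random ``apnea_fraction`` of minutes, so each minute carries the
    configured class signature end to end (through denoising, R-peak
    detection and feature extraction). Returns ``(segments, sim_output)``.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    apneic = np.sort(rng.choice(n_minutes, size=int(round(apnea_fraction * n_minutes)),
                                replace=False))
    forced = tuple((60.0 * k, 60.0) for k in apneic)
    sim_cfg = config.sim_config(duration_s=60.0 * n_minutes, seed=seed,
                                forced_events=forced)
    sim = simulate_subject(sim_cfg)
    dsp = config.dsp
    ecgf = denoise(sim.ecg, band=(dsp.band_low_hz, dsp.band_high_hz),
                   order=dsp.order, notch_hz=dsp.notch_hz)
    rpeaks = detect_rpeaks(ecgf)
    series = compute_beat_series(ecgf, rpeaks, uniform_fs)
    segments = segment_minutes(series, sim.minute_labels)
    return segments, sim
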