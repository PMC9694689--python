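import numpy as np
import pytest

from apneabelt.detect import LSTMSpec, train_lstm
from apneabelt.ecg_dsp import denoise, detect_rpeaks
from apneabelt.io import PipelineConfig, synthesize_training_minutes
from apneabelt.simgen import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def clean_sim():
    """300 s, noise-free, event-free record with exact ground truth."""
    cfg = SimConfig(duration_s=300, seed=11, apnea_rate_per_hour=0.0,
                    noise_sd_mV=0.0, baseline_wander_amp_mV=0.0,
                    motion_event_rate_per_hour=0.0)
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def apnea_sim():
    """600 s record with two forced apnea events and default noise."""
    cfg = SimConfig(duration_s=600, seed=5,
                    forced_events=((95.0, 20.0), (300.0, 60.0)))
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def denoised_clean(clean_sim):
    return denoise(clean_sim.ecg)


@pytest.fixture(scope="session")
def training_segments():
    """240 balanced minutes carrying the apneic/normal class signatures,
    extracted through the full pipeline (denoise, R peaks, features)."""
    segments, sim = synthesize_training_minutes(n_minutes=240, seed=7)
    return segments


@pytest.fixture(scope="session")
def tiny_trained_model(training_segments):
    """Small, quickly trained classifier for structural pipeline tests."""
    spec = LSTMSpec(lstm_hidden=8, epochs=2)
    model, _ = train_lstm(training_segments[:80], spec, seed=0)
    return model


def match_counts(true_idx, det_idx, tol):
    """Sensitivity/precision of detected indices vs truth within tol samples."""
    true_idx = np.asarray(true_idx)
    det_idx = np.asarray(det_idx)
    if det_idx.size == 0 or true_idx.size == 0:
        return 0.0, 0.0
    sens = np.mean([np.min(np.abs(det_idx - t)) <= tol for t in true_idx])
    prec = np.mean([np.min(np.abs(true_idx - d)) <= tol for d in det_idx])
    return float(sens), float(prec)
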