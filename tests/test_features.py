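import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram
from scipy.stats import kurtosis as scipy_kurtosis

from apneabelt.ecg_dsp import ECGRecord, RPeakIndex, denoise, detect_rpeaks
from apneabelt.features import (EDRComponents, beat_segments,
                                compute_beat_series, compute_ramp, compute_rri,
                                edr_sample, edr_sample_printed, edr_series,
                                excess_kurtosis, hrv_summary, segment_minutes,
                                segment_moments)
from apneabelt.simgen import SimConfig, simulate_subject


# ---------------------------------------------------------------------- RRI

def test_rri_direct_differences():
    rri = compute_rri(RPeakIndex(indices=np.array([0, 100, 200])), fs=100.0)
    assert np.allclose(rri, [1.0, 1.0])
    rri = compute_rri(RPeakIndex(indices=np.array([0, 90, 210])), fs=100.0)
    assert np.allclose(rri, [0.9, 1.2])
    with pytest.raises(ValueError):
        compute_rri(RPeakIndex(indices=np.array([5])), fs=100.0)


def test_rri_recovers_simulator_ground_truth(clean_sim, denoised_clean):
    det = detect_rpeaks(denoised_clean)
    fs = clean_sim.ecg.fs
    true_rri = np.diff(clean_sim.true_rpeaks.indices) / fs
    got_rri = compute_rri(det, fs)
    assert got_rri.size == true_rri.size
    assert np.max(np.abs(got_rri - true_rri)) <= 2 / fs


def test_rri_sum_telescopes(denoised_clean):
    det = detect_rpeaks(denoised_clean)
    rri = compute_rri(det, denoised_clean.fs)
    span = (det.indices[-1] - det.indices[0]) / denoised_clean.fs
    assert rri.sum() == pytest.approx(span, abs=1e-12)


# --------------------------------------------------------------------- RAMP

def test_ramp_recovers_constant_amplitude():
    cfg = SimConfig(duration_s=300, seed=1, ramp_normal_range=(0.7, 0.7),
                    noise_sd_mV=0.0, baseline_wander_amp_mV=0.0,
                    apnea_rate_per_hour=0.0)
    sim = simulate_subject(cfg)
    ramp = compute_ramp(denoise(sim.ecg), sim.true_rpeaks)
    assert np.all(np.abs(ramp - 0.7) <= 0.02)


def test_ramp_single_peak_and_bounds(denoised_clean):
    one = RPeakIndex(indices=np.array([500]))
    assert compute_ramp(denoised_clean, one).tolist() == [
        denoised_clean.samples[500]]
    with pytest.raises(IndexError):
        compute_ramp(denoised_clean, RPeakIndex(
            indices=np.array([denoised_clean.samples.size + 5])))


def test_ramp_lower_in_apneic_minutes(apnea_sim):
    ecgf = denoise(apnea_sim.ecg)
    ramp = compute_ramp(ecgf, apnea_sim.true_rpeaks)
    minute = (apnea_sim.true_rpeaks.indices / ecgf.fs // 60).astype(int)
    lab = apnea_sim.minute_labels[minute]
    assert ramp[lab == 1].mean() < ramp[lab == 0].mean()


# ----------------------------------------------------------------- kurtosis

def test_kurtosis_alternating_is_minus_two():
    assert excess_kurtosis(np.array([1.0, -1.0, 1.0, -1.0])) == pytest.approx(-2.0)


def test_kurtosis_constant_segment_errors():
    with pytest.raises(ValueError, match="variance"):
        excess_kurtosis(np.full(50, 3.3))


def test_kurtosis_gaussian_limit():
    x = np.random.default_rng(0).standard_normal(10 ** 6)
    assert abs(excess_kurtosis(x)) < 0.02


def test_kurtosis_matches_scipy_oracle():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        x = rng.standard_normal(rng.integers(5, 200)) * rng.uniform(0.1, 5)
        assert excess_kurtosis(x) == pytest.approx(
            scipy_kurtosis(x, fisher=True, bias=True), abs=1e-10)


@settings(deadline=None, derandomize=True)
@given(st.floats(0.01, 100.0))
def test_kurtosis_scale_invariant(scale):
    x = np.array([0.1, 0.5, -0.3, 2.0, -1.2, 0.05, 0.9])
    assert excess_kurtosis(scale * x) == pytest.approx(excess_kurtosis(x),
                                                       rel=1e-9)


# ---------------------------------------------------------------------- EDR

def test_edr_worked_example():
    # K=3, sigma=1 (gamma4=6): sqrt((sqrt(10)-1)/3)
    val = edr_sample(3.0, 1.0)
    assert val == pytest.approx(np.sqrt((np.sqrt(10) - 1) / 3), abs=1e-12)
    assert val == pytest.approx(0.8490, abs=5e-5)
    printed = edr_sample_printed(EDRComponents(kurtosis=3.0, sigma=1.0,
                                               gamma4=6.0))
    assert abs(val - printed) < 1e-9


def test_edr_gaussian_limit_and_guards():
    assert edr_sample(0.0, 1.0) == 0.0
    assert edr_sample(1e-12, 0.5) == 0.0
    with pytest.warns(UserWarning):
        assert edr_sample(-0.5, 1.0) == 0.0
    with pytest.raises(ValueError):
        edr_sample(1.0, 0.0)


def test_edr_printed_equals_simplified_form():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        k = rng.uniform(1e-6, 50)
        s = rng.uniform(0.01, 10)
        printed = edr_sample_printed(EDRComponents(
            kurtosis=k, sigma=s, gamma4=s ** 4 * (k + 3)))
        assert abs(edr_sample(k, s) - printed) < 1e-9


def test_moment_identity_on_simulated_beats(denoised_clean):
    det = detect_rpeaks(denoised_clean)
    for seg in beat_segments(denoised_clean, det)[:50]:
        c = segment_moments(seg)
        assert c.gamma4 == pytest.approx(c.sigma ** 4 * (c.kurtosis + 3),
                                         rel=1e-10)


def test_beat_segment_lengths_follow_index_differences(denoised_clean):
    det = detect_rpeaks(denoised_clean)
    segs = beat_segments(denoised_clean, det)
    for seg, j in zip(segs, np.diff(det.indices) + 1):
        assert seg.size == j


def test_edr_series_recovers_respiratory_modulation():
    cfg = SimConfig(duration_s=300, seed=2, rr_normal_range=(0.9, 0.9),
                    resp_freq_range=(0.25, 0.25), noise_sd_mV=0.0,
                    baseline_wander_amp_mV=0.0, apnea_rate_per_hour=0.0)
    sim = simulate_subject(cfg)
    ecgf = denoise(sim.ecg)
    _, grid, edr_u = edr_series(ecgf, detect_rpeaks(ecgf), uniform_fs=3.0)
    assert np.allclose(np.diff(grid), 1 / 3.0)
    f, p = periodogram(edr_u - edr_u.mean(), fs=3.0)
    sel = (f > 0.05) & (f < 1.4)
    assert abs(f[sel][np.argmax(p[sel])] - 0.25) <= 0.05


def test_edr_series_flat_for_constant_morphology():
    cfg = SimConfig(duration_s=300, seed=3, rr_normal_range=(0.9, 0.9),
                    ramp_normal_range=(0.7, 0.7), noise_sd_mV=0.0,
                    baseline_wander_amp_mV=0.0, apnea_rate_per_hour=0.0)
    sim = simulate_subject(cfg)
    ecgf = denoise(sim.ecg)
    edr, _, _ = edr_series(ecgf, sim.true_rpeaks, uniform_fs=3.0)
    assert edr.std() / edr.mean() < 0.1


def test_edr_series_needs_four_beats(denoised_clean):
    with pytest.raises(ValueError, match="4 beats"):
        edr_series(denoised_clean, RPeakIndex(indices=np.array([100, 200, 300])))


# ---------------------------------------------------------------------- HRV

def test_hrv_constant_series_zero_variability():
    out = hrv_summary(np.full(100, 0.9))
    assert out["sdnn_s"] == pytest.approx(0.0, abs=1e-12)
    assert out["rmssd_s"] == pytest.approx(0.0, abs=1e-12)
    assert out["pnn50"] == 0
    assert out["mean_rr_s"] == pytest.approx(0.9)


def test_hrv_rmssd_single_difference():
    assert hrv_summary(np.array([0.8, 0.9]))["rmssd_s"] == pytest.approx(0.1)


def test_hrv_lf_band_oscillation_dominates():
    n = 600
    beat_t = np.cumsum(np.full(n, 0.9))
    rri = 0.9 + 0.05 * np.sin(2 * np.pi * 0.1 * beat_t)
    out = hrv_summary(rri)
    assert out["lf_hf"] > 1

    with pytest.raises(ValueError):
        hrv_summary(np.array([0.9]))


# ----------------------------------------------------------- minute windows

def test_segment_minutes_shapes_and_normalization(clean_sim, denoised_clean):
    det = detect_rpeaks(denoised_clean)
    series = compute_beat_series(denoised_clean, det, uniform_fs=3.0)
    segs = segment_minutes(series, clean_sim.minute_labels)
    assert len(segs) == 5
    assert all(s.features.shape == (180, 3) for s in segs)
    stacked = np.concatenate([s.features for s in segs])
    assert np.all(np.abs(stacked.mean(axis=0)) < 0.1)
    assert np.all(np.abs(stacked.std(axis=0) - 1) < 0.1)


def test_segment_labels_pass_through(apnea_sim):
    ecgf = denoise(apnea_sim.ecg)
    series = compute_beat_series(ecgf, detect_rpeaks(ecgf), uniform_fs=3.0)
    segs = segment_minutes(series, apnea_sim.minute_labels)
    assert [s.label for s in segs] == apnea_sim.minute_labels.tolist()


def test_segment_minutes_label_mismatch_errors(denoised_clean):
    det = detect_rpeaks(denoised_clean)
    series = compute_beat_series(denoised_clean, det, uniform_fs=3.0)
    with pytest.raises(ValueError, match="labels"):
        segment_minutes(series, np.zeros(99, dtype=int))
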