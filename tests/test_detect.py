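import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apneabelt.detect import (BASELINE_NAMES, ApneaEvent, ConfusionSummary,
                              LSTMSpec, TrainingBatch, bce_grad, bce_loss,
                              bce_loss_single_term, breathing_rule,
                              compute_ahi, evaluate, motion_gate,
                              predict_minutes, stratified_split,
                              train_baselines, train_lstm)
from apneabelt.features import MinuteSegment
from apneabelt.simgen import MotionTrace, RespirationTrace


# --------------------------------------------------------------------- loss

def test_bce_perfect_prediction_near_zero():
    batch = TrainingBatch(Y=np.array([1.0, 0.0]), P=np.array([1.0, 0.0]))
    assert bce_loss(batch) < 1e-5


def test_bce_maximal_uncertainty_is_ln2():
    batch = TrainingBatch(Y=np.array([1.0, 0.0]), P=np.array([0.5, 0.5]))
    assert bce_loss(batch) == pytest.approx(np.log(2), abs=1e-12)


def test_bce_gradient_matches_finite_differences():
    Y = np.array([1.0, 0.0, 1.0, 0.0])
    P = np.array([0.7, 0.3, 0.2, 0.8])
    g = bce_grad(TrainingBatch(Y=Y, P=P))
    eps = 1e-6
    for i in range(4):
        Pp, Pm = P.copy(), P.copy()
        Pp[i] += eps
        Pm[i] -= eps
        fd = (bce_loss(TrainingBatch(Y=Y, P=Pp)) -
              bce_loss(TrainingBatch(Y=Y, P=Pm))) / (2 * eps)
        assert abs(g[i] - fd) / abs(fd) < 1e-4


def test_bce_empty_batch_errors_and_single_term_value():
    with pytest.raises(ValueError):
        bce_loss(TrainingBatch(Y=np.array([]), P=np.array([])))
    batch = TrainingBatch(Y=np.array([1.0, 0.0]), P=np.array([0.1, 0.9]))
    # one-term base-10 form only sees the positive sample
    assert bce_loss_single_term(batch) == pytest.approx(-np.log10(0.1))


# ------------------------------------------------------------------ metrics

def test_confusion_summary_worked_example():
    s = evaluate(np.r_[np.ones(9), np.zeros(1), np.ones(2), np.zeros(8)],
                 np.r_[np.ones(10), np.zeros(10)])
    assert (s.TP, s.FN, s.FP, s.TN) == (9, 1, 2, 8)
    assert s.Se == pytest.approx(0.9)
    assert s.Sp == pytest.approx(0.8)
    assert s.PPV == pytest.approx(9 / 11)
    assert s.Acc == pytest.approx(0.85)
    assert s.F == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))


def test_perfect_and_degenerate_predictors():
    y = np.array([1, 0, 1, 0])
    perfect = evaluate(y, y)
    assert (perfect.Se, perfect.Sp, perfect.PPV, perfect.Acc, perfect.F) == \
        (1, 1, 1, 1, 1)
    allpos = evaluate(np.ones(4), y)
    assert (allpos.Se, allpos.Sp, allpos.Acc) == (1, 0, 0.5)
    # no true positives predicted and none present -> undefined ratios are NaN
    empty = evaluate(np.zeros(3), np.zeros(3))
    assert np.isnan(empty.Se) and np.isnan(empty.PPV) and empty.Sp == 1


def test_evaluate_length_mismatch():
    with pytest.raises(ValueError):
        evaluate(np.ones(3), np.ones(4))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
       st.integers(0, 50))
def test_metrics_match_direct_count_oracle(tp, fp, tn, fn):
    pred = np.r_[np.ones(tp), np.ones(fp), np.zeros(tn), np.zeros(fn)]
    truth = np.r_[np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)]
    if pred.size == 0:
        return
    s = evaluate(pred, truth)
    assert (s.TP, s.FP, s.TN, s.FN) == (tp, fp, tn, fn)
    if tp + fn:
        assert s.Se == pytest.approx(tp / (tp + fn))
    if tn + fp:
        assert s.Sp == pytest.approx(tn / (tn + fp))
    if tp + fp:
        assert s.PPV == pytest.approx(tp / (tp + fp))
    assert s.Acc == pytest.approx((tp + tn) / pred.size)


def test_adding_true_positive_never_decreases_se_acc_f():
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, fp, tn, fn = rng.integers(1, 30, size=4)
        a = ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn)
        b = ConfusionSummary(TP=tp + 1, FP=fp, TN=tn, FN=fn)
        assert b.Se >= a.Se and b.Acc >= a.Acc and b.F >= a.F


# ---------------------------------------------------------------------- AHI

def test_ahi_examples():
    assert compute_ahi([ApneaEvent(0, 10)] * 6, usable_hours=2.0) == 3.0
    assert compute_ahi([], usable_hours=1.0) == 0.0
    assert compute_ahi(np.array([0, 1, 1, 0, 1]), usable_hours=5 / 60) == \
        pytest.approx(24.0)
    with pytest.raises(ValueError):
        compute_ahi([], usable_hours=0.0)


# ----------------------------------------------------------- breathing rule

def _sine_resp(duration=120.0, fs=25.0, f0=0.3, collapse=None):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * f0 * t)
    if collapse is not None:
        start, dur = collapse
        x[(t >= start) & (t < start + dur)] = 0.0
    return RespirationTrace(samples=x, fs=fs)


def test_breathing_rule_boundary_at_eight_seconds():
    assert breathing_rule(_sine_resp(collapse=(55.0, 7.5))) == []
    events = breathing_rule(_sine_resp(collapse=(55.0, 8.5)))
    assert len(events) == 1
    assert events[0].duration_s >= 8.0


def test_breathing_rule_finds_simulated_breath_hold(apnea_sim):
    events = breathing_rule(apnea_sim.respiration)
    for ev in apnea_sim.event_log:
        assert any(e.start_s < ev.end_s and ev.start_s < e.end_s
                   for e in events), f"missed hold at {ev.start_s}"


def test_breathing_rule_normal_trace_clean():
    assert breathing_rule(_sine_resp()) == []


def test_breathing_rule_silent_channel_flags_everything():
    trace = RespirationTrace(samples=np.zeros(3000), fs=25.0)
    with pytest.warns(UserWarning):
        events = breathing_rule(trace)
    assert len(events) == 1 and events[0].duration_s == pytest.approx(120.0)


# -------------------------------------------------------------- motion gate

def test_motion_gate_zero_trace_all_usable():
    fs = 25.0
    quiet = MotionTrace(x=np.zeros(int(300 * fs)), y=np.zeros(int(300 * fs)),
                        z=np.zeros(int(300 * fs)), fs=fs)
    flags = motion_gate(quiet, minutes=5)
    assert flags.tolist() == [True] * 5


def test_motion_gate_burst_minute_flagged():
    fs = 25.0
    n = int(300 * fs)
    rng = np.random.default_rng(0)
    x = 0.005 * rng.standard_normal(n)
    y = 0.005 * rng.standard_normal(n)
    z = 0.005 * rng.standard_normal(n)
    sl = slice(int(185 * fs), int(189 * fs))  # burst inside minute 3
    z[sl] += 0.4 * rng.standard_normal(sl.stop - sl.start)
    flags = motion_gate(MotionTrace(x=x, y=y, z=z, fs=fs), minutes=5)
    assert flags.tolist() == [True, True, True, False, True]


def test_motion_gate_on_simulated_bursts(apnea_sim):
    flags = motion_gate(apnea_sim.motion, minutes=10)
    assert flags.size == 10
    for ev in apnea_sim.motion_events:
        k = int(ev.start_s // 60)
        if ev.start_s + ev.duration_s <= 60 * (k + 1) and k < 10:
            assert not flags[k]


# --------------------------------------------------------------- classifier

def _toy_segments(n=24, T=30, seed=0):
    rng = np.random.default_rng(seed)
    segs = []
    for i in range(n):
        label = i % 2
        base = rng.standard_normal((T, 3)) * 0.3 + (1.5 if label else -1.5)
        segs.append(MinuteSegment(features=base, label=label, minute_index=i))
    return segs


def test_train_lstm_epoch_log_and_determinism():
    spec = LSTMSpec(lstm_hidden=6, epochs=3)
    segs = _toy_segments()
    m1, h1 = train_lstm(segs, spec, seed=4)
    m2, h2 = train_lstm(segs, spec, seed=4)
    assert len(h1["train_loss"]) == 3
    assert h1["train_loss"] == h2["train_loss"]
    p1, _ = predict_minutes(m1, segs)
    p2, _ = predict_minutes(m2, segs)
    assert np.array_equal(p1, p2)


def test_train_lstm_rejects_single_class():
    segs = [MinuteSegment(features=np.zeros((10, 3)), label=1, minute_index=i)
            for i in range(10)]
    with pytest.raises(ValueError, match="both classes"):
        train_lstm(segs, LSTMSpec(lstm_hidden=4, epochs=1), seed=0)


def test_predict_labels_follow_probability_threshold():
    segs = _toy_segments()
    model, _ = train_lstm(segs, LSTMSpec(lstm_hidden=6, epochs=2), seed=0)
    p, lab = predict_minutes(model, segs)
    assert set(np.unique(lab)) <= {0, 1}
    assert np.array_equal(lab, (p >= 0.5).astype(int))


def test_probability_half_maps_to_positive():
    segs = _toy_segments(n=4)
    model, _ = train_lstm(segs, LSTMSpec(lstm_hidden=4, epochs=1), seed=0)
    # zero the output layer: every logit 0, probability exactly 0.5
    W, b = model.dense[-1]
    model.dense[-1] = (np.zeros_like(W), np.zeros_like(b))
    p, lab = predict_minutes(model, segs)
    assert np.all(p == 0.5) and np.all(lab == 1)


def test_baselines_names_and_split_consistency(training_segments):
    subset = training_segments[:100]
    out = train_baselines(subset, seed=3)
    assert set(out.keys()) == set(BASELINE_NAMES)
    assert all(v.Acc > 0.5 for v in out.values())
    again = train_baselines(subset, seed=3)
    assert all(out[k].Acc == again[k].Acc for k in out)


def test_stratified_split_partitions_and_stratifies():
    y = np.r_[np.zeros(40), np.ones(20)]
    tr, va = stratified_split(y, 0.25, seed=0)
    assert np.array_equal(np.sort(np.r_[tr, va]), np.arange(60))
    assert np.sum(y[va]) == 5 and va.size == 15
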