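import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from activemon import features as feats
from activemon.types import (
    ConfigurationError,
    FeatureName,
    Hand,
    QcStatus,
    SensorRecording,
    TestSession,
    TestType,
)


# ---------------------------------------------------------------------------
# SDMT
# ---------------------------------------------------------------------------

class TestSdmt:
    def test_all_matching(self):
        key = {"a": 1, "b": 2}
        responses = [("a", 1), ("b", 2), ("a", 1), ("b", 2), ("a", 1)]
        assert feats.sdmt_correct_answers(responses, key) == 5

    def test_hand_count(self):
        key = {"s1": 3, "s2": 7}
        responses = [("s1", 3), ("s2", 7), ("s1", 4)]
        assert feats.sdmt_correct_answers(responses, key) == 2

    def test_empty_is_zero(self):
        assert feats.sdmt_correct_answers([], {"a": 1}) == 0

    def test_digit_out_of_range(self):
        with pytest.raises(ConfigurationError):
            feats.sdmt_correct_answers([("a", 0)], {"a": 1})

    def test_missing_symbol(self):
        with pytest.raises(ConfigurationError):
            feats.sdmt_correct_answers([("zzz", 1)], {"a": 1})


# ---------------------------------------------------------------------------
# SWR
# ---------------------------------------------------------------------------

class TestSwr:
    def test_identical_60(self):
        words = ["red", "green", "blue", "yellow"] * 15
        assert feats.swr_correct_words(words, list(words)) == 60

    def test_every_third_deleted(self):
        displayed = [f"w{i % 4}" for i in range(60)]
        recognized = [w for i, w in enumerate(displayed) if (i + 1) % 3 != 0]
        assert feats.swr_correct_words(displayed, recognized) == 40

    def test_empty_recognized(self):
        assert feats.swr_correct_words(["red"] * 10, []) == 0

    def test_cap_at_60(self):
        words = ["red"] * 70
        assert feats.swr_correct_words(words, list(words)) == 60

    @given(
        st.lists(st.sampled_from(["red", "green", "blue", "yellow"]), min_size=1, max_size=10),
        st.lists(st.sampled_from(["red", "green", "blue", "yellow"]), min_size=0, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, displayed, recognized):
        assert feats.swr_correct_words(displayed, recognized) == oracles.lcs_brute(
            displayed, recognized
        )


# ---------------------------------------------------------------------------
# Speeded Tapping
# ---------------------------------------------------------------------------

class TestIntertap:
    def test_hand_computation(self):
        t = [0, 0.5, 1, 1.5, 2, 2.5]
        phases = ["down", "up", "down", "up", "down", "up"]
        assert feats.mean_intertap_interval(t, phases) == pytest.approx(500.0)

    def test_constant_air_time(self):
        c = 0.137
        t, phases = [], []
        cur = 0.0
        for _ in range(10):
            t.append(cur)
            phases.append("down")
            cur += 0.05
            t.append(cur)
            phases.append("up")
            cur += c
        assert feats.mean_intertap_interval(t, phases) == pytest.approx(c * 1000, rel=1e-12)

    def test_random_events_match_oracle(self, rng):
        for _ in range(100):
            n_taps = int(rng.integers(2, 11))
            t, phases = [], []
            cur = float(rng.uniform(0, 1))
            for _ in range(n_taps):
                t.append(cur)
                phases.append("down")
                cur += float(rng.uniform(0.02, 0.3))
                t.append(cur)
                phases.append("up")
                cur += float(rng.uniform(0.02, 0.8))
            got = feats.mean_intertap_interval(t, phases)
            assert got == pytest.approx(oracles.intertap_oracle(t, phases), rel=1e-9)

    def test_too_few_taps(self):
        with pytest.raises(feats.ExtractionError):
            feats.mean_intertap_interval([0.0, 0.1], ["down", "up"])


# ---------------------------------------------------------------------------
# Draw-A-Shape
# ---------------------------------------------------------------------------

class TestSpiralCv:
    def test_constant_speed_zero(self):
        t = np.arange(10) * 0.1
        x = np.arange(10) * 2.0
        y = np.zeros(10)
        assert feats.spiral_speed_variability(t, x, y) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_speeds(self):
        # speeds alternate 10 and 20 mm/s in equal 0.1 s steps
        speeds = [10.0, 20.0] * 5
        t = np.arange(len(speeds) + 1) * 0.1
        x = np.concatenate([[0.0], np.cumsum(np.array(speeds) * 0.1)])
        y = np.zeros_like(x)
        expected = np.std(speeds) / np.mean(speeds)
        assert feats.spiral_speed_variability(t, x, y) == pytest.approx(expected, rel=1e-12)

    def test_shift_invariance(self, rng):
        t = np.sort(rng.uniform(0, 5, 20))
        t += np.arange(20) * 1e-4  # ensure strictly increasing
        x = rng.uniform(0, 50, 20)
        y = rng.uniform(0, 50, 20)
        a = feats.spiral_speed_variability(t, x, y)
        b = feats.spiral_speed_variability(t + 123.456, x, y)
        assert a == pytest.approx(b, rel=1e-9)

    def test_no_movement(self):
        with pytest.raises(feats.ExtractionError):
            feats.spiral_speed_variability([0, 1, 2], [1, 1, 1], [2, 2, 2])

    def test_matches_oracle_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 30))
            t = np.cumsum(rng.uniform(0.01, 0.2, n))
            x = rng.uniform(0, 60, n)
            y = rng.uniform(0, 60, n)
            got = feats.spiral_speed_variability(t, x, y)
            want = oracles.speed_cv_oracle(t.tolist(), x.tolist(), y.tolist())
            assert got == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# sway path
# ---------------------------------------------------------------------------

def _rec(acc, dt=0.02, gyro=None):
    acc = np.asarray(acc, dtype=float)
    t = np.arange(len(acc)) * dt
    return SensorRecording(t=t, acc=acc, gyro=gyro)


class TestSwayPath:
    def test_constant_gravity_zero(self):
        acc = np.tile([0.0, 0.0, 9.81], (100, 1))
        assert feats.sway_path(_rec(acc)) == 0.0

    def test_hand_summation(self):
        acc = [(0, 0, 0), (1, 0, 0), (1, 1, 0)]
        assert feats.sway_path(_rec(acc)) == pytest.approx(2.0, rel=1e-12)

    def test_amplitude_doubling(self, rng):
        acc = rng.normal(0, 1, (50, 3))
        centered = acc - acc.mean(axis=0)
        base = feats.sway_path(_rec(acc))
        doubled = feats.sway_path(_rec(acc.mean(axis=0) + 2 * centered))
        assert doubled == pytest.approx(2 * base, rel=1e-9)

    def test_matches_oracle_random(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 100))
            acc = rng.normal(0, 2, (n, 3))
            got = feats.sway_path(_rec(acc))
            want = oracles.sway_path_oracle([tuple(row) for row in acc])
            assert got == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# U-Turn
# ---------------------------------------------------------------------------

def _pulse_recording(speeds, pulse_s=2.1, gap_s=4.0, fs=50.0):
    """Rectangular yaw pulses of given angular speeds, grid-aligned."""
    chunks = []
    for speed in speeds:
        chunks.append(np.zeros(int(gap_s * fs)))
        chunks.append(np.full(int(pulse_s * fs), speed))
    chunks.append(np.zeros(int(gap_s * fs)))
    yaw = np.concatenate(chunks)
    t = np.arange(yaw.size) / fs
    gyro = np.column_stack([np.zeros_like(yaw), np.zeros_like(yaw), yaw])
    acc = np.tile([0.0, 0.0, 9.81], (yaw.size, 1))
    return SensorRecording(t=t, acc=acc, gyro=gyro)


class TestTurnSpeed:
    def test_five_rectangular_pulses(self):
        rec = _pulse_recording([1.5] * 5)
        assert feats.median_turn_speed(rec) == pytest.approx(1.5, rel=1e-9)

    def test_all_zero_gyro(self):
        n = 3000
        rec = SensorRecording(
            t=np.arange(n) / 50.0,
            acc=np.tile([0.0, 0.0, 9.81], (n, 1)),
            gyro=np.zeros((n, 3)),
        )
        with pytest.raises(feats.ExtractionError):
            feats.median_turn_speed(rec)

    def test_embedded_known_speeds(self):
        speeds = [1.0, 1.2, 1.4, 1.6, 1.8]
        rec = _pulse_recording(speeds, pulse_s=2.5)
        assert feats.median_turn_speed(rec) == pytest.approx(1.4, rel=1e-9)

    def test_random_pulse_constructions(self, rng):
        for _ in range(100):
            n_turns = int(rng.integers(3, 8))
            speeds = rng.uniform(0.8, 2.5, n_turns).round(3)
            rec = _pulse_recording(list(speeds), pulse_s=2.4)
            want = oracles.median_oracle(list(speeds))
            assert feats.median_turn_speed(rec) == pytest.approx(want, rel=1e-9)

    def test_too_few_turns(self):
        rec = _pulse_recording([1.5, 1.5])
        with pytest.raises(feats.ExtractionError):
            feats.median_turn_speed(rec)


# ---------------------------------------------------------------------------
# Walking
# ---------------------------------------------------------------------------

def _impulse_recording(step_times, duration=None, fs=50.0, amp=4.0):
    duration = duration or (step_times[-1] + 1.0)
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    acc = np.tile([0.0, 0.0, 9.81], (n, 1))
    for st_ in step_times:
        idx = int(round(st_ * fs))
        acc[idx, 2] += amp
    return SensorRecording(t=t, acc=acc)


class TestStepFrequencyVariance:
    def test_periodic_near_zero(self):
        times = np.arange(1.0, 25.0, 0.5)  # 2 Hz
        rec = _impulse_recording(times.tolist())
        assert feats.step_frequency_variance(rec) <= 1e-4

    def test_alternating_intervals(self):
        intervals = [0.50, 0.56] * 10
        times = 1.0 + np.concatenate([[0.0], np.cumsum(intervals)])
        rec = _impulse_recording(times.tolist())
        want = oracles.freq_variance_oracle(times.tolist())
        assert feats.step_frequency_variance(rec) == pytest.approx(want, rel=1e-6)

    def test_shift_invariance(self):
        intervals = [0.50, 0.56, 0.60, 0.48] * 5
        times = np.concatenate([[0.0], np.cumsum(intervals)])
        a = feats.step_frequency_variance(_impulse_recording((1.0 + times).tolist()))
        b = feats.step_frequency_variance(_impulse_recording((3.0 + times).tolist()))
        assert a == pytest.approx(b, rel=1e-6)

    def test_from_times_matches_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(11, 40))
            times = np.cumsum(rng.uniform(0.3, 0.9, n))
            got = feats.step_frequency_variance_from_times(times)
            want = oracles.freq_variance_oracle(times.tolist())
            assert got == pytest.approx(want, rel=1e-9)

    def test_too_few_steps(self):
        times = [1.0, 1.5, 2.0]
        with pytest.raises(feats.ExtractionError):
            feats.step_frequency_variance(_impulse_recording(times))


# ---------------------------------------------------------------------------
# resampling & dispatch
# ---------------------------------------------------------------------------

class TestResample:
    def test_linear_signal_preserved(self):
        t = np.array([0.0, 0.013, 0.031, 0.047, 0.08, 0.1])
        acc = np.column_stack([2 * t, -t, np.full_like(t, 9.81)])
        rec = feats.resample_uniform(SensorRecording(t=t, acc=acc), fs=50.0)
        assert np.allclose(np.diff(rec.t), 0.02)
        assert np.allclose(rec.acc[:, 0], 2 * rec.t)


class TestDispatch:
    def test_balance_yields_sway_path(self):
        acc = np.tile([0.0, 0.0, 9.81], (1501, 1))
        acc[10, 0] += 1.0
        session = TestSession(
            participant_id="p1",
            test=TestType.BALANCE,
            day=1,
            payload={"t_s": np.arange(1501) / 50.0, "acc": acc},
        )
        (fv,) = feats.extract_features(session)
        assert fv.feature is FeatureName.SWAY_PATH
        assert fv.units == "m/s^2"
        assert fv.qc_status.passed

    def test_chorea_hand_tagged(self):
        acc = np.tile([0.0, 0.0, 9.81], (1501, 1))
        session = TestSession(
            participant_id="p1",
            test=TestType.CHOREA,
            day=2,
            hand=Hand.NONDOMINANT,
            payload={"t_s": np.arange(1501) / 50.0, "acc": acc},
        )
        (fv,) = feats.extract_features(session)
        assert fv.hand is Hand.NONDOMINANT

    def test_failing_precondition_flagged(self):
        session = TestSession(
            participant_id="p1",
            test=TestType.SPEEDED_TAPPING,
            day=1,
            hand=Hand.DOMINANT,
            payload={"t_s": [0.0, 0.1], "phase": ["down", "up"], "x_mm": [0, 0], "y_mm": [0, 0]},
        )
        (fv,) = feats.extract_features(session)
        assert not fv.qc_status.passed
        assert fv.value is None

    def test_payload_mismatch_raises(self):
        session = TestSession(
            participant_id="p1", test=TestType.SDMT, day=1, payload={"t_s": [0, 1]}
        )
        with pytest.raises(ConfigurationError):
            feats.extract_features(session)
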