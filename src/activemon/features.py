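"""Per-session feature extraction.

Each active test is reduced to a single predefined scalar readout:

========================  ==========================  ========
test                      feature                     units
========================  ==========================  ========
SDMT                      number of correct answers   count
SWR                       number of correct words     count
Speeded Tapping           mean intertap interval      ms
Draw-A-Shape (spiral)     drawing-speed CV            unitless
Chorea / Balance          sway path                   m/s^2
U-Turn                    median turn speed           rad/s
Walking                   step frequency variance     Hz^2
========================  ==========================  ========

Signal-processing thresholds (turn detection, step detection) are not part of
the feature definitions and are exposed as keyword arguments with defaults
chosen for deliberate 180-degree turns and normal walking cadence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .types import (
    FEATURE_UNITS,
    TEST_FEATURE,
    ConfigurationError,
    FeatureName,
    FeatureValue,
    Hand,
    QcStatus,
    SensorRecording,
    TestSession,
    TestType,
)


class ExtractionError(ValueError):
    """A session's payload does not support its feature computation."""


# ---------------------------------------------------------------------------
# cognitive tests
# ---------------------------------------------------------------------------

def sdmt_correct_answers(
    responses: Sequence[tuple[str, int]], key: dict[str, int]
) -> int:
    """Count symbol-digit responses whose digit matches the key.

    Parameters
    ----------
    responses : sequence of (symbol, digit)
        The displayed symbol and the digit the participant entered (1-9).
    key : dict
        The symbol-to-digit mapping in force for the session.
    """
    count = 0
    for symbol, digit in responses:
        if symbol not in key:
            raise ConfigurationError(f"symbol {symbol!r} missing from key")
        if not 1 <= int(digit) <= 9:
            raise ConfigurationError(f"responded digit {digit} outside 1-9")
        if int(digit) == int(key[symbol]):
            count += 1
    return count


def swr_correct_words(
    displayed: Sequence[str], recognized: Sequence[str], cap: int = 60
) -> int:
    """Number of correctly read words: longest common subsequence length.

    LCS tolerates skipped and misread words without double-counting a
    displayed word. The result is capped at the display length (60 words).
    """
    n, m = len(displayed), len(recognized)
    if n == 0 or m == 0:
        return 0
    # O(n*m) DP over one rolling row.
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        di = displayed[i - 1]
        for j in range(1, m + 1):
            if di == recognized[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return min(prev[m], cap)


# ---------------------------------------------------------------------------
# touchscreen tests
# ---------------------------------------------------------------------------

def mean_intertap_interval(
    t_s: Sequence[float], phases: Sequence[str]
) -> float:
    """Mean finger-in-air time between consecutive taps, in milliseconds.

    The interval is measured from each lift-off (``up``) to the next
    touch-down (``down``); time on the glass does not count.
    """
    downs = [t for t, p in zip(t_s, phases) if p == "down"]
    ups = [t for t, p in zip(t_s, phases) if p == "up"]
    if len(downs) < 2 or len(ups) < 1:
        raise ExtractionError("fewer than 2 completed taps")
    intervals = []
    for up in ups:
        nxt = [d for d in downs if d > up]
        if nxt:
            intervals.append(min(nxt) - up)
    if not intervals:
        raise ExtractionError("no in-air interval between taps")
    return float(np.mean(intervals)) * 1000.0


def spiral_speed_variability(
    t_s: Sequence[float], x_mm: Sequence[float], y_mm: Sequence[float]
) -> float:
    """Coefficient of variation of instantaneous drawing speed (unitless)."""
    t = np.asarray(t_s, dtype=float)
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    if t.size < 3:
        raise ExtractionError("need at least 3 move events")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ExtractionError("timestamps must be strictly increasing")
    v = np.hypot(np.diff(x), np.diff(y)) / dt
    mean_v = float(np.mean(v))
    if mean_v == 0.0:
        raise ExtractionError("no movement in trace")
    return float(np.std(v) / mean_v)


# ---------------------------------------------------------------------------
# IMU tests
# ---------------------------------------------------------------------------

def resample_uniform(recording: SensorRecording, fs: float = 50.0) -> SensorRecording:
    """Linearly interpolate IMU streams onto a uniform grid at ``fs`` Hz."""
    t0, t1 = recording.t[0], recording.t[-1]
    n = int(np.floor((t1 - t0) * fs)) + 1
    tu = t0 + np.arange(n) / fs

    def interp(arr: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if arr is None:
            return None
        return np.column_stack([np.interp(tu, recording.t, arr[:, k]) for k in range(3)])

    return SensorRecording(t=tu, acc=interp(recording.acc), gyro=interp(recording.gyro))


def sway_path(recording: SensorRecording) -> float:
    """Cumulative tri-axial acceleration path length, sum of ||a_{i+1}-a_i||.

    Differencing cancels the constant gravity component, so no gravity
    removal is applied. Units are m/s^2 (path length in acceleration space).
    """
    if recording.acc is None:
        raise ExtractionError("sway path requires an accelerometer stream")
    da = np.diff(recording.acc, axis=0)
    return float(np.sum(np.linalg.norm(da, axis=1)))


@dataclass
class TurnDetectionParams:
    """Thresholds for yaw-rate turn detection (all configurable)."""

    smooth_window_s: float = 0.5
    rate_threshold: float = 0.3  # rad/s
    min_duration_s: float = 0.5
    min_angle_rad: float = np.pi / 2
    min_turns: int = 3


def detect_turns(
    t: np.ndarray, yaw_rate: np.ndarray, params: TurnDetectionParams
) -> list[tuple[float, float]]:
    """Detect discrete turns; return (cumulative angle, duration) per turn.

    Candidate regions come from a moving-average-smoothed |yaw rate|
    exceeding the threshold; boundaries are then refined to the raw-signal
    threshold crossings so rectangular test pulses keep their exact extent.
    """
    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(params.smooth_window_s / dt)))
    kernel = np.ones(win) / win
    smooth = np.convolve(yaw_rate, kernel, mode="same")

    above = np.abs(smooth) > params.rate_threshold
    turns: list[tuple[float, float]] = []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        # refine to raw threshold crossings inside the candidate region
        raw_idx = np.nonzero(np.abs(yaw_rate[i:j]) > params.rate_threshold)[0]
        if raw_idx.size:
            lo, hi = i + raw_idx[0], i + raw_idx[-1] + 1
            duration = (hi - lo) * dt
            angle = float(np.sum(np.abs(yaw_rate[lo:hi])) * dt)
            if duration >= params.min_duration_s and angle >= params.min_angle_rad:
                turns.append((angle, duration))
        i = j
    return turns


def median_turn_speed(
    recording: SensorRecording, params: Optional[TurnDetectionParams] = None
) -> float:
    """Median angular speed (cumulative angle / duration) over detected turns."""
    if recording.gyro is None:
        raise ExtractionError("turn speed requires a gyroscope stream")
    params = params or TurnDetectionParams()
    yaw = recording.gyro[:, 2]  # yaw axis for a waist-worn, upright device
    turns = detect_turns(recording.t, yaw, params)
    if len(turns) < params.min_turns:
        raise ExtractionError(f"only {len(turns)} turns detected (need {params.min_turns})")
    speeds = [angle / duration for angle, duration in turns]
    return float(np.median(speeds))


@dataclass
class StepDetectionParams:
    """Thresholds for step-peak detection on band-passed magnitude."""

    band_hz: tuple[float, float] = (0.5, 3.5)
    min_separation_s: float = 0.25
    prominence: float = 0.5  # m/s^2
    min_steps: int = 10


def detect_step_times(
    recording: SensorRecording, params: StepDetectionParams
) -> np.ndarray:
    """Step event times from band-passed acceleration magnitude peaks."""
    if recording.acc is None:
        raise ExtractionError("step detection requires an accelerometer stream")
    fs = 1.0 / float(np.median(np.diff(recording.t)))
    mag = np.linalg.norm(recording.acc, axis=1)
    lo, hi = params.band_hz
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, mag - np.mean(mag))
    distance = max(1, int(round(params.min_separation_s * fs)))
    peaks, _ = signal.find_peaks(filtered, distance=distance, prominence=params.prominence)
    return recording.t[peaks]


def step_frequency_variance_from_times(step_times: Sequence[float]) -> float:
    """Variance of per-step frequencies f_i = 1 / (t_{i+1} - t_i), in Hz^2."""
    times = np.asarray(step_times, dtype=float)
    if times.size < 2:
        raise ExtractionError("need at least 2 step events")
    freqs = 1.0 / np.diff(times)
    return float(np.var(freqs))


def step_frequency_variance(
    recording: SensorRecording, params: Optional[StepDetectionParams] = None
) -> float:
    """Variance of instantaneous step frequency during walking (Hz^2)."""
    params = params or StepDetectionParams()
    times = detect_step_times(recording, params)
    if times.size < params.min_steps:
        raise ExtractionError(f"only {times.size} steps detected (need {params.min_steps})")
    return step_frequency_variance_from_times(times)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _recording_from_payload(session: TestSession, need_gyro: bool = False) -> SensorRecording:
    payload = session.payload
    if "t_s" not in payload:
        raise ConfigurationError(f"{session.test.value} payload lacks IMU stream")
    rec = SensorRecording(
        t=np.asarray(payload["t_s"], dtype=float),
        acc=payload.get("acc"),
        gyro=payload.get("gyro"),
    )
    if need_gyro and rec.gyro is None:
        raise ConfigurationError(f"{session.test.value} payload lacks gyroscope data")
    return resample_uniform(rec)


def extract_features(session: TestSession) -> list[FeatureValue]:
    """Compute the session's feature; extraction failures become QC fails.

    Returns a single-element list (one feature per session; hand-specific
    tests carry their hand tag on the value).
    """
    feature = TEST_FEATURE[session.test]
    units = FEATURE_UNITS[feature]
    payload = session.payload
    value: Optional[float] = None
    status = QcStatus.ok()
    try:
        if session.test is TestType.SDMT:
            value = float(sdmt_correct_answers(payload["responses"], payload["key"]))
        elif session.test is TestType.SWR:
            value = float(swr_correct_words(payload["displayed"], payload["recognized"]))
        elif session.test is TestType.SPEEDED_TAPPING:
            value = mean_intertap_interval(payload["t_s"], payload["phase"])
        elif session.test is TestType.DRAW_A_SHAPE:
            value = spiral_speed_variability(
                payload["t_s"], payload["x_mm"], payload["y_mm"]
            )
        elif session.test in (TestType.CHOREA, TestType.BALANCE):
            value = sway_path(_recording_from_payload(session))
        elif session.test is TestType.U_TURN:
            value = median_turn_speed(_recording_from_payload(session, need_gyro=True))
        elif session.test is TestType.WALKING:
            value = step_frequency_variance(_recording_from_payload(session))
        else:  # pragma: no cover - enum is exhaustive
            raise ConfigurationError(f"unknown test type {session.test}")
    except KeyError as exc:
        raise ConfigurationError(
            f"payload for {session.test.value} missing field {exc}"
        ) from exc
    except (ExtractionError, ValueError) as exc:
        status = QcStatus.fail(f"extraction: {exc}")
        value = None

    hand = Hand(session.hand) if session.hand is not None else None
    return [
        FeatureValue(
            participant_id=session.participant_id,
            test=session.test,
            day=session.day,
            feature=feature,
            value=value,
            units=units,
            hand=hand,
            qc_status=status,
        )
    ]
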