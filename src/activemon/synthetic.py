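"""Synthetic cohorts, schedules and raw active-test sessions.

A single latent severity scalar in [0, 1] drives both the in-clinic scores
and every sensor signature, giving downstream validation statistics a
recoverable ground truth: impairment-increasing features (sway path,
intertap interval, spiral speed CV, step frequency variance) grow with
severity, while turn speed and the cognitive counts shrink.

Between-participant variation is injected through stable per-participant
trait multipliers (seeded from the participant record), and within-
participant variation through per-session noise, so test-retest reliability
is controlled by the trait/session noise ratio.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal, stats

from .types import (
    AMBULATORY_TESTS,
    PER_HAND_TESTS,
    TEST_DURATION_S,
    WEEKLY_TESTS,
    Cohort,
    ConfigurationError,
    Hand,
    ParticipantRecord,
    Placement,
    Schedule,
    ScheduleEntry,
    Study,
    TestSession,
    TestType,
)

#: Days on which weekly tests are scheduled within the 4-week window.
WEEKLY_DAYS = (1, 8, 15, 22)

SWR_VOCABULARY = ("red", "green", "blue", "yellow")
SDMT_SYMBOLS = tuple(f"sym{i}" for i in range(1, 10))


@dataclass
class CohortSpec:
    """Specification for one simulated cohort within one study."""

    study: Study
    cohort: Cohort
    n_participants: int
    severity_mean: float
    severity_sd: float
    seed: int

    def __post_init__(self) -> None:
        try:
            self.study = Study(self.study)
            self.cohort = Cohort(self.cohort)
        except ValueError as exc:
            raise ConfigurationError(str(exc)) from exc
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not 0.0 <= self.severity_mean <= 1.0:
            raise ConfigurationError("severity_mean must lie in [0, 1]")
        if self.severity_sd < 0:
            raise ConfigurationError("severity_sd must be >= 0")


@dataclass
class SignalParams:
    """Generator calibration: severity -> signal-model parameters.

    All are (intercept, slope) pairs in severity; defaults are tuned so each
    extracted feature is monotone in severity with effect sizes large enough
    for group separation at modest cohort sizes.
    """

    fs_hz: float = 50.0
    chorea_amp: tuple[float, float] = (0.05, 0.80)  # m/s^2 band-noise sigma
    balance_amp: tuple[float, float] = (0.05, 0.50)
    turn_speed: tuple[float, float] = (2.2, -1.3)  # rad/s
    step_jitter_sd: tuple[float, float] = (0.005, 0.060)  # s
    tap_air_mean: tuple[float, float] = (0.10, 0.40)  # s
    tap_air_sd: tuple[float, float] = (0.010, 0.050)
    spiral_cv: tuple[float, float] = (0.05, 0.50)
    sdmt_response_s: tuple[float, float] = (0.9, 2.2)
    sdmt_rt_jitter: float = 0.10  # per-response cadence CV
    sdmt_error_rate: tuple[float, float] = (0.02, 0.20)
    swr_rate: tuple[float, float] = (1.40, -0.90)  # words / s
    swr_miss_rate: tuple[float, float] = (0.02, 0.25)
    draw_incomplete_prob: tuple[float, float] = (0.03, 0.30)
    trait_sd: float = 0.10  # between-participant log-scale SD
    session_sd: float = 0.05  # within-participant log-scale SD
    #: per-feature trait-SD overrides; the lower-body features carry more
    #: idiosyncratic between-participant variation than the cognitive tests,
    #: which keeps the digital-vs-clinic cognitive correlations the strongest
    #: pairings while the turn/step features stay moderate.
    trait_sd_overrides: dict = field(
        default_factory=lambda: {"turn": 0.28, "step": 0.35, "sdmt": 0.07, "swr": 0.07}
    )


def _stable_hash(label: str) -> int:
    """Process-independent 32-bit hash (builtin hash() is randomized)."""
    return zlib.crc32(label.encode())


def _affine(pair: tuple[float, float], severity: float) -> float:
    return pair[0] + pair[1] * severity


def _participant_traits(participant: ParticipantRecord, params: SignalParams) -> dict[str, float]:
    """Stable per-participant multiplicative trait offsets (log-normal)."""
    rng = np.random.default_rng([participant.seed, 0xA11CE])
    names = [
        "chorea", "balance", "turn", "step", "tap", "spiral", "sdmt", "swr",
    ]
    return {
        name: float(
            np.exp(rng.normal(0.0, params.trait_sd_overrides.get(name, params.trait_sd)))
        )
        for name in names
    }


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _clinical_scores(rng: np.random.Generator, severity: float) -> dict[str, float]:
    s = severity

    def clip_round(x: float, lo: float, hi: float) -> float:
        return float(np.clip(round(x), lo, hi))

    return {
        "tms": clip_round(105 * s + rng.normal(0, 2.4), 0, 124),
        "tfc": clip_round(13 - 11.5 * s + rng.normal(0, 0.3), 0, 13),
        "chorea_d": clip_round(3.8 * s + rng.normal(0, 0.4), 0, 4),
        "chorea_nd": clip_round(3.8 * s + rng.normal(0, 0.4), 0, 4),
        "finger_taps_d": clip_round(3.8 * s + rng.normal(0, 0.4), 0, 4),
        "finger_taps_nd": clip_round(3.8 * s + rng.normal(0, 0.4), 0, 4),
        "balance_score": clip_round(6.5 * s + rng.normal(0, 0.6), 0, 8),
        "swr_clinic": clip_round(95 - 55 * s + rng.normal(0, 3.5), 0, 130),
        "sdmt_clinic": clip_round(55 - 35 * s + rng.normal(0, 2.5), 0, 110),
        "intertap_clinic_ms": float(np.clip(180 + 450 * s + rng.normal(0, 25), 50, 2000)),
    }


_AGE_BY_COHORT = {
    Cohort.CONTROL: (45.0, 12.0),
    Cohort.PREMANIFEST: (40.0, 10.0),
    Cohort.MANIFEST: (50.0, 10.0),
}


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Draw a cohort of participants with severity-linked clinical scores."""
    rng = np.random.default_rng([spec.seed, _stable_hash(spec.study.value)])
    age_mean, age_sd = _AGE_BY_COHORT[spec.cohort]
    records = []
    for i in range(spec.n_participants):
        severity = _truncnorm(rng, spec.severity_mean, spec.severity_sd, 0.0, 1.0)
        age = float(np.clip(rng.normal(age_mean, age_sd), 18.0, 80.0))
        pid = f"{spec.study.value}-{spec.cohort.value}-{i:04d}"
        records.append(
            ParticipantRecord(
                id=pid,
                study=spec.study,
                cohort=spec.cohort,
                age=age,
                dominant_hand="right" if rng.random() < 0.9 else "left",
                severity=severity,
                clinical=_clinical_scores(rng, severity),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def generate_schedule(
    participant: ParticipantRecord,
    adherence_prob: float,
    pocket_prob: float,
    seed: int,
    n_days: int = 28,
) -> Schedule:
    """28-day schedule: daily tests every day, SDMT/SWR on days 1/8/15/22."""
    if not 0.0 <= adherence_prob <= 1.0 or not 0.0 <= pocket_prob <= 1.0:
        raise ConfigurationError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng([seed, participant.seed, 0x5C4ED])
    entries: list[ScheduleEntry] = []
    for day in range(1, n_days + 1):
        for test in TestType:
            if test in WEEKLY_TESTS and day not in WEEKLY_DAYS:
                continue
            hands = (Hand.DOMINANT, Hand.NONDOMINANT) if test in PER_HAND_TESTS else (None,)
            for hand in hands:
                completed = bool(rng.random() < adherence_prob)
                placement = Placement.POUCH
                if test in AMBULATORY_TESTS and rng.random() < pocket_prob:
                    placement = Placement.POCKET
                entries.append(
                    ScheduleEntry(
                        day=day,
                        test=test,
                        hand=hand,
                        scheduled=True,
                        completed=completed,
                        placement=placement,
                    )
                )
    return Schedule(participant_id=participant.id, entries=entries)


# ---------------------------------------------------------------------------
# raw sessions
# ---------------------------------------------------------------------------

def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], sigma: float
) -> np.ndarray:
    """(n, 3) Gaussian noise band-limited to ``band`` with per-axis SD sigma."""
    white = rng.normal(0.0, 1.0, size=(n, 3))
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    shaped = signal.sosfiltfilt(sos, white, axis=0)
    std = shaped.std(axis=0)
    std[std == 0] = 1.0
    return shaped / std * sigma


def _sway_session(
    rng: np.random.Generator, amp: float, duration: float, fs: float
) -> dict:
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    acc = np.tile([0.0, 0.0, 9.81], (n, 1))
    acc += _bandlimited_noise(rng, n, fs, (1.0, 8.0), amp)
    return {"t_s": t, "acc": acc}


def _uturn_session(
    rng: np.random.Generator, turn_speed: float, fs: float, duration: float = 60.0
) -> dict:
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    gyro = rng.normal(0.0, 0.03, size=(n, 3))
    n_turns = 6
    centers = np.linspace(6.0, duration - 6.0, n_turns)
    sign = 1.0
    for c in centers:
        speed = max(0.4, turn_speed * (1.0 + rng.normal(0.0, 0.05)))
        dur = math.pi / speed  # 180-degree turn
        mask = (t >= c - dur / 2) & (t <= c + dur / 2)
        # half-sine pulse with peak pi^2/(2*dur); its integral over dur is pi
        phase = (t[mask] - (c - dur / 2)) / dur
        gyro[mask, 2] += sign * (math.pi**2 / (2 * dur)) * np.sin(math.pi * phase)
        sign = -sign
    acc = np.tile([0.0, 0.0, 9.81], (n, 1)) + rng.normal(0.0, 0.05, size=(n, 3))
    return {"t_s": t, "acc": acc, "gyro": gyro}


def _walking_session(
    rng: np.random.Generator, jitter_sd: float, fs: float, duration: float = 120.0
) -> dict:
    n = int(duration * fs) + 1
    t = np.arange(n) / fs
    acc = np.tile([0.0, 0.0, 9.81], (n, 1)) + rng.normal(0.0, 0.05, size=(n, 3))
    base_interval = 0.56  # multiple of the 50 Hz sample period, so the
    # zero-jitter limit yields exactly periodic, grid-aligned impulses
    step_t = 1.0
    width = 0.12
    while step_t < duration - 1.0:
        mask = np.abs(t - step_t) <= width / 2
        acc[mask, 2] += 3.0 * np.cos(np.pi * (t[mask] - step_t) / width) ** 2
        step_t += max(0.30, base_interval + rng.normal(0.0, jitter_sd))
    return {"t_s": t, "acc": acc}


def _tapping_session(
    rng: np.random.Generator, air_mean: float, air_sd: float, duration: float = 30.0
) -> dict:
    hold = 0.08
    t_events: list[float] = []
    phases: list[str] = []
    t = 0.2
    while t < duration:
        t_events.append(t)
        phases.append("down")
        t += hold
        if t >= duration:
            break
        t_events.append(t)
        phases.append("up")
        t += max(0.02, air_mean + rng.normal(0.0, air_sd))
    return {
        "t_s": t_events,
        "x_mm": [30.0] * len(t_events),
        "y_mm": [60.0] * len(t_events),
        "phase": phases,
    }


def _spiral_session(
    rng: np.random.Generator,
    cv: float,
    incomplete: bool,
    duration: float = 30.0,
    dt: float = 0.02,
) -> dict:
    # Archimedean spiral, traced at a speed with multiplicative noise of the
    # requested coefficient of variation.
    theta_max = 3 * 2 * math.pi
    theta_grid = np.linspace(0.0, theta_max, 4000)
    r = 2.0 + 1.2 * theta_grid
    x_grid = r * np.cos(theta_grid)
    y_grid = r * np.sin(theta_grid)
    seg = np.hypot(np.diff(x_grid), np.diff(y_grid))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]

    v0 = max(total / (0.6 * duration), 10.0)
    pos = 0.0
    positions = [0.0]
    t = dt
    while pos < total and t < duration:
        v = v0 * max(0.05, 1.0 + rng.normal(0.0, cv))
        pos = min(total, pos + v * dt)
        positions.append(pos)
        t += dt
    positions_arr = np.asarray(positions)
    if incomplete:
        frac = rng.uniform(0.10, 0.45)
        keep = max(3, int(len(positions_arr) * frac))
        positions_arr = np.minimum(positions_arr[:keep], total * frac)
    x = np.interp(positions_arr, arclen, x_grid)
    y = np.interp(positions_arr, arclen, y_grid)
    t_s = np.arange(len(positions_arr)) * dt
    return {
        "t_s": t_s.tolist(),
        "x_mm": x.tolist(),
        "y_mm": y.tolist(),
        "phase": ["move"] * len(positions_arr),
        "spiral_completeness": float(positions_arr[-1] / total),
    }


def _sdmt_session(
    rng: np.random.Generator,
    response_s: float,
    error_rate: float,
    duration: float = 90.0,
    rt_jitter: float = 0.10,
) -> dict:
    key = {sym: i + 1 for i, sym in enumerate(SDMT_SYMBOLS)}
    responses: list[tuple[str, int]] = []
    t = 0.0
    i = 0
    while True:
        t += max(0.3, response_s * (1.0 + rng.normal(0.0, rt_jitter)) if rt_jitter > 0 else response_s)
        if t > duration:
            break
        sym = SDMT_SYMBOLS[i % len(SDMT_SYMBOLS)]
        correct = key[sym]
        if rng.random() < error_rate:
            wrong = [d for d in range(1, 10) if d != correct]
            digit = int(rng.choice(wrong))
        else:
            digit = correct
        responses.append((sym, digit))
        i += 1
    return {"responses": responses, "key": key, "duration_s": duration}


def _swr_session(
    rng: np.random.Generator, rate: float, miss_rate: float, duration: float = 45.0
) -> dict:
    displayed = [str(rng.choice(SWR_VOCABULARY)) for _ in range(60)]
    n_read = int(np.clip(math.floor(max(0.0, rate) * duration), 0, 60))
    recognized = [w for w in displayed[:n_read] if rng.random() >= miss_rate]
    return {"displayed": displayed, "recognized": recognized, "duration_s": duration}


def synthesize_session(
    participant: ParticipantRecord,
    test: TestType,
    hand: Optional[Hand],
    seed: int,
    params: Optional[SignalParams] = None,
    placement: Placement = Placement.POUCH,
    day: int = 1,
) -> TestSession:
    """Generate one raw session whose extracted feature is monotone in severity."""
    try:
        test = TestType(test)
    except ValueError as exc:
        raise ConfigurationError(f"unknown test type: {test}") from exc
    params = params or SignalParams()
    s = participant.severity
    traits = _participant_traits(participant, params)
    rng = np.random.default_rng([seed, participant.seed, _stable_hash(test.value)])
    session_noise = float(np.exp(rng.normal(0.0, params.session_sd)))

    if test is TestType.CHOREA:
        amp = _affine(params.chorea_amp, s) * traits["chorea"] * session_noise
        payload = _sway_session(rng, amp, TEST_DURATION_S[test], params.fs_hz)
    elif test is TestType.BALANCE:
        amp = _affine(params.balance_amp, s) * traits["balance"] * session_noise
        payload = _sway_session(rng, amp, TEST_DURATION_S[test], params.fs_hz)
    elif test is TestType.U_TURN:
        speed = _affine(params.turn_speed, s) * traits["turn"] * session_noise
        payload = _uturn_session(rng, max(0.4, speed), params.fs_hz)
    elif test is TestType.WALKING:
        jitter = _affine(params.step_jitter_sd, s) * traits["step"] * session_noise
        payload = _walking_session(rng, jitter, params.fs_hz)
    elif test is TestType.SPEEDED_TAPPING:
        air = _affine(params.tap_air_mean, s) * traits["tap"] * session_noise
        air_sd = _affine(params.tap_air_sd, s)
        payload = _tapping_session(rng, air, air_sd)
    elif test is TestType.DRAW_A_SHAPE:
        cv = _affine(params.spiral_cv, s) * traits["spiral"] * session_noise
        incomplete = bool(rng.random() < _affine(params.draw_incomplete_prob, s))
        payload = _spiral_session(rng, cv, incomplete)
    elif test is TestType.SDMT:
        rt = _affine(params.sdmt_response_s, s) * traits["sdmt"] * session_noise
        err = float(np.clip(_affine(params.sdmt_error_rate, s), 0.0, 1.0))
        payload = _sdmt_session(rng, rt, err, rt_jitter=params.sdmt_rt_jitter)
    elif test is TestType.SWR:
        rate = _affine(params.swr_rate, s) * traits["swr"] / session_noise
        miss = float(np.clip(_affine(params.swr_miss_rate, s), 0.0, 1.0))
        payload = _swr_session(rng, rate, miss)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown test type: {test}")

    return TestSession(
        participant_id=participant.id,
        test=test,
        day=day,
        hand=hand,
        placement=placement,
        payload=payload,
    )


# ---------------------------------------------------------------------------
# study-level convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    participants: list[ParticipantRecord]
    schedules: dict[str, Schedule]
    sessions: list[TestSession]


def simulate_study(
    specs: list[CohortSpec],
    adherence_prob: float,
    pocket_prob: float,
    seed: int,
    params: Optional[SignalParams] = None,
    n_days: int = 28,
) -> SimulatedStudy:
    """Full generative pass: cohorts -> schedules -> raw sessions."""
    params = params or SignalParams()
    participants: list[ParticipantRecord] = []
    for spec in specs:
        participants.extend(generate_cohort(spec))
    schedules: dict[str, Schedule] = {}
    sessions: list[TestSession] = []
    for p in participants:
        sched = generate_schedule(p, adherence_prob, pocket_prob, seed, n_days=n_days)
        schedules[p.id] = sched
        for k, entry in enumerate(sched.entries):
            if not entry.completed:
                continue
            session = synthesize_session(
                p,
                entry.test,
                entry.hand,
                seed=seed * 100003 + k,
                params=params,
                placement=entry.placement,
                day=entry.day,
            )
            sessions.append(session)
    return SimulatedStudy(participants=participants, schedules=schedules, sessions=sessions)


def paired_interval_values(
    n_participants: int,
    sigma_between: float,
    sigma_within: float,
    seed: int,
    mu: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-interval feature values with known reliability.

    Each participant gets a stable level ``mu + b_i`` (``b_i ~ N(0,
    sigma_between)``) and each interval adds independent noise ``N(0,
    sigma_within)``; the population intraclass correlation is
    ``sigma_between^2 / (sigma_between^2 + sigma_within^2)``.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sigma_between, size=n_participants)
    v1 = mu + b + rng.normal(0.0, sigma_within, size=n_participants)
    v2 = mu + b + rng.normal(0.0, sigma_within, size=n_participants)
    return v1, v2
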