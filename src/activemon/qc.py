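"""Session-level quality control and QC reporting.

The QC criteria are *reconstructed*: the deployed platform's exact rules are
not public, so each predicate here is an explicit, configurable check chosen
to reproduce the reported behaviour — near-zero fail rates for the cognitive
and hand-held tests, higher fail rates for Draw-A-Shape (incomplete traces)
and for the waist-worn ambulatory tests (pocket carriage is always
discarded for Walking, U-Turn and Balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AMBULATORY_TESTS,
    TEST_DURATION_S,
    ConfigurationError,
    FeatureValue,
    ParticipantRecord,
    Placement,
    QcStatus,
    TestSession,
    TestType,
)

DEFAULT_N_MIN = {TestType.SDMT: 1, TestType.SWR: 1}
DEFAULT_N_MIN_OTHER = 3


def n_min_for(test: TestType, overrides: Optional[dict] = None) -> int:
    """Minimum passing observations per 2-week interval for evaluability."""
    table = dict(DEFAULT_N_MIN)
    if overrides:
        table.update({TestType(k): int(v) for k, v in overrides.items()})
    return table.get(TestType(test), DEFAULT_N_MIN_OTHER)


@dataclass
class QcRule:
    """Configurable per-test QC predicates; all pure functions of a session."""

    test: TestType
    min_duration_frac: float = 0.90
    require_pouch: bool = False
    min_events: int = 0  # taps / responses / trace points
    min_spiral_completeness: float = 0.50
    enabled: bool = True


def default_rules(placement_rule: bool = True) -> dict[TestType, QcRule]:
    """One rule set per active test (exactly one, per the invariant)."""
    rules = {}
    for test in TestType:
        rules[test] = QcRule(
            test=test,
            require_pouch=placement_rule and test in AMBULATORY_TESTS,
        )
    rules[TestType.SPEEDED_TAPPING].min_events = 4  # 2 completed taps
    rules[TestType.DRAW_A_SHAPE].min_events = 3
    return rules


def _payload_duration(session: TestSession) -> Optional[float]:
    payload = session.payload
    if "t_s" in payload and len(payload["t_s"]) >= 2:
        t = np.asarray(payload["t_s"], dtype=float)
        return float(t[-1] - t[0])
    if "duration_s" in payload:
        return float(payload["duration_s"])
    return None


def apply_qc(session: TestSession, rules: dict[TestType, QcRule]) -> QcStatus:
    """Evaluate all predicates; fail on the first violated one."""
    if session.test not in rules:
        raise ConfigurationError(f"no QC rule set for test {session.test}")
    rule = rules[session.test]
    if not rule.enabled:
        return QcStatus.ok()

    if rule.require_pouch and session.placement is Placement.POCKET:
        return QcStatus.fail("placement")

    payload = session.payload
    if not payload:
        return QcStatus.fail("empty_payload")

    if session.test in (TestType.CHOREA, TestType.BALANCE, TestType.U_TURN, TestType.WALKING):
        if "t_s" not in payload or payload.get("acc") is None:
            return QcStatus.fail("missing_sensor_stream")
        duration = _payload_duration(session)
        nominal = TEST_DURATION_S[session.test]
        # Walking stops at 200 m or 2 min, so only the stationary tests have
        # a sharp nominal duration; a generous floor still catches aborts.
        min_frac = rule.min_duration_frac if session.test is not TestType.WALKING else 0.25
        if duration is None or duration < min_frac * nominal:
            return QcStatus.fail("short_recording")

    if session.test is TestType.SPEEDED_TAPPING:
        if len(payload.get("t_s", [])) < rule.min_events:
            return QcStatus.fail("too_few_taps")

    if session.test is TestType.DRAW_A_SHAPE:
        if len(payload.get("t_s", [])) < rule.min_events:
            return QcStatus.fail("too_few_trace_points")
        completeness = payload.get("spiral_completeness")
        if completeness is not None and completeness < rule.min_spiral_completeness:
            return QcStatus.fail("incomplete_trace")

    if session.test is TestType.SDMT and "responses" not in payload:
        return QcStatus.fail("missing_responses")
    if session.test is TestType.SWR and "displayed" not in payload:
        return QcStatus.fail("missing_word_stream")

    return QcStatus.ok()


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def round_rate(numerator: int, denominator: int, precision: int) -> float:
    """Percentage 100 * numerator / denominator at the printed precision."""
    if denominator == 0:
        raise ZeroDivisionError("rate undefined for zero attempts")
    return round(100.0 * numerator / denominator, precision)


@dataclass
class QcReport:
    """Stratified fail rates, per-subject pass rates and participant losses."""

    strata: pd.DataFrame  # study, cohort, test, hand, excluded, total, fail_rate_pct
    subject_pass_rates: pd.DataFrame  # participant_id, test, passed, attempted, pass_rate
    participants_lost: pd.DataFrame = field(default_factory=pd.DataFrame)
    precision: int = 1


def qc_report(
    sessions: Sequence[TestSession],
    statuses: Sequence[QcStatus],
    participants: Optional[dict[str, ParticipantRecord]] = None,
    precision: int = 1,
) -> QcReport:
    """Aggregate session QC outcomes into printed-rate form.

    Strata with zero attempted sessions are simply absent (undefined rates
    are omitted, never printed as 0).
    """
    if len(sessions) != len(statuses):
        raise ValueError("sessions and statuses must align")
    rows = []
    for sess, status in zip(sessions, statuses):
        p = participants.get(sess.participant_id) if participants else None
        rows.append(
            {
                "participant_id": sess.participant_id,
                "study": p.study.value if p else "unknown",
                "cohort": p.cohort.value if p else "unknown",
                "test": sess.test.value,
                "hand": sess.hand.value if sess.hand else "",
                "passed": status.passed,
            }
        )
    columns = ["participant_id", "study", "cohort", "test", "hand", "passed"]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        return QcReport(
            strata=pd.DataFrame(
                columns=["study", "cohort", "test", "hand", "excluded", "total", "fail_rate_pct"]
            ),
            subject_pass_rates=pd.DataFrame(
                columns=["participant_id", "test", "passed", "attempted", "pass_rate"]
            ),
            precision=precision,
        )

    grouped = df.groupby(["study", "cohort", "test", "hand"], as_index=False).agg(
        excluded=("passed", lambda s: int((~s).sum())),
        total=("passed", "size"),
    )
    grouped["fail_rate_pct"] = [
        round_rate(e, t, precision) for e, t in zip(grouped["excluded"], grouped["total"])
    ]

    subj = df.groupby(["participant_id", "test"], as_index=False).agg(
        passed=("passed", "sum"), attempted=("passed", "size")
    )
    subj["pass_rate"] = subj["passed"] / subj["attempted"]

    return QcReport(strata=grouped, subject_pass_rates=subj, precision=precision)


def participants_lost(
    feature_values: Sequence[FeatureValue],
    participant_ids: Iterable[str],
    test: TestType,
    n_min: Optional[int] = None,
    precision: int = 1,
) -> dict:
    """Participants with no 2-week interval retaining >= n_min passing values.

    Returns lost/total counts and the printed percentage for one test.
    """
    n_min = n_min if n_min is not None else n_min_for(test)
    ids = list(participant_ids)
    passing_days: dict[str, list[int]] = {pid: [] for pid in ids}
    for fv in feature_values:
        if fv.test is TestType(test) and fv.qc_status.passed and fv.participant_id in passing_days:
            passing_days[fv.participant_id].append(fv.day)
    lost = 0
    for pid in ids:
        days = passing_days[pid]
        n1 = sum(1 for d in days if 1 <= d <= 14)
        n2 = sum(1 for d in days if 15 <= d <= 28)
        if n1 < n_min and n2 < n_min:
            lost += 1
    return {
        "test": TestType(test).value,
        "lost": lost,
        "total": len(ids),
        "lost_pct": round_rate(lost, len(ids), precision),
    }


def pass_rate_severity_association(
    report: QcReport,
    participants: dict[str, ParticipantRecord],
    test: TestType = TestType.DRAW_A_SHAPE,
    scores: Sequence[str] = ("tms", "chorea_d"),
) -> dict[str, dict]:
    """Spearman correlation of per-subject QC pass rate vs clinical scores."""
    subj = report.subject_pass_rates
    sel = subj[subj["test"] == TestType(test).value]
    if len(sel) < 10:
        raise ConfigurationError("need >= 10 participants with defined pass rates")
    out: dict[str, dict] = {}
    rates = sel.set_index("participant_id")["pass_rate"]
    for score in scores:
        vals = np.array([participants[pid].clinical[score] for pid in rates.index])
        if np.ptp(rates.values) == 0 or np.ptp(vals) == 0:
            out[score] = {"rho": None, "p": None, "flag": "constant_input"}
            continue
        rho, p = stats.spearmanr(rates.values, vals)
        out[score] = {"rho": float(rho), "p": float(p), "sign": int(np.sign(rho))}
    return out
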