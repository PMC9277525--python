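import numpy as np
import pytest

from activemon import qc as qcmod
from activemon.synthetic import CohortSpec, generate_cohort, synthesize_session
from activemon.types import (
    AMBULATORY_TESTS,
    Cohort,
    ConfigurationError,
    FeatureValue,
    FeatureName,
    Placement,
    QcStatus,
    Study,
    TestSession,
    TestType,
)


def imu_session(test, placement=Placement.POUCH, duration=30.0, pid="p1", day=1):
    n = int(duration * 50) + 1
    return TestSession(
        participant_id=pid,
        test=test,
        day=day,
        placement=placement,
        payload={
            "t_s": np.arange(n) / 50.0,
            "acc": np.tile([0.0, 0.0, 9.81], (n, 1)),
        },
    )


class TestApplyQc:
    def test_walking_pocket_fails(self):
        rules = qcmod.default_rules()
        session = imu_session(TestType.WALKING, Placement.POCKET, duration=120)
        status = qcmod.apply_qc(session, rules)
        assert not status.passed and status.reason == "placement"

    def test_all_ambulatory_pocket_fail(self):
        rules = qcmod.default_rules()
        for test in AMBULATORY_TESTS:
            dur = 120 if test is TestType.WALKING else 60
            status = qcmod.apply_qc(imu_session(test, Placement.POCKET, dur), rules)
            assert not status.passed and status.reason == "placement"

    def test_chorea_pocket_not_placement_checked(self):
        rules = qcmod.default_rules()
        status = qcmod.apply_qc(imu_session(TestType.CHOREA, Placement.POCKET), rules)
        assert status.passed

    def test_balance_pouch_full_duration_passes(self):
        rules = qcmod.default_rules()
        assert qcmod.apply_qc(imu_session(TestType.BALANCE), rules).passed

    def test_short_recording_fails(self):
        rules = qcmod.default_rules()
        status = qcmod.apply_qc(imu_session(TestType.BALANCE, duration=10.0), rules)
        assert not status.passed and status.reason == "short_recording"

    def test_incomplete_spiral_fails(self):
        rules = qcmod.default_rules()
        session = TestSession(
            participant_id="p1",
            test=TestType.DRAW_A_SHAPE,
            day=1,
            payload={
                "t_s": [0.0, 0.1, 0.2, 0.3],
                "x_mm": [0, 1, 2, 3],
                "y_mm": [0, 1, 2, 3],
                "phase": ["move"] * 4,
                "spiral_completeness": 0.35,
            },
        )
        status = qcmod.apply_qc(session, rules)
        assert not status.passed and status.reason == "incomplete_trace"

    def test_missing_rule_set_raises(self):
        session = imu_session(TestType.BALANCE)
        with pytest.raises(ConfigurationError):
            qcmod.apply_qc(session, {})

    def test_idempotent_and_order_independent(self):
        rules = qcmod.default_rules()
        sessions = [
            imu_session(TestType.WALKING, Placement.POCKET, 120),
            imu_session(TestType.BALANCE),
            imu_session(TestType.U_TURN, duration=60),
        ]
        first = [qcmod.apply_qc(s, rules).passed for s in sessions]
        again = [qcmod.apply_qc(s, rules).passed for s in reversed(sessions)]
        assert first == list(reversed(again))

    def test_placement_rule_removal_monotone(self):
        """Disabling the placement rule can only add passes, and only for
        the three ambulatory tests."""
        with_rule = qcmod.default_rules(placement_rule=True)
        without = qcmod.default_rules(placement_rule=False)
        durations = {TestType.WALKING: 120, TestType.U_TURN: 60}
        for test in TestType:
            if test not in AMBULATORY_TESTS and test not in (TestType.CHOREA,):
                continue
            dur = durations.get(test, 30)
            session = imu_session(test, Placement.POCKET, dur)
            p_with = qcmod.apply_qc(session, with_rule).passed
            p_without = qcmod.apply_qc(session, without).passed
            if test in AMBULATORY_TESTS:
                assert not p_with and p_without
            else:
                assert p_with == p_without


def make_report(n_total, n_fail, test=TestType.CHOREA, precision=1):
    sessions = [
        TestSession(participant_id=f"p{i % 10}", test=test, day=1, payload={"x": 1})
        for i in range(n_total)
    ]
    statuses = [
        QcStatus.fail("synthetic") if i < n_fail else QcStatus.ok()
        for i in range(n_total)
    ]
    return qcmod.qc_report(sessions, statuses, precision=precision)


class TestQcReport:
    def test_16_of_238_prints_6_7(self):
        report = make_report(238, 16)
        assert report.strata["fail_rate_pct"].iloc[0] == 6.7

    def test_zero_failures(self):
        report = make_report(100, 0)
        assert report.strata["fail_rate_pct"].iloc[0] == 0.0

    def test_84_of_272_prints_30_9(self):
        report = make_report(272, 84, test=TestType.WALKING)
        assert report.strata["fail_rate_pct"].iloc[0] == 30.9

    def test_subject_pass_rates(self):
        report = make_report(10, 5)
        subj = report.subject_pass_rates
        assert ((subj["passed"] <= subj["attempted"]).all())
        assert subj["pass_rate"].between(0, 1).all()

    def test_rates_bounded(self):
        report = make_report(37, 21)
        assert 0 <= report.strata["fail_rate_pct"].iloc[0] <= 100


class TestParticipantsLost:
    @staticmethod
    def fv(pid, day, passed=True):
        return FeatureValue(
            participant_id=pid,
            test=TestType.U_TURN,
            day=day,
            feature=FeatureName.TURN_SPEED_MEDIAN,
            value=1.5 if passed else None,
            units="rad/s",
            qc_status=QcStatus.ok() if passed else QcStatus.fail("x"),
        )

    def test_lost_iff_both_intervals_below_nmin(self):
        values = []
        # p_kept: 3 passing in interval 1 -> retained
        values += [self.fv("p_kept", d) for d in (2, 3, 4)]
        # p_lost: 2 passing per interval -> lost (n_min = 3 for U-Turn)
        values += [self.fv("p_lost", d) for d in (1, 2, 15, 16)]
        # p_second: only interval 2 has enough -> retained
        values += [self.fv("p_second", d) for d in (16, 17, 18)]
        out = qcmod.participants_lost(values, ["p_kept", "p_lost", "p_second"], TestType.U_TURN)
        assert out["lost"] == 1 and out["total"] == 3

    def test_failing_values_do_not_count(self):
        values = [self.fv("p1", d, passed=False) for d in (1, 2, 3, 4, 5)]
        out = qcmod.participants_lost(values, ["p1"], TestType.U_TURN)
        assert out["lost"] == 1

    def test_printed_percentage(self):
        values = []
        for i in range(179):
            pid = f"p{i}"
            if i < 23:
                values += [self.fv(pid, d) for d in (1, 15)]  # 1 per interval
            else:
                values += [self.fv(pid, d) for d in (1, 2, 3)]
        out = qcmod.participants_lost(values, [f"p{i}" for i in range(179)], TestType.U_TURN)
        assert out["lost_pct"] == 12.8


class TestPassRateSeverityAssociation:
    @staticmethod
    def _report_from_failures(participants, fail_prob_fn, rng):
        sessions, statuses = [], []
        for p in participants:
            for _ in range(20):
                sessions.append(
                    TestSession(
                        participant_id=p.id, test=TestType.DRAW_A_SHAPE, day=1, payload={"x": 1}
                    )
                )
                failed = rng.random() < fail_prob_fn(p)
                statuses.append(QcStatus.fail("incomplete_trace") if failed else QcStatus.ok())
        return qcmod.qc_report(sessions, statuses)

    def test_severity_linked_failures_negative_rho(self, rng):
        cohort = generate_cohort(
            CohortSpec(Study.OLE, Cohort.MANIFEST, 100, 0.5, 0.25, 3)
        )
        report = self._report_from_failures(cohort, lambda p: 0.6 * p.severity, rng)
        out = qcmod.pass_rate_severity_association(report, {p.id: p for p in cohort})
        assert out["tms"]["rho"] < 0
        assert out["chorea_d"]["rho"] < 0

    def test_independent_failures_null(self, rng):
        cohort = generate_cohort(
            CohortSpec(Study.OLE, Cohort.MANIFEST, 100, 0.5, 0.25, 3)
        )
        report = self._report_from_failures(cohort, lambda p: 0.3, rng)
        out = qcmod.pass_rate_severity_association(report, {p.id: p for p in cohort})
        assert abs(out["tms"]["rho"]) < 0.25
        assert out["tms"]["p"] > 0.05

    def test_constant_pass_rates_flagged(self):
        cohort = generate_cohort(
            CohortSpec(Study.OLE, Cohort.MANIFEST, 20, 0.5, 0.25, 3)
        )
        sessions = [
            TestSession(participant_id=p.id, test=TestType.DRAW_A_SHAPE, day=1, payload={"x": 1})
            for p in cohort
        ]
        statuses = [QcStatus.ok()] * len(sessions)
        report = qcmod.qc_report(sessions, statuses)
        out = qcmod.pass_rate_severity_association(report, {p.id: p for p in cohort})
        assert out["tms"]["flag"] == "constant_input"
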