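"""End-to-end orchestration: simulate -> extract -> qc -> aggregate -> validate.

Every stage is a pure function of its upstream artifacts plus the config, so
two runs with the same config and seed produce identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import features as feats
from . import qc as qcmod
from . import validation as val
from .config import PipelineConfig
from .synthetic import SimulatedStudy, simulate_study
from .types import (
    Cohort,
    FeatureName,
    FeatureValue,
    Hand,
    ParticipantRecord,
    QcStatus,
    Study,
    TestType,
)

logger = logging.getLogger(__name__)

#: The five known-groups comparison groups (study/cohort combinations).
KNOWN_GROUPS = [
    (Study.DIGITAL_HD, Cohort.CONTROL),
    (Study.DIGITAL_HD, Cohort.PREMANIFEST),
    (Study.DIGITAL_HD, Cohort.MANIFEST),
    (Study.OLE, Cohort.MANIFEST),
    (Study.HD_NHS, Cohort.MANIFEST),
]


def group_label(p: ParticipantRecord) -> str:
    if p.study is Study.DIGITAL_HD:
        return f"DIGITAL_HD/{p.cohort.value}"
    return p.study.value


#: Feature/hand -> clinical score used for convergent validity.
def clinical_score_for(feature: str, test: str, hand: str) -> str:
    suffix = {"D": "_d", "ND": "_nd"}.get(hand, "")
    if feature == "sdmt_correct":
        return "sdmt_clinic"
    if feature == "swr_correct":
        return "swr_clinic"
    if feature == "intertap_mean_ms":
        return "intertap_clinic_ms"
    if feature == "spiral_speed_cv":
        return f"finger_taps{suffix or '_d'}"
    if feature == "sway_path" and test == "chorea":
        return f"chorea{suffix or '_d'}"
    if feature == "sway_path":
        return "balance_score"
    if feature == "turn_speed_median":
        return "tms"
    if feature == "step_freq_variance":
        return "tms"
    raise KeyError(feature)


#: Default correlation method per feature (Pearson where the digital and
#: in-clinic measures share a pseudo-continuous scale).
DEFAULT_METHODS = {
    "sdmt_correct": "pearson",
    "swr_correct": "pearson",
    "intertap_mean_ms": "pearson",
    "spiral_speed_cv": "spearman",
    "sway_path": "spearman",
    "turn_speed_median": "spearman",
    "step_freq_variance": "spearman",
}


@dataclass
class PipelineResult:
    config: PipelineConfig
    study: SimulatedStudy
    feature_values: list[FeatureValue]
    features_df: pd.DataFrame
    qc_report: qcmod.QcReport
    aggregated: pd.DataFrame
    adherence: pd.DataFrame
    icc_table: pd.DataFrame
    convergent_table: pd.DataFrame
    known_groups_results: dict[str, val.KnownGroupsResult]
    exclusion_log: pd.DataFrame = field(default_factory=pd.DataFrame)


def extract_and_qc(
    study: SimulatedStudy, config: PipelineConfig
) -> tuple[list[FeatureValue], list[QcStatus], pd.DataFrame]:
    """Apply session QC, then extract features from passing sessions."""
    rules = qcmod.default_rules(placement_rule=config.placement_rule)
    values: list[FeatureValue] = []
    statuses: list[QcStatus] = []
    exclusions = []
    for session in study.sessions:
        status = qcmod.apply_qc(session, rules)
        if status.passed:
            fv = feats.extract_features(session)[0]
        else:
            from .types import FEATURE_UNITS, TEST_FEATURE

            feature = TEST_FEATURE[session.test]
            fv = FeatureValue(
                participant_id=session.participant_id,
                test=session.test,
                day=session.day,
                feature=feature,
                value=None,
                units=FEATURE_UNITS[feature],
                hand=session.hand,
                qc_status=status,
            )
        values.append(fv)
        statuses.append(fv.qc_status)
        if not fv.qc_status.passed:
            exclusions.append(
                {
                    "participant_id": session.participant_id,
                    "test": session.test.value,
                    "day": session.day,
                    "hand": session.hand.value if session.hand else "",
                    "reason": fv.qc_status.reason,
                }
            )
    return values, statuses, pd.DataFrame(exclusions)


def features_to_df(values: list[FeatureValue]) -> pd.DataFrame:
    columns = [
        "participant_id", "test", "day", "hand", "feature", "value", "units", "qc_status",
    ]
    return pd.DataFrame(
        [
            {
                "participant_id": fv.participant_id,
                "test": fv.test.value,
                "day": fv.day,
                "hand": fv.hand.value if fv.hand else "",
                "feature": fv.feature.value,
                "value": fv.value,
                "units": fv.units,
                "qc_status": str(fv.qc_status),
            }
            for fv in values
        ],
        columns=columns,
    )


def _interval_wide(aggregated: pd.DataFrame) -> pd.DataFrame:
    """participant x (feature, hand) with interval-1/2 medians as columns."""
    if aggregated.empty:
        return pd.DataFrame(columns=["participant_id", "feature", "hand", "m1", "m2"])
    return aggregated.pivot_table(
        index=["participant_id", "feature", "hand"],
        columns="interval",
        values="median",
        aggfunc="first",
        dropna=False,
    ).reset_index().rename(columns={1: "m1", 2: "m2"})


def _feature_test(values: list[FeatureValue]) -> dict[tuple[str, str], str]:
    out = {}
    for fv in values:
        out[(fv.feature.value, fv.hand.value if fv.hand else "")] = fv.test.value
    return out


def icc_table(
    aggregated: pd.DataFrame, participants: dict[str, ParticipantRecord]
) -> pd.DataFrame:
    """Test-retest ICC per (feature, hand, study) from interval medians."""
    wide = _interval_wide(aggregated)
    wide["study"] = wide["participant_id"].map(lambda pid: participants[pid].study.value)
    rows = []
    for (feature, hand, study), grp in wide.groupby(["feature", "hand", "study"]):
        pairs = grp.dropna(subset=["m1", "m2"])
        if len(pairs) < 3:
            continue
        try:
            res = val.test_retest_icc(pairs["m1"].to_numpy(), pairs["m2"].to_numpy())
        except val.InsufficientDataError:
            continue
        rows.append(
            {
                "feature": feature,
                "hand": hand,
                "study": study,
                "icc": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows, columns=["feature", "hand", "study", "icc", "ci_low", "ci_high", "n"])


def convergent_table(
    aggregated: pd.DataFrame,
    participants: dict[str, ParticipantRecord],
    feature_values: list[FeatureValue],
    methods: Optional[dict[str, str]] = None,
    cohort: Cohort = Cohort.MANIFEST,
) -> pd.DataFrame:
    """Interval-1 medians vs in-clinic scores, per feature/hand/study."""
    methods = {**DEFAULT_METHODS, **(methods or {})}
    test_of = _feature_test(feature_values)
    wide = _interval_wide(aggregated)
    wide["study"] = wide["participant_id"].map(lambda pid: participants[pid].study.value)
    wide["cohort"] = wide["participant_id"].map(lambda pid: participants[pid].cohort)
    rows = []
    sel = wide[wide["cohort"] == cohort]
    for (feature, hand, study), grp in sel.groupby(["feature", "hand", "study"]):
        test = test_of.get((feature, hand), "")
        score_name = clinical_score_for(feature, test, hand)
        scores = [participants[pid].clinical[score_name] for pid in grp["participant_id"]]
        try:
            res = val.convergent_validity(
                grp["m1"].to_numpy(), np.asarray(scores), method=methods[feature]
            )
        except val.InsufficientDataError:
            continue
        rows.append(
            {
                "feature": feature,
                "hand": hand,
                "test": test,
                "study": study,
                "clinical_score": score_name,
                "method": res.method,
                "coefficient": res.coefficient,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "hand", "test", "study", "clinical_score", "method",
            "coefficient", "ci_low", "ci_high", "p_value", "n",
        ],
    )


def known_groups_by_feature(
    aggregated: pd.DataFrame, participants: dict[str, ParticipantRecord]
) -> dict[str, val.KnownGroupsResult]:
    """Known-groups comparison per (feature, hand) on interval-1 medians."""
    wide = _interval_wide(aggregated)
    results: dict[str, val.KnownGroupsResult] = {}
    for (feature, hand), grp in wide.groupby(["feature", "hand"]):
        recs = [participants[pid] for pid in grp["participant_id"]]
        df = pd.DataFrame(
            {
                "value": grp["m1"].to_numpy(),
                "age": [r.age for r in recs],
                "study": [r.study.value for r in recs],
                "group": [group_label(r) for r in recs],
            }
        )
        df = df.dropna(subset=["value"])
        if df["group"].nunique() < 2:
            continue
        key = f"{feature}:{hand}" if hand else feature
        results[key] = val.known_groups(df)
    return results


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in memory and return all result tables."""
    logger.info("simulating %d cohorts (seed=%d)", len(config.cohorts), config.seed)
    study = simulate_study(
        config.cohort_specs(),
        adherence_prob=config.adherence_prob,
        pocket_prob=config.pocket_prob,
        seed=config.seed,
        params=config.make_signal_params(),
        n_days=config.n_days,
    )
    participants = {p.id: p for p in study.participants}

    values, statuses, exclusions = extract_and_qc(study, config)
    report = qcmod.qc_report(
        study.sessions, statuses, participants, precision=config.report_precision
    )
    features_df = features_to_df(values)

    aggregated = agg.aggregate_all(values, config.n_min_overrides)
    adher = agg.adherence_by_study(
        study.schedules,
        {pid: participants[pid].study.value for pid in study.schedules},
        precision=config.report_precision,
    )

    icc = icc_table(aggregated, participants)
    conv = convergent_table(
        aggregated, participants, values, methods=config.correlation_methods
    )
    kg = known_groups_by_feature(aggregated, participants)

    return PipelineResult(
        config=config,
        study=study,
        feature_values=values,
        features_df=features_df,
        qc_report=report,
        aggregated=aggregated,
        adherence=adher,
        icc_table=icc,
        convergent_table=conv,
        known_groups_results=kg,
        exclusion_log=exclusions,
    )


def write_artifacts(result: PipelineResult, outdir: str | Path) -> dict[str, str]:
    """Write all result tables under ``outdir``; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "config": "config.yaml",
        "features": "features.csv",
        "qc_strata": "qc_strata.csv",
        "qc_subjects": "qc_subject_pass_rates.csv",
        "exclusions": "exclusions.csv",
        "aggregated": "aggregated.csv",
        "adherence": "adherence.json",
        "icc": "icc.csv",
        "convergent": "convergent.csv",
        "known_groups": "known_groups.json",
    }
    result.config.to_yaml(out / paths["config"])
    result.features_df.to_csv(out / paths["features"], index=False)
    result.qc_report.strata.to_csv(out / paths["qc_strata"], index=False)
    result.qc_report.subject_pass_rates.to_csv(out / paths["qc_subjects"], index=False)
    result.exclusion_log.to_csv(out / paths["exclusions"], index=False)
    result.aggregated.to_csv(out / paths["aggregated"], index=False)
    result.adherence.to_json(out / paths["adherence"], orient="records", indent=2)
    result.icc_table.to_csv(out / paths["icc"], index=False)
    result.convergent_table.to_csv(out / paths["convergent"], index=False)
    kg_payload = {
        key: {
            "groups": res.groups,
            "group_sizes": res.group_sizes,
            "kruskal_h": res.kruskal_h,
            "kruskal_p": res.kruskal_p,
            "pairwise": res.pairwise,
            "age_coefficient": res.age_coefficient,
            "model": res.model,
        }
        for key, res in result.known_groups_results.items()
    }
    with open(out / paths["known_groups"], "w") as fh:
        json.dump(kg_payload, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(paths, fh, indent=2)
    return paths
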