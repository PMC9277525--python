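"""Plain-text serialization of simulated studies.

Layout under a study directory::

    manifest.json            # session index + file references
    participants.csv
    schedule.csv
    sessions/<sid>_imu.csv       t_s, ax, ay, az[, gx, gy, gz]
    sessions/<sid>_touch.csv     t_s, x_mm, y_mm, phase
    sessions/<sid>_responses.csv test-specific response log
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SimulatedStudy
from .types import (
    Hand,
    ParticipantRecord,
    Placement,
    Schedule,
    ScheduleEntry,
    TestSession,
    TestType,
)


def participants_to_df(participants: list[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for p in participants:
        row = {
            "id": p.id,
            "study": p.study.value,
            "cohort": p.cohort.value,
            "age": p.age,
            "dominant_hand": p.dominant_hand,
            "severity": p.severity,
            "seed": p.seed,
        }
        row.update({f"clin_{k}": v for k, v in p.clinical.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def participants_from_df(df: pd.DataFrame) -> list[ParticipantRecord]:
    out = []
    for _, row in df.iterrows():
        clinical = {
            c[len("clin_"):]: float(row[c]) for c in df.columns if c.startswith("clin_")
        }
        out.append(
            ParticipantRecord(
                id=row["id"],
                study=row["study"],
                cohort=row["cohort"],
                age=float(row["age"]),
                dominant_hand=row["dominant_hand"],
                severity=float(row["severity"]),
                clinical=clinical,
                seed=int(row["seed"]),
            )
        )
    return out


def schedules_to_df(schedules: dict[str, Schedule]) -> pd.DataFrame:
    rows = []
    for pid, sched in schedules.items():
        for e in sched.entries:
            rows.append(
                {
                    "participant_id": pid,
                    "day": e.day,
                    "test": e.test.value,
                    "hand": e.hand.value if e.hand else "",
                    "scheduled": int(e.scheduled),
                    "completed": int(e.completed),
                    "placement": e.placement.value,
                }
            )
    return pd.DataFrame(rows)


def schedules_from_df(df: pd.DataFrame) -> dict[str, Schedule]:
    out: dict[str, Schedule] = {}
    for pid, grp in df.groupby("participant_id"):
        entries = [
            ScheduleEntry(
                day=int(r.day),
                test=TestType(r.test),
                hand=Hand(r.hand) if r.hand else None,
                scheduled=bool(r.scheduled),
                completed=bool(r.completed),
                placement=Placement(r.placement),
            )
            for r in grp.itertuples()
        ]
        out[str(pid)] = Schedule(participant_id=str(pid), entries=entries)
    return out


def _write_session_payload(session: TestSession, sid: str, sessions_dir: Path) -> dict:
    payload = session.payload
    files: dict[str, str] = {}
    meta: dict = {}
    if "acc" in payload:
        df = pd.DataFrame(np.asarray(payload["t_s"]), columns=["t_s"])
        acc = np.asarray(payload["acc"])
        df[["ax", "ay", "az"]] = acc
        if payload.get("gyro") is not None:
            df[["gx", "gy", "gz"]] = np.asarray(payload["gyro"])
        name = f"{sid}_imu.csv"
        df.to_csv(sessions_dir / name, index=False, float_format="%.6f")
        files["imu"] = name
    elif "x_mm" in payload:
        df = pd.DataFrame(
            {
                "t_s": payload["t_s"],
                "x_mm": payload["x_mm"],
                "y_mm": payload["y_mm"],
                "phase": payload["phase"],
            }
        )
        name = f"{sid}_touch.csv"
        df.to_csv(sessions_dir / name, index=False, float_format="%.6f")
        files["touch"] = name
        if "spiral_completeness" in payload:
            meta["spiral_completeness"] = payload["spiral_completeness"]
    elif "responses" in payload:
        df = pd.DataFrame(payload["responses"], columns=["symbol", "digit"])
        name = f"{sid}_responses.csv"
        df.to_csv(sessions_dir / name, index=False)
        files["responses"] = name
        meta["key"] = payload["key"]
        meta["duration_s"] = payload.get("duration_s")
    elif "displayed" in payload:
        n = max(len(payload["displayed"]), len(payload["recognized"]))
        df = pd.DataFrame(
            {
                "displayed": list(payload["displayed"]) + [""] * (n - len(payload["displayed"])),
                "recognized": list(payload["recognized"]) + [""] * (n - len(payload["recognized"])),
            }
        )
        name = f"{sid}_words.csv"
        df.to_csv(sessions_dir / name, index=False)
        files["words"] = name
        meta["duration_s"] = payload.get("duration_s")
    return {"files": files, "meta": meta}


def _read_session_payload(entry: dict, sessions_dir: Path) -> dict:
    files = entry["files"]
    meta = entry.get("meta", {})
    payload: dict = {}
    if "imu" in files:
        df = pd.read_csv(sessions_dir / files["imu"])
        payload["t_s"] = df["t_s"].to_numpy()
        payload["acc"] = df[["ax", "ay", "az"]].to_numpy()
        if "gx" in df.columns:
            payload["gyro"] = df[["gx", "gy", "gz"]].to_numpy()
    elif "touch" in files:
        df = pd.read_csv(sessions_dir / files["touch"])
        payload["t_s"] = df["t_s"].tolist()
        payload["x_mm"] = df["x_mm"].tolist()
        payload["y_mm"] = df["y_mm"].tolist()
        payload["phase"] = df["phase"].tolist()
        if "spiral_completeness" in meta:
            payload["spiral_completeness"] = meta["spiral_completeness"]
    elif "responses" in files:
        df = pd.read_csv(sessions_dir / files["responses"])
        payload["responses"] = list(zip(df["symbol"], df["digit"].astype(int)))
        payload["key"] = {k: int(v) for k, v in meta["key"].items()}
        payload["duration_s"] = meta.get("duration_s")
    elif "words" in files:
        df = pd.read_csv(sessions_dir / files["words"], keep_default_na=False)
        payload["displayed"] = [w for w in df["displayed"].tolist() if w]
        payload["recognized"] = [w for w in df["recognized"].tolist() if w]
        payload["duration_s"] = meta.get("duration_s")
    return payload


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    out = Path(outdir)
    sessions_dir = out / "sessions"
    sessions_dir.mkdir(parents=True, exist_ok=True)
    participants_to_df(study.participants).to_csv(out / "participants.csv", index=False)
    schedules_to_df(study.schedules).to_csv(out / "schedule.csv", index=False)
    index = []
    for i, session in enumerate(study.sessions):
        sid = f"s{i:06d}"
        entry = _write_session_payload(session, sid, sessions_dir)
        entry.update(
            {
                "sid": sid,
                "participant_id": session.participant_id,
                "test": session.test.value,
                "day": session.day,
                "hand": session.hand.value if session.hand else None,
                "placement": session.placement.value,
            }
        )
        index.append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"sessions": index}, fh, indent=1)


def read_study(indir: str | Path) -> SimulatedStudy:
    src = Path(indir)
    participants = participants_from_df(pd.read_csv(src / "participants.csv"))
    # keep_default_na so the empty hand tag round-trips as "" rather than NaN
    schedules = schedules_from_df(pd.read_csv(src / "schedule.csv", keep_default_na=False))
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    sessions = []
    for entry in manifest["sessions"]:
        payload = _read_session_payload(entry, src / "sessions")
        sessions.append(
            TestSession(
                participant_id=entry["participant_id"],
                test=TestType(entry["test"]),
                day=int(entry["day"]),
                hand=Hand(entry["hand"]) if entry["hand"] else None,
                placement=Placement(entry["placement"]),
                payload=payload,
            )
        )
    return SimulatedStudy(participants=participants, schedules=schedules, sessions=sessions)
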