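"""Plain-text serialization of records, cohorts and models.

Each record is stored as two two-column CSV signal files (time_s, value)
plus a JSON sidecar holding the sampling rate, subject metadata, reference
pressures and the planted fiducial truth.  A cohort directory additionally
carries a ``manifest.csv`` with one row per record (subject_id, record_id,
sbp_ref, dbp_ref, split).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import BeatTruth, Cohort, SubjectProfile, SyntheticRecord

__all__ = ["save_record", "load_record", "save_cohort", "load_cohort"]


def save_record(record: SyntheticRecord, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(record.ppg)) / record.fs
    for channel in ("ppg", "ecg"):
        pd.DataFrame({"time_s": t, "value": getattr(record, channel)}).to_csv(
            directory / f"{record.record_id}_{channel}.csv", index=False
        )
    sidecar = {
        "record_id": record.record_id,
        "subject_id": record.subject_id,
        "fs": record.fs,
        "sbp_ref": record.sbp_ref,
        "dbp_ref": record.dbp_ref,
        "beats": [asdict(b) for b in record.beats],
        "meta": record.meta,
    }
    (directory / f"{record.record_id}.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def load_record(directory: str | Path, record_id: str) -> SyntheticRecord:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{record_id}.json").read_text())
    channels = {
        ch: pd.read_csv(directory / f"{record_id}_{ch}.csv")["value"].to_numpy()
        for ch in ("ppg", "ecg")
    }
    return SyntheticRecord(
        ppg=channels["ppg"],
        ecg=channels["ecg"],
        fs=sidecar["fs"],
        beats=tuple(BeatTruth(**b) for b in sidecar["beats"]),
        sbp_ref=sidecar["sbp_ref"],
        dbp_ref=sidecar["dbp_ref"],
        subject_id=sidecar["subject_id"],
        record_id=sidecar["record_id"],
        meta=sidecar["meta"],
    )


def _subject_dict(profile: SubjectProfile) -> dict:
    d = asdict(profile)
    d["coupling"] = profile.coupling.tolist()
    d["bmi"] = profile.bmi
    return d


def save_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for split, records in (
        ("train", cohort.train_records),
        ("test", cohort.test_records),
    ):
        for rec in records:
            save_record(rec, directory / split)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "record_id": rec.record_id,
                    "sbp_ref": rec.sbp_ref,
                    "dbp_ref": rec.dbp_ref,
                    "split": split,
                }
            )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    subjects = {
        "train": [_subject_dict(s) for s in cohort.train_subjects],
        "test": [_subject_dict(s) for s in cohort.test_subjects],
    }
    (directory / "subjects.json").write_text(json.dumps(subjects, indent=1))


def load_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    subjects = json.loads((directory / "subjects.json").read_text())

    def build(entry: dict) -> SubjectProfile:
        entry = dict(entry)
        entry.pop("bmi", None)
        entry["coupling"] = np.asarray(entry["coupling"], float)
        return SubjectProfile(**entry)

    out: dict[str, list] = {"train": [], "test": []}
    for _, row in manifest.iterrows():
        out[row["split"]].append(
            load_record(directory / row["split"], row["record_id"])
        )
    return Cohort(
        train_subjects=tuple(build(s) for s in subjects["train"]),
        test_subjects=tuple(build(s) for s in subjects["test"]),
        train_records=tuple(out["train"]),
        test_records=tuple(out["test"]),
    )
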