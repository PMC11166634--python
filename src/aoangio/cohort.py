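"""Study cohort annotations and deterministic tallies.

The packaged fixture transcribes the study's participant table (group,
age, sex, study eyes, per-eye ETDRS retinopathy grade) and the lesion
presence table for the diabetes group (capillary loops, dilated or
saccular capillaries, microaneurysms), one CSV row per study eye.
Participants whose two eyes carry different grades are stored per eye.
Lesion tallies count *patients* (group D only); eye tallies count study
eyes per group and per grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "GRADES",
    "LESIONS",
    "ParticipantRecord",
    "CohortTable",
    "TallyReport",
    "CohortValidationError",
    "packaged_cohort_path",
    "load_cohort",
    "tally_lesions",
    "tally_eyes",
]

GRADES = ("none", "very_mild_NPDR", "mild_NPDR", "moderate_NPDR")
LESIONS = ("capillary_loops", "dilated_or_saccular", "microaneurysms")
_LESION_COLS = {"capillary_loops": "loops",
                "dilated_or_saccular": "dilated_saccular",
                "microaneurysms": "microaneurysms"}
_COLUMNS = ["participant_id", "group", "age", "sex", "eye", "grade",
            "loops", "dilated_saccular", "microaneurysms"]


class CohortValidationError(ValueError):
    """A cohort table row violates the study schema."""


@dataclass
class ParticipantRecord:
    id: int
    group: str
    age_years: int
    sex: str
    study_eyes: tuple[str, ...]
    grade_by_eye: dict[str, str]
    lesions: dict[str, bool]


@dataclass
class CohortTable:
    """Per-eye cohort annotations with participant-level accessors."""

    eyes: pd.DataFrame

    @property
    def records(self) -> list[ParticipantRecord]:
        out = []
        for pid, grp in self.eyes.groupby("participant_id", sort=True):
            row0 = grp.iloc[0]
            out.append(ParticipantRecord(
                id=int(pid), group=row0["group"], age_years=int(row0["age"]),
                sex=row0["sex"], study_eyes=tuple(grp["eye"]),
                grade_by_eye=dict(zip(grp["eye"], grp["grade"])),
                lesions={k: bool(row0[v]) for k, v in _LESION_COLS.items()}))
        return out

    @property
    def n_participants(self) -> int:
        return self.eyes["participant_id"].nunique()


@dataclass
class TallyReport:
    patients_with_lesion: dict[str, int] = field(default_factory=dict)
    eyes_by_group: dict[str, int] = field(default_factory=dict)
    eyes_by_grade: dict[str, int] = field(default_factory=dict)


def packaged_cohort_path() -> Path:
    return Path(resources.files("aoangio").joinpath("data/cohort_tables.csv"))


def load_cohort(table_file: Optional[Union[str, Path]] = None) -> CohortTable:
    """Load and validate a cohort CSV (defaults to the packaged tables).

    Rows with eye = OU are expanded to one OD and one OS row sharing the
    row's grade and flags.
    """
    path = Path(table_file) if table_file is not None \
        else packaged_cohort_path()
    df = pd.read_csv(path, dtype={"participant_id": int, "age": int})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    # expand OU into both study eyes
    ou = df[df["eye"] == "OU"]
    if len(ou):
        expanded = []
        for _, row in df.iterrows():
            if row["eye"] == "OU":
                for e in ("OD", "OS"):
                    r = row.copy()
                    r["eye"] = e
                    expanded.append(r)
            else:
                expanded.append(row)
        df = pd.DataFrame(expanded).reset_index(drop=True)

    for _, row in df.iterrows():
        pid = row["participant_id"]
        if row["group"] not in ("D", "H"):
            raise CohortValidationError(
                f"participant {pid}: unknown group {row['group']!r}")
        if row["grade"] not in GRADES:
            raise CohortValidationError(
                f"participant {pid}: grade {row['grade']!r} outside the "
                f"study range {GRADES}")
        if row["eye"] not in ("OD", "OS"):
            raise CohortValidationError(
                f"participant {pid}: eye must be OD or OS")
        if row["group"] == "H":
            if row["grade"] != "none":
                raise CohortValidationError(
                    f"healthy participant {pid} has grade {row['grade']!r}")
            if any(int(row[c]) for c in _LESION_COLS.values()):
                raise CohortValidationError(
                    f"healthy participant {pid} carries lesion flags")
    dup = df.duplicated(subset=["participant_id", "eye"])
    if dup.any():
        pid = df.loc[dup, "participant_id"].iloc[0]
        raise CohortValidationError(f"duplicate eye rows for participant "
                                    f"{pid}")
    # participant-level fields must be consistent across their eye rows
    for pid, grp in df.groupby("participant_id"):
        for col in ("group", "age", "sex", *_LESION_COLS.values()):
            if grp[col].nunique() > 1:
                raise CohortValidationError(
                    f"participant {pid}: inconsistent {col} across eyes")
    return CohortTable(eyes=df.reset_index(drop=True))


def tally_lesions(table: CohortTable) -> TallyReport:
    """Per-lesion patient counts over the diabetes group."""
    d = table.eyes[table.eyes["group"] == "D"]
    per_patient = d.groupby("participant_id").first()
    counts = {lesion: int((per_patient[col] == 1).sum())
              for lesion, col in _LESION_COLS.items()}
    return TallyReport(patients_with_lesion=counts)


def tally_eyes(table: CohortTable) -> TallyReport:
    """Study-eye counts per group, and per grade within the D group."""
    eyes = table.eyes
    by_group = {g: int((eyes["group"] == g).sum()) for g in ("D", "H")}
    d = eyes[eyes["group"] == "D"]
    by_grade = {g: int((d["grade"] == g).sum()) for g in GRADES}
    return TallyReport(eyes_by_group=by_group, eyes_by_grade=by_grade)
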