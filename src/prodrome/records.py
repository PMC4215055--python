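"""Core longitudinal-record containers and the canonical on-disk tables.

Every fact in a patient's history is a timestamped :class:`ClinicalEvent`;
a :class:`PatientRecord` is demographics plus the date-ordered event stream.
Dates are integer day offsets from a fixed epoch (day 0 = Jan 1 of
:data:`EPOCH_YEAR`), which keeps all window arithmetic exact and avoids
calendar ambiguity.

At cohort scale the pipeline operates on plain :class:`pandas.DataFrame`
tables (one row per event / per patient); the dataclasses are the
per-patient view used by the record-level operations and are backed by
slices of the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

EPOCH_YEAR = 2000
DAYS_PER_YEAR = 365

#: Recognised event types.
EVENT_TYPES = ("visit", "icd9", "term", "drug_mention", "rx", "cpt", "phq9")

#: Canonical column order of the event table.
EVENT_COLUMNS = [
    "patient_id",
    "date",
    "event_type",
    "code",
    "negated",
    "family_history",
    "value",
]

PATIENT_COLUMNS = ["patient_id", "birth_year", "gender"]

TREATMENT_COLUMNS = [
    "patient_id",
    "start_day",
    "modality",
    "baseline_phq9",
    "followup_phq9",
]


@dataclass(frozen=True)
class ClinicalEvent:
    """One timestamped fact: a visit, a coded diagnosis, an annotated text
    term, a drug-ingredient mention, or a PHQ-9 score.

    Negation / family-history flags are only meaningful for text-derived
    term events; PHQ-9 events carry the total score (0-27) in ``value``.
    """

    patient_id: str
    date: int
    event_type: str
    code: str = ""
    negated: bool = False
    family_history: bool = False
    value: float | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.event_type == "phq9":
            if self.value is None or not (0 <= self.value <= 27):
                raise ValueError("phq9 events require a value in [0, 27]")


@dataclass
class PatientRecord:
    """Demographics plus a date-ordered event stream for one patient.

    ``events`` is a DataFrame with :data:`EVENT_COLUMNS`, sorted
    non-decreasing by date.
    """

    patient_id: str
    birth_year: int
    gender: str
    events: pd.DataFrame = field(default_factory=lambda: _empty_events())

    def __post_init__(self) -> None:
        dates = self.events["date"].to_numpy()
        if len(dates) and np.any(np.diff(dates) < 0):
            self.events = self.events.sort_values("date", kind="stable").reset_index(
                drop=True
            )

    @classmethod
    def from_events(
        cls, patient_id: str, events: list[ClinicalEvent], birth_year: int = 1970,
        gender: str = "F",
    ) -> "PatientRecord":
        frame = events_to_frame(events)
        return cls(patient_id=patient_id, birth_year=birth_year, gender=gender,
                   events=frame)

    def _visit_dates(self) -> np.ndarray:
        mask = self.events["event_type"].to_numpy() == "visit"
        if mask.any():
            return self.events.loc[mask, "date"].to_numpy()
        # degenerate records without explicit visit events: fall back to events
        return self.events["date"].to_numpy()

    @property
    def first_visit(self) -> int:
        dates = self._visit_dates()
        if len(dates) == 0:
            raise ValueError(f"patient {self.patient_id} has no events")
        return int(dates.min())

    @property
    def last_visit(self) -> int:
        dates = self._visit_dates()
        if len(dates) == 0:
            raise ValueError(f"patient {self.patient_id} has no events")
        return int(dates.max())

    @property
    def history_length(self) -> int:
        """Follow-up time in days: last visit minus first visit."""
        return self.last_visit - self.first_visit

    def age_at(self, day: int) -> int:
        """Completed years of age on the given day offset."""
        return EPOCH_YEAR + day // DAYS_PER_YEAR - self.birth_year

    def with_events(self, events: pd.DataFrame) -> "PatientRecord":
        return PatientRecord(self.patient_id, self.birth_year, self.gender,
                             events.reset_index(drop=True))


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype=object),
            "date": pd.Series(dtype=np.int64),
            "event_type": pd.Series(dtype=object),
            "code": pd.Series(dtype=object),
            "negated": pd.Series(dtype=bool),
            "family_history": pd.Series(dtype=bool),
            "value": pd.Series(dtype=float),
        }
    )


def events_to_frame(events: list[ClinicalEvent]) -> pd.DataFrame:
    if not events:
        return _empty_events()
    frame = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "date": np.asarray([e.date for e in events], dtype=np.int64),
            "event_type": [e.event_type for e in events],
            "code": [e.code for e in events],
            "negated": np.asarray([e.negated for e in events], dtype=bool),
            "family_history": np.asarray([e.family_history for e in events], dtype=bool),
            "value": np.asarray(
                [np.nan if e.value is None else e.value for e in events], dtype=float
            ),
        }
    )
    return frame.sort_values(["patient_id", "date"], kind="stable").reset_index(drop=True)


def frame_to_events(frame: pd.DataFrame) -> list[ClinicalEvent]:
    return [
        ClinicalEvent(
            patient_id=str(row.patient_id),
            date=int(row.date),
            event_type=str(row.event_type),
            code=str(row.code),
            negated=bool(row.negated),
            family_history=bool(row.family_history),
            value=None if pd.isna(row.value) else float(row.value),
        )
        for row in frame.itertuples()
    ]


def iter_records(
    events: pd.DataFrame, patients: pd.DataFrame
) -> Iterator[PatientRecord]:
    """Yield one :class:`PatientRecord` per row of the patients table."""
    groups = dict(tuple(events.groupby("patient_id", sort=False, observed=True)))
    for row in patients.itertuples():
        pid = row.patient_id
        ev = groups.get(pid)
        if ev is None:
            ev = _empty_events()
        yield PatientRecord(
            patient_id=str(pid),
            birth_year=int(row.birth_year),
            gender=str(row.gender),
            events=ev.reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# canonical CSV I/O


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    out["negated"] = out["negated"].astype(int)
    out["family_history"] = out["family_history"].astype(int)
    out[EVENT_COLUMNS].to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"patient_id": str, "event_type": str, "code": str},
        keep_default_na=False,
        na_values=[""],
    )
    frame["code"] = frame["code"].fillna("")
    frame["negated"] = frame["negated"].fillna(0).astype(bool)
    frame["family_history"] = frame["family_history"].fillna(0).astype(bool)
    frame["date"] = frame["date"].astype(np.int64)
    if "value" not in frame:
        frame["value"] = np.nan
    return frame[EVENT_COLUMNS]


def write_patients_csv(patients: pd.DataFrame, path: str | Path) -> None:
    patients[PATIENT_COLUMNS].to_csv(path, index=False)


def read_patients_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str, "gender": str})
    frame["birth_year"] = frame["birth_year"].astype(int)
    return frame[PATIENT_COLUMNS]


def write_treatments_csv(treatments: pd.DataFrame, path: str | Path) -> None:
    treatments[TREATMENT_COLUMNS].to_csv(path, index=False)


def read_treatments_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str, "modality": str})
    for col in ("start_day", "baseline_phq9", "followup_phq9"):
        frame[col] = frame[col].astype(int)
    return frame[TREATMENT_COLUMNS]
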