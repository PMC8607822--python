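"""Shared domain types for ward encounters, events, and cohort records.

Encounters, medication/culture events, and cohort records are plain
dataclasses; the (large) observation table lives in a long-format pandas
DataFrame with columns ``encounter_id, time, variable, value``.  All
timestamps are timezone-naive datetimes on a single monotonic scale and
all windows are closed on both ends unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import pandas as pd

from .vocab import DISPOSITIONS, RACES, SERVICES, SEXES, VASOPRESSORS

HOUR = timedelta(hours=1)


def hours_between(start: datetime, end: datetime) -> float:
    """Signed elapsed hours from ``start`` to ``end``."""
    return (end - start) / HOUR


@dataclass
class Encounter:
    encounter_id: str
    age: float
    sex: str
    race: str
    admit_time: datetime
    discharge_time: datetime
    admitting_service: str
    surgery_times: list[datetime] = field(default_factory=list)
    icu_intervals: list[tuple[datetime, datetime]] = field(default_factory=list)
    death_time: datetime | None = None
    disposition: str = "home"

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not self.admit_time < self.discharge_time:
            errs.append("admit_time must precede discharge_time")
        if self.sex not in SEXES:
            errs.append(f"unknown sex {self.sex!r}")
        if self.race not in RACES:
            errs.append(f"unknown race {self.race!r}")
        if self.admitting_service not in SERVICES:
            errs.append(f"unknown admitting_service {self.admitting_service!r}")
        if self.disposition not in DISPOSITIONS:
            errs.append(f"unknown disposition {self.disposition!r}")
        if self.death_time is not None and not (
            self.admit_time <= self.death_time <= self.discharge_time
        ):
            errs.append("death_time outside the stay")
        ivals = sorted(self.icu_intervals)
        for (s, e) in ivals:
            if not (self.admit_time <= s < e <= self.discharge_time):
                errs.append("ICU interval outside the stay")
        for (_, e), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e:
                errs.append("ICU intervals overlap")
        return errs

    @property
    def los_hours(self) -> float:
        return hours_between(self.admit_time, self.discharge_time)


@dataclass
class MedicationEvent:
    encounter_id: str
    time: datetime
    is_antibiotic: bool = False
    vasopressor: str | None = None
    dose: float | None = None  # ug/kg/min, vasopressors only

    def validate(self) -> list[str]:
        errs = []
        if not self.is_antibiotic and self.vasopressor is None:
            errs.append("medication event is neither antibiotic nor vasopressor")
        if self.vasopressor is not None and self.vasopressor not in VASOPRESSORS:
            errs.append(f"unknown vasopressor {self.vasopressor!r}")
        return errs


@dataclass
class CultureEvent:
    encounter_id: str
    time: datetime
    specimen: str = "blood"


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic encounter."""

    encounter_id: str
    is_sepsis: bool
    true_onset_time: datetime | None = None
    death_within_48h: bool = False
    icu_within_48h: bool = False


# ---------------------------------------------------------------- cohort

# Exclusion reason codes (cohort construction)
AGE_LT_18 = "AGE_LT_18"
LOS_LT_48H = "LOS_LT_48H"
DURATION_LT_12H = "DURATION_LT_12H"
DURATION_GT_14D = "DURATION_GT_14D"
DISCHARGE_LT_12H_AFTER_ONSET = "DISCHARGE_LT_12H_AFTER_ONSET"
RECENT_SURGERY = "RECENT_SURGERY"
NO_VITALS_PRE_INDEX = "NO_VITALS_PRE_INDEX"
NO_LABS_PRE_INDEX = "NO_LABS_PRE_INDEX"
SEPSIS_ON_ADMISSION = "SEPSIS_ON_ADMISSION"
EXCLUDED_SERVICE = "EXCLUDED_SERVICE"
INDEX_OUTSIDE_STAY = "INDEX_OUTSIDE_STAY"

LABEL_SEPSIS = "sepsis"
LABEL_CONTROL = "control"
LABEL_EXCLUDED = "excluded"


@dataclass
class SoiResult:
    """Earliest qualifying suspicion-of-infection event pair."""

    encounter_id: str
    soi_time: datetime | None = None
    culture_time: datetime | None = None
    antibiotic_time: datetime | None = None
    branch: str | None = None  # "culture_first" | "antibiotic_first"

    @property
    def found(self) -> bool:
        return self.soi_time is not None


@dataclass
class CohortRecord:
    encounter_id: str
    label: str = LABEL_CONTROL
    index_time: datetime | None = None
    soi_time: datetime | None = None
    exclusion_reasons: list[str] = field(default_factory=list)


def observations_frame(rows: list[tuple[str, datetime, str, float]]) -> pd.DataFrame:
    """Build a canonical long-format observation table, sorted and typed."""
    df = pd.DataFrame(rows, columns=["encounter_id", "time", "variable", "value"])
    df["time"] = pd.to_datetime(df["time"])
    df["value"] = df["value"].astype(float)
    return df.sort_values(["encounter_id", "time", "variable"], kind="mergesort").reset_index(
        drop=True
    )


EMPTY_OBSERVATIONS = pd.DataFrame(
    {
        "encounter_id": pd.Series(dtype=str),
        "time": pd.Series(dtype="datetime64[ns]"),
        "variable": pd.Series(dtype=str),
        "value": pd.Series(dtype=float),
    }
)
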