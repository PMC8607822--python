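"""Read and write the five CSV interchange tables.

Files are UTF-8 CSVs with a header row; timestamps are ISO-8601 strings at
one-second resolution.  ``read_tables(write_tables(x))`` is the identity,
field for field.

Column schemas
--------------
encounters.csv   encounter_id, age, sex, race, admit_time, discharge_time,
                 admitting_service, surgery_times (';'-joined ISO),
                 icu_intervals (';'-joined "start/end"), death_time, disposition
observations.csv encounter_id, time, variable, value   (long format; one row
                 per observation — wide layouts are rejected, not coerced)
medications.csv  encounter_id, time, is_antibiotic (0/1), vasopressor, dose
cultures.csv     encounter_id, time, specimen
ground_truth.csv encounter_id, is_sepsis, true_onset_time, death_within_48h,
                 icu_within_48h                         (synthetic runs only)
cohort.csv       encounter_id, label, index_time, soi_time,
                 exclusion_reasons (';'-joined codes)   (output of labeling)
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import pandas as pd

from .model import (
    CohortRecord,
    CultureEvent,
    EMPTY_OBSERVATIONS,
    Encounter,
    GroundTruth,
    MedicationEvent,
)
from .vocab import VOCABULARY

TIME_FMT = "%Y-%m-%dT%H:%M:%S"

ENCOUNTER_COLS = [
    "encounter_id", "age", "sex", "race", "admit_time", "discharge_time",
    "admitting_service", "surgery_times", "icu_intervals", "death_time", "disposition",
]
OBSERVATION_COLS = ["encounter_id", "time", "variable", "value"]
MEDICATION_COLS = ["encounter_id", "time", "is_antibiotic", "vasopressor", "dose"]
CULTURE_COLS = ["encounter_id", "time", "specimen"]
GROUND_TRUTH_COLS = [
    "encounter_id", "is_sepsis", "true_onset_time", "death_within_48h", "icu_within_48h",
]
COHORT_COLS = ["encounter_id", "label", "index_time", "soi_time", "exclusion_reasons"]

FILENAMES = {
    "encounters": "encounters.csv",
    "observations": "observations.csv",
    "medications": "medications.csv",
    "cultures": "cultures.csv",
    "ground_truth": "ground_truth.csv",
}


class WardDataError(Exception):
    """Fatal interchange-file problem (missing file, bad header, unknown variable)."""


@dataclass
class WardTables:
    """In-memory bundle of the interchange tables."""

    encounters: dict[str, Encounter] = field(default_factory=dict)
    observations: pd.DataFrame = field(default_factory=lambda: EMPTY_OBSERVATIONS.copy())
    medications: list[MedicationEvent] = field(default_factory=list)
    cultures: list[CultureEvent] = field(default_factory=list)
    ground_truth: dict[str, GroundTruth] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)


def fmt_time(t: datetime | None) -> str:
    return "" if t is None else t.strftime(TIME_FMT)


def parse_time(s: str) -> datetime | None:
    if s is None or s == "" or pd.isna(s):
        return None
    return datetime.strptime(str(s), TIME_FMT)


def _fmt_list(times: list[datetime]) -> str:
    return ";".join(fmt_time(t) for t in times)


def _fmt_intervals(ivals: list[tuple[datetime, datetime]]) -> str:
    return ";".join(f"{fmt_time(s)}/{fmt_time(e)}" for s, e in ivals)


def _require_header(path: Path, header: list[str], expected: list[str]) -> None:
    if header != expected:
        raise WardDataError(
            f"{path.name}: header {header!r} does not match expected {expected!r}"
        )


def _read_rows(path: Path, expected: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise WardDataError(f"missing file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise WardDataError(f"{path.name}: empty file, header required")
        _require_header(path, header, expected)
        return [dict(zip(expected, row)) for row in reader]


def read_tables(directory: str | Path, with_ground_truth: bool = False) -> WardTables:
    """Load the interchange CSVs from ``directory``, enforcing invariants.

    Rows violating per-row invariants (unparseable timestamp, non-finite
    value, observation outside [admit - 24 h, discharge], culture outside
    stay +/- 24 h) are rejected and reported in ``tables.diagnostics``.
    Unknown observation variables and missing files are fatal.
    """
    directory = Path(directory)
    tables = WardTables()
    diag = tables.diagnostics

    for i, row in enumerate(_read_rows(directory / FILENAMES["encounters"], ENCOUNTER_COLS), 2):
        try:
            enc = Encounter(
                encounter_id=row["encounter_id"],
                age=float(row["age"]),
                sex=row["sex"],
                race=row["race"],
                admit_time=parse_time(row["admit_time"]),
                discharge_time=parse_time(row["discharge_time"]),
                admitting_service=row["admitting_service"],
                surgery_times=[parse_time(s) for s in row["surgery_times"].split(";") if s],
                icu_intervals=[
                    tuple(parse_time(p) for p in pair.split("/"))
                    for pair in row["icu_intervals"].split(";")
                    if pair
                ],
                death_time=parse_time(row["death_time"]),
                disposition=row["disposition"],
            )
        except (ValueError, KeyError) as exc:
            diag.append(f"encounters.csv row {i}: unparseable ({exc})")
            continue
        errs = enc.validate()
        if errs:
            diag.append(f"encounters.csv row {i} ({enc.encounter_id}): " + "; ".join(errs))
            continue
        tables.encounters[enc.encounter_id] = enc

    obs_rows = _read_rows(directory / FILENAMES["observations"], OBSERVATION_COLS)
    unknown = sorted({r["variable"] for r in obs_rows} - set(VOCABULARY))
    if unknown:
        raise WardDataError(f"observations.csv: unknown variable(s) {unknown}")
    kept: list[tuple] = []
    slack = timedelta(hours=24)
    for i, row in enumerate(obs_rows, 2):
        try:
            t = parse_time(row["time"])
            v = float(row["value"])
        except ValueError as exc:
            diag.append(f"observations.csv row {i}: unparseable ({exc})")
            continue
        enc = tables.encounters.get(row["encounter_id"])
        if enc is None:
            diag.append(f"observations.csv row {i}: unknown encounter {row['encounter_id']!r}")
            continue
        if t is None or not (enc.admit_time - slack <= t <= enc.discharge_time):
            diag.append(
                f"observations.csv row {i}: time outside [admit-24h, discharge] "
                f"for {enc.encounter_id}"
            )
            continue
        if not pd.notna(v) or v != v or v in (float("inf"), float("-inf")):
            diag.append(f"observations.csv row {i}: non-finite value")
            continue
        kept.append((row["encounter_id"], t, row["variable"], v))
    if kept:
        tables.observations = pd.DataFrame(kept, columns=OBSERVATION_COLS)
        tables.observations["time"] = pd.to_datetime(tables.observations["time"])

    for i, row in enumerate(_read_rows(directory / FILENAMES["medications"], MEDICATION_COLS), 2):
        try:
            ev = MedicationEvent(
                encounter_id=row["encounter_id"],
                time=parse_time(row["time"]),
                is_antibiotic=row["is_antibiotic"] == "1",
                vasopressor=row["vasopressor"] or None,
                dose=float(row["dose"]) if row["dose"] else None,
            )
        except ValueError as exc:
            diag.append(f"medications.csv row {i}: unparseable ({exc})")
            continue
        errs = ev.validate()
        if errs or ev.time is None:
            diag.append(f"medications.csv row {i}: " + "; ".join(errs or ["missing time"]))
            continue
        tables.medications.append(ev)

    for i, row in enumerate(_read_rows(directory / FILENAMES["cultures"], CULTURE_COLS), 2):
        try:
            t = parse_time(row["time"])
        except ValueError as exc:
            diag.append(f"cultures.csv row {i}: unparseable ({exc})")
            continue
        enc = tables.encounters.get(row["encounter_id"])
        if enc is None or t is None or not (
            enc.admit_time - slack <= t <= enc.discharge_time + slack
        ):
            diag.append(f"cultures.csv row {i}: time outside stay +/- 24 h")
            continue
        tables.cultures.append(CultureEvent(row["encounter_id"], t, row["specimen"]))

    gt_path = directory / FILENAMES["ground_truth"]
    if with_ground_truth and gt_path.exists():
        for row in _read_rows(gt_path, GROUND_TRUTH_COLS):
            tables.ground_truth[row["encounter_id"]] = GroundTruth(
                encounter_id=row["encounter_id"],
                is_sepsis=row["is_sepsis"] == "1",
                true_onset_time=parse_time(row["true_onset_time"]),
                death_within_48h=row["death_within_48h"] == "1",
                icu_within_48h=row["icu_within_48h"] == "1",
            )
    return tables


def write_tables(tables: WardTables, directory: str | Path) -> dict[str, Path]:
    """Write the interchange CSVs into ``directory``; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _open(name: str):
        p = directory / FILENAMES[name]
        paths[name] = p
        return open(p, "w", newline="", encoding="utf-8")

    with _open("encounters") as fh:
        w = csv.writer(fh)
        w.writerow(ENCOUNTER_COLS)
        for enc in tables.encounters.values():
            w.writerow([
                enc.encounter_id, repr(float(enc.age)), enc.sex, enc.race,
                fmt_time(enc.admit_time), fmt_time(enc.discharge_time),
                enc.admitting_service, _fmt_list(enc.surgery_times),
                _fmt_intervals(enc.icu_intervals), fmt_time(enc.death_time),
                enc.disposition,
            ])

    with _open("observations") as fh:
        w = csv.writer(fh)
        w.writerow(OBSERVATION_COLS)
        for row in tables.observations.itertuples(index=False):
            w.writerow([
                row.encounter_id, fmt_time(row.time.to_pydatetime()),
                row.variable, repr(float(row.value)),
            ])

    with _open("medications") as fh:
        w = csv.writer(fh)
        w.writerow(MEDICATION_COLS)
        for ev in tables.medications:
            w.writerow([
                ev.encounter_id, fmt_time(ev.time), "1" if ev.is_antibiotic else "0",
                ev.vasopressor or "", "" if ev.dose is None else repr(float(ev.dose)),
            ])

    with _open("cultures") as fh:
        w = csv.writer(fh)
        w.writerow(CULTURE_COLS)
        for ev in tables.cultures:
            w.writerow([ev.encounter_id, fmt_time(ev.time), ev.specimen])

    if tables.ground_truth:
        with _open("ground_truth") as fh:
            w = csv.writer(fh)
            w.writerow(GROUND_TRUTH_COLS)
            for gt in tables.ground_truth.values():
                w.writerow([
                    gt.encounter_id, "1" if gt.is_sepsis else "0",
                    fmt_time(gt.true_onset_time),
                    "1" if gt.death_within_48h else "0",
                    "1" if gt.icu_within_48h else "0",
                ])
    return paths


def write_cohort(records: list[CohortRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COHORT_COLS)
        for r in records:
            w.writerow([
                r.encounter_id, r.label, fmt_time(r.index_time), fmt_time(r.soi_time),
                ";".join(r.exclusion_reasons),
            ])
    return path


def read_cohort(path: str | Path) -> list[CohortRecord]:
    records = []
    for row in _read_rows(Path(path), COHORT_COLS):
        records.append(
            CohortRecord(
                encounter_id=row["encounter_id"],
                label=row["label"],
                index_time=parse_time(row["index_time"]),
                soi_time=parse_time(row["soi_time"]),
                exclusion_reasons=[c for c in row["exclusion_reasons"].split(";") if c],
            )
        )
    return records
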