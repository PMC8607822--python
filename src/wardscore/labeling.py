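"""Sepsis-3 cohort construction: suspicion of infection, sepsis labeling,
onset assignment, and inclusion/exclusion filtering.

Suspicion of infection (SOI) is a culture collection followed by
antibiotics within 72 h, or antibiotics followed by culture procurement
within 24 h; both windows are closed on both ends.  Sepsis is SOI
accompanied by a qSOFA score >= 2 evaluated at the SOI time with a
worst-value 24-h lookback, and time of onset is the SOI time (the earlier
event of the earliest qualifying pair).  Only the first sepsis event per
encounter is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import pandas as pd

from . import model
from .model import (
    CohortRecord,
    CultureEvent,
    Encounter,
    MedicationEvent,
    SoiResult,
    hours_between,
)
from .scores import PatientHistory, ScoreDefinition, load_definition, score_at
from .vocab import EXCLUDED_SERVICES

CULTURE_TO_ABX_HOURS = 72.0
ABX_TO_CULTURE_HOURS = 24.0


@dataclass
class ExclusionConfig:
    """Inclusion/exclusion rule parameters (defaults mirror the study design)."""

    min_age: float = 18.0
    min_los_hours: float = 48.0
    min_duration_hours: float = 12.0
    max_duration_hours: float = 14 * 24.0
    min_discharge_after_onset_hours: float = 12.0
    surgery_lookback_hours: float = 72.0
    pre_index_window_hours: float = 24.0
    required_vitals: tuple[str, ...] = ("heart_rate", "resp_rate", "sbp", "temperature")
    required_labs: tuple[str, ...] = ("creatinine", "wbc")
    admission_sepsis_window_hours: float = 12.0
    qsofa_lookback_hours: float = 24.0
    qsofa_mode: str = "worst"


def detect_soi(
    culture_events: list[CultureEvent],
    medication_events: list[MedicationEvent],
) -> SoiResult:
    """Earliest qualifying culture/antibiotic pair for one encounter.

    Scans all culture x antibiotic pairs; the SOI time is the earlier event
    of the earliest qualifying pair.  Ties between simultaneous qualifying
    pairs are broken by (culture_time, antibiotic_time) lexicographic order.
    """
    eid = ""
    if culture_events:
        eid = culture_events[0].encounter_id
    elif medication_events:
        eid = medication_events[0].encounter_id
    abx_times = sorted(ev.time for ev in medication_events if ev.is_antibiotic)
    best: tuple | None = None  # (soi_time, culture_time, abx_time, branch)
    for cult in culture_events:
        for abx in abx_times:
            delta_h = hours_between(cult.time, abx)
            if 0.0 <= delta_h <= CULTURE_TO_ABX_HOURS:
                cand = (cult.time, cult.time, abx, "culture_first")
            elif -ABX_TO_CULTURE_HOURS <= delta_h < 0.0:
                cand = (abx, cult.time, abx, "antibiotic_first")
            else:
                continue
            if best is None or (cand[0], cand[1], cand[2]) < (best[0], best[1], best[2]):
                best = cand
    if best is None:
        return SoiResult(encounter_id=eid)
    return SoiResult(
        encounter_id=eid,
        soi_time=best[0],
        culture_time=best[1],
        antibiotic_time=best[2],
        branch=best[3],
    )


def qsofa_at_soi(
    history: PatientHistory,
    soi_time: datetime,
    config: ExclusionConfig | None = None,
    definition: ScoreDefinition | None = None,
) -> int:
    config = config or ExclusionConfig()
    definition = definition or load_definition("qSOFA")
    return score_at(
        history, soi_time, definition, config.qsofa_lookback_hours, config.qsofa_mode
    ).total


def label_sepsis(
    encounter: Encounter,
    soi_result: SoiResult,
    qsofa_at_soi_value: int | None,
) -> CohortRecord:
    """Sepsis iff SOI found and qSOFA at SOI >= 2; index time = SOI time."""
    rec = CohortRecord(encounter_id=encounter.encounter_id)
    if not soi_result.found:
        return rec
    if not (encounter.admit_time <= soi_result.soi_time <= encounter.discharge_time):
        rec.label = model.LABEL_EXCLUDED
        rec.soi_time = soi_result.soi_time
        rec.exclusion_reasons.append(model.INDEX_OUTSIDE_STAY)
        return rec
    rec.soi_time = soi_result.soi_time
    if qsofa_at_soi_value is not None and qsofa_at_soi_value >= 2:
        rec.label = model.LABEL_SEPSIS
        rec.index_time = soi_result.soi_time
    return rec


def _has_all_in_window(
    history: PatientHistory, variables: tuple[str, ...], lo_h: float, hi_h: float
) -> bool:
    return all(history.recent(v, lo_h, hi_h) is not None for v in variables)


def apply_exclusions(
    encounter: Encounter,
    record: CohortRecord,
    history: PatientHistory | None = None,
    config: ExclusionConfig | None = None,
) -> CohortRecord:
    """Append every applicable exclusion reason code; idempotent.

    Pre-index rules (age, service, duration, LOS) always apply.  Index-time
    rules (recent surgery, pre-index vitals/labs, early discharge after
    onset, sepsis on admission) apply when an index time is assigned and a
    history is supplied.
    """
    config = config or ExclusionConfig()
    reasons: list[str] = []
    if encounter.age < config.min_age:
        reasons.append(model.AGE_LT_18)
    if encounter.admitting_service in EXCLUDED_SERVICES:
        reasons.append(model.EXCLUDED_SERVICE)
    los = encounter.los_hours
    if los < config.min_duration_hours:
        reasons.append(model.DURATION_LT_12H)
    if los > config.max_duration_hours:
        reasons.append(model.DURATION_GT_14D)
    if los < config.min_los_hours:
        reasons.append(model.LOS_LT_48H)
    idx = record.index_time
    if idx is not None:
        if record.label == model.LABEL_SEPSIS and (
            hours_between(idx, encounter.discharge_time)
            < config.min_discharge_after_onset_hours
        ):
            reasons.append(model.DISCHARGE_LT_12H_AFTER_ONSET)
        if any(
            0.0 <= hours_between(s, idx) <= config.surgery_lookback_hours
            for s in encounter.surgery_times
        ):
            reasons.append(model.RECENT_SURGERY)
        if record.label == model.LABEL_SEPSIS and (
            hours_between(encounter.admit_time, idx)
            <= config.admission_sepsis_window_hours
        ):
            reasons.append(model.SEPSIS_ON_ADMISSION)
        if history is not None:
            hi = history.to_hours(idx)
            lo = hi - config.pre_index_window_hours
            if not _has_all_in_window(history, config.required_vitals, lo, hi):
                reasons.append(model.NO_VITALS_PRE_INDEX)
            if not _has_all_in_window(history, config.required_labs, lo, hi):
                reasons.append(model.NO_LABS_PRE_INDEX)
    out = CohortRecord(
        encounter_id=record.encounter_id,
        label=record.label,
        index_time=record.index_time,
        soi_time=record.soi_time,
        exclusion_reasons=sorted(set(reasons)),
    )
    if out.exclusion_reasons:
        out.label = model.LABEL_EXCLUDED
    return out


@dataclass
class LabelingResult:
    records: dict[str, CohortRecord]
    eligible_controls: list[str] = field(default_factory=list)


def build_labels(
    encounters: dict[str, Encounter],
    observations: pd.DataFrame,
    medications: list[MedicationEvent],
    cultures: list[CultureEvent],
    config: ExclusionConfig | None = None,
    histories: dict[str, PatientHistory] | None = None,
) -> LabelingResult:
    """Run SOI detection + sepsis labeling + exclusions over a whole cohort.

    Controls get no index time here; ``eligible_controls`` lists control
    encounters that pass the pre-index-independent exclusions and are
    candidates for matched index assignment.
    """
    config = config or ExclusionConfig()
    qsofa = load_definition("qSOFA")
    med_by_enc: dict[str, list[MedicationEvent]] = {}
    for ev in medications:
        med_by_enc.setdefault(ev.encounter_id, []).append(ev)
    cult_by_enc: dict[str, list[CultureEvent]] = {}
    for ev in cultures:
        cult_by_enc.setdefault(ev.encounter_id, []).append(ev)
    if histories is None:
        histories = build_histories(encounters, observations, medications)

    records: dict[str, CohortRecord] = {}
    eligible: list[str] = []
    for eid, enc in encounters.items():
        soi = detect_soi(
            sorted(cult_by_enc.get(eid, []), key=lambda e: e.time),
            sorted(med_by_enc.get(eid, []), key=lambda e: e.time),
        )
        q = None
        if soi.found:
            q = qsofa_at_soi(histories[eid], soi.soi_time, config, qsofa)
        rec = label_sepsis(enc, soi, q)
        rec = apply_exclusions(enc, rec, histories[eid], config)
        records[eid] = rec
        if rec.label == model.LABEL_CONTROL:
            eligible.append(eid)
    return LabelingResult(records=records, eligible_controls=eligible)


def build_histories(
    encounters: dict[str, Encounter],
    observations: pd.DataFrame,
    medications: list[MedicationEvent],
) -> dict[str, PatientHistory]:
    med_by_enc: dict[str, list[MedicationEvent]] = {}
    for ev in medications:
        med_by_enc.setdefault(ev.encounter_id, []).append(ev)
    groups: dict[str, pd.DataFrame] = {}
    if len(observations):
        groups = {str(k): g for k, g in observations.groupby("encounter_id", sort=False)}
    empty = observations.iloc[0:0]
    return {
        eid: PatientHistory.build(enc, groups.get(eid, empty), med_by_enc.get(eid))
        for eid, enc in encounters.items()
    }
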