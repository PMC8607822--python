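"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest

from wardscore.labeling import ExclusionConfig
from wardscore.matching import MatchingConfig
from wardscore.model import Encounter, observations_frame
from wardscore.pipeline import cohort_frame, label_and_match
from wardscore.scores import PatientHistory
from wardscore.synthetic import SyntheticConfig, generate_cohort

ADMIT = datetime(2021, 3, 1)


def make_encounter(
    eid: str = "e1",
    age: float = 50.0,
    los_hours: float = 120.0,
    admit: datetime = ADMIT,
    **kw,
) -> Encounter:
    return Encounter(
        encounter_id=eid,
        age=age,
        sex=kw.pop("sex", "female"),
        race=kw.pop("race", "white"),
        admit_time=admit,
        discharge_time=admit + timedelta(hours=los_hours),
        admitting_service=kw.pop("admitting_service", "medicine"),
        **kw,
    )


def make_history(rows, encounter: Encounter | None = None, medications=None):
    """``rows``: (hours_after_admit, variable, value) triples."""
    enc = encounter or make_encounter()
    obs = observations_frame(
        [
            (enc.encounter_id, enc.admit_time + timedelta(hours=h), var, val)
            for h, var, val in rows
        ]
    )
    return PatientHistory.build(enc, obs, medications)


# ---------------------------------------------------------------- oracles

def brute_force_auroc(labels, scores) -> float:
    """Exhaustive pairwise concordance with ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_auprc(labels, scores) -> float:
    """Step-integrated average precision over descending distinct thresholds."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_force_soi(cultures_h, antibiotics_h):
    """All-pairs suspicion-of-infection oracle over event hours.

    Returns (soi_hour, culture_hour, antibiotic_hour) or None, applying
    the closed 72 h culture->antibiotic and 24 h antibiotic->culture
    windows with (culture, antibiotic) lexicographic tie-break.
    """
    best = None
    for c in cultures_h:
        for a in antibiotics_h:
            if 0 <= a - c <= 72:
                cand = (c, c, a)
            elif 0 < c - a <= 24:
                cand = (a, c, a)
            else:
                continue
            if best is None or cand < best:
                best = cand
    return best


# --------------------------------------------------------------- cohorts

@pytest.fixture(scope="session")
def small_cohort():
    """A labeled, matched synthetic cohort shared across evaluation tests."""
    tables = generate_cohort(
        SyntheticConfig(n_encounters=1200, seed=202, derangement_effect=3.0)
    )
    cohort, histories = label_and_match(
        tables, ExclusionConfig(), MatchingConfig(ratio=30, seed=17)
    )
    return tables, cohort_frame(cohort), histories
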