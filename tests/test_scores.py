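"""Score engine: hand-computed vignettes for all seven scores, snapshot
resolution policies, and the worst/recent dominance properties."""

from datetime import timedelta

import numpy as np
import pytest

from wardscore.model import MedicationEvent
from wardscore.scores import (
    PatientHistory,
    SCORE_NAMES,
    compute_score,
    compute_series,
    load_definition,
    load_definitions,
    resolve_snapshot,
    score_at,
)
from wardscore.vocab import VOCABULARY

from conftest import ADMIT, make_encounter, make_history

T_EVAL_H = 50.0
DEL = object()  # sentinel: remove a variable from the all-normal panel

ALL_NORMAL = {
    "heart_rate": 80.0, "resp_rate": 14.0, "sbp": 120.0, "map": 85.0,
    "temperature": 37.0, "spo2": 98.0, "supplemental_o2": 0.0, "gcs": 15.0,
    "avpu": 0.0, "wbc": 8.0, "band_pct": 3.0, "platelets": 250.0,
    "bilirubin": 0.8, "creatinine": 1.0, "sodium": 140.0, "potassium": 4.2,
    "hematocrit": 40.0, "arterial_ph": 7.40, "paco2": 40.0, "pao2": 95.0,
    "fio2": 0.21, "respiratory_support": 0.0,
}


def _history(overrides=None, age=30.0, medications=None):
    panel = dict(ALL_NORMAL)
    for k, v in (overrides or {}).items():
        if v is DEL:
            panel.pop(k, None)
        else:
            panel[k] = v
    enc = make_encounter(age=age, los_hours=120.0)
    rows = [(T_EVAL_H, var, val) for var, val in panel.items()]
    return make_history(rows, enc, medications)


def _total(score, overrides=None, age=30.0, medications=None, mode="worst"):
    h = _history(overrides, age, medications)
    return score_at(h, ADMIT + timedelta(hours=T_EVAL_H), load_definition(score),
                    24.0, mode).total


def _norepi(dose):
    return [MedicationEvent("e1", ADMIT + timedelta(hours=T_EVAL_H),
                            vasopressor="norepinephrine", dose=dose)]


def _dopamine(dose):
    return [MedicationEvent("e1", ADMIT + timedelta(hours=T_EVAL_H),
                            vasopressor="dopamine", dose=dose)]


# Each row: (score, overrides, age, medications, expected total, worked arithmetic)
VIGNETTES = [
    # --- SIRS (1 point per criterion, strict inequalities) ---
    ("SIRS", {"temperature": 38.0, "heart_rate": 90, "resp_rate": 20, "wbc": 12.0},
     30, None, 0, "all four values sit ON the strict thresholds: 0+0+0+0"),
    ("SIRS", {"temperature": 38.1, "heart_rate": 91, "resp_rate": 21, "wbc": 12.1},
     30, None, 4, "temp>38:1, HR>90:1, RR>20:1, WBC>12:1"),
    ("SIRS", {"temperature": 35.9}, 30, None, 1, "temp<36:1, rest normal"),
    ("SIRS", {"paco2": 31.9}, 30, None, 1, "PaCO2<32 satisfies the respiratory criterion"),
    ("SIRS", {"wbc": 5.0, "band_pct": 10.1}, 30, None, 1, "bands>10%:1 (WBC normal)"),
    ("SIRS", {"heart_rate": 90.5}, 30, None, 1, "HR>90:1"),
    # --- qSOFA ---
    ("qSOFA", {"resp_rate": 22, "sbp": 100}, 30, None, 2,
     "RR>=22:1 + SBP<=100:1 (both boundaries inclusive)"),
    ("qSOFA", {"resp_rate": 21.9, "sbp": 100.1}, 30, None, 0, "both just miss"),
    ("qSOFA", {"gcs": 14, "avpu": DEL}, 30, None, 1, "GCS<15 = altered mentation"),
    ("qSOFA", {"avpu": 2, "resp_rate": 22}, 30, None, 2, "V on ACVPU:1 + RR:1"),
    ("qSOFA", {"avpu": 0, "gcs": 12}, 30, None, 0,
     "alert AVPU preferred over discordant GCS"),
    # --- MEWS (Subbe 2001) ---
    ("MEWS", {"sbp": 70, "heart_rate": 130, "resp_rate": 30, "temperature": 34.9, "avpu": 4},
     30, None, 14, "3+3+3+2+3 = maximum"),
    ("MEWS", {"sbp": 85, "heart_rate": 45, "resp_rate": 21, "temperature": 38.5, "avpu": 1},
     30, None, 7, "SBP 81-100:1 + HR 41-50:1 + RR 21-29:2 + temp>=38.5:2 + confusion:1"),
    ("MEWS", {"sbp": 100, "heart_rate": 101, "resp_rate": 9, "temperature": 38.4},
     30, None, 2, "SBP<=100:1 + HR 101-110:1 + RR 9-14:0 + temp<=38.4:0"),
    ("MEWS", {"gcs": 8, "avpu": DEL}, 30, None, 3, "GCS<=8 maps to unresponsive:3"),
    ("MEWS", {"sbp": 200}, 30, None, 2, "SBP>=200:2"),
    ("MEWS", {"heart_rate": 111}, 30, None, 2, "HR 111-129:2"),
    # --- NEWS (RCP 2012) ---
    ("NEWS", {"resp_rate": 25, "spo2": 93, "supplemental_o2": 1}, 30, None, 7,
     "RR>=25:3 + SpO2 92-93:2 + on O2:2"),
    ("NEWS", {"heart_rate": 40, "temperature": 35.0, "sbp": 90, "resp_rate": 8,
              "spo2": 91, "avpu": 2}, 30, None, 18, "3+3+3+3+3+3"),
    ("NEWS", {"resp_rate": 21, "spo2": 94, "temperature": 38.1, "sbp": 110,
              "heart_rate": 91}, 30, None, 6, "2+1+1+1+1 (low bands)"),
    ("NEWS", {"gcs": 14, "avpu": DEL}, 30, None, 3, "GCS<15 = not alert:3"),
    ("NEWS", {"supplemental_o2": 1}, 30, None, 2, "supplemental oxygen alone:2"),
    ("NEWS", {"sbp": 220}, 30, None, 3, "SBP>=220:3"),
    # --- NEWS2 (RCP 2017; Scale 1 default) ---
    ("NEWS2", {"resp_rate": 25, "spo2": 93, "supplemental_o2": 1}, 30, None, 7,
     "identical to NEWS on Scale 1"),
    ("NEWS2", {"avpu": 1}, 30, None, 3, "new confusion scores 3"),
    ("NEWS2", {"spo2": 88, "hypercapnic_failure": 1}, 30, None, 3,
     "Scale 2 disabled by default: SpO2 88 scores 3 on Scale 1"),
    ("NEWS2", {"temperature": 39.1}, 30, None, 2, "temp>=39.1:2"),
    ("NEWS2", {"heart_rate": 131}, 30, None, 3, "HR>=131:3"),
    # --- SOFA (Vincent 1996) ---
    ("SOFA", {"platelets": 90, "bilirubin": 2.5, "gcs": 12, "creatinine": 3.6,
              "map": 65}, 30, None, 10, "coag 2 + liver 2 + CNS 2 + renal 3 + CV 1"),
    ("SOFA", {}, 30, _norepi(0.2), 4, "norepinephrine >0.1 ug/kg/min: CV 4"),
    ("SOFA", {}, 30, _dopamine(6.0), 3, "dopamine 5-15: CV 3"),
    ("SOFA", {"pao2": 60, "fio2": 0.8}, 30, None, 2,
     "P/F 75 would be 4 but no respiratory support: capped at 2"),
    ("SOFA", {"pao2": 60, "fio2": 0.8, "respiratory_support": 1}, 30, None, 4,
     "P/F 75 with support: 4"),
    ("SOFA", {"platelets": 19, "bilirubin": 12.0, "creatinine": 5.0, "gcs": 5},
     30, None, 16, "4+4+4+4"),
    ("SOFA", {"platelets": 149.9}, 30, None, 1, "platelets <150: coagulation 1"),
    # --- APACHE II (Knaus 1985) ---
    ("APACHE_II", {}, 30, None, 0, "all physiology normal, age<=44: 0"),
    ("APACHE_II", {}, 70, None, 5, "age 65-74: 5 points only"),
    ("APACHE_II", {"temperature": 39.0, "heart_rate": 140, "resp_rate": 35, "map": 130},
     45, None, 14, "temp 3 + HR 3 + RR 3 + MAP 3 + age 45-54: 2"),
    ("APACHE_II", {"gcs": 3}, 30, None, 12, "GCS deficit 15-3"),
    ("APACHE_II", {"arterial_ph": 7.2, "sodium": 155, "potassium": 6.5,
                   "creatinine": 3.6, "hematocrit": 19, "wbc": 45}, 30, None, 20,
     "pH 3 + Na 2 + K 3 + creat 4 + Hct 4 + WBC 4"),
    ("APACHE_II", {"fio2": 0.6, "pao2": 100, "paco2": 40}, 30, None, 2,
     "FiO2>=0.5: A-a = 0.6*713 - 40/0.8 - 100 = 277.8 -> 2"),
    ("APACHE_II", {"fio2": 0.4, "pao2": 65}, 30, None, 1, "FiO2<0.5: PaO2 61-70 -> 1"),
]


@pytest.mark.parametrize(
    "score,overrides,age,meds,expected,why",
    VIGNETTES,
    ids=[f"{v[0]}-{i}" for i, v in enumerate(VIGNETTES)],
)
def test_vignette(score, overrides, age, meds, expected, why):
    assert _total(score, overrides, age, meds) == expected, why


@pytest.mark.parametrize("score", SCORE_NAMES)
def test_all_normal_scores_zero(score):
    """Normal-panel totals are 0 (APACHE II: 0 at age 30, age points otherwise)."""
    assert _total(score, {}, age=30.0) == 0


def test_apache_age_points_only():
    for age, pts in ((30, 0), (45, 2), (55, 3), (65, 5), (75, 6)):
        assert _total("APACHE_II", {}, age=age) == pts


def test_news2_spo2_scale2_when_enabled():
    d = load_definition("NEWS2", spo2_scale2=True)
    h = _history({"spo2": 88, "hypercapnic_failure": 1})
    t = ADMIT + timedelta(hours=T_EVAL_H)
    snap = resolve_snapshot(h, t, 24.0, "worst", d)
    assert compute_score(snap, d).total == 0  # 88-92 is target range on Scale 2
    h2 = _history({"spo2": 97, "supplemental_o2": 1, "hypercapnic_failure": 1})
    snap2 = resolve_snapshot(h2, t, 24.0, "worst", d)
    # SpO2 97 on oxygen scores 3 on Scale 2, plus 2 for supplemental oxygen
    assert compute_score(snap2, d).total == 5


def test_guard_range_violation_treated_absent():
    h = _history({"spo2": 101.0})
    assert h.errors and "spo2" in h.errors[0]
    assert len(h.series["spo2"][0]) == 0  # no usable observation survives
    assert _total("NEWS", {"spo2": 101.0}) == 0


def test_missing_variable_assumed_normal():
    h = make_history([(T_EVAL_H, "heart_rate", 80.0)])
    t = ADMIT + timedelta(hours=T_EVAL_H)
    d = load_definition("NEWS")
    snap = resolve_snapshot(h, t, 24.0, "worst", d)
    assert snap.value("temperature") is None
    assert compute_score(snap, d).components["temperature"] == 0


def test_worst_picks_most_abnormal_recent_picks_latest():
    t = ADMIT + timedelta(hours=T_EVAL_H)
    h = make_history([(T_EVAL_H - 20, "heart_rate", 130.0),
                      (T_EVAL_H - 2, "heart_rate", 88.0)])
    d = load_definition("NEWS")
    assert resolve_snapshot(h, t, 24.0, "worst", d).value("heart_rate") == 130.0
    assert resolve_snapshot(h, t, 24.0, "recent", d).value("heart_rate") == 88.0
    # 12-h lookback excludes the deranged value
    assert resolve_snapshot(h, t, 12.0, "worst", d).value("heart_rate") == 88.0


def test_worst_tie_broken_by_most_recent():
    t = ADMIT + timedelta(hours=T_EVAL_H)
    h = make_history([(T_EVAL_H - 10, "heart_rate", 120.0),
                      (T_EVAL_H - 2, "heart_rate", 115.0)])  # both 2 NEWS points
    snap = resolve_snapshot(h, t, 24.0, "worst", load_definition("NEWS"))
    assert snap.resolved["heart_rate"] == (115.0, T_EVAL_H - 2)


class TestSeries:
    def test_empty_observations_all_normal_totals(self):
        h = make_history([])
        series = compute_series(h, ADMIT + timedelta(hours=60), load_definition("NEWS"))
        assert len(series) == 25
        assert all(sv.total == 0 for sv in series)
        assert [sv.offset_hours for sv in series] == list(range(-12, 13))

    def test_offsets_beyond_discharge_emit_no_value(self):
        enc = make_encounter(los_hours=65.0)
        h = make_history([], enc)
        series = compute_series(h, ADMIT + timedelta(hours=60), load_definition("NEWS"))
        assert [sv.offset_hours for sv in series] == list(range(-12, 6))

    def test_single_deranged_vital_window_membership(self):
        # deranged HR one hour before index; 24-h lookback reaches it from
        # offsets -1..+12 but not -12..-2
        idx_h = 60.0
        enc = make_encounter(los_hours=120.0)
        h = make_history([(idx_h - 1, "heart_rate", 135.0)], enc)
        series = compute_series(h, ADMIT + timedelta(hours=idx_h), load_definition("NEWS"))
        by_off = {sv.offset_hours: sv.total for sv in series}
        for off in range(-12, -1):
            assert by_off[off] == 0
        for off in range(-1, 13):
            assert by_off[off] == 3


def _random_history(rng, variables, enc):
    series = {}
    for var in variables:
        n = int(rng.integers(1, 5))
        t = np.sort(rng.uniform(10.0, T_EVAL_H, size=n))
        spec = VOCABULARY[var]
        if var in ("avpu", "gcs", "supplemental_o2", "respiratory_support",
                   "hypercapnic_failure"):
            v = rng.integers(spec.lo, spec.hi + 1, size=n).astype(float)
        else:
            v = rng.uniform(spec.lo, spec.hi, size=n)
        series[var] = (t, v)
    return PatientHistory(encounter=enc, series=series, vasopressors=[])


def test_worst_dominates_recent_everywhere():
    """10 000 seeded random snapshots: total(worst) >= total(recent) for
    every score, and NEWS == NEWS 2 absent hypercapnic failure and new
    confusion."""
    rng = np.random.default_rng(2024)
    defs = load_definitions()
    enc = make_encounter(los_hours=120.0)
    t = ADMIT + timedelta(hours=T_EVAL_H)
    pool = [v for v in VOCABULARY if v not in ("urine_output_24h",)]
    for _ in range(10_000):
        k = int(rng.integers(1, 7))
        variables = list(rng.choice(pool, size=k, replace=False))
        h = _random_history(rng, variables, enc)
        # NEWS/NEWS2 comparison premise: no new-confusion coding, no flag
        if "avpu" in h.series:
            tv, vv = h.series["avpu"]
            h.series["avpu"] = (tv, np.where(vv == 1.0, 2.0, vv))
        h.series.pop("hypercapnic_failure", None)
        totals = {}
        for name, d in defs.items():
            worst = compute_score(resolve_snapshot(h, t, 24.0, "worst", d), d).total
            recent = compute_score(resolve_snapshot(h, t, 24.0, "recent", d), d).total
            assert worst >= recent, (name, h.series)
            totals[name] = worst
        assert totals["NEWS"] == totals["NEWS2"]


def test_adding_observation_never_decreases_worst_total():
    """Monotonicity under information for band-resolved variables."""
    rng = np.random.default_rng(99)
    defs = load_definitions()
    enc = make_encounter(los_hours=120.0)
    t = ADMIT + timedelta(hours=T_EVAL_H)
    banded = ["heart_rate", "resp_rate", "sbp", "map", "temperature", "spo2",
              "gcs", "wbc", "platelets", "bilirubin", "creatinine"]
    for _ in range(1000):
        variables = list(rng.choice(banded, size=3, replace=False))
        h = _random_history(rng, variables, enc)
        base = {n: compute_score(resolve_snapshot(h, t, 24.0, "worst", d), d).total
                for n, d in defs.items()}
        var = str(rng.choice(banded))
        spec = VOCABULARY[var]
        new_t = float(rng.uniform(T_EVAL_H - 24.0, T_EVAL_H))
        new_v = float(rng.uniform(spec.lo, spec.hi))
        tv, vv = h.series.get(var, (np.empty(0), np.empty(0)))
        order = np.argsort(np.append(tv, new_t), kind="stable")
        h2 = PatientHistory(
            encounter=enc,
            series={**h.series, var: (np.append(tv, new_t)[order], np.append(vv, new_v)[order])},
            vasopressors=[],
        )
        for n, d in defs.items():
            assert compute_score(resolve_snapshot(h2, t, 24.0, "worst", d), d).total >= base[n]


def test_band_tables_bounded_by_published_maxima():
    rng = np.random.default_rng(7)
    defs = load_definitions()
    enc = make_encounter(age=90.0, los_hours=120.0)
    t = ADMIT + timedelta(hours=T_EVAL_H)
    for _ in range(300):
        h = _random_history(rng, list(VOCABULARY), enc)
        for n, d in defs.items():
            total = compute_score(resolve_snapshot(h, t, 24.0, "worst", d), d).total
            assert 0 <= total <= d.max_total
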