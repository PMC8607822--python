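"""Canonical variable vocabulary shared by every module.

Each physiologic or laboratory variable has one canonical name, one fixed
unit, and a physiologic guard range.  Values outside the guard range are
never silently used by a score: they are reported and treated as absent.
Units are fixed per variable; no unit column exists in the interchange
files and no unit conversion is performed (silent Fahrenheit/Celsius
coercion is a known early-warning-score failure mode).

Consciousness on the ACVPU scale is stored as a numeric code because the
observation value column is numeric: A=0 (alert), C=1 (new confusion),
V=2 (responds to voice), P=3 (responds to pain), U=4 (unresponsive).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Variable:
    name: str
    unit: str
    lo: float  # physiologic guard range (inclusive)
    hi: float


_VARS = [
    Variable("heart_rate", "bpm", 10, 300),
    Variable("resp_rate", "breaths/min", 0, 90),
    Variable("sbp", "mmHg", 30, 300),
    Variable("map", "mmHg", 20, 250),
    Variable("temperature", "degC", 25, 45),
    Variable("spo2", "%", 50, 100),
    Variable("supplemental_o2", "0/1", 0, 1),
    Variable("avpu", "ACVPU code 0-4", 0, 4),
    Variable("gcs", "points 3-15", 3, 15),
    Variable("wbc", "10^3/uL", 0, 200),
    Variable("band_pct", "%", 0, 100),
    Variable("platelets", "10^3/uL", 0, 2000),
    Variable("bilirubin", "mg/dL", 0, 60),
    Variable("creatinine", "mg/dL", 0, 30),
    Variable("sodium", "mmol/L", 90, 200),
    Variable("potassium", "mmol/L", 1, 12),
    Variable("hematocrit", "%", 5, 75),
    Variable("arterial_ph", "pH", 6.5, 8.0),
    Variable("paco2", "mmHg", 5, 150),
    Variable("pao2", "mmHg", 20, 700),
    Variable("fio2", "fraction", 0.21, 1.0),
    Variable("urine_output_24h", "mL", 0, 20000),
    Variable("respiratory_support", "0/1", 0, 1),
    Variable("hypercapnic_failure", "0/1", 0, 1),
]

VOCABULARY: dict[str, Variable] = {v.name: v for v in _VARS}

AVPU_ALERT = 0
AVPU_CONFUSION = 1
AVPU_VOICE = 2
AVPU_PAIN = 3
AVPU_UNRESPONSIVE = 4

AVPU_CODES = {"A": 0, "C": 1, "V": 2, "P": 3, "U": 4}

SEXES = ("female", "male")
RACES = ("white", "black", "asian", "other")
SERVICES = ("medicine", "surgery", "hospice", "psychiatry", "obstetrics_gynecology", "other")
EXCLUDED_SERVICES = ("hospice", "psychiatry", "obstetrics_gynecology")
DISPOSITIONS = (
    "in_hospital_death",
    "hospice",
    "acute_care",
    "nonacute_facility",
    "home",
    "other",
)
VASOPRESSORS = ("dopamine", "dobutamine", "epinephrine", "norepinephrine")


def is_valid_value(variable: str, value: float) -> bool:
    """True when ``value`` lies inside the variable's physiologic guard range."""
    v = VOCABULARY[variable]
    return v.lo <= value <= v.hi
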