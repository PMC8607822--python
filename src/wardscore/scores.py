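"""Early-warning-score engine.

Seven scores are supported: SIRS, qSOFA, MEWS, NEWS, NEWS2, SOFA, and
APACHE II.  Their point-band tables are data, not code: one YAML file per
score under ``wardscore/score_tables/`` (see those files for provenance).
This module resolves per-variable snapshots from irregular observation
series under two lookback policies and turns snapshots into score values.

Resolution policies
-------------------
``recent``
    The last observation of each variable inside the closed lookback
    window ``[t - lookback, t]``.
``worst``
    Per score component, the observation contributing the most points to
    that component under *this score's* bands; ties broken by the most
    recent among the maximal.  Variables that enter a score only through
    a derived quantity (PaO2/FiO2 ratio, alveolar-arterial gradient) are
    resolved as the most recent paired values in both modes.

A variable with no eligible observation is ABSENT and its component
scores zero ("missing values were assumed normal").  Values outside the
physiologic guard range are reported and treated as absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .model import Encounter, MedicationEvent, hours_between
from .vocab import VOCABULARY

SCORE_NAMES = ("SIRS", "qSOFA", "MEWS", "NEWS", "NEWS2", "SOFA", "APACHE_II")

_TABLE_FILES = {
    "SIRS": "sirs.yaml",
    "qSOFA": "qsofa.yaml",
    "MEWS": "mews.yaml",
    "NEWS": "news.yaml",
    "NEWS2": "news2.yaml",
    "SOFA": "sofa.yaml",
    "APACHE_II": "apache2.yaml",
}

# Validated positivity thresholds (score >= threshold flags positive).
VALIDATED_THRESHOLDS = {
    "SIRS": 2, "qSOFA": 2, "MEWS": 4, "NEWS": 5, "NEWS2": 5, "SOFA": 2, "APACHE_II": 15,
}

DEFAULT_OFFSETS = tuple(range(-12, 13))

# Variables resolved as most-recent in both modes (paired derived quantities).
_RECENT_VARS = {"SOFA": {"pao2", "fio2"}, "APACHE_II": {"fio2", "paco2"}}
# Binary state flags resolved as max-in-window under worst mode.
_FLAG_MAX_VARS = {"NEWS2": {"hypercapnic_failure"}}


@dataclass(frozen=True)
class Band:
    points: int
    upper: float | None = None  # None = catch-all
    exclusive: bool = False

    def admits(self, value: float) -> bool:
        if self.upper is None:
            return True
        return value < self.upper if self.exclusive else value <= self.upper


def points_for(bands: tuple[Band, ...], value: float) -> int:
    for b in bands:
        if b.admits(value):
            return b.points
    raise AssertionError("band table does not cover the value domain")


def points_for_array(bands: tuple[Band, ...], values: np.ndarray) -> np.ndarray:
    conds = []
    choices = []
    default = 0
    for b in bands:
        if b.upper is None:
            default = b.points
        else:
            conds.append(values < b.upper if b.exclusive else values <= b.upper)
            choices.append(b.points)
    if not conds:
        return np.full(values.shape, default, dtype=np.int64)
    return np.select(conds, choices, default=default).astype(np.int64)


@dataclass(frozen=True)
class Criterion:
    variable: str
    bands: tuple[Band, ...]


@dataclass(frozen=True)
class Component:
    name: str
    criteria: tuple[Criterion, ...]
    rule: str = "max"  # "max" | "first_present"


@dataclass
class ScoreDefinition:
    name: str
    threshold: int
    max_total: int
    components: tuple[Component, ...]
    special: dict = field(default_factory=dict)
    worst_tables: dict[str, tuple[Band, ...]] = field(default_factory=dict)
    use_spo2_scale2: bool = False  # NEWS2 only

    @property
    def variables(self) -> set[str]:
        """Observation variables this score can consume."""
        vs = {c.variable for comp in self.components for c in comp.criteria}
        vs |= set(self.worst_tables)
        vs |= _RECENT_VARS.get(self.name, set())
        vs |= _FLAG_MAX_VARS.get(self.name, set())
        if self.name == "SOFA":
            vs |= {"map", "pao2", "fio2", "respiratory_support"}
        if self.name == "APACHE_II":
            vs |= {"pao2", "paco2", "fio2"}
        if self.use_spo2_scale2:
            vs |= {"hypercapnic_failure", "supplemental_o2"}
        return vs

    def validate(self) -> None:
        for v in self.variables:
            if v not in VOCABULARY:
                raise ValueError(f"{self.name}: variable {v!r} not in vocabulary")
        for comp in self.components:
            for crit in comp.criteria:
                if crit.bands[-1].upper is not None:
                    raise ValueError(
                        f"{self.name}.{comp.name}: bands must end with a catch-all"
                    )
                uppers = [b.upper for b in crit.bands if b.upper is not None]
                if uppers != sorted(uppers):
                    raise ValueError(f"{self.name}.{comp.name}: bands out of order")
                if any(b.points < 0 for b in crit.bands):
                    raise ValueError(f"{self.name}.{comp.name}: negative points")


def _parse_bands(raw: list[dict]) -> tuple[Band, ...]:
    return tuple(
        Band(points=int(b["points"]), upper=b.get("upper"), exclusive=bool(b.get("exclusive", False)))
        for b in raw
    )


@lru_cache(maxsize=None)
def _load_raw(name: str) -> dict:
    path = resources.files("wardscore") / "score_tables" / _TABLE_FILES[name]
    with path.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_definition(name: str, spo2_scale2: bool = False) -> ScoreDefinition:
    raw = _load_raw(name)
    comps = tuple(
        Component(
            name=c["name"],
            criteria=tuple(
                Criterion(variable=cr["variable"], bands=_parse_bands(cr["bands"]))
                for cr in c["criteria"]
            ),
            rule=c.get("rule", "max"),
        )
        for c in raw["components"]
    )
    worst = {v: _parse_bands(b) for v, b in raw.get("worst", {}).items()}
    d = ScoreDefinition(
        name=raw["name"],
        threshold=int(raw["threshold"]),
        max_total=int(raw["max_total"]),
        components=comps,
        special=raw.get("special", {}),
        worst_tables=worst,
        use_spo2_scale2=spo2_scale2 and raw["name"] == "NEWS2",
    )
    d.validate()
    return d


def load_definitions(names: tuple[str, ...] = SCORE_NAMES) -> dict[str, ScoreDefinition]:
    return {n: load_definition(n) for n in names}


# ------------------------------------------------------------------ history

ABSENT = None


@dataclass
class PatientHistory:
    """Per-encounter observation series indexed for fast window queries.

    Times are float hours on the encounter's own clock (0 = admission).
    """

    encounter: Encounter
    series: dict[str, tuple[np.ndarray, np.ndarray]]  # var -> (times_h, values)
    vasopressors: list[tuple[float, str, float | None]]  # (time_h, drug, dose)
    errors: list[str] = field(default_factory=list)
    _points_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def build(
        cls,
        encounter: Encounter,
        observations: pd.DataFrame,
        medications: list[MedicationEvent] | None = None,
    ) -> "PatientHistory":
        """``observations``: long-format rows for this encounter only."""
        series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        errors: list[str] = []
        if len(observations):
            t0 = encounter.admit_time
            t_h = (
                (pd.to_datetime(observations["time"]) - t0) / pd.Timedelta(hours=1)
            ).to_numpy(dtype=np.float64)
            vals = observations["value"].to_numpy(dtype=np.float64)
            var_arr = observations["variable"].to_numpy()
            order = np.argsort(t_h, kind="stable")
            t_h, vals, var_arr = t_h[order], vals[order], var_arr[order]
            for var in np.unique(var_arr):
                m = var_arr == var
                tv, vv = t_h[m], vals[m]
                spec = VOCABULARY[str(var)]
                ok = (vv >= spec.lo) & (vv <= spec.hi)
                n_bad = int((~ok).sum())
                if n_bad:
                    errors.append(
                        f"{encounter.encounter_id}: {n_bad} {var} value(s) outside "
                        f"guard range [{spec.lo}, {spec.hi}] treated as absent"
                    )
                series[str(var)] = (tv[ok], vv[ok])
        vaso = []
        for ev in medications or []:
            if ev.vasopressor is not None:
                vaso.append((hours_between(encounter.admit_time, ev.time), ev.vasopressor, ev.dose))
        vaso.sort(key=lambda x: x[0])
        return cls(encounter=encounter, series=series, vasopressors=vaso, errors=errors)

    def to_hours(self, t: datetime) -> float:
        return hours_between(self.encounter.admit_time, t)

    def _window(self, var: str, lo: float, hi: float):
        tv = self.series.get(var)
        if tv is None:
            return None
        t, v = tv
        i0 = int(np.searchsorted(t, lo, side="left"))
        i1 = int(np.searchsorted(t, hi, side="right"))
        if i0 >= i1:
            return None
        return t, v, i0, i1

    def _points(self, key: str, var: str, bands: tuple[Band, ...]) -> np.ndarray:
        cached = self._points_cache.get((key, var))
        if cached is None:
            cached = points_for_array(bands, self.series[var][1])
            self._points_cache[(key, var)] = cached
        return cached

    def recent(self, var: str, lo: float, hi: float):
        w = self._window(var, lo, hi)
        if w is None:
            return ABSENT
        t, v, _, i1 = w
        return float(v[i1 - 1]), float(t[i1 - 1])

    def worst(self, var: str, lo: float, hi: float, key: str, bands: tuple[Band, ...]):
        w = self._window(var, lo, hi)
        if w is None:
            return ABSENT
        t, v, i0, i1 = w
        pts = self._points(key, var, bands)[i0:i1]
        j = i0 + int(np.flatnonzero(pts == pts.max())[-1])
        return float(v[j]), float(t[j])

    def flag_max(self, var: str, lo: float, hi: float):
        w = self._window(var, lo, hi)
        if w is None:
            return ABSENT
        t, v, i0, i1 = w
        j = i0 + int(np.flatnonzero(v[i0:i1] == v[i0:i1].max())[-1])
        return float(v[j]), float(t[j])

    def vasopressors_in(self, lo: float, hi: float) -> list[tuple[str, float | None]]:
        return [(d, dose) for t, d, dose in self.vasopressors if lo <= t <= hi]


# ----------------------------------------------------------------- snapshot

@dataclass
class Snapshot:
    encounter_id: str
    evaluation_time: datetime
    lookback_hours: float
    mode: str  # "worst" | "recent"
    resolved: dict[str, tuple[float, float] | None]
    age: float = 0.0
    vasopressors: list[tuple[str, float | None]] = field(default_factory=list)

    def value(self, var: str) -> float | None:
        r = self.resolved.get(var)
        return None if r is None else r[0]


def resolve_snapshot(
    history: PatientHistory,
    evaluation_time: datetime,
    lookback_hours: float,
    mode: str,
    definition: ScoreDefinition,
) -> Snapshot:
    """Resolve one per-variable snapshot at ``evaluation_time``.

    The window is closed on both ends: ``[t - lookback, t]``.
    """
    if mode not in ("worst", "recent"):
        raise ValueError(f"unknown mode {mode!r}")
    hi = history.to_hours(evaluation_time)
    lo = hi - lookback_hours
    recent_vars = _RECENT_VARS.get(definition.name, set())
    flag_vars = _FLAG_MAX_VARS.get(definition.name, set())
    resolved: dict[str, tuple[float, float] | None] = {}
    for comp in definition.components:
        for crit in comp.criteria:
            var = crit.variable
            if var in resolved:
                continue
            if mode == "worst" and var not in recent_vars:
                resolved[var] = history.worst(var, lo, hi, definition.name, crit.bands)
            else:
                resolved[var] = history.recent(var, lo, hi)
    for var, bands in definition.worst_tables.items():
        if var in resolved:
            continue
        if mode == "worst" and var not in recent_vars:
            resolved[var] = history.worst(var, lo, hi, definition.name + ":worst", bands)
        else:
            resolved[var] = history.recent(var, lo, hi)
    for var in definition.variables - set(resolved):
        if mode == "worst" and var in flag_vars:
            resolved[var] = history.flag_max(var, lo, hi)
        else:
            resolved[var] = history.recent(var, lo, hi)
    return Snapshot(
        encounter_id=history.encounter.encounter_id,
        evaluation_time=evaluation_time,
        lookback_hours=lookback_hours,
        mode=mode,
        resolved=resolved,
        age=history.encounter.age,
        vasopressors=history.vasopressors_in(lo, hi),
    )


@dataclass
class ScoreValue:
    encounter_id: str
    score: str
    offset_hours: int | None
    total: int
    components: dict[str, int]
    mode: str
    lookback_hours: float


def _component_points(comp: Component, snapshot: Snapshot) -> int:
    if comp.rule == "first_present":
        for crit in comp.criteria:
            v = snapshot.value(crit.variable)
            if v is not None:
                return points_for(crit.bands, v)
        return 0
    pts = 0
    for crit in comp.criteria:
        v = snapshot.value(crit.variable)
        if v is not None:
            pts = max(pts, points_for(crit.bands, v))
    return pts


def _sofa_respiration(snapshot: Snapshot, special: dict) -> int:
    pao2, fio2 = snapshot.value("pao2"), snapshot.value("fio2")
    if pao2 is None or fio2 is None or fio2 <= 0:
        return 0
    pts = points_for(_parse_bands(special["pf_bands"]), pao2 / fio2)
    cap = int(special["support_required_above"])
    support = snapshot.value("respiratory_support")
    if pts > cap and support != 1:
        pts = cap
    return pts


def _sofa_cardiovascular(snapshot: Snapshot, special: dict) -> int:
    pts = 0
    m = snapshot.value("map")
    if m is not None:
        pts = points_for(_parse_bands(special["map_bands"]), m)
    for drug, dose in snapshot.vasopressors:
        bands = _parse_bands(special["vasopressor_bands"][drug])
        # A recorded vasopressor without a dose is scored at the drug's
        # lowest dose band.
        d = 0.0 if dose is None else dose
        pts = max(pts, points_for(bands, d))
    return pts


def _apache_oxygenation(snapshot: Snapshot, special: dict) -> int:
    pao2 = snapshot.value("pao2")
    fio2 = snapshot.value("fio2")
    paco2 = snapshot.value("paco2")
    thr = float(special["fio2_threshold"])
    if fio2 is not None and fio2 >= thr:
        if pao2 is None or paco2 is None:
            return 0
        aa = fio2 * 713.0 - paco2 / 0.8 - pao2
        return points_for(_parse_bands(special["aa_gradient_bands"]), aa)
    if pao2 is None:
        return 0
    return points_for(_parse_bands(special["pao2_bands"]), pao2)


def _news2_spo2_scale2(snapshot: Snapshot, special: dict) -> int:
    spo2 = snapshot.value("spo2")
    if spo2 is None:
        return 0
    on_o2 = snapshot.value("supplemental_o2") == 1
    key = "oxygen_bands" if on_o2 else "air_bands"
    return points_for(_parse_bands(special[key]), spo2)


def compute_score(snapshot: Snapshot, definition: ScoreDefinition) -> ScoreValue:
    """Deterministic band lookup and sum for one resolved snapshot."""
    comps: dict[str, int] = {}
    sc2 = definition.special.get("spo2_scale2")
    scale2_active = (
        definition.use_spo2_scale2
        and sc2 is not None
        and snapshot.value(sc2["trigger_variable"]) == 1
    )
    for comp in definition.components:
        if scale2_active and comp.name == "oxygen_saturation":
            comps[comp.name] = _news2_spo2_scale2(snapshot, sc2)
        else:
            comps[comp.name] = _component_points(comp, snapshot)
    if definition.name == "SOFA":
        comps["respiration"] = _sofa_respiration(snapshot, definition.special["respiration"])
        comps["cardiovascular"] = _sofa_cardiovascular(
            snapshot, definition.special["cardiovascular"]
        )
    elif definition.name == "APACHE_II":
        comps["age"] = points_for(
            _parse_bands(definition.special["age_bands"]), snapshot.age
        )
        comps["chronic_health"] = int(definition.special["chronic_health_points"])
        comps["oxygenation"] = _apache_oxygenation(
            snapshot, definition.special["oxygenation"]
        )
    return ScoreValue(
        encounter_id=snapshot.encounter_id,
        score=definition.name,
        offset_hours=None,
        total=int(sum(comps.values())),
        components=comps,
        mode=snapshot.mode,
        lookback_hours=snapshot.lookback_hours,
    )


def score_at(
    history: PatientHistory,
    evaluation_time: datetime,
    definition: ScoreDefinition,
    lookback_hours: float = 24.0,
    mode: str = "worst",
) -> ScoreValue:
    snap = resolve_snapshot(history, evaluation_time, lookback_hours, mode, definition)
    return compute_score(snap, definition)


def compute_series(
    history: PatientHistory,
    index_time: datetime,
    definition: ScoreDefinition,
    lookback_hours: float = 24.0,
    mode: str = "worst",
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
) -> list[ScoreValue]:
    """Hourly score values at the requested offsets around ``index_time``.

    Offsets whose evaluation time falls after discharge emit no value.
    """
    out = []
    for off in offsets:
        t = index_time + timedelta(hours=off)
        if t > history.encounter.discharge_time:
            continue
        sv = score_at(history, t, definition, lookback_hours, mode)
        sv.offset_hours = int(off)
        out.append(sv)
    return out


def score_table(
    histories: dict[str, PatientHistory],
    index_times: dict[str, datetime],
    definitions: dict[str, ScoreDefinition] | None = None,
    lookbacks: tuple[float, ...] = (24.0,),
    modes: tuple[str, ...] = ("worst", "recent"),
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
) -> pd.DataFrame:
    """Tidy score table: one row per encounter x score x offset x mode x lookback."""
    definitions = definitions or load_definitions()
    rows = []
    for eid, t_index in index_times.items():
        hist = histories[eid]
        for name, d in definitions.items():
            for lb in lookbacks:
                for mode in modes:
                    for sv in compute_series(hist, t_index, d, lb, mode, offsets):
                        rows.append((eid, name, sv.offset_hours, mode, lb, sv.total))
    return pd.DataFrame(
        rows, columns=["encounter_id", "score", "offset", "mode", "lookback", "total"]
    )
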