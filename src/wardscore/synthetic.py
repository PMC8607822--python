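"""Synthetic general-ward cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes rather than full physiology: ~3.3% sepsis prevalence, a
right-skewed time-to-onset (median ~48 h), irregular ward-frequency
vitals (roughly every 4-8 h) and daily labs, mental status suppressed by
default, and — for sepsis cases — a pre-onset physiologic derangement
ramp with sample-to-sample intensity fluctuation (spiking fevers,
transient hypotension) superimposed on mean-reverting per-patient
baselines.  Sepsis cases always carry a culture/antibiotic pair that
satisfies a suspicion-of-infection window anchored at the true onset;
a configurable share of controls carries decoy events that do not.

Vitals evolve as AR(1) mean-reverting noise around a per-patient
baseline plus, for cases, a linear ramp over ``ramp_hours`` before onset
that plateaus for 24 h after onset and then decays.  Each sample's
derangement is scaled by an intensity draw S ~ U(0.5, 1), so the most
recent measurement can miss the worst derangement in the lookback
window — the feature that separates worst-value from recent-value
snapshot resolution.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .io import WardTables
from .model import (
    CultureEvent,
    Encounter,
    GroundTruth,
    MedicationEvent,
    observations_frame,
)

_BASE_TIME = datetime(2021, 1, 1)

# (baseline mean, between-patient sd, within-patient noise sd,
#  derangement per unit effect at full ramp, rounding decimals)
_VITALS = {
    "heart_rate": (76.0, 5.0, 6.0, +15.0, 1),
    "resp_rate": (15.5, 1.0, 1.6, +5.5, 1),
    "sbp": (122.0, 7.0, 9.0, -18.0, 1),
    "map": (88.0, 5.0, 7.0, -13.0, 1),
    "temperature": (36.8, 0.2, 0.35, +0.9, 1),
    "spo2": (97.0, 0.8, 1.2, -2.5, 1),
}
_LABS = {
    "wbc": (7.5, 1.0, 1.2, +4.0, 1),
    "creatinine": (0.9, 0.1, 0.12, +0.5, 2),
    "bilirubin": (0.7, 0.12, 0.15, +0.4, 2),
    "platelets": (250.0, 30.0, 25.0, -50.0, 1),
    "band_pct": (3.0, 1.0, 1.5, +6.0, 1),
    "sodium": (139.0, 2.0, 2.2, 0.0, 1),
    "potassium": (4.1, 0.2, 0.25, 0.0, 2),
    "hematocrit": (38.0, 2.5, 2.5, 0.0, 1),
}
_CLIP = {"spo2": (50.0, 100.0), "temperature": (30.0, 43.0), "resp_rate": (4.0, 60.0)}
_AR_TAU_HOURS = 8.0  # mean-reversion time constant


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort."""

    n_encounters: int = 1000
    sepsis_prevalence: float = 0.033
    seed: int = 0
    vitals_interval_hours: float = 4.0
    labs_interval_hours: float = 24.0
    mental_status_missing_prob: float = 1.0
    derangement_effect: float = 2.0
    ramp_hours: float = 12.0
    # log-normal time-to-onset, median 48 h, IQR ~ 22-97 h
    onset_log_mu: float = math.log(48.0)
    onset_log_sigma: float = 1.08
    # log-normal length of stay, median ~103 h (4.3 d)
    los_log_mu: float = math.log(103.0)
    los_log_sigma: float = 0.65
    los_bounds_hours: tuple[float, float] = (12.0, 14 * 24.0)
    # control decoy event rates (mutually exclusive categories)
    control_culture_only: float = 0.20
    control_antibiotic_only: float = 0.20
    control_violating_pair: float = 0.05

    def validate(self) -> None:
        if not 0 < self.sepsis_prevalence < 1:
            raise ValueError("sepsis_prevalence must be in (0, 1)")
        for name in ("vitals_interval_hours", "labs_interval_hours", "ramp_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.derangement_effect < 0:
            raise ValueError("derangement_effect must be >= 0")
        lo, hi = self.los_bounds_hours
        if not 0 < lo < hi:
            raise ValueError("los_bounds_hours must be increasing and positive")


def _round_to_second(t: datetime) -> datetime:
    return t.replace(microsecond=0)


def generate_events_for_case(
    encounter_id: str,
    onset_time: datetime,
    rng: np.random.Generator,
    discharge_time: datetime | None = None,
) -> tuple[CultureEvent, MedicationEvent]:
    """Culture/antibiotic pair qualifying for suspicion of infection.

    The earlier event sits exactly at ``onset_time``.  The culture-first
    branch places antibiotics within (0, 72] h; the antibiotic-first
    branch places culture procurement within (0, 24] h.
    """
    avail = math.inf
    if discharge_time is not None:
        avail = max((discharge_time - onset_time) / timedelta(hours=1) - 0.5, 0.25)
    if rng.random() < 0.5:
        offset = min(float(rng.uniform(0.5, 48.0)), avail, 72.0)
        culture = CultureEvent(encounter_id, _round_to_second(onset_time))
        abx = MedicationEvent(
            encounter_id,
            _round_to_second(onset_time + timedelta(hours=offset)),
            is_antibiotic=True,
        )
    else:
        offset = min(float(rng.uniform(0.5, 20.0)), avail, 24.0)
        abx = MedicationEvent(encounter_id, _round_to_second(onset_time), is_antibiotic=True)
        culture = CultureEvent(
            encounter_id, _round_to_second(onset_time + timedelta(hours=offset))
        )
    return culture, abx


def _sample_times(rng, los_h, first, mean_gap, jitter_lo, jitter_hi, extra=None):
    times = [first]
    t = first
    while True:
        t = t + mean_gap * float(rng.uniform(jitter_lo, jitter_hi))
        if t >= los_h:
            break
        times.append(t)
    if extra is not None and 0 < extra < los_h:
        times.append(extra)
    return np.unique(np.round(np.asarray(times, dtype=float), 6))


def _ramp_fraction(t_h: np.ndarray, onset_h: float, ramp_h: float) -> np.ndarray:
    """0 before the ramp, linear up to 1 at onset, plateau 24 h, decay 24 h."""
    f = np.clip((t_h - (onset_h - ramp_h)) / ramp_h, 0.0, 1.0)
    decay = np.clip(1.0 - (t_h - onset_h - 24.0) / 24.0, 0.0, 1.0)
    return np.minimum(f, decay)


def _series(rng, times, spec, effect, frac, intensity):
    mean, b_sd, w_sd, delta, dec = spec
    baseline = mean + b_sd * float(rng.standard_normal())
    dev = np.empty(len(times))
    z = rng.standard_normal(len(times))
    dev[0] = w_sd * z[0]
    for i in range(1, len(times)):
        rho = math.exp(-(times[i] - times[i - 1]) / _AR_TAU_HOURS)
        dev[i] = rho * dev[i - 1] + math.sqrt(1.0 - rho * rho) * w_sd * z[i]
    vals = baseline + dev + effect * delta * frac * intensity
    return np.round(vals, dec)


def generate_cohort(
    config: SyntheticConfig, include_observations: bool = True
) -> WardTables:
    """Generate one synthetic ward cohort; deterministic given the seed.

    With ``include_observations=False`` only encounters, events, and
    ground truth are produced (sufficient for index-time matching
    experiments, which never read observations).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.sepsis_prevalence * config.n_encounters < 1:
        _warnings.warn("prevalence x n < 1: expect zero sepsis cases", stacklevel=2)

    tables = WardTables()
    lo_los, hi_los = config.los_bounds_hours
    obs_eids: list[np.ndarray] = []
    obs_times: list[np.ndarray] = []
    obs_vars: list[np.ndarray] = []
    obs_vals: list[np.ndarray] = []

    for i in range(config.n_encounters):
        eid = f"E{i:06d}"
        is_sepsis = bool(rng.random() < config.sepsis_prevalence)
        admit = _round_to_second(
            _BASE_TIME + timedelta(hours=float(rng.uniform(0, 180 * 24)))
        )
        los_h = float(
            np.clip(rng.lognormal(config.los_log_mu, config.los_log_sigma), lo_los, hi_los)
        )
        onset_h: float | None = None
        if is_sepsis:
            los_h = max(los_h, 48.0)
            for _ in range(200):
                cand = float(rng.lognormal(config.onset_log_mu, config.onset_log_sigma))
                if 12.0 <= cand <= los_h - 12.0:
                    onset_h = cand
                    break
            if onset_h is None:
                onset_h = float(rng.uniform(12.0, los_h - 12.0))
            onset_h = round(onset_h, 6)

        age = float(np.clip(rng.normal(64.0 if is_sepsis else 59.0, 14.0), 16.0, 95.0))
        sex = "female" if rng.random() < 0.48 else "male"
        race = str(rng.choice(["white", "black", "asian", "other"], p=[0.62, 0.31, 0.01, 0.06]))
        service = str(
            rng.choice(
                ["medicine", "surgery", "other", "hospice", "psychiatry", "obstetrics_gynecology"],
                p=[0.60, 0.20, 0.16, 0.01, 0.015, 0.015],
            )
        )
        surgery_times = []
        if rng.random() < 0.07:
            surgery_times.append(
                _round_to_second(admit + timedelta(hours=float(rng.uniform(0, los_h * 0.8))))
            )

        # Outcomes.
        death_h: float | None = None
        icu: list[tuple[float, float]] = []
        if is_sepsis:
            if rng.random() < 0.122:
                death_h = onset_h + float(rng.uniform(12.5, 60.0))
                los_h = min(max(death_h, onset_h + 12.5), hi_los)
                death_h = los_h
            if death_h is None and rng.random() < 0.18:
                s = onset_h + float(rng.uniform(3.0, 48.0))
                if s < los_h - 2.0:
                    icu.append((s, min(s + float(rng.uniform(24.0, 96.0)), los_h)))
        else:
            if rng.random() < 0.011:
                death_h = float(rng.uniform(min(24.0, los_h * 0.5), los_h))
                los_h = death_h
            elif rng.random() < 0.02:
                s = float(rng.uniform(6.0, max(los_h - 12.0, 7.0)))
                if s < los_h - 2.0:
                    icu.append((s, min(s + float(rng.uniform(24.0, 96.0)), los_h)))

        discharge = _round_to_second(admit + timedelta(hours=los_h))
        death_time = discharge if death_h is not None else None
        if death_time is not None:
            disposition = "in_hospital_death"
        else:
            disposition = str(
                rng.choice(
                    ["home", "nonacute_facility", "hospice", "acute_care", "other"],
                    p=[0.835, 0.135, 0.012, 0.008, 0.01],
                )
            )
        icu_intervals = [
            (
                _round_to_second(admit + timedelta(hours=s)),
                _round_to_second(admit + timedelta(hours=min(e, los_h))),
            )
            for s, e in icu
            if s < los_h - 1.0
        ]
        enc = Encounter(
            encounter_id=eid,
            age=round(age, 1),
            sex=sex,
            race=race,
            admit_time=admit,
            discharge_time=discharge,
            admitting_service=service,
            surgery_times=surgery_times,
            icu_intervals=icu_intervals,
            death_time=death_time,
            disposition=disposition,
        )
        tables.encounters[eid] = enc

        # floor to the same whole second the observation grid uses
        onset_time = (
            admit + timedelta(seconds=math.floor(onset_h * 3600.0))
            if onset_h is not None
            else None
        )
        tables.ground_truth[eid] = GroundTruth(
            encounter_id=eid,
            is_sepsis=is_sepsis,
            true_onset_time=onset_time,
            death_within_48h=death_h is not None and onset_h is not None
            and death_h - onset_h <= 48.0,
            icu_within_48h=bool(icu) and onset_h is not None
            and any(0.0 < s - onset_h <= 48.0 for s, _ in icu),
        )

        # Events.
        if is_sepsis:
            culture, abx = generate_events_for_case(eid, onset_time, rng, discharge)
            tables.cultures.append(culture)
            tables.medications.append(abx)
            if icu_intervals and rng.random() < 0.5:
                tables.medications.append(
                    MedicationEvent(
                        eid,
                        icu_intervals[0][0],
                        vasopressor="norepinephrine",
                        dose=round(float(rng.uniform(0.02, 0.3)), 3),
                    )
                )
        else:
            u = rng.random()
            if u < config.control_culture_only:
                t = admit + timedelta(hours=float(rng.uniform(1.0, los_h - 1.0)))
                tables.cultures.append(CultureEvent(eid, _round_to_second(t)))
            elif u < config.control_culture_only + config.control_antibiotic_only:
                t = admit + timedelta(hours=float(rng.uniform(1.0, los_h - 1.0)))
                tables.medications.append(
                    MedicationEvent(eid, _round_to_second(t), is_antibiotic=True)
                )
            elif (
                u
                < config.control_culture_only
                + config.control_antibiotic_only
                + config.control_violating_pair
                and los_h > 28.0
            ):
                t0 = float(rng.uniform(0.5, los_h - 26.0))
                gap = float(rng.uniform(24.5, min(47.0, los_h - t0 - 0.5)))
                tables.medications.append(
                    MedicationEvent(
                        eid, _round_to_second(admit + timedelta(hours=t0)), is_antibiotic=True
                    )
                )
                tables.cultures.append(
                    CultureEvent(eid, _round_to_second(admit + timedelta(hours=t0 + gap)))
                )

        if not include_observations:
            continue

        # Observation times; cases get a vitals set and a lab panel at onset
        # (the measurements that accompany a sepsis work-up).
        vt = _sample_times(
            rng, los_h, 0.25, config.vitals_interval_hours, 1.0, 2.0, extra=onset_h
        )
        lt = _sample_times(
            rng, los_h, 0.5, config.labs_interval_hours, 0.8, 1.0, extra=onset_h
        )
        effect = config.derangement_effect if is_sepsis else 0.0
        onset_ref = onset_h if onset_h is not None else -1e9

        def intensity_for(times: np.ndarray) -> np.ndarray:
            # Sample-to-sample derangement intensity: sepsis physiology is
            # intermittent (spiking fevers, transient hypotension), so any
            # single (most recent) reading can catch a quiescent trough
            # while the worst reading in the window catches the spike.
            spike = rng.uniform(0.5, 1.0, size=len(times))
            trough = rng.uniform(0.05, 0.3, size=len(times))
            return np.where(rng.random(len(times)) < 0.35, trough, spike)

        for times, specs in ((vt, _VITALS), (lt, _LABS)):
            frac = _ramp_fraction(times, onset_ref, config.ramp_hours)
            inten = intensity_for(times)
            for var, spec in specs.items():
                vals = _series(rng, times, spec, effect, frac, inten)
                if var in _CLIP:
                    vals = np.clip(vals, *_CLIP[var])
                obs_eids.append(np.repeat(eid, len(times)))
                obs_times.append(times)
                obs_vars.append(np.repeat(var, len(times)))
                obs_vals.append(vals)
            if specs is _VITALS:
                if rng.random() >= config.mental_status_missing_prob:
                    avpu = np.where(
                        (frac >= 0.5) & (rng.random(len(times)) < 0.4 * effect / 2.0), 2.0, 0.0
                    )
                    obs_eids.append(np.repeat(eid, len(times)))
                    obs_times.append(times)
                    obs_vars.append(np.repeat("avpu", len(times)))
                    obs_vals.append(avpu)
        if is_sepsis and rng.random() < 0.4:
            obs_eids.append(np.array([eid]))
            obs_times.append(np.array([onset_h]))
            obs_vars.append(np.array(["supplemental_o2"]))
            obs_vals.append(np.array([1.0]))

    if include_observations and obs_eids:
        eid_col = np.concatenate(obs_eids)
        # hours -> absolute datetimes (second resolution), per encounter admit
        admits = pd.Series({e: enc.admit_time for e, enc in tables.encounters.items()})
        t_hours = np.concatenate(obs_times)
        t_abs = pd.to_datetime(admits.loc[eid_col].to_numpy()) + pd.to_timedelta(
            np.floor(t_hours * 3600.0), unit="s"
        )
        df = pd.DataFrame(
            {
                "encounter_id": eid_col,
                "time": t_abs,
                "variable": np.concatenate(obs_vars),
                "value": np.concatenate(obs_vals),
            }
        )
        tables.observations = df.sort_values(
            ["encounter_id", "time", "variable"], kind="mergesort"
        ).reset_index(drop=True)
    return tables
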