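"""Matched index-time assignment for the nonsepsis cohort.

Controls are subsampled at ``ratio`` controls per sepsis case (default
30:1) and assigned index times so that the histogram of
time-from-admission-to-index in ``bin_hours`` bins (default 3 h) equals
``ratio`` times the sepsis histogram wherever feasible.

Algorithm: target per-bin counts are ratio x sepsis bin counts; bins are
filled scarcest-first (fewest eligible controls first); within a bin,
controls are sampled without replacement and each selected control draws
its exact index time uniformly over the bin clipped to its feasible
interval (index >= admission + bin start, index <= discharge - 12 h).
Controls failing post-assignment exclusions are replaced from the same
bin up to ``max_resample_attempts`` draws; remaining deficits are
reported, never silently absorbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import timedelta
from typing import Callable

import numpy as np
import pandas as pd

from . import model
from .model import CohortRecord, Encounter, hours_between


@dataclass
class MatchingConfig:
    ratio: int = 30
    bin_hours: float = 3.0
    seed: int = 0
    max_resample_attempts: int = 200
    min_discharge_after_index_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.bin_hours <= 0:
            raise ValueError("bin_hours must be positive")


@dataclass
class MatchingResult:
    records: list[CohortRecord]
    warnings: list[str] = field(default_factory=list)
    per_bin: pd.DataFrame | None = None  # bin, target, achieved


def time_to_index_hours(encounter: Encounter, record: CohortRecord) -> float:
    return hours_between(encounter.admit_time, record.index_time)


def assign_control_index_times(
    sepsis_records: list[CohortRecord],
    eligible_controls: list[Encounter],
    config: MatchingConfig,
    encounters: dict[str, Encounter],
    post_exclusion_fn: Callable[[str, object], list[str]] | None = None,
) -> MatchingResult:
    """Select and index controls to mirror the sepsis time-to-index histogram.

    ``post_exclusion_fn(encounter_id, index_time)`` returns the index-
    dependent exclusion reasons for a candidate assignment (empty = keep);
    pass None to skip post-assignment exclusion checks.
    """
    rng = np.random.default_rng(config.seed)
    warnings: list[str] = []

    ttis = [
        time_to_index_hours(encounters[r.encounter_id], r)
        for r in sepsis_records
        if r.index_time is not None
    ]
    if not ttis:
        return MatchingResult(records=[], warnings=["no sepsis cases to match"])
    bin_of = lambda t: int(math.floor(t / config.bin_hours))
    targets: dict[int, int] = {}
    for t in ttis:
        targets[bin_of(t)] = targets.get(bin_of(t), 0) + config.ratio

    # Feasible time-to-index upper bound per control.
    max_tti = {
        enc.encounter_id: enc.los_hours - config.min_discharge_after_index_hours
        for enc in eligible_controls
    }
    eligible_per_bin: dict[int, list[str]] = {}
    for enc in sorted(eligible_controls, key=lambda e: e.encounter_id):
        for b in targets:
            if b * config.bin_hours <= max_tti[enc.encounter_id]:
                eligible_per_bin.setdefault(b, []).append(enc.encounter_id)

    total_target = sum(targets.values())
    if len(eligible_controls) < total_target:
        warnings.append(
            f"only {len(eligible_controls)} eligible controls for a target of "
            f"{total_target}; selecting all that fit"
        )

    used: set[str] = set()
    records: list[CohortRecord] = []
    achieved: dict[int, int] = {b: 0 for b in targets}
    # Scarcest bin first: fewest eligible controls relative to its target.
    order = sorted(targets, key=lambda b: (len(eligible_per_bin.get(b, [])), b))
    for b in order:
        target = targets[b]
        pool = [e for e in eligible_per_bin.get(b, []) if e not in used]
        if not pool:
            warnings.append(f"bin {b}: no feasible control (deficit {target})")
            continue
        pool = list(rng.permutation(pool))
        lo = b * config.bin_hours
        attempts = 0
        while achieved[b] < target and pool and attempts < config.max_resample_attempts + target:
            eid = pool.pop()
            attempts += 1
            hi = min((b + 1) * config.bin_hours, max_tti[eid])
            tti = float(rng.uniform(lo, hi)) if hi > lo else lo
            enc = encounters[eid]
            # floor to whole seconds (file timestamps are second-resolution)
            index_time = enc.admit_time + timedelta(seconds=math.floor(tti * 3600.0))
            if post_exclusion_fn is not None:
                reasons = post_exclusion_fn(eid, index_time)
                if reasons:
                    continue
            used.add(eid)
            achieved[b] += 1
            records.append(
                CohortRecord(
                    encounter_id=eid,
                    label=model.LABEL_CONTROL,
                    index_time=index_time,
                )
            )
        if achieved[b] < target:
            warnings.append(
                f"bin {b}: achieved {achieved[b]} of target {target} controls"
            )
    per_bin = pd.DataFrame(
        {
            "bin": sorted(targets),
            "target": [targets[b] for b in sorted(targets)],
            "achieved": [achieved[b] for b in sorted(targets)],
        }
    )
    return MatchingResult(records=records, warnings=warnings, per_bin=per_bin)
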