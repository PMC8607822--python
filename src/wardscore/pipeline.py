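"""End-to-end orchestration: simulate -> label -> match -> score -> evaluate.

A single master seed derives per-stage seeds as a pure function (seed
sequences keyed by stage), so one integer reproduces a whole run.  Every
stage logs counts in/out and exclusion tallies to ``run.log``; outputs
are written with SHA-256 checksums and a resolved-config snapshot that
replays the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model
from .evaluation import build_eval_samples, evaluate_grid
from .io import WardTables, fmt_time, write_cohort, write_tables
from .labeling import ExclusionConfig, apply_exclusions, build_histories, build_labels
from .matching import MatchingConfig, assign_control_index_times
from .model import CohortRecord, Encounter, hours_between
from .scores import (
    DEFAULT_OFFSETS,
    SCORE_NAMES,
    VALIDATED_THRESHOLDS,
    load_definition,
    score_table,
)
from .synthetic import SyntheticConfig, generate_cohort


def stage_seed(master_seed: int, stage: str) -> int:
    """Pure function of (master seed, stage name); < 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 42
    n_encounters: int = 1000
    sepsis_prevalence: float = 0.033
    derangement_effect: float = 2.0
    vitals_interval_hours: float = 4.0
    labs_interval_hours: float = 24.0
    ramp_hours: float = 12.0
    ratio: int = 30
    bin_hours: float = 3.0
    scores: tuple[str, ...] = SCORE_NAMES
    lookbacks: tuple[float, ...] = (24.0,)
    modes: tuple[str, ...] = ("worst", "recent")
    offsets: tuple[int, ...] = DEFAULT_OFFSETS
    metrics: tuple[str, ...] = ("AUROC", "AUPRC")
    outcomes: tuple[str, ...] = ("sepsis",)
    thresholds: dict = field(default_factory=lambda: dict(VALIDATED_THRESHOLDS))
    n_boot: int = 1000

    def validate(self) -> None:
        if not self.scores:
            raise ValueError("score list must not be empty")
        unknown = set(self.scores) - set(SCORE_NAMES)
        if unknown:
            raise ValueError(f"unknown scores {sorted(unknown)}")
        for m in self.modes:
            if m not in ("worst", "recent"):
                raise ValueError(f"unknown mode {m!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def label_and_match(
    tables: WardTables,
    exclusion_config: ExclusionConfig | None = None,
    matching_config: MatchingConfig | None = None,
    log: list[str] | None = None,
):
    """Label sepsis, apply exclusions, and assign matched control indices.

    Returns (cohort records list, histories dict).
    """
    log = log if log is not None else []
    exclusion_config = exclusion_config or ExclusionConfig()
    matching_config = matching_config or MatchingConfig()
    histories = build_histories(tables.encounters, tables.observations, tables.medications)
    labels = build_labels(
        tables.encounters,
        tables.observations,
        tables.medications,
        tables.cultures,
        exclusion_config,
        histories,
    )
    sepsis_records = [
        r for r in labels.records.values() if r.label == model.LABEL_SEPSIS
    ]
    tally: dict[str, int] = {}
    for r in labels.records.values():
        for reason in r.exclusion_reasons:
            tally[reason] = tally.get(reason, 0) + 1
    log.append(
        f"label: {len(tables.encounters)} encounters -> {len(sepsis_records)} sepsis, "
        f"{len(labels.eligible_controls)} eligible controls, "
        f"{sum(1 for r in labels.records.values() if r.label == model.LABEL_EXCLUDED)} excluded"
    )
    log.append(f"label: exclusion tallies {dict(sorted(tally.items()))}")

    def post_fn(eid: str, index_time) -> list[str]:
        cand = CohortRecord(
            encounter_id=eid, label=model.LABEL_CONTROL, index_time=index_time
        )
        checked = apply_exclusions(
            tables.encounters[eid], cand, histories[eid], exclusion_config
        )
        return checked.exclusion_reasons

    match = assign_control_index_times(
        sepsis_records,
        [tables.encounters[eid] for eid in labels.eligible_controls],
        matching_config,
        tables.encounters,
        post_exclusion_fn=post_fn,
    )
    for w in match.warnings:
        log.append(f"match: warning: {w}")
    log.append(
        f"match: {len(match.records)} controls indexed "
        f"(target {matching_config.ratio} x {len(sepsis_records)})"
    )
    matched_ids = {r.encounter_id for r in match.records}
    cohort: list[CohortRecord] = []
    for eid, rec in labels.records.items():
        if rec.label == model.LABEL_CONTROL and eid not in matched_ids:
            continue  # unselected control
        cohort.append(rec)
    by_id = {r.encounter_id: r for r in match.records}
    cohort = [r for r in cohort if r.label != model.LABEL_CONTROL] + [
        by_id[eid] for eid in sorted(by_id)
    ]
    return cohort, histories


def cohort_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "encounter_id": [r.encounter_id for r in records],
            "label": [r.label for r in records],
            "index_time": [pd.Timestamp(r.index_time) if r.index_time else pd.NaT for r in records],
            "soi_time": [pd.Timestamp(r.soi_time) if r.soi_time else pd.NaT for r in records],
            "exclusion_reasons": [";".join(r.exclusion_reasons) for r in records],
        }
    )


def summarize_cohort(
    cohort: pd.DataFrame, encounters: dict[str, Encounter]
) -> pd.DataFrame:
    """Count/median summary per cohort label (no hypothesis tests)."""
    rows = []
    total = len(cohort)
    if total == 0:
        import warnings

        warnings.warn("empty cohort: empty summary", stacklevel=2)
        return pd.DataFrame(
            columns=["label", "n", "pct", "age_median", "age_iqr", "los_days_median",
                     "los_days_iqr", "tti_hours_median", "tti_hours_iqr", "death_n"]
        )
    labels = sorted(set(cohort["label"]) | {"sepsis", "control"})
    for label in labels:
        grp = cohort[cohort["label"] == label]
        if not len(grp):
            rows.append({"label": label, "n": 0, "pct": 0.0})
            continue
        encs = [encounters[e] for e in grp["encounter_id"]]
        ages = np.array([e.age for e in encs])
        los = np.array([e.los_hours / 24.0 for e in encs])
        tti = np.array(
            [
                hours_between(encounters[r.encounter_id].admit_time, r.index_time)
                for r in grp.itertuples(index=False)
                if not pd.isna(r.index_time)
            ]
        )
        q = lambda a, p: float(np.percentile(a, p)) if len(a) else float("nan")
        rows.append(
            {
                "label": label,
                "n": len(grp),
                "pct": 100.0 * len(grp) / total,
                "age_median": q(ages, 50),
                "age_iqr": f"{q(ages,25):.1f}-{q(ages,75):.1f}",
                "los_days_median": round(q(los, 50), 2),
                "los_days_iqr": f"{q(los,25):.2f}-{q(los,75):.2f}",
                "tti_hours_median": round(q(tti, 50), 1) if len(tti) else float("nan"),
                "tti_hours_iqr": f"{q(tti,25):.1f}-{q(tti,75):.1f}" if len(tti) else "",
                "death_n": sum(1 for e in encs if e.death_time is not None),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline into ``outdir``; returns output paths."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"run: master seed {config.seed}"]

    syn = SyntheticConfig(
        n_encounters=config.n_encounters,
        sepsis_prevalence=config.sepsis_prevalence,
        seed=stage_seed(config.seed, "simulate"),
        vitals_interval_hours=config.vitals_interval_hours,
        labs_interval_hours=config.labs_interval_hours,
        derangement_effect=config.derangement_effect,
        ramp_hours=config.ramp_hours,
    )
    tables = generate_cohort(syn)
    n_sepsis_truth = sum(1 for g in tables.ground_truth.values() if g.is_sepsis)
    log.append(
        f"simulate: {config.n_encounters} encounters, {n_sepsis_truth} true sepsis, "
        f"{len(tables.observations)} observations"
    )
    paths = write_tables(tables, outdir)

    cohort, histories = label_and_match(
        tables,
        ExclusionConfig(),
        MatchingConfig(
            ratio=config.ratio,
            bin_hours=config.bin_hours,
            seed=stage_seed(config.seed, "match"),
        ),
        log,
    )
    paths["cohort"] = write_cohort(cohort, outdir / "cohort.csv")
    cdf = cohort_frame(cohort)

    indexed = cdf[cdf["label"].isin(["sepsis", "control"]) & cdf["index_time"].notna()]
    index_times = {
        r.encounter_id: r.index_time.to_pydatetime()
        for r in indexed.itertuples(index=False)
    }
    defs = {n: load_definition(n) for n in config.scores}
    sdf = score_table(
        histories, index_times, defs,
        lookbacks=config.lookbacks, modes=config.modes, offsets=config.offsets,
    )
    paths["scores"] = outdir / "scores.csv"
    sdf.to_csv(paths["scores"], index=False)
    log.append(f"score: {len(sdf)} score rows for {len(index_times)} encounters")

    samples = build_eval_samples(cdf, tables.encounters)
    mdf = evaluate_grid(
        sdf, samples,
        metrics=config.metrics, outcomes=config.outcomes,
        thresholds=config.thresholds, n_boot=config.n_boot,
        seed=stage_seed(config.seed, "evaluate"),
    )
    paths["metrics"] = outdir / "metrics.csv"
    mdf.to_csv(paths["metrics"], index=False)
    log.append(f"evaluate: {len(mdf)} metric estimates")

    paths["summary"] = outdir / "summary.csv"
    summarize_cohort(cdf, tables.encounters).to_csv(paths["summary"], index=False)

    paths["config"] = outdir / "config.resolved.yaml"
    config.to_yaml(paths["config"])
    for name in sorted(paths):
        log.append(f"checksum: {paths[name].name} sha256={_sha256(paths[name])}")
    paths["log"] = outdir / "run.log"
    paths["log"].write_text("\n".join(log) + "\n", encoding="utf-8")
    return paths
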