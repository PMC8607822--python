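# Methods

This note documents the models and procedures `wardscore` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Cohort construction

**Suspicion of infection (SOI).** An encounter's SOI is the earliest
qualifying culture/antibiotic pair: culture collection followed by an
antibiotic administration within 72 h, or an antibiotic followed by culture
procurement within 24 h. Both windows are treated as closed intervals —
boundary events at exactly 72 h / 24 h qualify — which matches common
operationalisations of the Sepsis-3 "suspected infection" proxy; the window
boundaries are module constants. The SOI time is the *earlier* event of the
pair in both branches, so that "time of onset = time of SOI" is well defined
when antibiotics precede the culture. Ties between simultaneous qualifying
pairs break lexicographically on (culture time, antibiotic time) for
determinism. `detect_soi` is brute-force over culture × antibiotic pairs
(event counts per encounter are tiny) and is property-tested against an
independent all-pairs oracle.

**Sepsis label and onset.** Sepsis = SOI plus qSOFA ≥ 2 evaluated *at* the
SOI time with the worst-value 24-h lookback (the pipeline's primary snapshot
policy). The evaluation window around SOI is not externally standardised, so
both the lookback and the mode are parameters of `ExclusionConfig`. Only the
first sepsis event per encounter is used; the index time of a sepsis case is
its onset.

**Exclusions.** Applied as pure, idempotent reason-code annotation: age
< 18; LOS < 48 h; encounter duration < 12 h or > 14 d; discharge < 12 h
after onset; surgery within the 72 h preceding index; fewer than one
observation of each required vital (HR, RR, SBP, temperature) or of both
creatinine and WBC in the 24 h before index; admission to hospice,
psychiatry, or obstetrics/gynecology; and sepsis present on admission.
"Sepsis on admission" is operationalised as a qualifying SOI with qSOFA ≥ 2
within the first 12 h of the stay (configurable window), and "one set of
vital signs" as at least one observation of each required vital
(configurable list) — both points on which reasonable definitions differ,
hence both exposed as parameters.

## Matched control indexing

Controls have no onset event, so index times are assigned to a 30:1
subsample such that the per-3-h-bin histogram of time-to-index equals 30×
the sepsis histogram wherever feasible. The assignment is per-bin: target
counts are ratio × case counts; bins fill scarcest-first (fewest eligible
controls first, a greedy feasibility heuristic); controls are drawn without
replacement; each selected control draws its exact index time uniformly over
the bin clipped to its feasible interval (index ≥ admission + bin start and
≤ discharge − 12 h). Index-dependent exclusions are re-applied after
assignment, with per-bin refills up to a resample budget; residual deficits
are reported per bin rather than silently reallocated, keeping the histogram
contract local and auditable. With an ample control pool the scaled case and
control histograms agree exactly (χ² = 0 over feasible bins) and the case
vs. control time-to-index distributions are statistically indistinguishable.

## Score engine

Seven scores are supported; their point bands live in YAML files
(`score_tables/*.yaml`), one per score, sourced from the original
publications: SIRS (Bone 1992), qSOFA (Sepsis-3, 2016), MEWS (Subbe 2001),
NEWS (RCP 2012), NEWS 2 (RCP 2017), SOFA (Vincent 1996), APACHE II (Knaus
1985). Bands are ordered inclusive-upper cutoffs (with explicit exclusive
bounds where a published threshold is strict, e.g. all SIRS criteria), so
every real value maps to exactly one band; values falling in gaps between
published integer bands (e.g. a charted RR of 24.3 under NEWS) take the next
band up.

**Snapshot resolution.** At evaluation time *t* with lookback *L*, the
window is the closed interval [t − L, t]. `recent` resolves each variable to
its last observation in the window; `worst` resolves each variable, *per
score*, to the observation maximising that component's points under that
score's bands, ties broken by recency. Missing variables contribute zero
points ("missing assumed normal") — implemented as absent-component-scores-
zero rather than value imputation. Values outside per-variable physiologic
guard ranges (e.g. SpO₂ > 100%) are reported and treated as absent.
Consciousness prefers the charted ACVPU code where present and otherwise
maps GCS (15 → alert; 13–14 → voice; 9–12 → pain; ≤ 8 → unresponsive; any
GCS < 15 is "not alert" for NEWS/NEWS 2 and qSOFA).

Ward adaptations for the ICU-native scores: SOFA respiration uses the most
recent paired PaO₂/FiO₂ in both modes (a ratio of mixed-time worst values is
not physiologic), and 3–4 points require a respiratory-support flag, else
the component caps at 2; SOFA cardiovascular uses vasopressor dose bands
from medication events in the window, else MAP < 70 → 1; APACHE II
chronic-health points default to 0 (not derivable from the data model;
configurable constant), creatinine points are not doubled (ARF not
ascertainable), and oxygenation uses the alveolar–arterial gradient only
when FiO₂ ≥ 0.5 with PaO₂/PaCO₂/FiO₂ all present, PaO₂ bands when FiO₂
< 0.5, and zero otherwise. NEWS 2's SpO₂ Scale 2 applies only when a
confirmed-hypercapnic-failure flag is set *and* Scale 2 is enabled
(disabled by default); under Scale 2, worst-mode SpO₂ selection still uses
Scale 1 bands — a documented approximation that is irrelevant while Scale 2
is off. With no hypercapnic flag and no new-confusion coding, NEWS and
NEWS 2 are provably identical, which the suite asserts.

Two invariants are property-tested over 10 000 random snapshots: worst-mode
totals dominate recent-mode totals, and adding an observation never lowers a
worst-mode total (for band-resolved variables; derived-pair variables are
recency-resolved by design).

**Series.** Scores are computed at whole-hour offsets −12…+12 anchored
exactly at the index time; offsets past discharge emit no value.

## Evaluation

AUROC is the Mann–Whitney concordance probability with ties counted ½;
AUPRC is step-wise average precision (Σ Δrecall × precision over descending
distinct thresholds, ties grouped) — trapezoidal PR interpolation is
deliberately avoided as it over-estimates the area. Both are computed via
scikit-learn and verified in the suite against exhaustive brute-force
oracles. Threshold metrics use positivity score ≥ threshold with the
validated thresholds as defaults; zero-denominator cases return flagged
NaNs. Confidence intervals are percentile bootstrap (2.5/50/97.5) over
evaluation samples — an encounter at a fixed offset, not a trajectory —
resampled with replacement at the original size, 1000 resamples by default;
single-class resamples are redrawn up to 10× then dropped with a count, and
estimates with > 50% dropped resamples are flagged unreliable. An optional
class-stratified bootstrap is provided as a sensitivity. Secondary outcomes
are death within (index, index + 48 h] and the composite adding any ICU
interval starting in that window.

## Synthetic ward generator

The generator emulates the statistical structure the analysis depends on,
not physiology:

- **Cohort shape.** Encounters Bernoulli-labeled sepsis at 3.3% prevalence;
  log-normal LOS (median ≈ 4.3 d) clipped to [12 h, 14 d]; log-normal
  time-to-onset (median ≈ 48 h, IQR ≈ 22–97 h) truncated to keep onset ≥
  12 h after admission and ≥ 12 h before discharge; sepsis cases get longer
  stays and ~12% in-hospital mortality, controls ~1%.
- **Observations.** Per-patient baselines (between-patient SD per variable)
  with AR(1) mean-reverting within-patient noise (τ = 8 h); vitals every
  4–8 h, labs roughly daily (gap ≤ 24 h so any 24-h pre-index window
  contains a panel); an extra vitals set and lab panel at onset, emulating a
  sepsis work-up. Mental status is generated but suppressed with probability
  1.0 by default, mirroring wards where it is not charted discretely; blood
  gases are never generated, which is why the ICU-native scores rely on
  their MAP/lab components here.
- **Derangement.** Cases ramp linearly toward abnormal over `ramp_hours`
  (12 h) before onset, plateau 24 h, then decay. Each sample's displacement
  is scaled by `derangement_effect` times an intensity draw that is a trough
  (U(0.05, 0.3)) with probability 0.35 and a spike (U(0.5, 1)) otherwise —
  intermittent derangement (spiking fevers, transient hypotension) is what
  makes the most recent reading an unreliable summary and gives worst-value
  resolution its advantage, reproducing the qualitative mode ordering.
  Per-unit full-ramp displacements are fixed in `synthetic.py` (e.g. HR
  +15 bpm, RR +5.5, SBP −18 mmHg per effect unit). The default effect (2.0)
  gives moderate separation; 3.0 ("strong") makes qSOFA capture at onset
  near-certain and is the setting used for end-to-end recovery checks and
  the acceptance script. At effect 0 case vitals are distributionally
  identical to controls.
- **Events.** Every case carries a qualifying SOI pair anchored at onset
  (culture-first with antibiotics in (0, 72] h, or antibiotic-first with
  culture in (0, 24] h, equiprobable). Controls draw one decoy category:
  isolated culture (20%), isolated antibiotic (20%), window-violating pair
  (5%, antibiotics then culture after > 24 h), or nothing — exercising the
  SOI algorithm's negative space. Cases with an ICU transfer may carry a
  dosed norepinephrine event.

What passing tests on this generator demonstrate: the pipeline recovers
known ground truth (labels, onsets, histogram contracts, mode ordering,
temporal shape) under controlled conditions. What they do not demonstrate:
performance on real wards — real data have correlated comorbidity,
treatment feedback, charting artifacts, unit errors, and informative
missingness that the generator does not model, and the labeled prevalence
here falls below the generated prevalence because cases whose worst-window
qSOFA misses 2 are (realistically) labeled controls.

## Numerical and reproducibility choices

Timestamps are second-resolution ISO-8601 in files and naive datetimes in
memory; all windows are closed unless stated otherwise; observation values
round-trip exactly through CSV. Units are fixed per variable with no unit
column and no auto-conversion (silent °F/°C coercion is a known EWS failure
mode); out-of-range values are rejected at the guard ranges, not coerced. A
single master seed derives per-stage seeds as SHA-256 of
`"{seed}:{stage}"` (mod 2³¹), so a full run — including the bootstrap grid,
which derives one sub-seed per metric combination — is byte-reproducible.
The acceptance script runs 5000 encounters with a 200-resample bootstrap at
offsets {−12, 0}; these sizes keep the whole recomputation under a couple
of minutes on one core while leaving ~100 labeled cases, enough for stable
AUROC ordering.

## Known limitations

- Band-gap values (non-integer observations between published integer bands)
  take the next band up; charted clinical data are integer-valued for the
  affected variables, so this is a corner case.
- The SOFA renal urine-output bands and the NEWS 2 Scale 2 worst-mode
  selection are carried in the fixtures but intentionally inert by default.
- Bootstrap resampling treats evaluation samples as independent across
  offsets; per-offset CIs are comparable but not jointly calibrated across
  the time axis.
- The generator's decoy rates, baselines, and displacement scales are
  package choices — no public per-variable distributions exist for the
  target cohort — and are documented constants rather than fitted values.
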