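# Methods

This note documents the models, numerical conventions and design choices
behind `swinescore`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Threshold derivation

Species-specific thresholds are derived from healthy baseline data of
surgically instrumented, conscious Yorkshire swine:

* **Window.** The 48 h immediately preceding injury (configurable via
  `BaselineWindow`); the window must precede injury.
* **Diurnal phases.** Samples are assigned to *day* or *night* by the
  facility light cycle (default lights on 06:00–18:00). Phase assignment
  is instantaneous at the transitions — the lights-on instant belongs to
  day, lights-off to night; no twilight ramp is modeled.
* **Statistics.** Per parameter × phase mean and *sample* SD (n−1
  denominator; the convention of common statistics software). WBC comes
  from blood draws, which carry no meaningful diurnal split at 8-h
  resolution, and is pooled across phases. Fewer than two samples in any
  requested cell is an error naming the cell.
* **Thresholds.** SIRS limits at mean ± 2 SD; NEWS2 band edges at
  mean ± {1, 2, 3, 4} SD. All thresholds are rounded **half away from
  zero** at the parameter's display precision (integer bpm, breaths/min
  and mmHg; 0.1 °C; 0.1 ×10³/µL). This convention reproduces the
  published reference tables where they are internally consistent
  (e.g. 130.2→130, 69.8→70, 39.88→39.9, 115.1→115, 84.9→85).

**Derived-vs-published audit.** The published reference tables print both
the thresholds and the means/SDs they came from, each rounded for display.
A few cells therefore cannot be recovered from the printed means to the
printed precision (they differ by one display unit — several RR cells, the
WBC upper limit, the night temperature rows, and the daytime heart-rate
extreme boundary). `audit_tables` compares every derivable cell and flags
these discrepancies explicitly; the package treats the printed means as
the authoritative inputs and does not reverse-engineer unrounded means.

The systolic-pressure NEWS2 rows have published band edges but no
published baseline mean/SD; the baseline values shipped in
`reference.py` (day 140.3 ± 13.9, night 132.5 ± 12.5 mmHg) were
back-derived so that the derivation reproduces every published SBP cell
exactly, and are marked as such.

## 2. Scoring conventions

Band-edge conventions, each covered by a unit test on both sides:

* **SIRS** criteria are *strict* inequalities beyond the rounded
  thresholds (a value exactly at the limit is not a hit); the state rule
  is ≥ 2 of 4 criteria.
* **SOFA.** Respiratory is a descending half-open chain (≥400→0, <400→1,
  <300→2, <200→3, <100→4). Hematological has closed upper edges (≤150→1,
  ≤100→2, ≤50→3, ≤20→4). Renal and hepatic values are rounded to one
  decimal before interval lookup so the printed inter-band gaps (e.g.
  1.4–1.5) cannot be hit; values below the lowest defined band (e.g.
  healthy porcine bilirubin ≈ 0.11 mg/dL) score 0 with an out-of-table
  note. Cardiovascular maps >70→0 and 60–70→1 (70 mmHg scores 1), with
  MAP rounded to an integer first. Neurological maps SNORT
  [10,11]→0, [8,10)→1, [6,8)→2, [4,6)→3, [2,4)→4; fractional SNORT
  values (medians of integer assessments) are accepted.
* **NEWS2.** The 0-point band (mean ± 1 SD) is closed; points are awarded
  on *reaching* the ±2/±3/±4 SD thresholds (1/2/3 points respectively, on
  either side), so the 1–2 SD gap scores 0. The 3-point band sets the
  extreme flag; positivity is total ≥ 5 or any extreme. SpO₂ uses absolute
  cut-offs (≥96→0, 94–95→1, 92–93→2, ≤91→3) and any SNORT below 10 is an
  extreme 3. Missing parameters (telemetry-only snapshots often lack SpO₂
  and SBP) score 0 points and are listed on the result — penalizing
  missingness would fabricate signal; the completeness field records the
  ambiguity about whether such parameters were available at every
  assessment in practice.

The SNORT rubric itself (sub-items with per-item point ranges summing to
the 2–11 scale, including a "response to offered food and treat" item) is
facility configuration; a documented default is provided and
`snort_score` validates sub-scores against it.

## 3. Synthetic cohort generator

The generator emulates the *statistical* structure of a 72-h conscious
penetrating-abdominal-trauma (PAT) study — it is phenomenological, not a
mechanistic ODE model of sepsis.

* **Baseline.** Telemetry = phase mean + stationary AR(1) noise with
  marginal SD `noise_sd` (default: the day/night SD average of the
  channel) and lag-1 autocorrelation at the telemetry step (default
  5-min step; 0.8–0.95 per channel, capturing within-animal
  autocorrelation without full mixed-effects machinery). Lab analytes get
  independent Gaussian noise per draw. `noise_sd = 0` yields exactly the
  phase means.
* **Injury response.** A normalized gamma kernel
  `g(t) = (t/τ)^k · e^{k(1−t/τ)}` (zero at injury, exactly 1 at the peak
  time τ, relaxing back at a rate set by k) scaled by a per-channel
  amplitude; biphasic channels (WBC, glucose) sum two kernels of opposite
  sign. Default amplitudes/peaks reproduce the published group-level
  extrema: HR peaking at 201 bpm at 8 h, WBC nadir 3.9 ×10³/µL at 8 h
  recovering by ~40 h, platelet nadir 132.2 at 32 h without full
  recovery, creatinine peaking at 2.0 mg/dL at 24 h and normalizing,
  bilirubin peaking late at 0.53 mg/dL, lactate 6.3 mM acutely, glucose
  174 mg/dL then hypoglycemia, cytokine impulses at 8 h with TNF-α at
  16 h, and a P/F ratio drifting from ~449 toward ~418 but never below
  400. Channels with no published baseline (MAP, activity, platelet and
  chemistry baselines, cytokine baselines) use values a veterinary
  clinician would call normal for ~50-kg female Yorkshire swine.
* **Physical floors.** Every channel has a configurable lower bound (HR,
  RR, WBC, platelets, MAP, temperature, etc. can never go below
  physiological minima); clipping is applied and logged.
* **SNORT.** A bounded integer process: healthy ceiling 11, post-injury
  pulled along a gamma-kernel target (default depression −4.6, deepest
  near 8 h, very slow recovery) with a mean-reverting AR(1) residual,
  rounded and clipped to [2, 11].
* **Mortality.** Each injured animal dies with probability 0.25; death
  times are log-normal (meanlog 2.83, sdlog 0.45) truncated to (0, 40] h
  — both aspects chosen so that an 8-animal cohort has an expected 75%
  survival and mean survival ≈ 58.5 h over the 72-h protocol, and that
  deaths fall before the 40-h assessment as the shrinking published
  denominators imply. Individual death times were never published; the
  generator is calibrated only to these group summaries. All records are
  censored strictly at death.
* **Reproducibility.** A single seed drives a `SeedSequence` tree
  (survival draw + one stream per animal); the same seed reproduces
  output files byte for byte.

**What the generator does not emulate.** Post-surgical stress at the t=0
draw (both groups scored non-zero immediately after surgery in vivo; the
simulated t=0 snapshot reflects the healthy pre-injury window), anesthesia
effects, electrolyte panels, inter-animal heterogeneity in response
amplitude, spleen-mediated count rebounds, and any imaging/histology.
Passing tests on synthetic cohorts therefore demonstrate correctness of
the *pipeline* under the assumed statistical structure, not fidelity of
any individual animal trajectory.

## 4. Pipeline conventions

* **Snapshot grid.** Timepoints at 0, 8, …, 72 h post-injury, matching
  the blood-draw schedule. Telemetry is averaged over the *trailing*
  window (t−8, t]; empty windows propagate missingness. The snapshot's
  phase is the phase at the draw instant.
* **SOFA baseline.** The ≥2-increase rule is anchored at each animal's
  own t = 0 (pre-injury) total — the only defensible anchor when
  "baseline" is otherwise undefined.
* **Prevalence.** Percent of *alive* animals meeting each state rule per
  timepoint × group; denominators shrink only through death (dead animals
  are censored, not imputed). Exact percentages are kept; display values
  round to the nearest integer.
* **Group comparison.** Exact Mann–Whitney per timepoint: the conditional
  null distribution is enumerated over all C(N, n₁) mid-rank assignments
  (exact under ties) for N ≤ 14, which covers the 4-vs-8 design; larger
  samples fall back to a seeded permutation estimate with an add-one
  p-value. Two-sided p counts assignments whose rank-sum deviates from
  its null mean at least as much as observed. Holm–Šídák step-down
  adjustment (via statsmodels) controls multiplicity across timepoints.
  Mixed-effects modeling of continuous endpoints is out of scope; the
  rank-based comparison is applied to the categorical score data.
* **Classification.** The computational analog of blinded review is a
  deterministic rule: injured iff NEWS2-positive at ≥ 2 timepoints or in
  a SIRS state within the first 16 h (both configurable); the result
  carries the triggering criteria as justification. Animals censored
  before a second timepoint are labelled from their single snapshot.
* **Outlier annotation.** `robust_outlier_flag` marks values with
  |value − median| > k · 1.4826 · MAD (k = 5 by default). It only
  annotates, never removes; a zero MAD degenerates the scale (warning
  issued), in which case any nonzero deviation exceeds the threshold.
  This is a simple robust flag, not a reimplementation of any specific
  commercial outlier routine.

## 5. Problem sizes and tolerances in the test suite

The suite runs entirely on synthetic data generated at test time. Sizes
are the package's own choices: telemetry at 5-min (default) to 60-min
steps; threshold-recovery checks over 100 replicate 8-animal baseline
cohorts (3-SE criterion with an autocorrelation-adjusted effective n);
survival calibration over 10 000 replicate survival draws (±0.01 band
around 0.75); oracle-equivalence checks over 200 enumerated Mann–Whitney
datasets and 1 000 random snapshots; the qualitative cohort-level pattern
(injured group fully NEWS2-positive at ≥ 8 of 10 timepoints with all
control prevalence columns at zero) over 100 replicate cohorts with a 95%
pass criterion. Numeric comparisons use exact equality for rounded
thresholds and band lookups, and Monte-Carlo-appropriate (3–4 SE) bands
for stochastic quantities.

## 6. Known limitations

* Trajectories are group-mean kinetics plus noise; no per-animal random
  effects on amplitudes or peak times, so between-animal spread late in
  the course is understated relative to real cohorts.
* The published SIRS prevalence fluctuations mid-course (partial criteria
  crossings driven by temperature/RR excursions) are only weakly
  reproduced, since RR and temperature effects are small by design.
* SpO₂ is not simulated (it was not telemetered continuously); NEWS2 on
  simulated cohorts runs with the missing-parameter convention.
* The exact SNORT sub-item catalogue is configuration, not data; only the
  2–11 total scale is normative.
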