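# swinescore

Pig-specific sepsis severity scoring for conscious Yorkshire swine trauma
studies: species-adapted SIRS criteria, an adapted SOFA score whose
neurological component is the swine neurological observed response test
(SNORT), and a pig NEWS2 — plus the baseline-derived threshold machinery,
a synthetic cohort generator, and an end-to-end analysis pipeline.

## Who this is for

Preclinical researchers running conscious large-animal models of abdominal
sepsis (e.g. fecal peritonitis after penetrating abdominal trauma) who need
clinically interpretable severity scores. Human score thresholds do not
transfer to swine, whose resting heart rate, respiration rate, temperature
and leukocyte counts differ substantially and oscillate with the 12-h
facility light cycle. The package derives species- and phase-specific
thresholds from healthy baseline telemetry and applies the standard state
rules on top of them.

## The model

**Threshold derivation.** For each parameter and light phase
(day = lights on, night = lights off), thresholds are placed at

```
mean ± k·SD        (k = 2 for SIRS; k = 1, 2, 3, 4 for the NEWS2 bands)
```

computed over the 48 h of baseline telemetry immediately preceding injury
(WBC from the baseline blood draws, pooled across phases; sample SD;
half-away-from-zero rounding at display precision).

**State rules.**

* *SIRS state*: ≥ 2 of the 4 criteria (HR, RR, temperature, WBC) strictly
  outside their mean ± 2 SD band.
* *SOFA*: six organ components (P/F ratio, creatinine, bilirubin,
  platelets, MAP, SNORT), 0–4 each, total 0–24; an increase of ≥ 2 over the
  animal's own pre-injury total indicates organ dysfunction (sepsis, since
  infection is given by the study design).
* *NEWS2*: per-parameter points 0–3 from the ±SD bands (SpO₂ on absolute
  cut-offs; SNORT < 10 is an extreme 3); positive at total ≥ 5 **or** any
  single extreme (3-point) parameter.

The synthetic generator produces control animals fluctuating around the
phase means with AR(1) noise and injured animals with gamma-kernel injury
impulses (`g(t) = (t/τ)^k e^{k(1−t/τ)}`, peaking exactly at τ), a
truncated log-normal death process, and a bounded integer SNORT walk —
see `docs/methods.md`.

## Worked example

```python
import swinescore as sw

# canonical tables derived from the 48-animal healthy baseline statistics
sirs, news2 = sw.reference_tables()
print(sirs.table[["lower", "upper"]])
#                   lower  upper
# parameter phase
# hr        day      70.0  130.0
#           night    68.0  116.0
# rr        day      14.0   30.0
#           night    10.0   22.0
# temp      day      37.1   39.9
#           night    37.9   39.7
# wbc       pooled   12.1   26.1

# an injured animal at the 8-h peak of its course
snap = sw.VitalsSnapshot(animal_id="pat01", time_h=8.0, phase="day",
                         hr=201.0, rr=20.0, temp=39.2, wbc=3.9,
                         platelets=132.2, creatinine=2.0, bilirubin=0.53,
                         map=100.0, pf_ratio=418.15, snort=6.6)

sw.evaluate_sirs(snap, sirs)
# SirsResult(criteria={'hr': True, 'rr': False, 'temp': False, 'wbc': True},
#            n_met=2, sirs_state=True, complete=True)

sw.sofa_total(snap, baseline_total=0)
# SofaResult(components={'respiratory': 0, 'renal': 1, 'hepatic': 0,
#                        'hematological': 1, 'cardiovascular': 0,
#                        'neurological': 2},
#            total=4, complete=True, baseline_total=0, sepsis_flag=True)

sw.news2_total(snap, news2)
# News2Result(points={'rr': 0, 'spo2': 0, 'sbp': 0, 'hr': 3, 'snort': 3,
#                     'temp': 0},
#             total=6, extreme_flag=True, positive=True,
#             missing=('spo2', 'sbp'))
```

Reading the output: heart rate 201 bpm exceeds the daytime SIRS threshold
of 130 and WBC 3.9 falls below 12.1, so two criteria are met and the animal
is in a SIRS state. SOFA picks up mild thrombocytopenia (platelets
132.2 ≤ 150 → 1), the creatinine peak (2.0 → 1) and neurological depression
(SNORT 6.6 → 2), total 4 ≥ baseline + 2, flagging organ dysfunction. For
NEWS2, HR 201 is beyond the +4 SD boundary (160) and SNORT 6.6 is below 10 —
two extreme variations, total 6, unambiguously positive.

A full in-silico study from the shell:

```bash
swinescore simulate --out cohort/ --seed 3              # telemetry, labs, SNORT, manifest
swinescore derive-thresholds --baseline cohort/ --out thresholds.yaml
swinescore score --cohort cohort/ --thresholds thresholds.yaml --out scores.csv
swinescore report --scores scores.csv --out report/     # prevalence, comparisons, survival
swinescore classify --scores scores.csv
```

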