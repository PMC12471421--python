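"""SIRS, SOFA (with SNORT) and NEWS2 scoring engines for swine.

A :class:`VitalsSnapshot` bundles everything scoreable for one animal at
one timepoint.  Scoring is pure: the same snapshot and the same threshold
tables always give the same result.

State rules:

* SIRS state is declared when at least two of the four criteria (HR, RR,
  temperature, WBC) fall strictly outside the phase-specific mean ± 2 SD
  thresholds.
* SOFA sums six organ components (0–4 each, total 0–24); an increase of
  ≥ 2 over the animal's own baseline total indicates organ dysfunction
  (the sepsis flag, infection being given by the study design).
* NEWS2 sums per-parameter points (0–3); positive at total ≥ 5 or any
  single parameter in a 3-point ("extreme") band.

Missing values are explicit: SIRS reports per-criterion ``None`` and a
completeness flag; NEWS2 scores missing parameters as 0 points and lists
them (penalizing missingness would fabricate signal); SOFA marks the total
partial, leaving the sepsis flag undefined unless the partial total
already clears the baseline + 2 rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .thresholds import News2BandTable, SirsThresholdTable

logger = logging.getLogger(__name__)

SIRS_CRITERIA = ("hr", "rr", "temp", "wbc")
SOFA_SYSTEMS = ("respiratory", "renal", "hepatic", "hematological",
                "cardiovascular", "neurological")
NEWS2_PARAMETERS = ("rr", "spo2", "sbp", "hr", "snort", "temp")


@dataclass
class VitalsSnapshot:
    """All scoreable parameters for one animal at one timepoint.

    Times are hours relative to injury; ``phase`` is the light-cycle phase
    at the timepoint.  Missing measurements are ``None``.  Units: hr bpm,
    rr breaths/min, temp °C, wbc and platelets 10³/µL, creatinine and
    bilirubin mg/dL, map and sbp mmHg, pf_ratio dimensionless
    (PaO₂/FiO₂), snort 2–11 rubric points, spo2 %.
    """

    animal_id: str
    time_h: float
    phase: str
    hr: float | None = None
    rr: float | None = None
    temp: float | None = None
    wbc: float | None = None
    platelets: float | None = None
    creatinine: float | None = None
    bilirubin: float | None = None
    map: float | None = None
    pf_ratio: float | None = None
    snort: float | None = None
    spo2: float | None = None
    sbp: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("day", "night"):
            raise ValueError("phase must be 'day' or 'night'")
        positive = ("hr", "rr", "wbc", "platelets", "map", "sbp", "pf_ratio")
        for name in positive:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.spo2 is not None and not 0 < self.spo2 <= 100:
            raise ValueError(f"spo2 must be in (0, 100], got {self.spo2}")
        if self.snort is not None and not 2 <= self.snort <= 11:
            raise ValueError(f"snort must be in [2, 11], got {self.snort}")


# ---------------------------------------------------------------------------
# SIRS


@dataclass(frozen=True)
class SirsResult:
    criteria: Mapping[str, bool | None]
    n_met: int
    sirs_state: bool
    complete: bool


def evaluate_sirs(snapshot: VitalsSnapshot, table: SirsThresholdTable) -> SirsResult:
    """Flag each SIRS criterion; a criterion is met when the value lies
    strictly above the upper or strictly below the lower threshold for the
    snapshot's phase (WBC uses the pooled thresholds)."""
    criteria: dict[str, bool | None] = {}
    for param in SIRS_CRITERIA:
        value = getattr(snapshot, param)
        if value is None:
            criteria[param] = None
            continue
        phase = "pooled" if param == "wbc" else snapshot.phase
        upper, lower = table.get(param, phase)
        criteria[param] = bool(value > upper or value < lower)
    known = [v for v in criteria.values() if v is not None]
    n_met = sum(known)
    return SirsResult(criteria=criteria, n_met=n_met,
                      sirs_state=n_met >= 2, complete=len(known) == len(SIRS_CRITERIA))


# ---------------------------------------------------------------------------
# SOFA

# Band conventions follow the adapted swine table: the respiratory chain is
# half-open descending (≥400 → 0, then <400, <300, <200, <100); the
# hematological chain has closed upper edges (≤150, ≤100, ≤50, ≤20); renal
# and hepatic values are rounded to one decimal so the printed interval
# gaps (e.g. 1.4–1.5) cannot be hit; cardiovascular 60–70 scores 1 with
# > 70 scoring 0; neurological maps SNORT ranges 11–10/9–8/7–6/5–4/3–2.


def _sofa_component(system: str, value: float) -> tuple[int, str | None]:
    if system == "respiratory":
        if value >= 400:
            return 0, None
        if value >= 300:
            return 1, None
        if value >= 200:
            return 2, None
        if value >= 100:
            return 3, None
        return 4, None
    if system == "renal":
        v = round_half_away(value, 1)
        if v < 0.3:
            return 0, f"creatinine {value} below lowest band (0.3)"
        if v <= 1.4:
            return 0, None
        if v <= 2.4:
            return 1, None
        if v <= 3.4:
            return 2, None
        if v <= 4.9:
            return 3, None
        return 4, None
    if system == "hepatic":
        v = round_half_away(value, 1)
        if v < 0.3:
            return 0, f"bilirubin {value} below lowest band (0.3)"
        if v <= 0.6:
            return 0, None
        if v <= 2.0:
            return 1, None
        if v <= 5.0:
            return 2, None
        if v <= 10.0:
            return 3, None
        return 4, None
    if system == "hematological":
        if value <= 20:
            return 4, None
        if value <= 50:
            return 3, None
        if value <= 100:
            return 2, None
        if value <= 150:
            return 1, None
        return 0, None
    if system == "cardiovascular":
        v = round_half_away(value, 0)
        if v > 70:
            return 0, None
        if v >= 60:
            return 1, None
        if v >= 50:
            return 2, None
        if v >= 40:
            return 3, None
        return 4, None
    if system == "neurological":
        if value >= 10:
            return 0, None
        if value >= 8:
            return 1, None
        if value >= 6:
            return 2, None
        if value >= 4:
            return 3, None
        return 4, None
    raise ValueError(f"unknown SOFA system: {system}")


def sofa_component(system: str, value: float) -> int:
    """Score one organ system (0–4) by band lookup."""
    score, note = _sofa_component(system, value)
    if note:
        logger.debug("SOFA %s: %s", system, note)
    return score


_SOFA_INPUT = {"respiratory": "pf_ratio", "renal": "creatinine",
               "hepatic": "bilirubin", "hematological": "platelets",
               "cardiovascular": "map", "neurological": "snort"}


@dataclass(frozen=True)
class SofaResult:
    components: Mapping[str, int | None]
    total: int
    complete: bool
    baseline_total: int
    sepsis_flag: bool | None
    notes: tuple[str, ...] = ()


def sofa_total(snapshot: VitalsSnapshot, baseline_total: int = 0) -> SofaResult:
    """Total SOFA and the ≥ 2-over-baseline organ-dysfunction flag.

    Missing components leave the total partial; the flag is then undefined
    (``None``) unless the partial total already reaches baseline + 2.
    """
    components: dict[str, int | None] = {}
    notes: list[str] = []
    for system in SOFA_SYSTEMS:
        value = getattr(snapshot, _SOFA_INPUT[system])
        if value is None:
            components[system] = None
            continue
        score, note = _sofa_component(system, value)
        components[system] = score
        if note:
            notes.append(note)
    known = [v for v in components.values() if v is not None]
    total = int(sum(known))
    complete = len(known) == len(SOFA_SYSTEMS)
    if complete:
        flag: bool | None = total - baseline_total >= 2
    else:
        flag = True if total - baseline_total >= 2 else None
    return SofaResult(components=components, total=total, complete=complete,
                      baseline_total=baseline_total, sepsis_flag=flag,
                      notes=tuple(notes))


# ---------------------------------------------------------------------------
# NEWS2


@dataclass(frozen=True)
class News2Result:
    points: Mapping[str, int]
    total: int
    extreme_flag: bool
    positive: bool
    missing: tuple[str, ...] = ()


def news2_points(parameter: str, value: float, phase: str,
                 bands: News2BandTable) -> tuple[int, bool]:
    """Points (0–3) and extreme flag for one parameter.

    Derived parameters: 0 inside/near the 0-point band, 1/2/3 on reaching
    the ±2/±3/±4 SD thresholds (the 3-point band is extreme).  SpO2 uses
    absolute cut-offs; any SNORT below the cut-off is an extreme 3.
    """
    if parameter == "spo2":
        v = round_half_away(value, 0)
        for cutoff, pts in bands.spo2_bands:
            if v >= cutoff:
                return pts, pts == 3
        return 3, True
    if parameter == "snort":
        if value < bands.snort_cutoff:
            return 3, True
        return 0, False
    row = bands.row(parameter, phase)  # raises for unknown parameter
    if value >= row["upper3"]:
        return 3, True
    if value >= row["upper2"]:
        return 2, False
    if value >= row["upper1"]:
        return 1, False
    if value <= row["lower3"]:
        return 3, True
    if value <= row["lower2"]:
        return 2, False
    if value <= row["lower1"]:
        return 1, False
    return 0, False


def news2_total(snapshot: VitalsSnapshot, bands: News2BandTable,
                parameters: Sequence[str] = NEWS2_PARAMETERS) -> News2Result:
    """Sum NEWS2 points over available parameters and apply the positivity
    rule (total ≥ 5, or any extreme variation)."""
    points: dict[str, int] = {}
    missing: list[str] = []
    extreme = False
    for param in parameters:
        value = getattr(snapshot, param)
        if value is None:
            points[param] = 0
            missing.append(param)
            continue
        pts, ext = news2_points(param, value, snapshot.phase, bands)
        points[param] = pts
        extreme = extreme or ext
    if len(missing) == len(parameters):
        raise ValueError("cannot score NEWS2: every parameter is missing")
    total = int(sum(points.values()))
    return News2Result(points=points, total=total, extreme_flag=extreme,
                       positive=total >= 5 or extreme, missing=tuple(missing))


# ---------------------------------------------------------------------------
# SNORT rubric


@dataclass(frozen=True)
class SnortRubric:
    """Neurological assessment rubric: ordered sub-items with point ranges.

    The default items sum to the 2–11 range of the adapted ovine
    neurological assessment; the exact sub-item catalogue is facility
    configuration, so the rubric is data-driven.
    """

    items: tuple[tuple[str, int, int], ...] = (
        ("alertness", 1, 3),
        ("locomotion", 0, 2),
        ("posture", 0, 2),
        ("response_to_offered_food_and_treat", 1, 2),
        ("response_to_handler", 0, 2),
    )

    def __post_init__(self) -> None:
        lo = sum(i[1] for i in self.items)
        hi = sum(i[2] for i in self.items)
        if not (lo >= 2 and hi <= 11):
            raise ValueError(f"rubric range [{lo}, {hi}] outside [2, 11]")
        for name, mn, mx in self.items:
            if mn > mx:
                raise ValueError(f"item {name}: min exceeds max")


DEFAULT_SNORT_RUBRIC = SnortRubric()


def snort_score(subscores: Mapping[str, float] | Sequence[float],
                rubric: SnortRubric = DEFAULT_SNORT_RUBRIC) -> int:
    """Sum rubric sub-scores, validated against item ranges, clipped to [2, 11]."""
    if isinstance(subscores, Mapping):
        values = [subscores[name] for name, _, _ in rubric.items]
    else:
        values = list(subscores)
        if len(values) != len(rubric.items):
            raise ValueError("one sub-score per rubric item required")
    total = 0.0
    for (name, mn, mx), v in zip(rubric.items, values):
        if not mn <= v <= mx:
            raise ValueError(f"sub-score {name}={v} outside [{mn}, {mx}]")
        total += v
    return int(np.clip(round(total), 2, 11))


# ---------------------------------------------------------------------------
# snapshot I/O helpers

_SNAPSHOT_FIELDS = ("hr", "rr", "temp", "wbc", "platelets", "creatinine",
                    "bilirubin", "map", "pf_ratio", "snort", "spo2", "sbp")


def snapshots_from_wide(frame: pd.DataFrame) -> list[VitalsSnapshot]:
    """Read snapshots from a wide table (one row per animal × timepoint)."""
    out = []
    for _, row in frame.iterrows():
        kwargs = {f: (None if f not in row or pd.isna(row[f]) else float(row[f]))
                  for f in _SNAPSHOT_FIELDS}
        out.append(VitalsSnapshot(animal_id=str(row["animal_id"]),
                                  time_h=float(row["time_h"]),
                                  phase=str(row["phase"]), **kwargs))
    return out


def snapshots_from_tidy(frame: pd.DataFrame) -> list[VitalsSnapshot]:
    """Read snapshots from tidy rows (animal_id, time_h, phase, parameter, value)."""
    wide = frame.pivot_table(index=["animal_id", "time_h", "phase"],
                             columns="parameter", values="value").reset_index()
    return snapshots_from_wide(wide)


def snapshots_to_wide(snapshots: Sequence[VitalsSnapshot]) -> pd.DataFrame:
    rows = []
    for s in snapshots:
        row = {"animal_id": s.animal_id, "time_h": s.time_h, "phase": s.phase}
        row.update({f: getattr(s, f) for f in _SNAPSHOT_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows)
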