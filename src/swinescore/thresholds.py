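"""Derivation of pig-specific SIRS thresholds and NEWS2 bands from baseline data.

The procedure mirrors how species-specific early-warning thresholds are
established from healthy instrumented animals: take the 48 h of telemetry
immediately preceding injury, split samples into 12-h day/night phases by
the facility light cycle, compute per-parameter phase means and sample
standard deviations (WBC comes from blood draws and is pooled across
phases), and place thresholds at ``mean ± k·SD`` rounded to each
parameter's display precision.

* SIRS thresholds: mean ± 2 SD (upper/lower per phase).
* NEWS2 bands: 0-point band mean ± 1 SD; crossing ±2 SD scores 1 point,
  ±3 SD scores 2 points, ±4 SD scores 3 points (an "extreme" variation).
  SpO2 and SNORT rows are fixed absolute cut-offs, not derived.

Rounding is half-away-from-zero at the display precision (integer bpm and
mmHg, 0.1 °C, 0.1 ×10³/µL).  :func:`audit_tables` compares a derived table
against the published reference tables cell by cell and flags the cells
that the published (rounded) means cannot reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from ._util import round_half_away
from .cohortsim import AnimalCourse

DAY = "day"
NIGHT = "night"
POOLED = "pooled"

#: parameters whose thresholds are derived per phase from telemetry
DIURNAL_PARAMS = ("hr", "rr", "temp", "map", "sbp")
#: blood-draw parameters pooled across phases
POOLED_PARAMS = ("wbc",)

SIRS_PARAMS = (("hr", DAY), ("hr", NIGHT), ("rr", DAY), ("rr", NIGHT),
               ("temp", DAY), ("temp", NIGHT), ("wbc", POOLED))
NEWS2_PARAMS = (("rr", DAY), ("rr", NIGHT), ("sbp", DAY), ("sbp", NIGHT),
                ("hr", DAY), ("hr", NIGHT), ("temp", DAY), ("temp", NIGHT))


# ---------------------------------------------------------------------------
# light cycle and diurnal partitioning


@dataclass(frozen=True)
class LightCycle:
    """Facility light cycle defining two 12-h phases (day = lights on)."""

    lights_on: float = 6.0
    lights_off: float = 18.0

    def __post_init__(self) -> None:
        if (self.lights_off - self.lights_on) % 24 != 12:
            raise ValueError("light cycle must define two 12-h phases")

    def phase_of_clock(self, clock_hours) -> np.ndarray:
        h = np.asarray(clock_hours, dtype=float) % 24.0
        on, off = self.lights_on % 24.0, self.lights_off % 24.0
        day = (h >= on) & (h < off) if on < off else (h >= on) | (h < off)
        out = np.where(day, DAY, NIGHT)
        return out if out.ndim else str(out)

    def phase_of_time(self, timestamps) -> np.ndarray:
        ts = pd.DatetimeIndex(pd.Series(timestamps))
        if ts.isna().any():
            raise ValueError("samples without a timestamp cannot be phased")
        clock = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
        return self.phase_of_clock(np.asarray(clock))


def partition_diurnal(frame: pd.DataFrame, cycle: LightCycle = LightCycle(),
                      time_col: str = "timestamp") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split timestamped samples into (day, night) frames; counts conserved."""
    if frame[time_col].isna().any():
        raise ValueError("samples without a timestamp cannot be phased")
    phase = cycle.phase_of_time(frame[time_col])
    day = frame[phase == DAY]
    night = frame[phase == NIGHT]
    return day, night


# ---------------------------------------------------------------------------
# baseline window and diurnal statistics


@dataclass(frozen=True)
class BaselineWindow:
    """Healthy-baseline window in hours relative to injury (default −48..0 h)."""

    start_h: float = -48.0
    end_h: float = 0.0

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ValueError("window end must be after start")
        if self.end_h > 0:
            raise ValueError("baseline window must precede injury")

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


class DiurnalStats:
    """Per parameter × phase mean/SD/n, as a tidy DataFrame.

    Index: (parameter, phase); columns: mean, sd, n.  Sample SD (n−1
    denominator) throughout.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"mean", "sd", "n"}
        if not required.issubset(table.columns):
            raise ValueError(f"stats table needs columns {sorted(required)}")
        if (table["sd"] < 0).any():
            raise ValueError("sd must be >= 0")
        self.table = table

    @classmethod
    def from_summary(cls, summary: Mapping[tuple[str, str], tuple[float, float]],
                     n: int = reference.BASELINE_N) -> "DiurnalStats":
        """Build from already-summarized (mean, sd) pairs, e.g. a published table."""
        idx = pd.MultiIndex.from_tuples(summary.keys(), names=["parameter", "phase"])
        rows = [(m, s, n) for m, s in summary.values()]
        return cls(pd.DataFrame(rows, index=idx, columns=["mean", "sd", "n"]))

    def get(self, parameter: str, phase: str) -> tuple[float, float]:
        try:
            row = self.table.loc[(parameter, phase)]
        except KeyError as exc:
            raise KeyError(f"no baseline statistics for {parameter}/{phase}") from exc
        return float(row["mean"]), float(row["sd"])

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.table.index


def compute_diurnal_stats(courses: Iterable[AnimalCourse],
                          window: BaselineWindow = BaselineWindow(),
                          cycle: LightCycle = LightCycle(),
                          diurnal_params: Sequence[str] = DIURNAL_PARAMS,
                          pooled_params: Sequence[str] = POOLED_PARAMS) -> DiurnalStats:
    """Pool baseline-window samples across a cohort into diurnal statistics.

    Telemetry parameters get day and night cells; blood-draw parameters are
    pooled across the window's draws.  Raises if any requested cell has
    fewer than two samples, naming the parameter/phase.
    """
    courses = list(courses)
    tel = pd.concat(
        [c.telemetry[(c.telemetry["time_h"] >= window.start_h)
                     & (c.telemetry["time_h"] <= window.end_h)]
         for c in courses], ignore_index=True)
    labs = pd.concat(
        [c.labs[(c.labs["time_h"] >= window.start_h)
                & (c.labs["time_h"] <= window.end_h)]
         for c in courses], ignore_index=True)

    rows = {}
    if len(tel):
        tel = tel.copy()
        tel["phase"] = cycle.phase_of_time(tel["timestamp"])
    for param in diurnal_params:
        sub = tel[tel["channel"] == param] if len(tel) else tel
        for phase in (DAY, NIGHT):
            vals = sub[sub["phase"] == phase]["value"].to_numpy() if len(sub) else np.empty(0)
            if vals.size < 2:
                raise ValueError(
                    f"insufficient baseline data for {param}/{phase} "
                    f"({vals.size} samples; need >= 2)")
            rows[(param, phase)] = (vals.mean(), vals.std(ddof=1), vals.size)
    for param in pooled_params:
        vals = labs[labs["analyte"] == param]["value"].to_numpy()
        if vals.size < 2:
            raise ValueError(
                f"insufficient baseline data for {param}/{POOLED} "
                f"({vals.size} samples; need >= 2)")
        rows[(param, POOLED)] = (vals.mean(), vals.std(ddof=1), vals.size)

    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["parameter", "phase"])
    return DiurnalStats(pd.DataFrame(list(rows.values()), index=idx,
                                     columns=["mean", "sd", "n"]))


# ---------------------------------------------------------------------------
# threshold tables


class SirsThresholdTable:
    """SIRS thresholds: per (parameter, phase) rounded mean ± k·SD."""

    def __init__(self, table: pd.DataFrame, k_sd: float = 2.0):
        if not (table["lower"] <= table["upper"]).all():
            raise ValueError("lower threshold above upper")
        self.table = table
        self.k_sd = k_sd

    def get(self, parameter: str, phase: str) -> tuple[float, float]:
        """Return (upper, lower) for a parameter/phase."""
        try:
            row = self.table.loc[(parameter, phase)]
        except KeyError as exc:
            raise KeyError(f"no SIRS thresholds for {parameter}/{phase}") from exc
        return float(row["upper"]), float(row["lower"])


def derive_sirs_table(stats: DiurnalStats, k_sd: float = 2.0,
                      params: Sequence[tuple[str, str]] = SIRS_PARAMS) -> SirsThresholdTable:
    """Thresholds at ``round(mean ± k·SD)`` in display precision."""
    rows = {}
    for param, phase in params:
        mean, sd = stats.get(param, phase)  # raises on missing parameter
        dec = reference.DISPLAY_DECIMALS.get(param, 1)
        rows[(param, phase)] = (
            round_half_away(mean - k_sd * sd, dec),
            round_half_away(mean + k_sd * sd, dec),
            mean, sd)
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["parameter", "phase"])
    table = pd.DataFrame(list(rows.values()), index=idx,
                         columns=["lower", "upper", "mean", "sd"])
    return SirsThresholdTable(table, k_sd=k_sd)


_BAND_COLS = ("lower3", "lower2", "lower1", "zero_lo", "zero_hi",
              "upper1", "upper2", "upper3")


class News2BandTable:
    """NEWS2 bands per (parameter, phase) plus the fixed SpO2/SNORT rows.

    Columns: ``zero_lo``/``zero_hi`` (0-point band, mean ± 1 SD),
    ``lower1``..``lower3`` and ``upper1``..``upper3`` (1/2/3-point
    thresholds at mean ∓/± 2, 3, 4 SD).  Reaching a threshold scores its
    points; the 3-point band is the extreme flag.
    """

    def __init__(self, table: pd.DataFrame,
                 spo2_bands=reference.SPO2_BANDS,
                 snort_cutoff: float = reference.SNORT_NEWS2_CUTOFF):
        ordered = table[list(_BAND_COLS)].to_numpy(dtype=float)
        if (np.diff(ordered, axis=1) < 0).any():
            raise ValueError("band boundaries must be non-decreasing")
        self.table = table
        self.spo2_bands = tuple(spo2_bands)
        self.snort_cutoff = snort_cutoff

    def row(self, parameter: str, phase: str) -> pd.Series:
        try:
            return self.table.loc[(parameter, phase)]
        except KeyError as exc:
            raise KeyError(f"no NEWS2 bands for {parameter}/{phase}") from exc

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.table.index


def derive_news2_table(stats: DiurnalStats,
                       params: Sequence[tuple[str, str]] = NEWS2_PARAMS) -> News2BandTable:
    """Band edges at ``round(mean ± {1,2,3,4}·SD)`` in display precision."""
    rows = {}
    for param, phase in params:
        mean, sd = stats.get(param, phase)  # raises on missing parameter
        dec = reference.DISPLAY_DECIMALS.get(param, 1)
        r = lambda v: round_half_away(v, dec)
        rows[(param, phase)] = (
            r(mean - 4 * sd), r(mean - 3 * sd), r(mean - 2 * sd),
            r(mean - sd), r(mean + sd),
            r(mean + 2 * sd), r(mean + 3 * sd), r(mean + 4 * sd))
    idx = pd.MultiIndex.from_tuples(rows.keys(), names=["parameter", "phase"])
    return News2BandTable(pd.DataFrame(list(rows.values()), index=idx,
                                       columns=list(_BAND_COLS)))


# ---------------------------------------------------------------------------
# derived-vs-published audit


def audit_tables(sirs: SirsThresholdTable | None = None,
                 news2: News2BandTable | None = None,
                 printed_sirs=None, printed_news2=None) -> pd.DataFrame:
    """Compare derived tables against the published reference cell by cell.

    Returns a tidy report (table, parameter, phase, cell, derived, printed,
    match).  Cells the published rounded means cannot reproduce appear with
    ``match == False``; they are reported, never silently matched.
    """
    printed_sirs = reference.PRINTED_SIRS if printed_sirs is None else printed_sirs
    printed_news2 = reference.PRINTED_NEWS2 if printed_news2 is None else printed_news2
    records = []
    if sirs is not None:
        for (param, phase), (p_upper, p_lower) in printed_sirs.items():
            if (param, phase) not in sirs.table.index:
                continue
            d_upper, d_lower = sirs.get(param, phase)
            for cell, d, p in (("upper", d_upper, p_upper), ("lower", d_lower, p_lower)):
                records.append(("sirs", param, phase, cell, d, p,
                                bool(np.isclose(d, p))))
    if news2 is not None:
        for (param, phase), printed in printed_news2.items():
            if (param, phase) not in news2:
                continue
            row = news2.row(param, phase)
            cells = {"lower3": printed["lower3"], "lower2": printed["lower2"],
                     "lower1": printed["lower1"],
                     "zero_lo": printed["zero"][0], "zero_hi": printed["zero"][1],
                     "upper1": printed["upper1"], "upper2": printed["upper2"],
                     "upper3": printed["upper3"]}
            for cell, p in cells.items():
                if p is None:
                    continue
                d = float(row[cell])
                records.append(("news2", param, phase, cell, d, float(p),
                                bool(np.isclose(d, float(p)))))
    return pd.DataFrame(records, columns=["table", "parameter", "phase",
                                          "cell", "derived", "printed", "match"])


# ---------------------------------------------------------------------------
# serialization


def save_thresholds(path: str | Path, sirs: SirsThresholdTable,
                    news2: News2BandTable, provenance: Mapping | None = None) -> None:
    """Write both tables plus a provenance block to YAML."""
    doc = {
        "provenance": dict(provenance or {}),
        "rounding": "half away from zero at display precision",
        "k_sd": sirs.k_sd,
        "sirs": {f"{p}/{ph}": {k: float(v) for k, v in row.items()}
                 for (p, ph), row in sirs.table.iterrows()},
        "news2": {f"{p}/{ph}": {k: float(v) for k, v in row.items()}
                  for (p, ph), row in news2.table.iterrows()},
        "news2_fixed": {
            "spo2_bands": [list(b) for b in news2.spo2_bands],
            "snort_cutoff": news2.snort_cutoff,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_thresholds(path: str | Path) -> tuple[SirsThresholdTable, News2BandTable]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)

    def to_frame(section):
        idx, rows = [], []
        for key, row in section.items():
            param, phase = key.split("/")
            idx.append((param, phase))
            rows.append(row)
        frame = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
            idx, names=["parameter", "phase"]))
        return frame

    sirs = SirsThresholdTable(to_frame(doc["sirs"]), k_sd=doc.get("k_sd", 2.0))
    fixed = doc.get("news2_fixed", {})
    news2 = News2BandTable(
        to_frame(doc["news2"]),
        spo2_bands=tuple(tuple(b) for b in fixed.get("spo2_bands", reference.SPO2_BANDS)),
        snort_cutoff=fixed.get("snort_cutoff", reference.SNORT_NEWS2_CUTOFF))
    return sirs, news2


def reference_tables() -> tuple[SirsThresholdTable, News2BandTable]:
    """Canonical tables derived from the published baseline statistics."""
    stats = DiurnalStats.from_summary(reference.BASELINE_STATS)
    return derive_sirs_table(stats), derive_news2_table(stats)
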