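"""End-to-end analysis: aggregate courses, score the cohort, summarize.

Raw animal courses are reduced to 8-hourly snapshots (trailing-window
telemetry means aligned to each blood draw), scored against the SIRS /
SOFA / NEWS2 engines, and rolled up into prevalence tables (percent of
alive animals meeting each criterion, denominators shrinking only through
death), rank-based group comparisons with Holm–Šídák correction, the two
survival summaries, and a deterministic rule-based classifier standing in
for blinded human review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away
from .cohortsim import AnimalCourse, PAT, CONTROL
from .scores import (VitalsSnapshot, evaluate_sirs, news2_total, sofa_total)
from .stats import exact_mann_whitney, holm_sidak_adjust, robust_outlier_flag  # noqa: F401
from .thresholds import LightCycle, News2BandTable, SirsThresholdTable

logger = logging.getLogger(__name__)

#: lab analytes copied into snapshots
_SNAPSHOT_LABS = ("wbc", "platelets", "creatinine", "bilirubin", "pf_ratio")
#: telemetry channels averaged into snapshots
_SNAPSHOT_TELEMETRY = ("hr", "rr", "temp", "map", "sbp")


# ---------------------------------------------------------------------------
# aggregation


def window_average(telemetry: pd.DataFrame, draw_times: Sequence[float],
                   window_h: float = 8.0, time_col: str = "time_h") -> pd.DataFrame:
    """Trailing-window channel means: for each draw time t, the mean of all
    samples in ``(t − window_h, t]``.  Empty windows give NaN."""
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    draw_times = np.asarray(draw_times, dtype=float)
    if np.any(np.diff(draw_times) < 0):
        raise ValueError("draw times must be sorted")
    wide = telemetry.pivot_table(index=time_col, columns="channel",
                                 values="value", aggfunc="mean").sort_index()
    times = wide.index.to_numpy(dtype=float)
    lo = np.searchsorted(times, draw_times - window_h, side="right")
    hi = np.searchsorted(times, draw_times, side="right")
    rows = []
    for a, b in zip(lo, hi):
        if b > a:
            rows.append(wide.iloc[a:b].mean())
        else:
            rows.append(pd.Series(np.nan, index=wide.columns))
    out = pd.DataFrame(rows, index=pd.Index(draw_times, name=time_col))
    return out


def diurnal_average(telemetry: pd.DataFrame, cycle: LightCycle = LightCycle(),
                    time_col: str = "timestamp") -> pd.DataFrame:
    """Mean per consecutive 12-h light phase block per channel.

    Returns a tidy frame (block, phase, start_h, channel, mean) with blocks
    numbered in time order from the first sample.
    """
    df = telemetry.copy()
    ts = pd.DatetimeIndex(df[time_col])
    # absolute hours since epoch put every sample into a 12-h block aligned
    # to the lights-on transition
    abs_h = ts.asi8 / 3.6e12
    block_edges = np.floor((abs_h - cycle.lights_on) / 12.0)
    df["_block_abs"] = block_edges
    df["phase"] = np.where(block_edges.astype(int) % 2 == 0, "day", "night")
    first = df["_block_abs"].min()
    df["block"] = (df["_block_abs"] - first).astype(int)
    grouped = (df.groupby(["block", "phase", "channel"], as_index=False)["value"]
               .mean().rename(columns={"value": "mean"}))
    start = (df.groupby("block", as_index=False)["time_h"].min()
             .rename(columns={"time_h": "start_h"})) if "time_h" in df else None
    if start is not None:
        grouped = grouped.merge(start, on="block")
    return grouped.sort_values(["block", "channel"]).reset_index(drop=True)


def build_snapshots(course: AnimalCourse, cycle: LightCycle = LightCycle(),
                    draw_times: Sequence[float] | None = None,
                    window_h: float = 8.0,
                    duration_h: float = 72.0,
                    draw_interval_h: float = 8.0) -> list[VitalsSnapshot]:
    """Reduce one course to per-draw snapshots (no records after death)."""
    if draw_times is None:
        draw_times = np.arange(0.0, duration_h + draw_interval_h / 2, draw_interval_h)
    draw_times = np.asarray(draw_times, dtype=float)
    if course.death_time_h is not None:
        draw_times = draw_times[draw_times < course.death_time_h]
    if draw_times.size == 0:
        return []
    tel_means = window_average(course.telemetry, draw_times, window_h=window_h)
    labs = course.labs.pivot_table(index="time_h", columns="analyte",
                                   values="value", aggfunc="mean")
    snort = course.snort.set_index("time_h")["score"] if len(course.snort) else pd.Series(dtype=float)

    # phase at the draw instant, from the course's own clock
    t0 = course.telemetry["timestamp"].iloc[0]
    t0_h = course.telemetry["time_h"].iloc[0]
    clock0 = t0.hour + t0.minute / 60.0 + t0.second / 3600.0 - t0_h
    phases = cycle.phase_of_clock(clock0 + draw_times)

    snapshots = []
    for t, phase in zip(draw_times, phases):
        def tel(ch):
            if ch in tel_means.columns:
                v = tel_means.at[t, ch]
                return None if pd.isna(v) else float(v)
            return None

        def lab(an):
            if an in labs.columns and t in labs.index:
                v = labs.at[t, an]
                return None if pd.isna(v) else float(v)
            return None

        snapshots.append(VitalsSnapshot(
            animal_id=course.animal_id, time_h=float(t), phase=str(phase),
            hr=tel("hr"), rr=tel("rr"), temp=tel("temp"), map=tel("map"),
            sbp=tel("sbp"), wbc=lab("wbc"), platelets=lab("platelets"),
            creatinine=lab("creatinine"), bilirubin=lab("bilirubin"),
            pf_ratio=lab("pf_ratio"),
            snort=float(snort.at[t]) if t in snort.index else None))
    return snapshots


# ---------------------------------------------------------------------------
# scored timecourse


@dataclass
class CohortTimecourse:
    """Scored cohort: one row per animal × alive timepoint, plus the roster."""

    scores: pd.DataFrame
    roster: pd.DataFrame  # animal_id, group, death_time_h (NaN = survived)
    draw_times: np.ndarray
    protocol_end_h: float = 72.0

    def alive_at(self, t: float) -> pd.Series:
        dt = self.roster["death_time_h"]
        return dt.isna() | (dt > t)


def score_cohort(courses: Iterable[AnimalCourse],
                 sirs_table: SirsThresholdTable,
                 news2_bands: News2BandTable,
                 cycle: LightCycle = LightCycle(),
                 duration_h: float = 72.0,
                 draw_interval_h: float = 8.0,
                 window_h: float = 8.0) -> CohortTimecourse:
    """Score every animal at every 8-h timepoint it is alive for.

    The SOFA baseline for the ≥ 2-increase rule is each animal's own
    pre-injury (t = 0) total; t = 0 reflects the trailing pre-injury
    window.
    """
    courses = list(courses)
    draw_times = np.arange(0.0, duration_h + draw_interval_h / 2, draw_interval_h)
    rows, roster = [], []
    for course in courses:
        roster.append({"animal_id": course.animal_id, "group": course.group,
                       "death_time_h": np.nan if course.death_time_h is None
                       else course.death_time_h})
        snaps = build_snapshots(course, cycle=cycle, draw_times=draw_times,
                                window_h=window_h)
        baseline_total = 0
        for i, snap in enumerate(snaps):
            if i == 0 and snap.time_h == 0.0:
                baseline_total = sofa_total(snap, baseline_total=0).total
            sirs = evaluate_sirs(snap, sirs_table)
            sofa = sofa_total(snap, baseline_total=baseline_total)
            news2 = news2_total(snap, news2_bands)
            rows.append({
                "animal_id": course.animal_id, "group": course.group,
                "time_h": snap.time_h, "phase": snap.phase,
                "hr": snap.hr, "rr": snap.rr, "temp": snap.temp,
                "wbc": snap.wbc, "platelets": snap.platelets,
                "creatinine": snap.creatinine, "bilirubin": snap.bilirubin,
                "map": snap.map, "pf_ratio": snap.pf_ratio,
                "snort": snap.snort, "sbp": snap.sbp,
                "sirs_n_met": sirs.n_met, "sirs_state": sirs.sirs_state,
                "sirs_complete": sirs.complete,
                "sofa_total": sofa.total, "sofa_baseline": baseline_total,
                "sofa_flag": sofa.sepsis_flag, "sofa_complete": sofa.complete,
                "news2_total": news2.total, "news2_extreme": news2.extreme_flag,
                "news2_positive": news2.positive,
                "death_time_h": np.nan if course.death_time_h is None
                else course.death_time_h,
            })
    return CohortTimecourse(scores=pd.DataFrame(rows),
                            roster=pd.DataFrame(roster),
                            draw_times=draw_times,
                            protocol_end_h=duration_h)


# ---------------------------------------------------------------------------
# prevalence, comparison, survival


def prevalence_table(tc: CohortTimecourse) -> pd.DataFrame:
    """Percent of alive animals meeting each criterion per timepoint × group.

    SIRS uses the ≥ 2-criteria state, SOFA the ≥ 2-over-baseline flag,
    NEWS2 the positivity rule.  Denominators are the animals alive at the
    timepoint and can shrink only through death.  Returns a tidy frame
    (time_h, group, n_alive, sirs_pct, sofa_pct, news2_pct,
    *_pct_display); an empty group yields NaN percentages and a warning.
    """
    records = []
    for t in tc.draw_times:
        alive = tc.alive_at(t)
        for group in (CONTROL, PAT):
            members = tc.roster[(tc.roster["group"] == group) & alive]
            n_alive = len(members)
            sub = tc.scores[(tc.scores["group"] == group)
                            & (tc.scores["time_h"] == t)
                            & tc.scores["animal_id"].isin(members["animal_id"])]
            rec = {"time_h": t, "group": group, "n_alive": n_alive}
            for name, col in (("sirs", "sirs_state"), ("sofa", "sofa_flag"),
                              ("news2", "news2_positive")):
                if n_alive == 0:
                    logger.warning("no alive %s animals at %s h; prevalence undefined",
                                   group, t)
                    rec[f"{name}_pct"] = np.nan
                    rec[f"{name}_pct_display"] = np.nan
                    continue
                met = sub[col].fillna(False).astype(bool).sum()
                pct = 100.0 * met / n_alive
                rec[f"{name}_pct"] = pct
                rec[f"{name}_pct_display"] = round_half_away(pct, 0)
            records.append(rec)
    return pd.DataFrame(records)


def group_comparison(tc: CohortTimecourse, value_col: str = "news2_total",
                     seed: int = 0) -> pd.DataFrame:
    """Per-timepoint exact Mann–Whitney (control vs injured) on a score
    column, with Holm–Šídák adjustment across timepoints."""
    records = []
    for t in tc.draw_times:
        sub = tc.scores[tc.scores["time_h"] == t]
        x = sub[sub["group"] == CONTROL][value_col].dropna().to_numpy()
        y = sub[sub["group"] == PAT][value_col].dropna().to_numpy()
        if x.size == 0 or y.size == 0:
            continue
        res = exact_mann_whitney(x, y, seed=seed)
        records.append({"time_h": t, "u": res.u, "p_raw": res.p,
                        "method": res.method})
    out = pd.DataFrame(records)
    if len(out):
        out["p_adj"] = holm_sidak_adjust(out["p_raw"].to_numpy())
    return out


def survival_summary(death_times: Sequence[float | None] | Iterable[AnimalCourse],
                     protocol_end_h: float = 72.0) -> tuple[float, float]:
    """(survival rate %, mean survival time h) for a cohort.

    Accepts death times (``None``/NaN = survived to protocol end) or
    courses.  Mean survival averages ``min(death time, protocol end)``
    over all animals.
    """
    times = []
    for item in death_times:
        if isinstance(item, AnimalCourse):
            item = item.death_time_h
        times.append(np.nan if item is None else float(item))
    arr = np.asarray(times, dtype=float)
    if arr.size == 0:
        raise ValueError("empty cohort")
    survived = np.isnan(arr)
    rate = 100.0 * survived.mean()
    mean_surv = float(np.where(survived, protocol_end_h,
                               np.minimum(arr, protocol_end_h)).mean())
    return float(rate), mean_surv


# ---------------------------------------------------------------------------
# rule-based classification (computational analog of blinded review)


@dataclass(frozen=True)
class ClassificationRule:
    """Deterministic sorting rule: injured iff NEWS2 positive at
    ``min_news2_positive`` or more timepoints, or in a SIRS state within
    the first ``sirs_window_h`` hours."""

    min_news2_positive: int = 2
    sirs_window_h: float = 16.0


@dataclass(frozen=True)
class ClassificationResult:
    animal_id: str
    label: str
    reasons: tuple[str, ...]


def classify_animal(trajectory: pd.DataFrame,
                    rule: ClassificationRule = ClassificationRule()) -> ClassificationResult:
    """Label one animal's scored trajectory as injured (pat) or control."""
    required = {"time_h", "news2_positive", "sirs_state"}
    if not required.issubset(trajectory.columns):
        raise ValueError("trajectory is not scored (need NEWS2/SIRS columns)")
    if len(trajectory) < 2:
        raise ValueError("need at least 2 scored timepoints")
    animal_id = str(trajectory["animal_id"].iloc[0]) if "animal_id" in trajectory else ""
    reasons = []
    n_pos = int(trajectory["news2_positive"].fillna(False).astype(bool).sum())
    if n_pos >= rule.min_news2_positive:
        reasons.append(f"NEWS2 positive at {n_pos} timepoints "
                       f"(rule: >= {rule.min_news2_positive})")
    early = trajectory[trajectory["time_h"] <= rule.sirs_window_h]
    early_sirs = early["sirs_state"].fillna(False).astype(bool)
    if early_sirs.any():
        hits = early.loc[early_sirs, "time_h"].tolist()
        reasons.append(f"SIRS state within first {rule.sirs_window_h:g} h "
                       f"(at {hits})")
    label = PAT if reasons else CONTROL
    return ClassificationResult(animal_id=animal_id, label=label,
                                reasons=tuple(reasons))


def classify_cohort(tc: CohortTimecourse,
                    rule: ClassificationRule = ClassificationRule()) -> pd.DataFrame:
    """Classify every animal; returns (animal_id, group, label, correct, reasons).

    Animals censored before the second timepoint cannot satisfy the
    repeated-positivity rule; they are labelled from the single snapshot
    available (injured iff it is NEWS2 positive or in a SIRS state).
    """
    records = []
    for animal_id, traj in tc.scores.groupby("animal_id", sort=False):
        traj = traj.sort_values("time_h")
        if len(traj) < 2:
            pos = bool(traj["news2_positive"].fillna(False).astype(bool).any()
                       or traj["sirs_state"].fillna(False).astype(bool).any())
            res = ClassificationResult(
                animal_id=str(animal_id), label=PAT if pos else CONTROL,
                reasons=("trajectory censored before second timepoint; "
                         "labelled from the single snapshot",))
        else:
            res = classify_animal(traj, rule=rule)
        group = tc.roster.set_index("animal_id").at[animal_id, "group"]
        records.append({"animal_id": animal_id, "group": group,
                        "label": res.label, "correct": res.label == group,
                        "reasons": "; ".join(res.reasons)})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# scored-timecourse I/O


def write_scores(tc: CohortTimecourse, path: str | Path) -> None:
    tc.scores.to_csv(path, index=False)


def read_scores(path: str | Path, protocol_end_h: float = 72.0) -> CohortTimecourse:
    scores = pd.read_csv(path)
    roster = (scores.groupby("animal_id", sort=False)
              .agg(group=("group", "first"), death_time_h=("death_time_h", "first"))
              .reset_index())
    draw_times = np.sort(scores["time_h"].unique())
    return CohortTimecourse(scores=scores, roster=roster, draw_times=draw_times,
                            protocol_end_h=protocol_end_h)
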