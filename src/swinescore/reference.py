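"""Reference baseline statistics and published threshold tables for Yorkshire swine.

The scoring tables in this package are anchored to a healthy-baseline
cohort: 48 conscious, surgically instrumented Yorkshire pigs whose
telemetry (heart rate, respiration rate, core temperature) was summarized
over the 48 h immediately preceding injury, split by the animal facility's
12-h light cycle, together with complete blood counts drawn in the same
window.  ``BASELINE_STATS`` records the per-parameter day/night means and
standard deviations of that cohort; ``PRINTED_SIRS`` and ``PRINTED_NEWS2``
hold the corresponding published threshold tables, against which a fresh
derivation can be audited (:func:`swinescore.thresholds.audit_tables`).

Both the printed thresholds and the printed means are rounded for display,
so a handful of table cells cannot be reproduced exactly from the printed
means alone; re-derivation differs by one display unit in those cells.
The audit reports them rather than silently matching.

Systolic blood pressure appears in the published NEWS2 band table but its
baseline mean/SD were never printed; the values here are back-derived from
the published band edges (they reproduce every printed SBP cell exactly
under this package's rounding rule) and are used as simulator defaults.
"""

from __future__ import annotations

#: Number of animals behind the baseline statistics.
BASELINE_N = 48

#: (parameter, phase) -> (mean, sd).  Units: hr bpm, rr breaths/min,
#: temp deg C, wbc 10^3 cells/uL, sbp mmHg.  WBC comes from blood draws and
#: carries no diurnal split (phase "pooled").
BASELINE_STATS: dict[tuple[str, str], tuple[float, float]] = {
    ("hr", "day"): (100.0, 15.1),
    ("hr", "night"): (92.0, 12.0),
    ("rr", "day"): (22.0, 3.9),
    ("rr", "night"): (16.0, 3.1),
    ("temp", "day"): (38.5, 0.69),
    ("temp", "night"): (38.8, 0.47),
    ("wbc", "pooled"): (19.1, 3.5),
    # back-derived, see module docstring
    ("sbp", "day"): (140.3, 13.9),
    ("sbp", "night"): (132.5, 12.5),
}

#: Published SIRS thresholds, (parameter, phase) -> (upper, lower),
#: defined as baseline mean +/- 2 SD at display precision.
PRINTED_SIRS: dict[tuple[str, str], tuple[float, float]] = {
    ("hr", "day"): (130, 70),
    ("hr", "night"): (116, 68),
    ("rr", "day"): (29, 14),
    ("rr", "night"): (23, 10),
    ("temp", "day"): (39.9, 37.1),
    ("temp", "night"): (39.7, 37.8),
    ("wbc", "pooled"): (26.2, 12.1),
}

#: Published NEWS2 band table for the baseline-derived parameters.
#: Cell keys: the 0-point band is ``(zero_lo, zero_hi)`` = mean +/- 1 SD;
#: ``lower1``/``upper1`` are the 1-point thresholds (mean -/+ 2 SD),
#: ``lower2``/``upper2`` the 2-point thresholds (3 SD) and
#: ``lower3``/``upper3`` the 3-point ("extreme") thresholds (4 SD).
#: ``None`` marks cells left blank in the published table.
PRINTED_NEWS2: dict[tuple[str, str], dict[str, object]] = {
    ("rr", "day"): {
        "lower3": 6, "lower2": None, "lower1": 14,
        "zero": (18, 26),
        "upper1": None, "upper2": 33, "upper3": 37,
    },
    ("rr", "night"): {
        "lower3": 4, "lower2": None, "lower1": 10,
        "zero": (13, 20),
        "upper1": None, "upper2": 26, "upper3": 29,
    },
    ("sbp", "day"): {
        "lower3": 85, "lower2": 99, "lower1": 113,
        "zero": (126, 154),
        "upper1": None, "upper2": None, "upper3": 196,
    },
    ("sbp", "night"): {
        "lower3": 83, "lower2": 95, "lower1": 108,
        "zero": (120, 145),
        "upper1": None, "upper2": None, "upper3": 183,
    },
    ("hr", "day"): {
        "lower3": 40, "lower2": None, "lower1": 70,
        "zero": (85, 115),
        "upper1": 130, "upper2": 145, "upper3": 161,
    },
    ("hr", "night"): {
        "lower3": 45, "lower2": None, "lower1": 68,
        "zero": (80, 104),
        "upper1": 116, "upper2": 128, "upper3": 140,
    },
    ("temp", "day"): {
        "lower3": 35.7, "lower2": None, "lower1": 37.1,
        "zero": (37.8, 39.2),
        "upper1": 39.9, "upper2": 40.5, "upper3": None,
    },
    ("temp", "night"): {
        "lower3": 36.9, "lower2": None, "lower1": 37.8,
        "zero": (38.3, 39.2),
        "upper1": 39.7, "upper2": 40.2, "upper3": None,
    },
}

#: Fixed (human-derived) NEWS2 rows: peripheral oxygen saturation is scored
#: on absolute cut-offs, and any SNORT below 10 is an extreme (3-point)
#: variation.  These rows are constants, not derived from baseline data.
SPO2_BANDS: tuple[tuple[float, int], ...] = (
    (96.0, 0),   # >= 96 -> 0
    (94.0, 1),   # 94-95 -> 1
    (92.0, 2),   # 92-93 -> 2
    (0.0, 3),    # <= 91 -> 3
)
SNORT_NEWS2_CUTOFF = 10.0  # score < 10 -> 3 points, extreme

#: Display precision per parameter (decimal places) used for every rounded
#: threshold in this package: integer bpm / breaths/min / mmHg, 0.1 deg C,
#: 0.1 x10^3 cells/uL.
DISPLAY_DECIMALS: dict[str, int] = {
    "hr": 0,
    "rr": 0,
    "sbp": 0,
    "map": 0,
    "activity": 0,
    "temp": 1,
    "wbc": 1,
}
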