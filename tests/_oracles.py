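"""Independent brute-force comparators used only by the test suite.

Deliberately written with a different structure from the package code
(decimal rounding, linear band scans, explicit loops) so that agreement is
meaningful.
"""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from swinescore import reference


def dec_round(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sirs_thresholds() -> dict:
    """(param, phase) -> (upper, lower) straight from the baseline stats."""
    out = {}
    for (param, phase), (mean, sd) in reference.BASELINE_STATS.items():
        if param == "sbp":
            continue
        nd = reference.DISPLAY_DECIMALS[param]
        out[(param, phase)] = (dec_round(mean + 2 * sd, nd),
                               dec_round(mean - 2 * sd, nd))
    return out


def sirs_flags(hr, rr, temp, wbc, phase) -> dict:
    thr = sirs_thresholds()
    flags = {}
    for param, value in (("hr", hr), ("rr", rr), ("temp", temp), ("wbc", wbc)):
        ph = "pooled" if param == "wbc" else phase
        upper, lower = thr[(param, ph)]
        flags[param] = value > upper or value < lower
    return flags


def sofa(system: str, value: float) -> int:
    if system == "respiratory":
        for lo, sc in ((400, 0), (300, 1), (200, 2), (100, 3)):
            if value >= lo:
                return sc
        return 4
    if system == "renal":
        v = dec_round(value, 1)
        for hi, sc in ((1.4, 0), (2.4, 1), (3.4, 2), (4.9, 3)):
            if v <= hi:
                return sc
        return 4
    if system == "hepatic":
        v = dec_round(value, 1)
        for hi, sc in ((0.6, 0), (2.0, 1), (5.0, 2), (10.0, 3)):
            if v <= hi:
                return sc
        return 4
    if system == "hematological":
        for hi, sc in ((20, 4), (50, 3), (100, 2), (150, 1)):
            if value <= hi:
                return sc
        return 0
    if system == "cardiovascular":
        v = dec_round(value, 0)
        for lo, sc in ((71, 0), (60, 1), (50, 2), (40, 3)):
            if v >= lo:
                return sc
        return 4
    if system == "neurological":
        for lo, sc in ((10, 0), (8, 1), (6, 2), (4, 3)):
            if value >= lo:
                return sc
        return 4
    raise ValueError(system)


def news2(param: str, value: float, phase: str) -> tuple[int, bool]:
    if param == "spo2":
        v = dec_round(value, 0)
        if v >= 96:
            return 0, False
        if v >= 94:
            return 1, False
        if v >= 92:
            return 2, False
        return 3, True
    if param == "snort":
        return (3, True) if value < 10 else (0, False)
    mean, sd = reference.BASELINE_STATS[(param, phase)]
    nd = reference.DISPLAY_DECIMALS[param]
    edges = {k: dec_round(mean + k * sd, nd) for k in (-4, -3, -2, 2, 3, 4)}
    if value >= edges[4]:
        return 3, True
    if value >= edges[3]:
        return 2, False
    if value >= edges[2]:
        return 1, False
    if value <= edges[-4]:
        return 3, True
    if value <= edges[-3]:
        return 2, False
    if value <= edges[-2]:
        return 1, False
    return 0, False


def window_mean(times, values, t, window_h):
    picked = [v for ti, v in zip(times, values) if t - window_h < ti <= t]
    return float(np.mean(picked)) if picked else float("nan")


def rank_sum_enumeration(x, y, alternative="two-sided") -> float:
    """Exact Mann-Whitney p by bitmask enumeration over subsets."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, nx = pooled.size, len(x)
    t_obs = ranks[:nx].sum()
    mean_t = nx * (n + 1) / 2.0
    eps = 1e-9
    count = total = 0
    for mask in range(1 << n):
        if bin(mask).count("1") != nx:
            continue
        total += 1
        t = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if alternative == "two-sided":
            hit = abs(t - mean_t) >= abs(t_obs - mean_t) - eps
        elif alternative == "greater":
            hit = t >= t_obs - eps
        else:
            hit = t <= t_obs + eps
        if hit:
            count += 1
    return count / total
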