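"""Rank-based group comparison and robust outlier annotation.

The exact Mann–Whitney test here enumerates every assignment of the pooled
mid-ranks to the two groups (exact conditional null distribution, correct
under ties), which is feasible at preclinical group sizes; larger samples
fall back to a seeded Monte-Carlo permutation test.  Multiplicity across
timepoints is controlled with the Holm–Šídák step-down procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "permutation"


def exact_mann_whitney(x, y, alternative: str = "two-sided",
                       max_exact_n: int = 14, n_permutations: int = 20000,
                       seed: int | np.random.Generator | None = 0) -> MannWhitneyResult:
    """Mann–Whitney U test with an exact conditional null distribution.

    For ``len(x) + len(y) <= max_exact_n`` every C(N, n_x) assignment of the
    pooled mid-ranks is enumerated; ties are handled by conditioning on the
    observed mid-ranks.  Above that size a seeded random-permutation
    estimate is used (add-one p so p > 0 always).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative}")

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n_x, n = x.size, pooled.size
    t_obs = ranks[:n_x].sum()
    u_obs = t_obs - n_x * (n_x + 1) / 2.0
    mean_t = n_x * (n + 1) / 2.0

    def extreme(t):
        if alternative == "greater":
            return t >= t_obs - _TIE_EPS
        if alternative == "less":
            return t <= t_obs + _TIE_EPS
        return np.abs(t - mean_t) >= abs(t_obs - mean_t) - _TIE_EPS

    if n <= max_exact_n:
        count = 0
        for idx in combinations(range(n), n_x):
            if extreme(ranks[list(idx)].sum()):
                count += 1
        p = count / comb(n, n_x)
        return MannWhitneyResult(u=u_obs, p=p, method="exact")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_perm = np.empty(n_permutations)
    for i in range(n_permutations):
        t_perm[i] = ranks[rng.permutation(n)[:n_x]].sum()
    count = int(extreme(t_perm).sum())
    p = (1 + count) / (1 + n_permutations)
    return MannWhitneyResult(u=u_obs, p=min(p, 1.0), method="permutation")


def holm_sidak_adjust(pvalues) -> np.ndarray:
    """Holm–Šídák step-down adjusted p-values, in the input order.

    Sorted ascending, adjusted_i = max_{j<=i} 1 − (1 − p_j)^(m − j + 1),
    clipped to 1; the output is monotone in the sorted order and invariant
    to input permutation.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 hits log1p(-1) internally
        return multipletests(p, method="holm-sidak")[1]


def robust_outlier_flag(values, k: float = 5.0) -> np.ndarray:
    """Annotate values more than ``k`` scaled MADs from the median.

    Flags ``|value − median| > k · 1.4826 · MAD`` (1.4826 makes the MAD a
    consistent σ estimate for normal data).  Never removes data.  When the
    MAD degenerates to zero a warning is issued and any nonzero deviation
    exceeds the threshold.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to flag outliers")
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        warnings.warn("MAD is zero; outlier scale degenerate", stacklevel=2)
    return np.abs(v - med) > k * 1.4826 * mad
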