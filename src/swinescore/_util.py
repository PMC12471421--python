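"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

# Guard against float representation error (e.g. 26.1 stored as 26.099...)
# flipping a half-way case; one part in 1e12 is far below any physiological
# display precision.
_EPS = 1e-9


def round_half_away(x, decimals: int = 0):
    """Round half away from zero at ``decimals`` places.

    This is the convention of common clinical/statistics software (130.2 ->
    130, 69.8 -> 70, 39.88 -> 39.9, 115.1 -> 115, 84.9 -> 85, -0.5 -> -1),
    unlike Python's banker's rounding.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5 + _EPS) / factor
    if decimals <= 0:
        out = out.astype(float)
    if out.ndim == 0:
        val = float(out)
        return int(val) if decimals <= 0 else val
    return out
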