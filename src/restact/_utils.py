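"""Small shared numeric helpers."""
from __future__ import annotations

import math

import numpy as np

TWO_PI = 2.0 * math.pi


def circular_mean(angles) -> float:
    """Mean resultant-vector angle of ``angles`` (radians), mapped to [0, 2*pi).

    NaN entries are ignored; returns NaN if nothing remains.
    """
    a = np.asarray(angles, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        return math.nan
    return math.atan2(float(np.sin(a).mean()), float(np.cos(a).mean())) % TWO_PI


def circular_diff(a: float, b: float) -> float:
    """Signed angular difference a - b wrapped to (-pi, pi]."""
    d = (a - b) % TWO_PI
    if d > math.pi:
        d -= TWO_PI
    return d
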