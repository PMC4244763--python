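"""Core geometry of the nestedness temperature of a fixed matrix arrangement.

The matrix is mapped onto the unit square: cell (i, j) sits at the midpoint
of its grid square, with the origin at the top-left corner.  An isocline of
perfect order — a monotone decreasing boundary — splits the square so that
the area on the presence (top-left) side equals the fill proportion
p = F/(n*m).  A perfectly ordered matrix at that fill has every presence on
the presence side and every absence on the absence side.

Each *unexpected* cell (a presence below the isocline or an absence above
it) contributes an unexpectedness u = (d/D)^2, where d is the distance from
the cell midpoint to the isocline measured along the negative-slope
diagonal direction through the cell and D is the full main-diagonal length
of the square.  Temperature is the normalised total

    T = 100 * sum(u) / (U_MAX * n * m),

with U_MAX = 0.04145 calibrated so that maximally disordered matrices score
near 100.

The isocline used here is the straight line x + y = c with c chosen so the
area constraint holds; along the (1, 1) diagonal direction the distance
from a midpoint (x, y) to it is |x + y - c| / sqrt(2) and D = sqrt(2), so
u = ((x + y - c) / 2)^2.
"""

from __future__ import annotations

import numpy as np

U_MAX = 0.04145


def isocline_offset(p: float) -> float:
    """Intercept c of the line x + y = c cutting off presence-side area p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("fill proportion must lie in [0, 1]")
    if p <= 0.5:
        return float(np.sqrt(2.0 * p))
    return float(2.0 - np.sqrt(2.0 * (1.0 - p)))


def temperature_of(B: np.ndarray) -> float:
    """Temperature of a binary matrix in its *current* arrangement.

    No sorting is applied; callers wanting the context-free score minimise
    this over row/column orders first (see :func:`nestkit.sorting.ntc_sort`).
    """
    B = np.asarray(B)
    n, m = B.shape
    if n * m < 4:
        raise ValueError("temperature is undefined for matrices smaller than 4 cells")
    F = int(np.count_nonzero(B))
    p = F / (n * m)
    c = isocline_offset(p)
    y = (np.arange(n)[:, None] + 0.5) / n
    x = (np.arange(m)[None, :] + 0.5) / m
    s = x + y  # position along the negative-slope diagonal sweep
    present = B != 0
    unexpected = np.where(present, s > c, s < c)
    u = ((s - c) / 2.0) ** 2
    return float(100.0 * np.sum(u[unexpected]) / (U_MAX * n * m))
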