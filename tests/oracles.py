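"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the measure definitions with plain scalar
loops and (for the temperature) numeric root-finding, deliberately sharing
no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize


def nodf_oracle(B: np.ndarray) -> float:
    """NODF by direct enumeration of ordered line pairs."""
    B = np.asarray(B) != 0
    n, m = B.shape
    total = 0.0
    for lines in (list(B), list(B.T)):
        for k in range(len(lines)):
            for l in range(k + 1, len(lines)):
                fk, fl = lines[k].sum(), lines[l].sum()
                if fk > fl and fl > 0:
                    shared = np.logical_and(lines[k], lines[l]).sum()
                    total += 100.0 * shared / fl
    return total / (n * (n - 1) / 2 + m * (m - 1) / 2)


def wnodf_oracle(W: np.ndarray) -> float:
    W = np.asarray(W, dtype=float)
    n, m = W.shape
    total = 0.0
    for lines in (list(W), list(W.T)):
        for k in range(len(lines)):
            for l in range(k + 1, len(lines)):
                fk = (lines[k] != 0).sum()
                fl = (lines[l] != 0).sum()
                if fk > fl and fl > 0:
                    wins = sum(
                        1 for a, b in zip(lines[k], lines[l]) if 0 < b < a
                    )
                    total += 100.0 * wins / fl
    return total / (n * (n - 1) / 2 + m * (m - 1) / 2)


def jdm_oracle(B: np.ndarray) -> float:
    """Observed/expected configuration-model overlap, scalar loops."""
    B = np.asarray(B) != 0
    n, m = B.shape
    obs = 0.0
    exp = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            obs += np.logical_and(B[a], B[b]).sum()
            exp += B[a].sum() * B[b].sum() / m
    for a in range(m):
        for b in range(a + 1, m):
            obs += np.logical_and(B[:, a], B[:, b]).sum()
            exp += B[:, a].sum() * B[:, b].sum() / n
    return obs / exp


def md_oracle(B: np.ndarray) -> float:
    B = np.asarray(B) != 0
    return float(
        sum((i - 1) + (j - 1) for i in range(1, B.shape[0] + 1) for j in range(1, B.shape[1] + 1) if B[i - 1, j - 1])
    )


def br_oracle(B: np.ndarray) -> int:
    B = np.asarray(B) != 0
    total = 0
    for row in B:
        r = int(row.sum())
        total += r - int(row[:r].sum())
    return total


def temperature_oracle(B: np.ndarray) -> float:
    """Temperature from first principles: numeric isocline + root-finding.

    The isocline offset c is found by bisection on the numerically
    integrated presence-side area of {x + y <= c}; each cell's distance to
    the isocline is found by solving along its (1, 1) diagonal with a
    root-finder.  Matches the analytic implementation to ~1e-6.
    """
    B = np.asarray(B) != 0
    n, m = B.shape
    F = int(B.sum())
    p = F / (n * m)

    def area(c: float) -> float:
        val, _ = integrate.quad(lambda x: min(max(c - x, 0.0), 1.0), 0.0, 1.0, limit=200)
        return val

    if p <= 0:
        c = 0.0
    elif p >= 1:
        c = 2.0
    else:
        c = optimize.brentq(lambda c: area(c) - p, 0.0, 2.0, xtol=1e-12)

    total_u = 0.0
    D = np.sqrt(2.0)
    for i in range(n):
        for j in range(m):
            y = (i + 0.5) / n
            x = (j + 0.5) / m
            side = x + y - c
            present = bool(B[i, j])
            unexpected = (present and side > 0) or (not present and side < 0)
            if not unexpected:
                continue
            # intersection of (x + t, y + t) with the isocline
            t = optimize.brentq(lambda t: (x + t) + (y + t) - c, -2.0, 2.0, xtol=1e-14)
            d = abs(t) * np.sqrt(2.0)
            total_u += (d / D) ** 2
    return 100.0 * total_u / (0.04145 * n * m)


def mann_whitney_exact_oracle(x, y) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    from itertools import combinations

    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    mean_u = nx * len(y) / 2.0
    us = [
        u_stat([pooled[i] for i in idx], [pooled[i] for i in range(len(pooled)) if i not in idx])
        for idx in combinations(range(len(pooled)), nx)
    ]
    tail = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return tail / len(us)
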