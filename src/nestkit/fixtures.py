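"""Deterministic fixture matrices for demos, tests and direction checks."""

from __future__ import annotations

import numpy as np

from .core_io import BipartiteMatrix

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("nested", "checkerboard", "random", "weighted_nested")


def _staircase_support(n: int, m: int, fill: int) -> np.ndarray:
    """Boolean mask of a perfectly nested staircase with `fill` presences.

    Cells are admitted anti-diagonal by anti-diagonal (ties toward the top
    rows), so every row's support is a left-packed prefix and row lengths
    decrease: each row's presences are a subset of the previous row's.
    """
    cells = sorted(((i + j, i, j) for i in range(n) for j in range(m)))
    mask = np.zeros((n, m), dtype=bool)
    for _, i, j in cells[:fill]:
        mask[i, j] = True
    return mask


def make_fixture(kind: str, n: int, m: int, fill: int | None = None, seed: int = 0) -> BipartiteMatrix:
    """Build a deterministic fixture matrix.

    kind
        ``nested`` — perfectly nested binary staircase with ``fill`` ones;
        ``weighted_nested`` — same support, weight S+1-(i+j) decreasing
        toward the bottom-right (0-based i, j; S the outermost occupied
        anti-diagonal), so for 10x10 with fill 55 this reproduces the
        reference nested matrix used for direction detection;
        ``checkerboard`` — weight 4 wherever i+j is even (fill implied by
        shape; if given it must match);
        ``random`` — ``fill`` cells placed uniformly at random (seeded).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; valid kinds: {FIXTURE_KINDS}")
    if n < 1 or m < 1:
        raise ValueError("fixture needs at least one row and one column")

    if kind == "checkerboard":
        i = np.arange(n)[:, None]
        j = np.arange(m)[None, :]
        mask = (i + j) % 2 == 0
        if fill is not None and fill != int(mask.sum()):
            raise ValueError(
                f"checkerboard of shape {n}x{m} has exactly {int(mask.sum())} occupied cells"
            )
        return BipartiteMatrix(np.where(mask, 4.0, 0.0))

    if fill is None:
        raise ValueError(f"fixture kind {kind!r} requires a fill")
    if not 1 <= fill <= n * m:
        raise ValueError(f"fill must be between 1 and {n * m}, got {fill}")

    if kind == "random":
        rng = np.random.default_rng(seed)
        flat = np.zeros(n * m)
        flat[rng.choice(n * m, size=fill, replace=False)] = 1.0
        return BipartiteMatrix(flat.reshape(n, m))

    mask = _staircase_support(n, m, fill)
    if kind == "nested":
        return BipartiteMatrix(mask.astype(float))
    i = np.arange(n)[:, None]
    j = np.arange(m)[None, :]
    s_max = int((i + j)[mask].max())
    return BipartiteMatrix(np.where(mask, s_max + 1.0 - (i + j), 0.0))
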