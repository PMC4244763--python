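import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nestkit import BipartiteMatrix

REPO_ROOT = Path(__file__).resolve().parent.parent

#: path where a user can drop the published 53x27 users-by-hashtags case
#: study matrix to enable the two case-study replication tests
CASE_STUDY_CSV = REPO_ROOT / "data" / "IPCC_HTuse_10_10_1_53x27.csv"


def random_binary(n: int, m: int, fill: int, seed: int) -> BipartiteMatrix:
    rng = np.random.default_rng(seed)
    flat = np.zeros(n * m)
    flat[rng.choice(n * m, size=fill, replace=False)] = 1.0
    return BipartiteMatrix(flat.reshape(n, m))


def random_weighted(n: int, m: int, fill: int, seed: int, integer: bool = False) -> BipartiteMatrix:
    rng = np.random.default_rng(seed)
    flat = np.zeros(n * m)
    cells = rng.choice(n * m, size=fill, replace=False)
    if integer:
        flat[cells] = rng.integers(1, 9, size=fill).astype(float)
    else:
        flat[cells] = rng.uniform(0.5, 5.0, size=fill)
    return BipartiteMatrix(flat.reshape(n, m))


@pytest.fixture
def triangle3() -> BipartiteMatrix:
    """3x3 strictly nested triangle."""
    return BipartiteMatrix(np.array([[1.0, 1, 1], [1, 1, 0], [1, 0, 0]]))
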