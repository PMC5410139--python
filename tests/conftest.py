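import numpy as np
import pytest

from fukomys.alignment import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_alignment():
    return Alignment.from_strings(
        ["a", "b", "c", "d"],
        ["ACGTACGTAA", "ACGTACGTAA", "ACGTACGGCA", "ACGTACGGCA"],
    )


def diverged_alignment(rng, n, length, sub_rate=0.08):
    """Rows derived from one ancestor with a moderate substitution rate,
    so corrected distances stay estimable."""
    chars = np.array(list("ACGT"))
    base = rng.integers(0, 4, size=length)
    rows = [base]
    for _ in range(n - 1):
        row = base.copy()
        mask = rng.random(length) < sub_rate
        row[mask] = (row[mask] + rng.integers(1, 4, size=mask.sum())) % 4
        rows.append(row)
    mat = chars[np.stack(rows)]
    return Alignment(ids=[f"s{i}" for i in range(n)], matrix=mat)


def random_alignment(rng, n, length, missing_frac=0.0):
    chars = np.array(list("ACGT"))
    mat = chars[rng.integers(0, 4, size=(n, length))]
    if missing_frac:
        mask = rng.random(mat.shape) < missing_frac
        mat[mask] = rng.choice(np.array(list("-N?")), size=mask.sum())
    return Alignment(ids=[f"s{i}" for i in range(n)], matrix=mat)
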