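import numpy as np
import pytest

from prophagepop.io_formats import LabeledMatrix

BASES = np.array(list("ACGT"))


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def substituted_copy(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    """Copy of ``seq`` with exactly ``n_sub`` positions changed to a
    different base (so Hamming identity is known by construction)."""
    arr = np.array(list(seq))
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    for i in sites:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def block_matrix(block_sizes, within: float, between: float) -> LabeledMatrix:
    """Similarity matrix with planted blocks: ``within`` inside a block,
    ``between`` across blocks, 100 on the diagonal."""
    labels = []
    block_of = []
    for bi, size in enumerate(block_sizes):
        for j in range(size):
            labels.append(f"b{bi}_m{j}")
            block_of.append(bi)
    n = len(labels)
    vals = np.full((n, n), between)
    for i in range(n):
        for j in range(n):
            if block_of[i] == block_of[j]:
                vals[i, j] = within
    np.fill_diagonal(vals, 100.0)
    return LabeledMatrix(labels, vals)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
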