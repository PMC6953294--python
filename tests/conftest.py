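import numpy as np
import pytest

from coevonet import EncodedAlignment, SyntheticSpec, generate_protein


@pytest.fixture
def toy_enc():
    """The 3-sequence, 2-column alignment {AC, AD, GC} (A=0, C=1, D=2, G=5)."""
    return EncodedAlignment(codes=np.array([[0, 1], [0, 2], [5, 1]], dtype=np.int8))


@pytest.fixture(scope="session")
def small_protein():
    """One synthetic protein at desk scale (L=30, 50 evolved + 25 noise rows)."""
    return generate_protein(SyntheticSpec(seed=11), seed=1234, identifier="fixture")


def random_alignment(rng, n, length):
    """Uniform random codes with a gap-free query row."""
    codes = rng.integers(0, 21, size=(n, length)).astype(np.int8)
    codes[0] = rng.integers(0, 20, size=length)
    return EncodedAlignment(codes=codes)


def brute_force_covariance(codes, weights):
    """Independent counting oracle for the weighted covariance tensor.

    Tallies single and joint weighted counts pair by pair, sequence by
    sequence; shares no code with the vectorized einsum-style path.
    """
    n, length = codes.shape
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    single = np.zeros((length, 21))
    for s in range(n):
        for i in range(length):
            single[i, codes[s, i]] += weights[s]
    single /= total
    cov = np.zeros((length, length, 441))
    for i in range(length):
        for j in range(length):
            joint = np.zeros((21, 21))
            for s in range(n):
                joint[codes[s, i], codes[s, j]] += weights[s]
            joint /= total
            for a in range(21):
                for b in range(21):
                    cov[i, j, 21 * a + b] = joint[a, b] - single[i, a] * single[j, b]
    return cov
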