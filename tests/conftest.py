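import numpy as np
import pytest

from targetsel import BioactivityMatrix, SyntheticSpec, generate_matrix


@pytest.fixture
def toy_matrix():
    """2×3 fully measured matrix; row c1 is the worked spectrum
    {t1: 9, t2: 7, t3: 5} used across the potency tests."""
    return BioactivityMatrix(
        compounds=["c1", "c2"],
        targets=["t1", "t2", "t3"],
        values=np.array([[9.0, 7.0, 5.0], [6.0, 6.0, 6.0]]),
        mask=np.ones((2, 3), dtype=bool),
    )


@pytest.fixture
def masked_matrix():
    """3×3 matrix with holes: c2 has one missing cell, c3 only one measured."""
    vals = np.array([[9.0, 7.0, 5.0], [6.0, 0.0, 8.0], [0.0, 7.5, 0.0]])
    mask = np.array([[True, True, True], [True, False, True], [False, True, False]])
    return BioactivityMatrix(
        compounds=["c1", "c2", "c3"], targets=["t1", "t2", "t3"],
        values=vals, mask=mask,
    )


@pytest.fixture(scope="session")
def synth_default():
    """One default synthetic panel (20×50, 5 selective, 3 promiscuous)."""
    return generate_matrix(SyntheticSpec(seed=11))


def random_matrix(rng, n_c=6, n_t=8, missing=0.0):
    """Random fully- or partially-measured matrix for property tests."""
    vals = rng.normal(6.5, 1.5, size=(n_c, n_t))
    mask = np.ones((n_c, n_t), dtype=bool)
    if missing:
        mask &= rng.random((n_c, n_t)) > missing
        # keep every compound scoreable: ≥2 measured targets
        for i in range(n_c):
            while mask[i].sum() < 2:
                mask[i, rng.integers(n_t)] = True
    return BioactivityMatrix(
        compounds=[f"c{i}" for i in range(n_c)],
        targets=[f"t{j}" for j in range(n_t)],
        values=vals, mask=mask,
    )
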