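import numpy as np
import pytest

from metimpute import METArray, SimConfig, generate_missing, simulate_met, standardize
from metimpute.base import pattern_from_mask
from metimpute.evaluation import _mask_pattern


@pytest.fixture
def tiny_array() -> METArray:
    """Deterministic fully observed 4 x 3 x 2 array with distinct values."""
    rng = np.random.default_rng(42)
    vals = rng.normal(size=(4, 3, 2)) + np.arange(24).reshape(4, 3, 2) * 0.1
    return METArray(vals)


@pytest.fixture
def small_sim() -> METArray:
    """Simulated 20 x 6 x 3 trial array (fully observed)."""
    return simulate_met(SimConfig(I=20, J=6, K=3, seed=7))


@pytest.fixture
def masked_sim(small_sim):
    """Standardized 20 x 6 x 3 array with 10% missing cells and one column."""
    std = standardize(small_sim)
    pat = generate_missing(small_sim, 0.10, n_columns=1, seed=3)
    return _mask_pattern(std, pat), std, pat


def naive_ward(d2: np.ndarray):
    """Independent O(J^3) Lance-Williams Ward agglomeration oracle.

    Operates on squared dissimilarities; at each step merges the active
    pair with the smallest current dissimilarity (lowest-index pair on
    ties) and updates the rest with the Ward (incremental sum of
    squares) recurrence.  Returns the merge list in scipy numbering.
    """
    d2 = d2.astype(float).copy()
    J = d2.shape[0]
    active = {i: (i, 1) for i in range(J)}  # slot -> (cluster id, size)
    dist = {}
    for a in range(J):
        for b in range(a + 1, J):
            dist[(a, b)] = d2[a, b]
    merges = []
    next_id = J
    slots = sorted(active)
    for step in range(J - 1):
        best = min(dist, key=lambda p: (dist[p], p))
        a, b = best
        (ca, na), (cb, nb) = active[a], active[b]
        h = dist[best]
        merges.append((min(ca, cb), max(ca, cb), h))
        for c in list(active):
            if c in (a, b):
                continue
            nc = active[c][1]
            dac = dist[tuple(sorted((a, c)))]
            dbc = dist[tuple(sorted((b, c)))]
            new = ((na + nc) * dac + (nb + nc) * dbc - nc * h) / (na + nb + nc)
            dist[tuple(sorted((a, c)))] = new
        active[a] = (next_id, na + nb)
        next_id += 1
        del active[b]
        dist = {p: v for p, v in dist.items() if b not in p}
    return merges


@pytest.fixture
def ward_oracle():
    return naive_ward
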