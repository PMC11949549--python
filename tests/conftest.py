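"""Shared fixtures: small planted scenarios and graph helpers."""

import itertools

import numpy as np
import pytest

import neuromaxent as nm


@pytest.fixture(scope="session")
def small_scenario():
    """A 150-node planted multilayer scenario (contactome ⊇ connectome)."""
    return nm.generate_scenario(n=150, seed=3)


@pytest.fixture(scope="session")
def cloud_scenario():
    """A 60-node scenario with per-node surface point clouds."""
    return nm.generate_cloud_scenario(n=60, seed=7)


@pytest.fixture(scope="session")
def kl_truth():
    """Planted degree-plus-wiring-length ground truth on 500 nodes.

    Returns (nodes, distances, x_true, d0_true, k_star, L_star) where the
    targets are the exact ensemble expectations of the truth.
    """
    n = 500
    nodes = nm.generate_positions(n, seed=41)
    d = nm.condensed_distances(nodes)
    rng = np.random.default_rng(42)
    x_true = 4.0 * rng.lognormal(0.0, 1.0, n)
    d0_true = 12.0
    iu, ju = np.triu_indices(n, k=1)
    p_true = 1.0 / (1.0 + x_true[iu] * x_true[ju] * np.exp(d / d0_true))
    k_star = np.zeros(n)
    np.add.at(k_star, iu, p_true)
    np.add.at(k_star, ju, p_true)
    L_star = float((p_true * d).sum())
    return nodes, d, x_true, d0_true, k_star, L_star, p_true


def random_adjacency(rng, n, p):
    """Random symmetric boolean adjacency with zero diagonal."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return a | a.T


def enumerate_graphlets(a):
    """Exhaustive induced graphlet counts on a small adjacency matrix.

    Independent oracle: classify every 3- and 4-node induced subgraph by
    its edge count and degree sequence.
    """
    a = np.asarray(a, dtype=int)
    n = a.shape[0]
    tri = sq = dia = k4 = 0
    for c in itertools.combinations(range(n), 3):
        if a[c[0], c[1]] + a[c[0], c[2]] + a[c[1], c[2]] == 3:
            tri += 1
    for c in itertools.combinations(range(n), 4):
        sub = a[np.ix_(c, c)]
        e = int(sub.sum()) // 2
        if e == 6:
            k4 += 1
        elif e == 5:
            dia += 1
        elif e == 4 and sorted(sub.sum(axis=0)) == [2, 2, 2, 2]:
            sq += 1  # the other 4-edge graph (triangle + pendant) differs
    return tri, sq, dia, k4


def is_interior_sequence(k):
    """True when a degree sequence admits an interior soft-configuration fit.

    Sequences touching the degree-polytope boundary (a zero or full
    degree, or an Erdős–Gallai prefix inequality holding with equality)
    only have limiting solutions with some p_ij in {0, 1}; neither the
    fixed point nor a generic root finder converges to an interior point
    there.
    """
    k = np.sort(np.asarray(k, dtype=int))[::-1]
    n = len(k)
    if k.min() <= 0 or k.max() >= n - 1:
        return False
    for r in range(1, n + 1):
        lhs = int(k[:r].sum())
        rhs = r * (r - 1) + int(np.minimum(k[r:], r).sum())
        if lhs >= rhs:
            return False
    return True


def net_from_adjacency(a, seed=0):
    """Wrap an adjacency matrix in a SpatialNetwork with random positions."""
    n = a.shape[0]
    nodes = nm.generate_positions(n, seed=seed)
    iu, ju = np.triu_indices(n, k=1)
    on = a[iu, ju]
    edges = nm.EdgeList((nodes.ids[i], nodes.ids[j])
                        for i, j in zip(iu[on], ju[on]))
    return nm.SpatialNetwork(nodes, edges)
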