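"""Deterministic test fixtures: graphs, stable sparse Jacobians, model presets.

The 6-node graph is an arbitrary documented identity-only-automorphism
("completely asymmetric") topology; the asymmetry is asserted by brute force
over all 720 vertex permutations.  The 15-patch topology is a connected
random geometric graph with a fixed seed.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .constraints import PatchNetwork
from .exceptions import ValidationError
from .lyap_core import ZeroPattern, required_constraints

__all__ = [
    "asym6",
    "rgg15",
    "stable_sparse_jacobian",
    "automorphism_count",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("asym6", "rgg15", "stable-jacobian")

_ASYM6_EDGES = ((0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (0, 5))


def asym6() -> PatchNetwork:
    """6-node, 6-edge connected graph whose only automorphism is the identity."""
    return PatchNetwork(6, _ASYM6_EDGES)


def automorphism_count(net: PatchNetwork) -> int:
    """Number of vertex permutations preserving the edge set (brute force)."""
    eset = {frozenset(e) for e in net.edges}
    count = 0
    for perm in itertools.permutations(range(net.n_nodes)):
        if all(frozenset((perm[u], perm[v])) in eset for u, v in net.edges):
            count += 1
    return count


def rgg15(seed: int = 1, radius: float = 0.4) -> PatchNetwork:
    """Connected 15-node random geometric graph (unit square, fixed seed)."""
    g = nx.random_geometric_graph(15, radius, seed=seed)
    if not nx.is_connected(g):
        raise ValidationError(
            f"random geometric graph (seed={seed}, radius={radius}) is "
            "disconnected; pick another seed or larger radius"
        )
    return PatchNetwork(15, list(g.edges()))


def stable_sparse_jacobian(
    n: int,
    n_zeros: int | None = None,
    seed: int = 0,
    margin: float = 0.2,
) -> tuple[np.ndarray, ZeroPattern]:
    """Random Hurwitz Jacobian whose sparsity follows a random interaction graph.

    A connected Erdos-Renyi interaction graph is drawn; both ordered entries
    of every *non-adjacent* pair are structural zeros (the network scenario:
    non-interacting variables cannot enter each other's equations), at least
    ``n_zeros`` of them (default ``n*(n-1)//2 + n``, a determined system with
    a small surplus).  Free entries are standard normal and the diagonal is
    shifted so all eigenvalue real parts are at most ``-margin``.

    Placing zeros pairwise on a *connected* graph avoids unidentifiable
    configurations: an isolated densely-coupled block keeps the skew-symmetric
    gauge freedom ``J -> J + W Gamma^{-1}`` of the Lyapunov relation no matter
    how many zeros sit elsewhere.
    """
    if n < 2:
        raise ValidationError(f"need n >= 2, got {n}")
    max_zeros_even = n * (n - 1) - 2 * (n - 1)  # leave room for a spanning tree
    if n_zeros is None:
        n_zeros = min(required_constraints(n) + n, max_zeros_even)
    if n_zeros > max_zeros_even:
        raise ValidationError(
            f"cannot place {n_zeros} pairwise zeros and keep the interaction "
            f"graph connected (max {max_zeros_even} for n={n})"
        )
    m_edges = max(n - 1, (n * (n - 1) - n_zeros) // 2)
    rng = np.random.default_rng(seed)
    for _ in range(100):
        g = nx.gnm_random_graph(n, m_edges, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    else:  # pragma: no cover - p(disconnect)^100 is negligible
        raise ValidationError(f"no connected interaction graph found for n={n}")
    adjacent = {frozenset(e) for e in g.edges()}
    positions = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and frozenset((i, j)) not in adjacent
    ]
    jac = rng.standard_normal((n, n))
    for i, j in positions:
        jac[i, j] = 0.0
    shift = np.max(np.linalg.eigvals(jac).real)
    jac -= (shift + margin) * np.eye(n)
    return jac, ZeroPattern(positions, n)
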