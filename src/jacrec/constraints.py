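"""Structural zero patterns from network and multilayer topology.

Direct interactions in networked dynamical systems follow the wiring: a
variable can only enter another variable's equation of motion if the two are
adjacent.  Every non-adjacent ordered pair therefore contributes a structural
zero of the Jacobian.  In a multilayer metacommunity — S species replicated
over P habitat patches coupled by dispersal — an individual can affect its own
species in a neighbouring patch (by dispersing) and other species in its own
patch (e.g. by predation), but never a *different* species in a *different*
patch, which alone yields S*P*(S-1)*(P-1) zeros.

State flattening is species-fastest: variable index = species + S * patch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .exceptions import DimensionError, ValidationError
from .lyap_core import ZeroPattern, required_constraints

__all__ = [
    "PatchNetwork",
    "FoodwebGraph",
    "MultilayerIndex",
    "SufficiencyReport",
    "network_zero_pattern",
    "multilayer_zero_pattern",
    "sufficiency_check",
]


@dataclass(frozen=True)
class PatchNetwork:
    """Undirected spatial network of habitat patches.

    Edges are unordered 0-based pairs; self-loops and duplicates are rejected,
    disconnected networks are accepted with a warning.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]

    def __init__(self, n_nodes: int, edges: Iterable[Sequence[int]]):
        n = int(n_nodes)
        if n < 1:
            raise ValidationError(f"network needs at least one node, got {n}")
        canon = []
        seen = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < n and 0 <= v < n):
                raise ValidationError(f"edge ({u}, {v}) out of range for {n} nodes")
            if u == v:
                raise ValidationError(f"self-loop at node {u} not allowed")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValidationError(f"duplicate edge ({u}, {v})")
            seen.add(key)
            canon.append(key)
        object.__setattr__(self, "n_nodes", n)
        object.__setattr__(self, "edges", tuple(canon))
        g = self.to_networkx()
        if n > 1 and not nx.is_connected(g):
            warnings.warn(
                "patch network is not connected", UserWarning, stacklevel=3
            )

    @property
    def mean_degree(self) -> float:
        return 2.0 * len(self.edges) / self.n_nodes

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    def adjacency_set(self) -> set[tuple[int, int]]:
        """Ordered adjacent pairs (both directions)."""
        s = set()
        for u, v in self.edges:
            s.add((u, v))
            s.add((v, u))
        return s


@dataclass(frozen=True)
class FoodwebGraph:
    """Directed trophic network: links are (predator, prey) pairs."""

    n_species: int
    links: tuple[tuple[int, int], ...]

    def __init__(self, n_species: int, links: Iterable[Sequence[int]]):
        s = int(n_species)
        if s < 1:
            raise ValidationError(f"foodweb needs at least one species, got {s}")
        canon = []
        seen = set()
        for pred, prey in links:
            pred, prey = int(pred), int(prey)
            if not (0 <= pred < s and 0 <= prey < s):
                raise ValidationError(
                    f"link ({pred}, {prey}) out of range for {s} species"
                )
            if (pred, prey) in seen:
                raise ValidationError(f"duplicate link ({pred}, {prey})")
            seen.add((pred, prey))
            canon.append((pred, prey))
        object.__setattr__(self, "n_species", s)
        object.__setattr__(self, "links", tuple(canon))

    def interacting_pairs(self) -> set[tuple[int, int]]:
        """Unordered species pairs linked in either direction."""
        return {(min(p, q), max(p, q)) for p, q in self.links}


@dataclass(frozen=True)
class MultilayerIndex:
    """Species-fastest flattening of an S-species, P-patch multilayer system."""

    n_species: int
    n_patches: int

    def __post_init__(self):
        if self.n_species < 1 or self.n_patches < 1:
            raise ValidationError("species and patch counts must be positive")

    @property
    def dimension(self) -> int:
        return self.n_species * self.n_patches

    def flatten(self, species: int, patch: int) -> int:
        if not (0 <= species < self.n_species and 0 <= patch < self.n_patches):
            raise DimensionError(
                f"(species={species}, patch={patch}) out of range for "
                f"S={self.n_species}, P={self.n_patches}"
            )
        return species + self.n_species * patch

    def unflatten(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.dimension:
            raise DimensionError(f"index {index} out of range for N={self.dimension}")
        return index % self.n_species, index // self.n_species


def network_zero_pattern(net: PatchNetwork) -> ZeroPattern:
    """Structural zeros of single-species dynamics on a patch network.

    Only neighbouring nodes interact, so every ordered pair of distinct
    non-adjacent nodes is a Jacobian zero.  Diagonal entries (self-regulation)
    are never constrained.
    """
    adj = net.adjacency_set()
    n = net.n_nodes
    positions = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and (i, j) not in adj
    ]
    return ZeroPattern(positions, n)


def multilayer_zero_pattern(
    idx: MultilayerIndex,
    net: PatchNetwork,
    web: FoodwebGraph | None = None,
    include_cross_layer: bool = True,
    include_spatial: bool = True,
    include_trophic: bool = False,
) -> ZeroPattern:
    """Structural zeros of an S-species metacommunity on a patch network.

    Categories (union of the selected ones):

    - *cross-layer* — different species in different patches can never
      interact directly: exactly ``S*P*(S-1)*(P-1)`` ordered pairs, for any
      topology.
    - *spatial* — the same species in two distinct non-adjacent patches.
    - *trophic* (default off) — distinct species in the same patch with no
      trophic link in either direction.  Off by default because within-patch
      indirect effects (shared predators, prey switching) can make unlinked
      species interact dynamically, so the absence of a link does not
      guarantee a Jacobian zero.
    """
    if net.n_nodes != idx.n_patches:
        raise DimensionError(
            f"network has {net.n_nodes} patches but index expects {idx.n_patches}"
        )
    if web is not None and web.n_species != idx.n_species:
        raise DimensionError(
            f"foodweb has {web.n_species} species but index expects {idx.n_species}"
        )
    if include_trophic and web is None:
        raise ValidationError("trophic zeros requested but no foodweb given")

    s, p = idx.n_species, idx.n_patches
    adj = net.adjacency_set()
    positions = []
    for sp_i in range(s):
        for pa_i in range(p):
            i = idx.flatten(sp_i, pa_i)
            for sp_j in range(s):
                for pa_j in range(p):
                    j = idx.flatten(sp_j, pa_j)
                    if i == j:
                        continue
                    if sp_i != sp_j and pa_i != pa_j:
                        if include_cross_layer:
                            positions.append((i, j))
                    elif sp_i == sp_j and pa_i != pa_j:
                        if include_spatial and (pa_i, pa_j) not in adj:
                            positions.append((i, j))
                    elif pa_i == pa_j and sp_i != sp_j:
                        if include_trophic and (
                            min(sp_i, sp_j),
                            max(sp_i, sp_j),
                        ) not in web.interacting_pairs():
                            positions.append((i, j))
    return ZeroPattern(positions, idx.dimension)


@dataclass(frozen=True)
class SufficiencyReport:
    """Whether a zero pattern can make the reconstruction determined."""

    sufficient: bool
    count: int
    required: int
    dimension: int


def sufficiency_check(pattern: ZeroPattern, n: int | None = None) -> SufficiencyReport:
    """Check ``|pattern| >= N(N-1)/2`` by explicit enumeration.

    The Lyapunov relation supplies N(N+1)/2 of the N**2 degrees of freedom;
    the pattern must cover the rest.  The count is taken from the pattern
    itself rather than from closed-form mean-degree or species/patch
    inequalities, which misstate the available zeros on small topologies.
    """
    if n is None:
        n = pattern.dimension
    elif n != pattern.dimension:
        raise DimensionError(
            f"pattern has dimension {pattern.dimension}, expected {n}"
        )
    req = required_constraints(n)
    return SufficiencyReport(len(pattern) >= req, len(pattern), req, n)
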