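"""Grow hierarchical networks by iterated edge replacement.

Generation ``t`` is obtained from generation ``t-1`` by replacing every
edge with a fresh copy of a generator, identifying the edge endpoints with
the generator's roots.  The default initial network ``G0`` is a single
edge, whose two endpoints are the *renormalized root nodes* (RRNs) — the
oldest two nodes of every later generation.

Symmetric single-generator growth is deterministic: the built graph is
identical for every seed.  An asymmetric generator is oriented by a fair
coin per edge; a list of generators with selection probabilities draws one
generator per edge independently (the stochastic multi-generator model).

Node identity is reproducible without global counters: a node born when
edge number ``e`` (position in the lexicographically sorted edge list of
the previous generation) was replaced at generation ``t`` is the tuple
``(t, e, label)`` where ``label`` is the generator-local node label.  The
two ``G0`` endpoints are ``(0, 0, "rrn1")`` and ``(0, 0, "rrn2")``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .generators import Generator, is_symmetric

__all__ = [
    "HierarchicalNetwork",
    "expand_once",
    "build_network",
    "degree_census",
    "triangle_census",
]

NodeId = tuple[int, int, str]


@dataclass
class HierarchicalNetwork:
    """A generation-``t`` network with provenance.

    ``graph`` carries per-node ``birth`` attributes (generation of first
    appearance); ``rrns`` are the two oldest nodes when growth started from
    a single edge, else ``None``.
    """

    graph: nx.Graph
    t: int
    rrns: tuple[NodeId, NodeId] | None
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sorted_edges(self) -> list[tuple[NodeId, NodeId]]:
        """Canonical edge order: lexicographic on (min, max) endpoint ids."""
        return sorted(tuple(sorted(e)) for e in self.graph.edges())


def _normalize_gens(gens) -> list[tuple[Generator, float]]:
    if isinstance(gens, Generator):
        return [(gens, 1.0)]
    pairs = [(g, float(p)) for g, p in gens]
    if not pairs:
        raise ValueError("at least one generator is required")
    total = sum(p for _, p in pairs)
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"selection probabilities sum to {total}, not 1")
    return pairs


def _initial_network(g0: nx.Graph | None) -> HierarchicalNetwork:
    graph = nx.Graph()
    if g0 is None:
        a: NodeId = (0, 0, "rrn1")
        b: NodeId = (0, 0, "rrn2")
        graph.add_node(a, birth=0)
        graph.add_node(b, birth=0)
        graph.add_edge(a, b)
        return HierarchicalNetwork(graph, 0, (a, b), {"g0": "edge"})
    for n in g0.nodes():
        graph.add_node((0, 0, str(n)), birth=0)
    for u, v in g0.edges():
        graph.add_edge((0, 0, str(u)), (0, 0, str(v)))
    # no canonical RRN pair for a custom G0; size closed forms do not apply
    return HierarchicalNetwork(graph, 0, None, {"g0": "custom"})


def expand_once(net: HierarchicalNetwork, gens, seed: int | None = 0,
                ) -> HierarchicalNetwork:
    """Replace every edge of ``net`` with a generator copy.

    Generator choice (if several) and orientation (if asymmetric) are drawn
    from a stream keyed by ``(seed, generation)``; edges are processed in
    canonical sorted order, so results do not depend on iteration order.
    For a single symmetric generator no randomness is consumed and the
    result is bit-identical across seeds.
    """
    pairs = _normalize_gens(gens)
    t = net.t + 1
    edges = net.sorted_edges()
    n_e = len(edges)

    symmetric = [is_symmetric(g) for g, _ in pairs]
    deterministic = len(pairs) == 1 and symmetric[0]
    if deterministic:
        choices = np.zeros(n_e, dtype=np.intp)
        flips = np.zeros(n_e, dtype=bool)
    else:
        rng = np.random.default_rng([0 if seed is None else int(seed), t])
        probs = np.array([p for _, p in pairs])
        choices = rng.choice(len(pairs), size=n_e, p=probs)
        flips = rng.random(n_e) < 0.5

    out = nx.Graph()
    for n, data in net.graph.nodes(data=True):
        out.add_node(n, birth=data.get("birth", 0))
    for ei, (u, v) in enumerate(edges):
        gen = pairs[choices[ei]][0]
        r1, r2 = gen.roots
        # symmetric generators are orientation-invariant: fix u -> r1
        if symmetric[choices[ei]] or not flips[ei]:
            mapping = {r1: u, r2: v}
        else:
            mapping = {r1: v, r2: u}
        for label in gen.nodes:
            if label not in mapping:
                nid = (t, ei, label)
                mapping[label] = nid
                out.add_node(nid, birth=t)
        for a, b in gen.edges:
            out.add_edge(mapping[a], mapping[b])
    prov = dict(net.provenance)
    prov.update(seed=seed, generators=[g.name or "custom" for g, _ in pairs],
                probabilities=[p for _, p in pairs])
    return HierarchicalNetwork(out, t, net.rrns, prov)


def build_network(gens, t: int, seed: int | None = 0,
                  g0: nx.Graph | None = None,
                  node_cap: int = 10_000_000) -> HierarchicalNetwork:
    """Build the generation-``t`` network by ``t``-fold edge replacement.

    Deterministic given ``(gens, t, seed, g0)``.  ``node_cap`` guards
    against runaway growth (the node count is known in advance from the
    generator sizes when ``g0`` is the default single edge).
    """
    if t < 0:
        raise ValueError("generation t must be non-negative")
    pairs = _normalize_gens(gens)
    net = _initial_network(g0)
    m_max = max(g.m_gen for g, _ in pairs)
    n_max = max(g.n_gen for g, _ in pairs)
    est_nodes = net.n_nodes + net.n_edges * (n_max - 2) * (
        (m_max ** t - 1) // (m_max - 1) if m_max > 1 else t)
    if est_nodes > node_cap:
        raise ValueError(
            f"generation {t} could reach {est_nodes} nodes, above the cap "
            f"{node_cap}"
        )
    for _ in range(t):
        net = expand_once(net, pairs, seed=seed)
    return net


def degree_census(net: HierarchicalNetwork) -> dict[int, int]:
    """Exact degree -> node count table of a built network."""
    return dict(Counter(d for _, d in net.graph.degree()))


def triangle_census(net: HierarchicalNetwork) -> dict:
    """Per-node triangle counts of a built network."""
    return nx.triangles(net.graph)
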