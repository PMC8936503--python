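"""Generator graphs: the small rooted graphs that drive edge replacement.

A *generator* is a small connected, undirected, simple graph with two
designated *root nodes*.  A hierarchical fractal scale-free network (FSFN)
is grown by repeatedly replacing every edge of the current network with a
copy of the generator, identifying the edge's endpoints with the roots.
Every closed-form property of the grown network is determined by a handful
of integer descriptors of the generator, collected here in
:class:`GeneratorDescriptors`.

Deterministic growth requires three conditions on the generator:

1. both root degrees are at least 2 (scale-free property),
2. the roots are at shortest-path distance 2 or more (fractality),
3. the roots are *symmetric*: deleting either root (with its edges)
   yields isomorphic graphs (determinism).

Violating any of them is allowed — the growth and most analytics still make
sense — so :func:`validate_conditions` reports warnings rather than raising.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

__all__ = [
    "Generator",
    "GeneratorDescriptors",
    "ConditionReport",
    "GeneratorError",
    "load_generator",
    "validate_conditions",
    "is_symmetric",
    "compute_descriptors",
    "core_subgraph",
    "builtin_generator",
    "BUILTIN_NAMES",
]


class GeneratorError(ValueError):
    """Raised for malformed generator descriptions."""


@dataclass(frozen=True)
class Generator:
    """A rooted generator graph.

    Parameters
    ----------
    nodes :
        Opaque string labels, all distinct.
    edges :
        Unordered pairs of labels; no self-loops or duplicates.
    roots :
        The ordered root pair ``(r1, r2)``.  Order matters only for
        asymmetric generators, where the two roots are inequivalent.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    roots: tuple[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        nodes = tuple(str(n) for n in self.nodes)
        edges = tuple(tuple(sorted((str(u), str(v)))) for u, v in self.edges)
        roots = tuple(str(r) for r in self.roots)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "roots", roots)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise GeneratorError("duplicate node labels")
        node_set = set(self.nodes)
        seen = set()
        for u, v in self.edges:
            if u == v:
                raise GeneratorError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise GeneratorError(f"edge ({u!r}, {v!r}) uses unknown label")
            if (u, v) in seen:
                raise GeneratorError(f"duplicate edge ({u!r}, {v!r})")
            seen.add((u, v))
        if len(self.roots) != 2:
            raise GeneratorError("exactly two roots are required")
        r1, r2 = self.roots
        if r1 == r2:
            raise GeneratorError("the two roots must be distinct")
        for r in self.roots:
            if r not in node_set:
                raise GeneratorError(f"root {r!r} is not a node")
        g = self.graph()
        if len(self.nodes) and not nx.is_connected(g):
            raise GeneratorError("generator graph is not connected")

    def graph(self) -> nx.Graph:
        """Return the generator as a fresh :class:`networkx.Graph`."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_gen(self) -> int:
        return len(self.nodes)

    @property
    def m_gen(self) -> int:
        return len(self.edges)

    def remaining_nodes(self) -> tuple[str, ...]:
        rset = set(self.roots)
        return tuple(n for n in self.nodes if n not in rset)

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": [list(e) for e in self.edges],
            "roots": list(self.roots),
        }

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_dict(cls, data: Mapping, name: str = "") -> "Generator":
        try:
            nodes = data["nodes"]
            edges = data["edges"]
            roots = data["roots"]
        except (KeyError, TypeError) as exc:
            raise GeneratorError(
                "generator description needs 'nodes', 'edges' and 'roots' keys"
            ) from exc
        edges = tuple((u, v) for u, v in edges)
        return cls(tuple(nodes), edges, tuple(roots), name=name)


def load_generator(source: str | Path | Mapping) -> Generator:
    """Load a generator from a JSON file, JSON text, or a mapping.

    The file format is a UTF-8 JSON object with three keys: ``nodes`` (list
    of labels), ``edges`` (list of two-label lists) and ``roots`` (two-label
    list).
    """
    if isinstance(source, Mapping):
        return Generator.from_dict(source)
    path = Path(source)
    if path.exists():
        text = path.read_text(encoding="utf-8")
        name = path.stem
    else:
        text = str(source)
        name = ""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise GeneratorError(f"cannot parse generator description: {exc}") from exc
    return Generator.from_dict(data, name=name)


@dataclass
class ConditionReport:
    """Outcome of the three deterministic-growth conditions."""

    cond1: bool   # min root degree >= 2
    cond2: bool   # root distance >= 2
    cond3: bool   # roots symmetric under deletion
    messages: list[str] = field(default_factory=list)

    @property
    def all_ok(self) -> bool:
        return self.cond1 and self.cond2 and self.cond3


def validate_conditions(g: Generator) -> ConditionReport:
    """Check the three growth conditions; violations are warnings only.

    With condition 1 or 2 violated the grown network loses the scale-free
    or fractal property respectively (degree exponents and the fractal
    dimension are then meaningless) but sizes, clustering and the joint
    degree distribution remain valid.  With condition 3 violated the growth
    is stochastic rather than deterministic.
    """
    graph = g.graph()
    r1, r2 = g.roots
    k1, k2 = graph.degree(r1), graph.degree(r2)
    lam = nx.shortest_path_length(graph, r1, r2)
    msgs: list[str] = []
    cond1 = min(k1, k2) >= 2
    if not cond1:
        msgs.append(
            f"condition 1 violated: root degree {min(k1, k2)} < 2; "
            "the grown network is not scale-free"
        )
    cond2 = lam >= 2
    if not cond2:
        msgs.append(
            "condition 2 violated: roots are adjacent; the grown network "
            "is small-world, not fractal"
        )
    cond3 = is_symmetric(g)
    if not cond3:
        msgs.append(
            "condition 3 violated: roots are asymmetric; growth is "
            "stochastic (fair-coin edge orientation)"
        )
    return ConditionReport(cond1, cond2, cond3, msgs)


def is_symmetric(g: Generator, size_cap: int = 32) -> bool:
    """Decide root symmetry by the deletion test.

    The roots are symmetric iff the graph with ``r1`` (and its edges)
    removed is isomorphic to the graph with ``r2`` removed.  Isomorphism is
    decided exactly (VF2), which is cheap at generator scale.

    Note this is deliberately *not* the same as asking for an automorphism
    swapping the roots; the deletion test is the defining notion here.
    """
    if g.n_gen > size_cap:
        raise GeneratorError(
            f"generator has {g.n_gen} nodes, above the symmetry test cap "
            f"{size_cap}"
        )
    graph = g.graph()
    r1, r2 = g.roots
    h1 = graph.copy()
    h1.remove_node(r1)
    h2 = graph.copy()
    h2.remove_node(r2)
    return nx.is_isomorphic(h1, h2)


@dataclass(frozen=True)
class GeneratorDescriptors:
    """Integer/rational descriptors of a generator.

    These are the *only* inputs to the closed-form structure theory.
    Notation: ``kappa1``/``kappa2`` are the root degrees, ``kappa_bar``
    their mean, ``kappa_check`` half their absolute difference, ``lam`` the
    root-to-root shortest-path distance, ``k_rem`` the degree sequence of
    the remaining (non-root) nodes and ``tri_rem`` the per-remaining-node
    triangle counts (aligned with ``k_rem``).  ``mu1(k)``/``mu2(k)`` count
    the degree-``k`` neighbours of each root, and ``m_rem[(k, k')]`` the
    edges joining two remaining nodes of degrees ``k`` and ``k'``.
    """

    m_gen: int
    n_gen: int
    n_rem: int
    kappa1: int
    kappa2: int
    kappa_bar: Fraction
    kappa_check: Fraction
    lam: int
    k_rem: tuple[int, ...]
    tri_rem: tuple[int, ...]
    K2rem: int
    delta_gen: int
    delta_r1: int
    delta_r2: int
    c_rem: Fraction
    mu1: Mapping[int, int]
    mu2: Mapping[int, int]
    m_rem: Mapping[tuple[int, int], int]
    symmetric: bool
    k_mean_gen: Fraction
    k2_mean_gen: Fraction

    @property
    def kappa(self) -> int:
        """Root degree of a symmetric generator."""
        if self.kappa1 != self.kappa2:
            raise ValueError("kappa is defined only when the root degrees agree")
        return self.kappa1

    @property
    def delta_root(self) -> int:
        """Per-root triangle count of a symmetric generator."""
        if self.delta_r1 != self.delta_r2:
            raise ValueError("delta_root requires equal per-root triangle counts")
        return self.delta_r1

    def mu(self, k: int) -> int:
        """Degree-``k`` neighbour count of one root (symmetric case)."""
        if dict(self.mu1) != dict(self.mu2):
            raise ValueError("mu is defined only for symmetric root neighbourhoods")
        return self.mu1.get(k, 0)


def compute_descriptors(g: Generator) -> GeneratorDescriptors:
    """Measure every structural descriptor of a generator, exactly."""
    graph = g.graph()
    r1, r2 = g.roots
    deg = dict(graph.degree())
    tri = nx.triangles(graph)
    rem = g.remaining_nodes()
    k_rem = tuple(deg[n] for n in rem)
    tri_rem = tuple(tri[n] for n in rem)
    kappa1, kappa2 = deg[r1], deg[r2]
    lam = nx.shortest_path_length(graph, r1, r2)
    c_rem = Fraction(0)
    for kn, dn in zip(k_rem, tri_rem):
        if kn >= 2:
            c_rem += Fraction(2 * dn, kn * (kn - 1))
    c_rem = c_rem / len(rem) if rem else Fraction(0)
    mu1 = Counter(deg[n] for n in graph.neighbors(r1))
    mu2 = Counter(deg[n] for n in graph.neighbors(r2))
    rem_set = set(rem)
    m_rem: Counter = Counter()
    for u, v in graph.edges():
        if u in rem_set and v in rem_set:
            m_rem[tuple(sorted((deg[u], deg[v])))] += 1
    n = g.n_gen
    degsum = sum(deg.values())
    sqsum = sum(d * d for d in deg.values())
    return GeneratorDescriptors(
        m_gen=g.m_gen,
        n_gen=n,
        n_rem=len(rem),
        kappa1=kappa1,
        kappa2=kappa2,
        kappa_bar=Fraction(kappa1 + kappa2, 2),
        kappa_check=Fraction(abs(kappa1 - kappa2), 2),
        lam=lam,
        k_rem=k_rem,
        tri_rem=tri_rem,
        K2rem=sum(k * k for k in k_rem),
        delta_gen=sum(tri.values()) // 3,
        delta_r1=tri[r1],
        delta_r2=tri[r2],
        c_rem=c_rem,
        mu1=dict(mu1),
        mu2=dict(mu2),
        m_rem=dict(m_rem),
        symmetric=is_symmetric(g),
        k_mean_gen=Fraction(degsum, n),
        k2_mean_gen=Fraction(sqsum, n),
    )


def core_subgraph(g: Generator) -> Generator:
    """Extract the core: edges lying on at least one simple root-to-root path.

    Edges off the core never influence whether the roots stay connected, so
    bond-percolation quantities of the grown network depend on the core
    alone.  Decided by exhaustive simple-path enumeration, which is exact at
    generator scale.
    """
    graph = g.graph()
    r1, r2 = g.roots
    used: set[tuple[str, str]] = set()
    for path in nx.all_simple_paths(graph, r1, r2):
        for u, v in zip(path, path[1:]):
            used.add(tuple(sorted((u, v))))
    edges = tuple(e for e in g.edges if e in used)
    nodes = tuple(n for n in g.nodes
                  if n in g.roots or any(n in e for e in edges))
    return Generator(nodes, edges, g.roots, name=g.name + "-core" if g.name else "")


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------

BUILTIN_NAMES = ("A", "B", "C", "flower", "shm")

_FIXTURE_A = Generator(
    nodes=("r1", "r2", "a", "b", "c", "d"),
    edges=(("r1", "a"), ("r1", "b"), ("a", "b"), ("a", "c"),
           ("b", "d"), ("c", "d"), ("r2", "c"), ("r2", "d")),
    roots=("r1", "r2"),
    name="A",
)

_FIXTURE_B = Generator(
    nodes=("r1", "r2", "a", "b", "c", "d"),
    edges=(("r1", "a"), ("r1", "b"), ("a", "c"), ("a", "d"),
           ("b", "c"), ("b", "d"), ("r2", "c"), ("r2", "d")),
    roots=("r1", "r2"),
    name="B",
)

_FIXTURE_C = Generator(
    nodes=("R1", "R2", "a", "b", "c"),
    edges=(("R1", "a"), ("R1", "b"), ("R1", "c"), ("a", "b"),
           ("b", "c"), ("R2", "a"), ("R2", "c")),
    roots=("R1", "R2"),
    name="C",
)


def builtin_generator(name: str, *, u: int | None = None, v: int | None = None,
                      z: int | None = None) -> Generator:
    """Return a built-in generator fixture.

    ``A`` and ``B`` are the two symmetric 6-node/8-edge reference
    generators (equal in every descriptor except triangle content); ``C``
    is the asymmetric 5-node/7-edge reference.  ``flower`` (parameters
    ``u >= v >= 2``) is a cycle of ``u + v`` nodes with roots at cyclic
    distance ``v``, reproducing the (u, v)-flower family.  ``shm``
    (parameter ``z >= 2``) joins two ``z``-leaf stars by one leaf-to-leaf
    bridge, reproducing the Song-Havlin-Makse family.
    """
    if name == "A":
        return _FIXTURE_A
    if name == "B":
        return _FIXTURE_B
    if name == "C":
        return _FIXTURE_C
    if name == "flower":
        if u is None or v is None:
            raise GeneratorError("flower generator needs parameters u and v")
        if not (u >= v >= 2):
            raise GeneratorError("flower parameters must satisfy u >= v >= 2")
        n = u + v
        nodes = tuple(f"n{i}" for i in range(n))
        edges = tuple((f"n{i}", f"n{(i + 1) % n}") for i in range(n))
        return Generator(nodes, edges, (f"n0", f"n{v}"), name=f"flower({u},{v})")
    if name == "shm":
        if z is None:
            raise GeneratorError("shm generator needs parameter z")
        if z < 2:
            raise GeneratorError("shm parameter must satisfy z >= 2")
        nodes = ["r1", "r2"] + [f"a{i}" for i in range(z)] + [f"b{i}" for i in range(z)]
        edges = [("r1", f"a{i}") for i in range(z)]
        edges += [("r2", f"b{i}") for i in range(z)]
        edges.append(("a0", "b0"))
        return Generator(tuple(nodes), tuple(edges), ("r1", "r2"), name=f"shm({z})")
    raise GeneratorError(
        f"unknown builtin generator {name!r}; choose from {BUILTIN_NAMES}"
    )


def resolve_generator(spec: str) -> Generator:
    """Resolve ``fixture:NAME`` / ``fixture:flower:u,v`` / file path specs."""
    if spec.startswith("fixture:"):
        parts = spec.split(":")
        name = parts[1]
        if name == "flower":
            u, v = (int(x) for x in parts[2].split(","))
            return builtin_generator("flower", u=u, v=v)
        if name == "shm":
            return builtin_generator("shm", z=int(parts[2]))
        return builtin_generator(name)
    return load_generator(spec)
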