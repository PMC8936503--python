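"""Renormalization theory of bond percolation on hierarchical FSFNs.

Removing each edge independently with probability ``1 - p`` renormalizes
exactly under edge replacement: the probability ``R_t(p)`` that the two
renormalized root nodes stay connected obeys ``R_t = pi(R_{t-1})`` where
``pi`` is the two-terminal reliability polynomial of the generator,

    pi(p) = sum_m s_m p^m (1 - p)^(m_gen - m),

with ``s_m`` the number of ``m``-edge spanning subgraphs connecting the
roots.  The unstable fixed point ``pi(p_c) = p_c`` with ``pi'(p_c) > 1``
is the percolation threshold of the infinite network, and the map's
linearization yields the correlation exponents.  The order-parameter
exponent follows from a 2x2 transfer matrix propagating the probabilities
of a random node touching exactly one / both renormalized roots.

Everything is exact combinatorics (bitmask enumeration over edge subsets,
union-find connectivity) plus one scalar root find.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .generators import (Generator, GeneratorDescriptors, compute_descriptors,
                         core_subgraph)
from .structure_theory import fractal_dimension

__all__ = [
    "ConnectivityPolynomial",
    "TransferMatrix",
    "PercolationReport",
    "MultipleFixedPointsError",
    "root_connectivity_counts",
    "pi_eval",
    "pi_derivative",
    "pi_iterate",
    "critical_point",
    "correlation_exponents",
    "transfer_matrix_coefficients",
    "transfer_matrix_at",
    "order_parameter_exponent",
    "percolation_report",
]


class MultipleFixedPointsError(RuntimeError):
    """More than one unstable fixed point of ``pi(p) = p`` in (0, 1)."""

    def __init__(self, roots):
        self.roots = list(roots)
        super().__init__(
            f"pi(p) - p has several unstable roots in (0, 1): {self.roots}"
        )


# ---------------------------------------------------------------------------
# Union-find over generator nodes (tiny, but called 2^m times)
# ---------------------------------------------------------------------------

class _DSU:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass
class ConnectivityPolynomial:
    """Two-terminal reliability polynomial of a generator core.

    ``s[m]`` counts ``m``-edge subsets of the core subgraph connecting the
    roots; ``m_edges`` is the core edge count (the polynomial degree) and
    ``lam`` the root distance (smallest ``m`` with ``s_m > 0``).
    """

    s: dict[int, int]
    m_edges: int
    lam: int

    def coefficients(self) -> list[int]:
        """``s_m`` for ``m = 0 .. m_edges`` as a dense list."""
        return [self.s.get(m, 0) for m in range(self.m_edges + 1)]


def root_connectivity_counts(g: Generator,
                             enumeration_cap: int = 24) -> ConnectivityPolynomial:
    """Count root-connecting edge subsets of the generator core, exactly.

    Enumerates all ``2**m`` subsets of the core subgraph's edges (edges off
    the core cannot affect root connectivity, and dropping them keeps the
    polynomial degree minimal) and tests root connectivity with union-find.
    """
    core = core_subgraph(g)
    m = core.m_gen
    if m > enumeration_cap:
        raise ValueError(
            f"core subgraph has {m} edges, above the enumeration cap "
            f"{enumeration_cap}"
        )
    idx = {n: i for i, n in enumerate(core.nodes)}
    edges = [(idx[u], idx[v]) for u, v in core.edges]
    r1, r2 = idx[core.roots[0]], idx[core.roots[1]]
    n = len(core.nodes)
    s: dict[int, int] = {}
    for mask in range(1 << m):
        dsu = _DSU(n)
        for i in range(m):
            if mask >> i & 1:
                dsu.union(*edges[i])
        if dsu.find(r1) == dsu.find(r2):
            mm = mask.bit_count()
            s[mm] = s.get(mm, 0) + 1
    lam = min(s) if s else m + 1
    return ConnectivityPolynomial(s, m, lam)


def pi_eval(poly: ConnectivityPolynomial, p: float) -> float:
    """Root-connection probability ``pi(p)`` at occupation probability ``p``."""
    q = 1.0 - p
    return sum(c * p ** m * q ** (poly.m_edges - m) for m, c in poly.s.items())


def pi_derivative(poly: ConnectivityPolynomial, p: float) -> float:
    """Exact first derivative ``pi'(p)``."""
    q = 1.0 - p
    tot = 0.0
    for m, c in poly.s.items():
        mm = poly.m_edges - m
        if m:
            tot += c * m * p ** (m - 1) * q ** mm
        if mm:
            tot -= c * mm * p ** m * q ** (mm - 1)
    return tot


def pi_iterate(poly: ConnectivityPolynomial, p: float, t: int) -> float:
    """``t``-fold composition ``R_t(p)`` with ``R_0(p) = p``."""
    r = float(p)
    for _ in range(t):
        r = pi_eval(poly, r)
    return r


def critical_point(poly: ConnectivityPolynomial,
                   grid_points: int = 10_001,
                   xtol: float = 1e-12) -> tuple[float, float]:
    """Unstable fixed point of ``pi`` in (0, 1) and the slope there.

    A sign-change scan on a uniform grid brackets every root of
    ``pi(p) - p``; each bracket is refined by bisection.  The root with
    ``pi'(p) > 1`` is the percolation threshold.  If no unstable root
    exists (tree-like cores, where ``pi(p) < p`` throughout) the threshold
    is 1 and no transition occurs below full occupation.
    """
    f = lambda p: pi_eval(poly, p) - p
    grid = np.linspace(0.0, 1.0, grid_points)
    vals = np.array([f(x) for x in grid])
    roots = []
    for i in range(1, grid_points - 1):
        a, b = grid[i], grid[i + 1]
        if vals[i] == 0.0:
            roots.append(a)
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(brentq(f, a, b, xtol=xtol))
    unstable = [r for r in roots if 0.0 < r < 1.0 and pi_derivative(poly, r) > 1.0]
    if not unstable:
        return 1.0, pi_derivative(poly, 1.0)
    if len(unstable) > 1:
        raise MultipleFixedPointsError(unstable)
    pc = unstable[0]
    return pc, pi_derivative(poly, pc)


def correlation_exponents(poly: ConnectivityPolynomial,
                          d: GeneratorDescriptors,
                          pc: float) -> tuple[float, float]:
    """Correlation length and volume exponents ``(nu, nu_tilde)``.

    ``nu = log(lambda)/log(pi'(p_c))`` and
    ``nu_tilde = log(m_gen)/log(pi'(p_c))``; the identity
    ``nu_tilde = D_f * nu`` holds by construction and is asserted.
    """
    if not (0.0 < pc < 1.0):
        raise ValueError("correlation exponents need p_c in (0, 1)")
    slope = pi_derivative(poly, pc)
    if slope <= 1.0:
        raise ValueError(f"pi'(p_c) = {slope} <= 1: not an unstable fixed point")
    nu = math.log(d.lam) / math.log(slope)
    # the volume exponent uses the full edge count m_gen (it sets the size
    # growth per generation), even when the polynomial lives on a smaller core
    nu_tilde = math.log(d.m_gen) / math.log(slope)
    d_f = fractal_dimension(d)
    assert abs(nu_tilde - d_f * nu) < 1e-9
    return nu, nu_tilde


# ---------------------------------------------------------------------------
# Transfer matrix
# ---------------------------------------------------------------------------

@dataclass
class TransferMatrix:
    """Coefficients ``c_ij(m)`` of the 2x2 generation-transfer matrix.

    Entry ``w_ij`` propagates (exactly-one-root, both-roots) connection
    probabilities across one renormalization step:

        w_ij(R) = 1/(m_gen (1 + delta_{1j}))
                  * sum_m c_ij(m) R^m (1 - R)^(m_gen - 1 - m).

    ``c[(i, j)][m]`` counts, over all host edges ``e0`` (and for ``j = 1``
    over both terminal choices of ``e0``), the configurations of ``m``
    percolating sibling copies in which exactly ``i`` roots of the
    generator are reached from the walker's attachment set.
    """

    c: dict[tuple[int, int], np.ndarray]
    m_gen: int


def transfer_matrix_coefficients(g: Generator,
                                 enumeration_cap: int = 24) -> TransferMatrix:
    """Enumerate the transfer-matrix coefficients ``c_ij(m)``.

    For each edge ``e0`` of the full generator the walker's own copy of the
    previous generation sits on ``e0``; each other edge is a sibling copy
    that either percolates between its endpoints (weight ``R``) or not.
    For ``j = 1`` the walker reaches exactly one terminal of ``e0`` (both
    terminal choices are counted; the ``1/2`` lives in the ``w_1j``
    prefactor); for ``j = 2`` it reaches both terminals, which are then
    effectively merged even though ``e0`` itself carries no sibling copy.
    ``i`` is the number of generator roots reachable from the attachment
    set through percolating siblings.
    """
    m = g.m_gen
    if m > enumeration_cap:
        raise ValueError(
            f"generator has {m} edges, above the enumeration cap "
            f"{enumeration_cap}"
        )
    idx = {n: i for i, n in enumerate(g.nodes)}
    edges = [(idx[u], idx[v]) for u, v in g.edges]
    r1, r2 = idx[g.roots[0]], idx[g.roots[1]]
    n = len(g.nodes)
    c = {(i, j): np.zeros(m, dtype=np.int64) for i in (1, 2) for j in (1, 2)}
    for e0 in range(m):
        rest = [edges[i] for i in range(m) if i != e0]
        u, v = edges[e0]
        for mask in range(1 << (m - 1)):
            dsu = _DSU(n)
            for i in range(m - 1):
                if mask >> i & 1:
                    dsu.union(*rest[i])
            mm = mask.bit_count()
            fr1, fr2 = dsu.find(r1), dsu.find(r2)
            # j = 1: walker holds a single terminal of e0
            for w in (u, v):
                fw = dsu.find(w)
                hit = (fw == fr1) + (fw == fr2)
                if hit:
                    c[(hit, 1)][mm] += 1
            # j = 2: walker holds both terminals, merged through its copy
            dsu.union(u, v)
            fu = dsu.find(u)
            hit = (fu == dsu.find(r1)) + (fu == dsu.find(r2))
            if hit:
                c[(hit, 2)][mm] += 1
    return TransferMatrix(c, m)


def transfer_matrix_at(tm: TransferMatrix, r: float) -> np.ndarray:
    """Evaluate the 2x2 matrix ``W`` at root-connection probability ``r``."""
    m = tm.m_gen
    w = np.zeros((2, 2))
    for (i, j), coeffs in tm.c.items():
        pref = 1.0 / (m * (2 if j == 1 else 1))
        w[i - 1, j - 1] = pref * sum(
            coeffs[k] * r ** k * (1.0 - r) ** (m - 1 - k) for k in range(m)
        )
    return w


def _largest_eigenvalue_2x2(w: np.ndarray) -> float:
    # closed-form quadratic: no library ordering ambiguity
    a, b = w[0, 0], w[0, 1]
    c, d = w[1, 0], w[1, 1]
    half_tr = (a + d) / 2.0
    disc = ((a - d) / 2.0) ** 2 + b * c
    return half_tr + math.sqrt(max(disc, 0.0))


def order_parameter_exponent(tm: TransferMatrix,
                             poly: ConnectivityPolynomial,
                             pc: float) -> tuple[float, float]:
    """Largest eigenvalue ``omega_c`` of ``W`` at ``p_c`` and the exponent
    ``beta = -log(omega_c)/log(pi'(p_c))``."""
    if not (0.0 < pc < 1.0):
        raise ValueError("order-parameter exponent needs p_c in (0, 1)")
    omega_c = _largest_eigenvalue_2x2(transfer_matrix_at(tm, pc))
    if not (0.0 < omega_c < 1.0):
        raise ValueError(f"largest eigenvalue {omega_c} outside (0, 1)")
    slope = pi_derivative(poly, pc)
    beta = -math.log(omega_c) / math.log(slope)
    return omega_c, beta


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PercolationReport:
    p_c: float
    pi_slope: float | None
    nu: float | None
    nu_tilde: float | None
    omega_c: float | None
    beta: float | None
    polynomial: ConnectivityPolynomial = None
    transfer_matrix: TransferMatrix = None
    core_edges: int = 0
    has_transition: bool = True


def percolation_report(g: Generator,
                       enumeration_cap: int = 24) -> PercolationReport:
    """Critical point and exponents of bond percolation for one generator."""
    d = compute_descriptors(g)
    poly = root_connectivity_counts(g, enumeration_cap)
    pc, slope = critical_point(poly)
    if pc >= 1.0:
        return PercolationReport(1.0, None, None, None, None, None,
                                 polynomial=poly, core_edges=poly.m_edges,
                                 has_transition=False)
    nu, nu_tilde = correlation_exponents(poly, d, pc)
    tm = transfer_matrix_coefficients(g, enumeration_cap)
    omega_c, beta = order_parameter_exponent(tm, poly, pc)
    return PercolationReport(pc, slope, nu, nu_tilde, omega_c, beta,
                             polynomial=poly, transfer_matrix=tm,
                             core_edges=poly.m_edges, has_transition=True)
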