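"""Closed-form structural theory of hierarchical FSFNs.

Every quantity here is computed from generator descriptors alone — no
network is ever built.  The central recurrences are the degree-count
evolution (a degree-``k`` node of generation ``t-1`` acquires degree
``kappa * k``, or a binomial mixture of ``kappa1``/``kappa2`` multipliers
for asymmetric generators, while each replaced edge injects the remaining
nodes of the generator) and the triangle bookkeeping that follows from the
fact that *all* triangles of generation ``t`` are created inside generator
copies during the last replacement step.

Exact integer/rational arithmetic is used wherever the formulas permit
(sizes, tables, moments, global clustering); floats appear only in
logarithms, infinite series and asymmetric expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .generators import Generator, GeneratorDescriptors, compute_descriptors

__all__ = [
    "DegreeCountTable",
    "JointDegreeTable",
    "MomentReport",
    "ExponentReport",
    "CorrelationReport",
    "CorrelationLimitReport",
    "StructureReport",
    "closed_form_sizes",
    "degree_count_table",
    "degree_moments",
    "degree_exponents",
    "fractal_dimension",
    "clustering_average",
    "clustering_global",
    "joint_degree_distribution",
    "degree_correlation_measures",
    "degree_correlation_limit",
    "mixed_generator_exponents",
    "structure_report",
]


# ---------------------------------------------------------------------------
# Sizes
# ---------------------------------------------------------------------------

def closed_form_sizes(d: GeneratorDescriptors, t: int) -> tuple[int, int]:
    """Exact node and edge counts ``(N_t, M_t)`` of generation ``t``.

    ``M_t = m_gen**t`` and ``N_t = 2 + n_rem (m_gen**t - 1)/(m_gen - 1)``,
    valid for any generator (symmetry plays no role) with the single-edge
    initial network.
    """
    if t < 0:
        raise ValueError("generation t must be non-negative")
    m_t = d.m_gen ** t
    n_t = 2 + d.n_rem * (m_t - 1) // (d.m_gen - 1)
    return n_t, m_t


# ---------------------------------------------------------------------------
# Degree-count tables
# ---------------------------------------------------------------------------

@dataclass
class DegreeCountTable:
    """Degree -> (expected) node count at generation ``t``.

    Counts are exact integers for symmetric generators and ensemble
    expectations (floats) for asymmetric ones.
    """

    counts: dict[int, int | float]
    t: int
    exact: bool

    def total(self) -> int | float:
        return sum(self.counts.values())

    def moment(self, order: int) -> Fraction | float:
        num = sum(c * k ** order for k, c in self.counts.items())
        if self.exact:
            return Fraction(num, sum(self.counts.values()))
        return num / self.total()


def _resolve_mode(d: GeneratorDescriptors, mode: str | None) -> str:
    if mode is None:
        return "symmetric" if d.symmetric else "asymmetric"
    if mode not in ("symmetric", "asymmetric"):
        raise ValueError("mode must be 'symmetric' or 'asymmetric'")
    if mode == "symmetric" and d.kappa1 != d.kappa2:
        raise ValueError("symmetric mode requires equal root degrees")
    return mode


def _sym_degree_counts(d: GeneratorDescriptors, t: int) -> dict[int, int]:
    # exact evaluation of the deterministic degree recurrence
    kappa = d.kappa1
    counts: dict[int, int] = {}
    counts[kappa ** t] = counts.get(kappa ** t, 0) + 2
    for tp in range(1, t + 1):
        mult = d.m_gen ** (tp - 1)
        for kn in d.k_rem:
            k = kappa ** (t - tp) * kn
            counts[k] = counts.get(k, 0) + mult
    return counts

# Expected asymmetric tables are dense numpy arrays indexed by degree; the
# degree range grows like max(kappa1, kappa2)**t, hence the cap.

def _asym_degree_array(d: GeneratorDescriptors, t: int,
                       max_degree_cap: int = 2_000_000) -> np.ndarray:
    kmax_mult = max(d.kappa1, d.kappa2)
    if kmax_mult ** t > max_degree_cap:
        raise ValueError(
            f"asymmetric table at t={t} would span degrees up to "
            f"{kmax_mult ** t}, above the cap {max_degree_cap}"
        )
    n = np.zeros(2, dtype=float)
    n[1] = 2.0  # G0: two nodes of degree 1
    for s in range(1, t + 1):
        new = np.zeros(kmax_mult * (len(n) - 1) + 1, dtype=float)
        for k in np.nonzero(n)[0]:
            k1 = np.arange(k + 1)
            target = d.kappa1 * k1 + d.kappa2 * (k - k1)
            np.add.at(new, target, n[k] * binom.pmf(k1, k, 0.5))
        m_prev = d.m_gen ** (s - 1)
        for kn in d.k_rem:
            new[kn] += m_prev
        n = new
    return n


def degree_count_table(d: GeneratorDescriptors, t: int,
                       mode: str | None = None) -> DegreeCountTable:
    """Degree-count table ``N_t(k)`` at generation ``t``.

    Symmetric generators admit an exact closed form: two root-lineage nodes
    of degree ``kappa**t`` plus, for each replacement wave ``t'``,
    ``m_gen**(t'-1)`` copies of every remaining node whose degree has since
    been multiplied by ``kappa**(t-t')``.  For asymmetric generators each
    inherited degree is redistributed binomially over the two root-degree
    multipliers and the table holds ensemble expectations.
    """
    if t < 0:
        raise ValueError("generation t must be non-negative")
    mode = _resolve_mode(d, mode)
    if mode == "symmetric":
        return DegreeCountTable(_sym_degree_counts(d, t), t, exact=True)
    arr = _asym_degree_array(d, t)
    counts = {int(k): float(arr[k]) for k in np.nonzero(arr)[0]}
    return DegreeCountTable(counts, t, exact=False)


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

@dataclass
class MomentReport:
    """First two degree moments; ``second`` is ``None`` when divergent."""

    mean: Fraction | float
    second: Fraction | float | None
    second_diverges: bool
    t: int | None  # None denotes the infinite-generation limit


def degree_moments(d: GeneratorDescriptors, t: int | None = None,
                   mode: str | None = None) -> MomentReport:
    """Average degree and average squared degree at generation ``t``.

    ``t=None`` gives the infinite-generation limit: the mean is always
    ``2 (m_gen - 1)/n_rem``; the second moment is finite iff
    ``m_gen > kappa_bar**2`` (equivalently the degree exponent exceeds 3).
    """
    mode = _resolve_mode(d, mode)
    m, n_rem = d.m_gen, d.n_rem
    if t is None:
        mean = Fraction(2 * (m - 1), n_rem)
        kb2 = d.kappa_bar ** 2
        if Fraction(m) > kb2:
            if mode == "symmetric":
                second = Fraction(d.K2rem * (m - 1), n_rem * (m - d.kappa1 ** 2))
            else:
                second = (Fraction(m - 1) * (2 * d.kappa_check ** 2 + d.K2rem)
                          / (n_rem * (m - kb2)))
            return MomentReport(mean, second, False, None)
        return MomentReport(mean, None, True, None)

    n_t, m_t = closed_form_sizes(d, t)
    mean = Fraction(2 * m_t, n_t)
    if mode == "symmetric":
        kappa = d.kappa1
        k2 = kappa ** 2
        if m != k2:
            num = (m - 1) * (2 * k2 ** t * (m - k2) + d.K2rem * (m_t - k2 ** t))
            den = (m - k2) * (2 * (m - 1) + n_rem * (m_t - 1))
            second: Fraction | float = Fraction(num, den)
        else:
            num = k2 ** (t - 1) * (k2 - 1) * (2 * k2 + t * d.K2rem) if t >= 1 else 1
            den = 2 * (k2 - 1) + n_rem * (k2 ** t - 1)
            second = Fraction(num, den) if t >= 1 else Fraction(1)
        return MomentReport(mean, second, False, t)
    table = degree_count_table(d, t, mode="asymmetric")
    return MomentReport(float(mean), float(table.moment(2)), False, t)


# ---------------------------------------------------------------------------
# Exponents
# ---------------------------------------------------------------------------

@dataclass
class ExponentReport:
    """Degree-distribution exponents; ``scale_free`` is False when the
    mean root degree is 1 or less (exponential tail instead)."""

    scale_free: bool
    gamma: float | None
    gamma_prime: float | None


def degree_exponents(d: GeneratorDescriptors) -> ExponentReport:
    """Power-law exponents of ``P(k)`` and of the count table ``N_t(k)``.

    ``gamma = 1 + log(m_gen)/log(kappa_bar)``.  For equal root degrees the
    attainable degrees are exponentially spaced and ``gamma' = gamma - 1``;
    for unequal root degrees the degrees fill in densely and
    ``gamma' = gamma``.
    """
    if d.kappa_bar <= 1:
        return ExponentReport(False, None, None)
    gamma = 1.0 + math.log(d.m_gen) / math.log(d.kappa_bar)
    gamma_prime = gamma - 1.0 if d.kappa1 == d.kappa2 else gamma
    return ExponentReport(True, gamma, gamma_prime)


def fractal_dimension(d: GeneratorDescriptors) -> float:
    """Fractal dimension ``log(m_gen)/log(lambda)``.

    Returns ``inf`` when the roots are adjacent (``lambda = 1``): diameters
    then stop growing geometrically and the network is small-world.
    """
    if d.lam <= 1:
        return math.inf
    return math.log(d.m_gen) / math.log(d.lam)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _sym_clustering_finite(d: GeneratorDescriptors, t: int) -> Fraction:
    if t == 0:
        return Fraction(0)
    kappa = d.kappa1
    d_root = d.delta_root
    n_t, _ = closed_form_sizes(d, t)
    acc = Fraction(d.n_rem * d.m_gen ** (t - 1)) * d.c_rem
    if d_root:
        prev = _sym_degree_counts(d, t - 1)
        for k, cnt in prev.items():
            acc += 2 * d_root * Fraction(cnt, kappa * (kappa * k - 1))
    return acc / n_t


def _sym_clustering_infinite(d: GeneratorDescriptors,
                             series_tol: float = 1e-15) -> float:
    m, kappa = d.m_gen, d.kappa1
    total = float(d.c_rem)
    d_root = d.delta_root
    if d_root:
        series = 0.0
        for kn in d.k_rem:
            s = 1
            while True:
                # geometric tail: terms decay at least like 1/(kappa*m)
                term = 1.0 / ((kappa * m) ** s * kn - m ** s)
                series += term
                if term < series_tol:
                    break
                s += 1
        total += 2.0 * d_root / (kappa * d.n_rem) * series
    return (m - 1) / m * total


def _asym_clustering_finite(d: GeneratorDescriptors, t: int) -> float:
    if t == 0:
        return 0.0
    n_t, _ = closed_form_sizes(d, t)
    acc = d.n_rem * d.m_gen ** (t - 1) * float(d.c_rem)
    if (d.delta_r1 or d.delta_r2) and t >= 1:
        prev = _asym_degree_array(d, t - 1)
        for k in np.nonzero(prev)[0]:
            k1 = np.arange(k + 1)
            h = d.kappa1 * k1 + d.kappa2 * (k - k1)
            tri = d.delta_r1 * k1 + d.delta_r2 * (k - k1)
            ok = h >= 2
            vals = np.zeros(k + 1)
            vals[ok] = 2.0 * tri[ok] / (h[ok] * (h[ok] - 1.0))
            acc += prev[k] * float(np.sum(binom.pmf(k1, k, 0.5) * vals))
    return acc / n_t


def clustering_average(d: GeneratorDescriptors, t: int | None = None,
                       mode: str | None = None, tol: float = 1e-6,
                       series_tol: float = 1e-15,
                       t_cap: int = 10) -> Fraction | float:
    """Average (local) clustering coefficient at generation ``t``.

    All triangles are created inside generator copies, so the coefficient
    splits into the fresh remaining-node contribution (mean ``c_rem``) and
    the inherited-node contribution driven by the per-root triangle counts.
    The symmetric infinite limit is a rapidly converging series truncated
    at ``series_tol``; the asymmetric infinite limit is obtained by
    iterating generations until successive values differ by less than
    ``tol`` (the convergence is geometric, roughly one factor of
    ``1/m_gen`` per generation).
    """
    mode = _resolve_mode(d, mode)
    if t is not None:
        if mode == "symmetric":
            return _sym_clustering_finite(d, t)
        return _asym_clustering_finite(d, t)
    if mode == "symmetric":
        return _sym_clustering_infinite(d, series_tol)
    prev = None
    for s in range(1, t_cap + 1):
        cur = _asym_clustering_finite(d, s)
        if prev is not None and abs(cur - prev) < tol:
            return cur
        prev = cur
    return prev


def clustering_global(d: GeneratorDescriptors, t: int | None = None,
                      mode: str | None = None) -> Fraction | float:
    """Global clustering (transitivity) at generation ``t``.

    Triangles total ``M_{t-1} * delta_gen``; triplets follow from the first
    two degree moments.  The infinite limit vanishes whenever the second
    moment diverges (``m_gen <= kappa_bar**2``), and otherwise equals an
    exact rational in the generator's own degree moments.
    """
    mode = _resolve_mode(d, mode)
    if d.delta_gen == 0:
        return Fraction(0) if mode == "symmetric" else 0.0
    if t is not None:
        if t == 0:
            return Fraction(0) if mode == "symmetric" else 0.0
        mom = degree_moments(d, t, mode=mode)
        num = 3 * d.delta_gen * mom.mean
        den = d.m_gen * (mom.second - mom.mean)
        return num / den
    if Fraction(d.m_gen) <= d.kappa_bar ** 2:
        return Fraction(0)
    return (Fraction(6) * (d.m_gen - d.kappa_bar ** 2) * d.delta_gen
            / (d.n_gen * d.m_gen * (d.k2_mean_gen - d.k_mean_gen)))


# ---------------------------------------------------------------------------
# Joint degree distribution and correlation measures
# ---------------------------------------------------------------------------

@dataclass
class JointDegreeTable:
    """Ordered-pair joint degree distribution ``P_t(k, k')``.

    ``entries[(k, k')]`` is the probability that a uniformly random edge,
    read in a uniformly random direction, joins end degrees ``k`` and
    ``k'``; the table is symmetric and sums to 1.
    """

    entries: dict[tuple[int, int], Fraction | float]
    t: int

    def total_mass(self) -> Fraction | float:
        return sum(self.entries.values())

    def marginal(self) -> dict[int, Fraction | float]:
        q: dict[int, Fraction | float] = {}
        for (k, _), w in self.entries.items():
            q[k] = q.get(k, 0) + w
        return q


def _add(entries: dict, key: tuple[int, int], w) -> None:
    entries[key] = entries.get(key, 0) + w


def _joint_sym(d: GeneratorDescriptors, t: int) -> JointDegreeTable:
    m, kappa = d.m_gen, d.kappa1
    entries: dict[tuple[int, int], Fraction] = {}
    for (k, kp), cnt in d.m_rem.items():
        w = Fraction((1 + (k == kp)) * cnt, 2 * m)
        _add(entries, (k, kp), w)
        if k != kp:
            _add(entries, (kp, k), w)
    prev = _sym_degree_counts(d, t - 1) if t >= 1 else {}
    pref = Fraction(1, 2 * m ** t)
    for kpp, cnt in prev.items():
        big = kappa * kpp
        for kdeg, mu_k in d.mu1.items():
            w = pref * kpp * mu_k * cnt
            _add(entries, (kdeg, big), w)
            _add(entries, (big, kdeg), w)
    return JointDegreeTable(entries, t)


def _joint_asym(d: GeneratorDescriptors, t: int) -> JointDegreeTable:
    m = d.m_gen
    entries: dict[tuple[int, int], float] = {}
    for (k, kp), cnt in d.m_rem.items():
        w = (1 + (k == kp)) * cnt / (2 * m)
        _add(entries, (k, kp), w)
        if k != kp:
            _add(entries, (kp, k), w)
    prev = _asym_degree_array(d, t - 1)
    pref = 1.0 / (2 * m ** t)
    kdegs = sorted(set(d.mu1) | set(d.mu2))
    for kpp in np.nonzero(prev)[0]:
        k1 = np.arange(kpp + 1)
        h = d.kappa1 * k1 + d.kappa2 * (kpp - k1)
        pm = binom.pmf(k1, kpp, 0.5)
        for kdeg in kdegs:
            wvec = (prev[kpp] * pm
                    * (k1 * d.mu1.get(kdeg, 0) + (kpp - k1) * d.mu2.get(kdeg, 0))
                    * pref)
            # accumulate both orderings so the table stays symmetric
            for hv, w in zip(h, wvec):
                if w:
                    _add(entries, (kdeg, int(hv)), w)
                    _add(entries, (int(hv), kdeg), w)
    mass = sum(entries.values())
    if abs(mass - 1.0) > 1e-10:
        raise RuntimeError(f"joint table mass {mass} deviates from 1")
    entries = {k: w / mass for k, w in entries.items()}
    return JointDegreeTable(entries, t)


def joint_degree_distribution(d: GeneratorDescriptors, t: int,
                              mode: str | None = None) -> JointDegreeTable:
    """Joint degree distribution of edge-end pairs at generation ``t >= 1``.

    Edges between freshly added remaining nodes contribute ``m_rem``-driven
    mass; edges from inherited nodes to their new neighbours contribute via
    the root neighbourhood profiles ``mu1``/``mu2`` and the previous
    generation's degree counts.
    """
    if t < 1:
        raise ValueError("the joint distribution needs t >= 1")
    mode = _resolve_mode(d, mode)
    if mode == "symmetric":
        return _joint_sym(d, t)
    return _joint_asym(d, t)


@dataclass
class CorrelationReport:
    assortativity: float | None
    spearman: float | None
    degenerate: bool = False


def degree_correlation_measures(jt: JointDegreeTable) -> CorrelationReport:
    """Assortativity and Spearman rank correlation from a joint table.

    Assortativity is the Pearson correlation of the two end degrees;
    the Spearman coefficient is the Pearson correlation of their mid-rank
    grades (ties resolved by mid-ranks, the standard convention).
    """
    q = jt.marginal()
    if len(q) < 2:
        return CorrelationReport(None, None, degenerate=True)
    ks = sorted(q)
    grade: dict[int, float] = {}
    cum = 0.0
    for k in ks:
        w = float(q[k])
        grade[k] = cum + w / 2.0
        cum += w
    gmean = sum(float(q[k]) * grade[k] for k in ks)
    gvar = sum(float(q[k]) * (grade[k] - gmean) ** 2 for k in ks)
    kmean = sum(float(q[k]) * k for k in ks)
    kvar = sum(float(q[k]) * (k - kmean) ** 2 for k in ks)
    gcov = 0.0
    kcov = 0.0
    for (k, kp), w in jt.entries.items():
        w = float(w)
        gcov += w * (grade[k] - gmean) * (grade[kp] - gmean)
        kcov += w * (k - kmean) * (kp - kmean)
    return CorrelationReport(kcov / kvar, gcov / gvar)


@dataclass
class CorrelationLimitReport:
    spearman: float
    assortativity: float
    spearman_converged: bool
    assortativity_from_theory: bool
    t_stop: int


def degree_correlation_limit(d: GeneratorDescriptors, tol: float = 1e-4,
                             t_max: int = 30,
                             mode: str | None = None) -> CorrelationLimitReport:
    """Infinite-generation correlation measures.

    The Spearman coefficient is iterated over generations until successive
    values differ by less than ``tol``.  The assortativity limit is zero
    whenever ``m_gen <= kappa_bar**3`` (degree exponent at most 4, so the
    third moment diverges); otherwise it is iterated like the Spearman
    coefficient.
    """
    mode = _resolve_mode(d, mode)
    if mode == "asymmetric":
        t_max = min(t_max, 9)  # expected tables grow like kappa_max**t
    r_is_zero = Fraction(d.m_gen) <= d.kappa_bar ** 3
    prev_rho = prev_r = None
    rho = r = 0.0
    t_stop = 1
    converged = False
    for t in range(1, t_max + 1):
        rep = degree_correlation_measures(joint_degree_distribution(d, t, mode))
        rho, r = rep.spearman, rep.assortativity
        t_stop = t
        if prev_rho is not None and abs(rho - prev_rho) < tol and (
                r_is_zero or abs(r - prev_r) < tol):
            converged = True
            break
        prev_rho, prev_r = rho, r
    return CorrelationLimitReport(
        spearman=rho,
        assortativity=0.0 if r_is_zero else r,
        spearman_converged=converged,
        assortativity_from_theory=r_is_zero,
        t_stop=t_stop,
    )


# ---------------------------------------------------------------------------
# Multi-generator exponents
# ---------------------------------------------------------------------------

@dataclass
class MixedExponents:
    gamma: float | None
    d_f: float
    mean_m_gen: Fraction
    mean_kappa: Fraction
    mean_lambda: Fraction


def mixed_generator_exponents(
        pairs: Sequence[tuple[GeneratorDescriptors, float | Fraction]],
) -> MixedExponents:
    """Exponents of the stochastic multi-generator model.

    With each edge replaced by generator ``i`` with probability ``p_i``,
    the degree exponent and fractal dimension keep their single-generator
    forms with ``m_gen``, ``kappa_bar`` and ``lambda`` replaced by their
    selection-probability means.
    """
    probs = [Fraction(p).limit_denominator(10 ** 12) if not isinstance(p, Fraction)
             else p for _, p in pairs]
    if abs(float(sum(probs)) - 1.0) > 1e-12:
        raise ValueError("selection probabilities must sum to 1")
    mean_m = sum(p * d.m_gen for (d, _), p in zip(pairs, probs))
    mean_k = sum(p * d.kappa_bar for (d, _), p in zip(pairs, probs))
    mean_l = sum(p * d.lam for (d, _), p in zip(pairs, probs))
    gamma = (1.0 + math.log(float(mean_m)) / math.log(float(mean_k))
             if mean_k > 1 else None)
    d_f = (math.log(float(mean_m)) / math.log(float(mean_l))
           if mean_l > 1 else math.inf)
    return MixedExponents(gamma, d_f, mean_m, mean_k, mean_l)


# ---------------------------------------------------------------------------
# Orchestrating report
# ---------------------------------------------------------------------------

@dataclass
class StructureReport:
    t: int | None
    n_nodes: int | None
    n_edges: int | None
    k_mean: Fraction | float
    k2_mean: Fraction | float | None
    k2_diverges: bool
    gamma: float | None
    gamma_prime: float | None
    scale_free: bool
    d_f: float
    fractal: bool
    clustering_avg: Fraction | float
    clustering_global: Fraction | float
    assortativity: float | None
    spearman: float | None
    descriptors: GeneratorDescriptors = None


def structure_report(g: Generator, t: int | None = None,
                     corr_tol: float = 1e-4) -> StructureReport:
    """Full structural report for a generator at generation ``t`` (or the
    infinite-generation limit when ``t`` is None).

    Scale-free and fractal sections are flagged inapplicable when the
    corresponding growth condition is violated (roots of degree 1, or
    adjacent roots).
    """
    d = compute_descriptors(g)
    mom = degree_moments(d, t)
    exp = degree_exponents(d)
    fractal = d.lam >= 2
    d_f = fractal_dimension(d)
    c_avg = clustering_average(d, t)
    c_glob = clustering_global(d, t)
    if t is None:
        corr = degree_correlation_limit(d, tol=corr_tol)
        r, rho = corr.assortativity, corr.spearman
        n_nodes = n_edges = None
    else:
        if t >= 1:
            rep = degree_correlation_measures(joint_degree_distribution(d, t))
            r, rho = rep.assortativity, rep.spearman
        else:
            r = rho = None
        n_nodes, n_edges = closed_form_sizes(d, t)
    return StructureReport(
        t=t, n_nodes=n_nodes, n_edges=n_edges,
        k_mean=mom.mean, k2_mean=mom.second, k2_diverges=mom.second_diverges,
        gamma=exp.gamma, gamma_prime=exp.gamma_prime, scale_free=exp.scale_free,
        d_f=d_f, fractal=fractal,
        clustering_avg=c_avg, clustering_global=c_glob,
        assortativity=r, spearman=rho,
        descriptors=d,
    )
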