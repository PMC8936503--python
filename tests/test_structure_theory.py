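"""Closed-form structure analytics against hand-derived and printed values."""

import math
from fractions import Fraction

import pytest

from fsfn import (builtin_generator, closed_form_sizes, clustering_average,
                  clustering_global, compute_descriptors,
                  degree_correlation_limit, degree_correlation_measures,
                  degree_count_table, degree_exponents, degree_moments,
                  fractal_dimension, joint_degree_distribution,
                  mixed_generator_exponents, structure_report)
from fsfn.structure_theory import JointDegreeTable


def desc(name, **kw):
    return compute_descriptors(builtin_generator(name, **kw))


class TestSizes:
    @pytest.mark.parametrize("name, t, expected", [
        ("A", 0, (2, 1)),
        ("A", 3, (294, 512)),
        ("B", 3, (294, 512)),
        ("C", 6, (58826, 117649)),
    ])
    def test_closed_form_sizes(self, name, t, expected):
        assert closed_form_sizes(desc(name), t) == expected


class TestDegreeTables:
    def test_symmetric_tables_for_a(self, desc_a):
        assert degree_count_table(desc_a, 1).counts == {2: 2, 3: 4}
        assert degree_count_table(desc_a, 2).counts == {3: 32, 4: 2, 6: 4}

    def test_asymmetric_first_generation_is_generator_census(self, desc_c):
        t1 = degree_count_table(desc_c, 1)
        assert {k: round(v) for k, v in t1.counts.items()} == {2: 1, 3: 4}

    @pytest.mark.parametrize("name, t", [("A", 4), ("B", 5), ("C", 4)])
    def test_conservation(self, name, t):
        d = desc(name)
        table = degree_count_table(d, t)
        n, m = closed_form_sizes(d, t)
        assert math.isclose(float(table.total()), n, rel_tol=1e-12)
        total_degree = sum(k * c for k, c in table.counts.items())
        assert math.isclose(float(total_degree), 2 * m, rel_tol=1e-12)


class TestMoments:
    def test_infinite_moments_a(self, desc_a):
        mom = degree_moments(desc_a)
        assert mom.mean == Fraction(7, 2)
        assert mom.second == Fraction(63, 4)

    def test_infinite_moments_c(self, desc_c):
        mom = degree_moments(desc_c)
        assert mom.mean == Fraction(4)
        assert mom.second == Fraction(220, 3)

    def test_divergent_second_moment_at_boundary(self):
        mom = degree_moments(desc("flower", u=2, v=2))
        assert mom.second_diverges and mom.second is None

    @pytest.mark.parametrize("t", [1, 2, 3, 4])
    def test_finite_moments_match_table(self, desc_a, t):
        """Closed-form finite-t moments equal the table-derived moments."""
        mom = degree_moments(desc_a, t)
        table = degree_count_table(desc_a, t)
        assert mom.mean == table.moment(1)
        assert mom.second == table.moment(2)

    def test_equal_branch_of_second_moment(self):
        # flower(2,2) sits exactly at m_gen = kappa^2
        d = desc("flower", u=2, v=2)
        mom = degree_moments(d, 3)
        table = degree_count_table(d, 3)
        assert mom.second == table.moment(2)

    def test_asymmetric_mean_equals_size_ratio(self, desc_c):
        mom = degree_moments(desc_c, 3)
        n, m = closed_form_sizes(desc_c, 3)
        assert math.isclose(mom.mean, 2 * m / n, rel_tol=1e-12)


class TestExponents:
    def test_reference_values(self, desc_a, desc_c):
        assert degree_exponents(desc_a).gamma == pytest.approx(4.0, abs=1e-12)
        assert degree_exponents(desc_a).gamma_prime == pytest.approx(3.0)
        assert degree_exponents(desc_c).gamma == pytest.approx(3.1237, abs=5e-5)
        # unequal root degrees: count exponent equals distribution exponent
        assert degree_exponents(desc_c).gamma_prime == \
            degree_exponents(desc_c).gamma

    @pytest.mark.parametrize("u, v", [(2, 2), (3, 2), (4, 3)])
    def test_flower_family(self, u, v):
        d = desc("flower", u=u, v=v)
        assert degree_exponents(d).gamma == \
            pytest.approx(1 + math.log(u + v) / math.log(2))
        assert fractal_dimension(d) == \
            pytest.approx(math.log(u + v) / math.log(v))

    @pytest.mark.parametrize("z", [2, 3, 4])
    def test_shm_family(self, z):
        d = desc("shm", z=z)
        assert degree_exponents(d).gamma == \
            pytest.approx(1 + math.log(2 * z + 1) / math.log(z))
        assert fractal_dimension(d) == \
            pytest.approx(math.log(2 * z + 1) / math.log(3))

    def test_gamma_at_least_two(self):
        for d in [desc("A"), desc("B"), desc("C"), desc("flower", u=4, v=2),
                  desc("shm", z=5)]:
            assert degree_exponents(d).gamma >= 2.0

    def test_degree_one_roots_not_scale_free(self):
        from fsfn import Generator
        path = Generator(("r1", "x", "r2"), (("r1", "x"), ("x", "r2")),
                         ("r1", "r2"))
        rep = degree_exponents(compute_descriptors(path))
        assert not rep.scale_free and rep.gamma is None


class TestFractalDimension:
    def test_reference_values(self, desc_a, desc_c):
        assert fractal_dimension(desc_a) == \
            pytest.approx(math.log(8) / math.log(3))
        assert fractal_dimension(desc_c) == \
            pytest.approx(math.log(7) / math.log(2))

    def test_adjacent_roots_small_world(self):
        from fsfn import Generator
        tri = Generator(("r1", "r2", "x"),
                        (("r1", "r2"), ("r1", "x"), ("x", "r2")),
                        ("r1", "r2"))
        assert math.isinf(fractal_dimension(compute_descriptors(tri)))


class TestClustering:
    def test_average_clustering_limit_a(self, desc_a):
        assert clustering_average(desc_a) == pytest.approx(0.31486, abs=5e-6)

    def test_triangle_free_is_zero_any_generation(self, desc_b):
        for t in [0, 1, 3, None]:
            assert clustering_average(desc_b, t) == 0
            assert clustering_global(desc_b, t) == 0

    def test_average_clustering_limit_c(self, desc_c):
        assert clustering_average(desc_c) == pytest.approx(0.3952, abs=1e-4)

    def test_global_clustering_limits(self, desc_a, desc_c):
        assert clustering_global(desc_a) == Fraction(3, 14)
        assert clustering_global(desc_c) == Fraction(9, 182)

    def test_global_clustering_vanishes_when_second_moment_diverges(self):
        d = desc("flower", u=2, v=2)
        # the flower is triangle-free anyway; force the moment branch with
        # a triangular small-world generator
        from fsfn import Generator
        g = Generator(("r1", "r2", "x", "y"),
                      (("r1", "r2"), ("r1", "x"), ("x", "r2"), ("r1", "y"),
                       ("y", "r2")), ("r1", "r2"))
        dd = compute_descriptors(g)
        assert dd.delta_gen > 0 and dd.m_gen <= float(dd.kappa_bar ** 2)
        assert clustering_global(dd) == 0

    def test_finite_generation_average_converges_to_limit(self, desc_a):
        # t=1 is the generator itself
        assert clustering_average(desc_a, 1) == Fraction(5, 9)
        limit = float(clustering_average(desc_a))
        errors = [abs(float(clustering_average(desc_a, t)) - limit)
                  for t in (2, 4, 6)]
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-4


class TestJointDistribution:
    def test_first_generation_table_of_a(self, desc_a):
        jt = joint_degree_distribution(desc_a, 1)
        assert jt.entries == {(3, 3): Fraction(1, 2),
                              (2, 3): Fraction(1, 4),
                              (3, 2): Fraction(1, 4)}

    @pytest.mark.parametrize("name, t", [("A", 3), ("B", 4), ("C", 3)])
    def test_normalization(self, name, t):
        jt = joint_degree_distribution(desc(name), t)
        assert float(jt.total_mass()) == pytest.approx(1.0, abs=1e-10)
        for w in jt.entries.values():
            assert w >= 0

    @pytest.mark.parametrize("t", [1, 2, 3])
    def test_a_and_b_share_joint_tables(self, desc_a, desc_b, t):
        assert joint_degree_distribution(desc_a, t).entries == \
            joint_degree_distribution(desc_b, t).entries

    def test_symmetric_in_arguments(self, desc_c):
        jt = joint_degree_distribution(desc_c, 3)
        for (k, kp), w in jt.entries.items():
            assert jt.entries[(kp, k)] == pytest.approx(w)


class TestCorrelations:
    def test_spearman_limit_symmetric(self, desc_a, desc_b):
        for d in (desc_a, desc_b):
            rep = degree_correlation_limit(d)
            assert rep.spearman == pytest.approx(-21 / 64, abs=1e-3)

    def test_spearman_limit_asymmetric(self, desc_c):
        rep = degree_correlation_limit(desc_c)
        assert rep.spearman == pytest.approx(-0.5221, abs=1e-3)
        # third moment diverges (gamma < 4): assortativity limit is zero
        assert rep.assortativity == 0.0 and rep.assortativity_from_theory

    def test_product_form_table_is_uncorrelated(self):
        f = {2: 0.3, 5: 0.7}
        entries = {(k, kp): f[k] * f[kp] for k in f for kp in f}
        rep = degree_correlation_measures(JointDegreeTable(entries, t=1))
        assert rep.assortativity == pytest.approx(0.0, abs=1e-12)
        assert rep.spearman == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_table_flagged(self):
        rep = degree_correlation_measures(
            JointDegreeTable({(3, 3): 1.0}, t=1))
        assert rep.degenerate


class TestMixedGenerators:
    def test_single_generator_reduces(self, desc_a):
        mix = mixed_generator_exponents([(desc_a, 1.0)])
        assert mix.gamma == pytest.approx(degree_exponents(desc_a).gamma)
        assert mix.d_f == pytest.approx(fractal_dimension(desc_a))

    def test_identical_descriptors_are_invariant(self, desc_a, desc_b):
        mix = mixed_generator_exponents([(desc_a, 0.5), (desc_b, 0.5)])
        assert mix.gamma == pytest.approx(4.0)
        assert mix.d_f == pytest.approx(math.log(8) / math.log(3))

    def test_gamma_interpolates_monotonically(self):
        d1, d2 = desc("flower", u=2, v=2), desc("flower", u=3, v=3)
        gammas = [mixed_generator_exponents([(d1, p), (d2, 1 - p)]).gamma
                  for p in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert gammas == sorted(gammas, reverse=True)
        assert gammas[-1] == pytest.approx(3.0)

    def test_probabilities_must_sum_to_one(self, desc_a, desc_b):
        with pytest.raises(ValueError):
            mixed_generator_exponents([(desc_a, 0.6), (desc_b, 0.6)])


class TestStructureReport:
    def test_infinite_report_for_a(self, gen_a):
        rep = structure_report(gen_a)
        assert rep.k_mean == Fraction(7, 2)
        assert rep.gamma == pytest.approx(4.0)
        assert rep.clustering_global == Fraction(3, 14)
        assert rep.scale_free and rep.fractal

    def test_finite_report_sizes(self, gen_c):
        rep = structure_report(gen_c, t=3)
        assert (rep.n_nodes, rep.n_edges) == closed_form_sizes(
            compute_descriptors(gen_c), 3)
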