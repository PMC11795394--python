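"""Temporal/interaction structures, constraints, constrained sampling."""

import numpy as np
import pytest

import stmrf
from stmrf.gmrf import (
    HyperParams,
    constraint_set,
    iid_structure,
    interaction_structure,
    rw1_structure,
    sample_constrained_gmrf,
)

from conftest import random_disconnected_graph


class TestRw1:
    def test_T3_matrix(self):
        s = rw1_structure(3)
        np.testing.assert_array_equal(
            s.matrix, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])
        assert s.rank == 2

    def test_T2(self):
        s = rw1_structure(2)
        np.testing.assert_array_equal(s.matrix, [[1, -1], [-1, 1]])
        assert s.rank == 1

    def test_closed_form_eigenvalues(self):
        # eigenvalues of the RW1 structure are 2 - 2 cos(pi k / T)
        T = 8
        s = rw1_structure(T)
        w = np.sort(np.linalg.eigvalsh(s.matrix))
        expected = np.sort(2 - 2 * np.cos(np.pi * np.arange(T) / T))
        np.testing.assert_allclose(w, expected, atol=1e-10)
        assert s.rank == 7

    def test_too_short(self):
        with pytest.raises(ValueError):
            rw1_structure(1)


class TestIid:
    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_identity(self, n):
        s = iid_structure(n)
        np.testing.assert_array_equal(s.matrix, np.eye(n))
        assert s.rank == n
        assert s.null_dim == 0


class TestInteraction:
    def test_type_I_identity(self, toy_graph):
        g = stmrf.build_adjacency([("a", "b"), ("b", "c")], ["a", "b", "c"])
        s = interaction_structure("I", 2, g)
        np.testing.assert_array_equal(s.matrix, np.eye(6))
        assert s.rank == 6

    def test_type_IV_path_rank(self):
        g = stmrf.build_adjacency([("a", "b"), ("b", "c")], ["a", "b", "c"])
        s = interaction_structure("IV", 3, g)
        assert s.rank == 4  # (3-1)(3-1)
        assert s.null_dim == 5
        assert np.linalg.matrix_rank(s.matrix, tol=1e-8) == 4

    def test_type_IV_default_graph(self, default_graph):
        # trim to 4 components of 9 areas for the closed-form count
        g = stmrf.generate_graph(4, ((3, 3),) * 4)
        s = interaction_structure("IV", 4, g)
        assert s.rank == 3 * 32
        assert s.null_dim == 48
        w = np.linalg.eigvalsh(s.matrix)
        assert int((w > 1e-8 * w.max()).sum()) == 96

    @pytest.mark.parametrize("itype,rank_fn", [
        ("I", lambda T, S, C: T * S),
        ("II", lambda T, S, C: (T - 1) * S),
        ("III", lambda T, S, C: T * (S - C)),
        ("IV", lambda T, S, C: (T - 1) * (S - C)),
    ])
    def test_rank_closed_forms(self, itype, rank_fn):
        rng = np.random.default_rng(7)
        for _ in range(5):
            g = random_disconnected_graph(rng, max_components=3)
            T = int(rng.integers(2, 5))
            s = interaction_structure(itype, T, g)
            assert s.rank == rank_fn(T, g.n_areas, g.n_components)

    def test_kronecker_rank_identity(self):
        # rank(IV) = rank(RW1) * rank(ICAR), against numerical rank
        rng = np.random.default_rng(11)
        for _ in range(20):
            g = random_disconnected_graph(rng, max_components=3)
            T = int(rng.integers(2, 5))
            s = interaction_structure("IV", T, g)
            r_t = rw1_structure(T).rank
            r_s = stmrf.icar_structure(g).rank
            assert s.rank == r_t * r_s
            assert np.linalg.matrix_rank(s.matrix, tol=1e-8) == s.rank

    def test_unknown_type(self, default_graph):
        with pytest.raises(ValueError, match="unknown interaction type"):
            interaction_structure("V", 4, default_graph)

    def test_null_basis_annihilated(self, default_graph):
        for itype in ("II", "III", "IV"):
            s = interaction_structure(itype, 3, default_graph)
            np.testing.assert_allclose(s.matrix @ s.null_basis, 0, atol=1e-10)


class TestConstraintSet:
    def test_icar_two_components(self):
        g = stmrf.build_adjacency([("a", "b"), ("c", "d")], list("abcd"))
        cs = constraint_set(stmrf.icar_structure(g))
        assert cs.n_constraints == 2

    def test_rw1_sum_to_zero(self):
        cs = constraint_set(rw1_structure(5))
        assert cs.n_constraints == 1
        np.testing.assert_allclose(cs.matrix[0], cs.matrix[0][0])

    def test_type_IV_connected_S3(self):
        g = stmrf.build_adjacency([("a", "b"), ("b", "c")], ["a", "b", "c"])
        s = interaction_structure("IV", 3, g)
        cs = constraint_set(s)
        assert cs.n_constraints == 5
        # A psi = 0 for any range-space vector
        x = sample_constrained_gmrf(s, 1.0, cs, seed=5)
        assert cs.residual(x) < 1e-8


class TestSampler:
    def test_iid_sample_variance(self):
        s = iid_structure(1000)
        x = sample_constrained_gmrf(s, 1.0, constraint_set(s), seed=1)
        assert 0.9 < x.var() < 1.1

    def test_icar_component_sums_zero(self):
        g = stmrf.build_adjacency([("a", "b"), ("b", "c"), ("d", "e")],
                                  list("abcde"))
        s = stmrf.icar_structure(g)
        x = sample_constrained_gmrf(s, 2.0, constraint_set(s), seed=2)
        labels = g.component_labels
        for c in range(g.n_components):
            assert abs(x[labels == c].sum()) < 1e-10

    def test_rw1_increment_variance(self):
        s = rw1_structure(200)
        x = sample_constrained_gmrf(s, 1.0, constraint_set(s), seed=3)
        incr = np.diff(x)
        assert 0.85 < (incr**2).mean() < 1.15

    def test_invalid_variance(self):
        s = iid_structure(3)
        with pytest.raises(ValueError):
            sample_constrained_gmrf(s, 0.0, None, seed=0)

    def test_deterministic_for_seed(self):
        s = rw1_structure(10)
        a = sample_constrained_gmrf(s, 1.0, constraint_set(s), seed=9)
        b = sample_constrained_gmrf(s, 1.0, constraint_set(s), seed=9)
        np.testing.assert_array_equal(a, b)

    def test_relabel_invariance_moments(self):
        # variance of the constrained field does not depend on area order
        rng = np.random.default_rng(5)
        g = random_disconnected_graph(rng, max_components=2)
        s = stmrf.icar_structure(g)
        draws = np.array([sample_constrained_gmrf(s, 1.0, constraint_set(s), k)
                          for k in range(400)])
        perm = rng.permutation(g.n_areas)
        ids = [g.area_ids[p] for p in perm]
        g2 = stmrf.build_adjacency(
            [(g.area_ids[i], g.area_ids[j]) for i, j in g.edges], ids)
        s2 = stmrf.icar_structure(g2)
        draws2 = np.array([sample_constrained_gmrf(s2, 1.0, constraint_set(s2), k)
                           for k in range(400)])
        inv = np.argsort([ids.index(a) for a in g.area_ids])
        # per-area marginal variances agree after undoing the relabelling
        v1 = draws.var(axis=0)
        v2 = draws2.var(axis=0)[[ids.index(a) for a in g.area_ids]]
        np.testing.assert_allclose(v1, v2, rtol=0.35, atol=0.05)


def test_hyperparams_positive():
    with pytest.raises(ValueError):
        HyperParams(sigma2_u=0.0)
    hp = HyperParams(delta2_v=np.array([0.5, 1.5]))
    assert np.all(np.atleast_1d(hp.delta2_v) > 0)
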