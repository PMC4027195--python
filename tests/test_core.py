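import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promise_mmi.core import (
    ModelConfig,
    expected_reduction,
    fit,
    fuse_with_sequence_score,
    prob_mirna_competition,
    prob_mrna_competition,
    update_total_mrna,
)
from promise_mmi.preprocess import ExpressionPair
from promise_mmi.seedmatch import SeedMatchMatrix

from conftest import random_system


def matrix(counts):
    counts = np.asarray(counts, dtype=np.int64)
    return SeedMatchMatrix([f"g{i}" for i in range(counts.shape[0])],
                           [f"m{k}" for k in range(counts.shape[1])],
                           counts)


def naive_prob_mrna(x, z, counts):
    """Double-loop reference for the mRNA-competition probabilities."""
    N, M = counts.shape
    p = np.zeros((N, M))
    for i in range(N):
        for k in range(M):
            denom = sum(counts[j, k] * x[j] for j in range(N))
            if counts[i, k] == 0 or z[k] == 0 or denom == 0:
                continue
            numer = sum(counts[j, k] * x[j] for j in range(N) if j != i)
            p[i, k] = 1 - (numer / denom) ** z[k]
    return p


def naive_prob_mirna(x, z, counts):
    """Double-loop reference for the miRNA-competition probabilities."""
    N, M = counts.shape
    p = np.zeros((N, M))
    for i in range(N):
        for k in range(M):
            denom = sum(counts[i, l] * z[l] for l in range(M))
            if counts[i, k] == 0 or x[i] == 0 or denom == 0:
                continue
            numer = sum(counts[i, l] * z[l] for l in range(M) if l != k)
            p[i, k] = 1 - (numer / denom) ** x[i]
    return p


class TestProbMrnaCompetition:
    def test_two_equal_genes_share_the_mirna(self):
        # equal site mass: the competing fraction is 1/2, p = 1 - 0.5^z
        C = matrix([[1], [1]])
        p = prob_mrna_competition(np.array([5.0, 5.0]), np.array([1.0]), C)
        np.testing.assert_allclose(p[:, 0], [0.5, 0.5])

    def test_mirna_abundance_amplifies(self):
        C = matrix([[1], [1]])
        p = prob_mrna_competition(np.array([5.0, 5.0]), np.array([2.0]), C)
        np.testing.assert_allclose(p[0, 0], 0.75)

    def test_zero_seed_count_zero_probability(self):
        C = matrix([[0, 1], [1, 1]])
        p = prob_mrna_competition(np.array([1.0, 2.0]), np.array([1.0, 1.0]), C)
        assert p[0, 0] == 0.0

    def test_sole_site_carrier_has_probability_one(self):
        C = matrix([[1], [0]])
        p = prob_mrna_competition(np.array([3.0, 9.0]), np.array([2.0]), C)
        assert p[0, 0] == 1.0

    def test_unexpressed_mirna_gives_zero(self):
        C = matrix([[1], [1]])
        p = prob_mrna_competition(np.array([1.0, 1.0]), np.array([0.0]), C)
        np.testing.assert_array_equal(p, 0.0)

    def test_negative_input_rejected(self):
        C = matrix([[1]])
        with pytest.raises(ValueError):
            prob_mrna_competition(np.array([-1.0]), np.array([1.0]), C)


class TestProbMirnaCompetition:
    def test_single_matching_mirna_has_probability_one(self):
        # no other miRNA recognizes the gene's sites
        C = matrix([[0, 1]])
        p = prob_mirna_competition(np.array([1.0]), np.array([2.0, 3.0]), C)
        assert p[0, 1] == 1.0 and p[0, 0] == 0.0

    def test_two_equal_mirnas_split(self):
        C = matrix([[1, 1]])
        p = prob_mirna_competition(np.array([1.0]), np.array([5.0, 5.0]), C)
        np.testing.assert_allclose(p[0], [0.5, 0.5])

    def test_zero_seed_count_zero_probability(self):
        C = matrix([[0, 1]])
        p = prob_mirna_competition(np.array([1.0]), np.array([1.0, 1.0]), C)
        assert p[0, 0] == 0.0

    def test_unexpressed_gene_gives_zero(self):
        C = matrix([[1, 1]])
        p = prob_mirna_competition(np.array([0.0]), np.array([1.0, 1.0]), C)
        np.testing.assert_array_equal(p, 0.0)


class TestUpdateSteps:
    def test_expected_reduction_formula(self):
        delta = expected_reduction(np.array([[0.5]]), np.array([10.0]), 0.001)
        np.testing.assert_allclose(delta, [[0.005]])

    def test_zero_probability_zero_reduction(self):
        delta = expected_reduction(np.zeros((2, 2)), np.ones(2), 0.001)
        np.testing.assert_array_equal(delta, 0.0)

    def test_nonpositive_eta_rejected(self):
        with pytest.raises(ValueError):
            expected_reduction(np.ones((1, 1)), np.ones(1), 0.0)

    def test_update_adds_rowsums_then_renormalizes(self):
        x = update_total_mrna(np.array([1.0, 1.0]),
                              np.array([[0.25, 0.25], [0.5, 0.0]]), 4.0)
        np.testing.assert_allclose(x, [2.0, 2.0])

    def test_zero_delta_fixed_point(self):
        x0 = np.array([1.0, 3.0])
        x = update_total_mrna(x0, np.zeros((2, 1)), x0.sum())
        np.testing.assert_allclose(x, x0)

    def test_zero_delta_doubled_capacity_doubles(self):
        x0 = np.array([1.0, 3.0])
        x = update_total_mrna(x0, np.zeros((2, 1)), 2 * x0.sum())
        np.testing.assert_allclose(x, 2 * x0)

    def test_degenerate_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            update_total_mrna(np.zeros(2), np.zeros((2, 1)), 1.0)

    def test_capacity_conserved_exactly(self, rng):
        x = rng.lognormal(0, 1, 50)
        delta = rng.random((50, 5)) * 0.01
        T = 1.3 * x.sum()
        out = update_total_mrna(x, delta, T)
        assert abs(out.sum() - T) / T <= 1e-9


class TestFit:
    def test_toy_converges_with_invariants(self, toy):
        sig = fit(toy.pair, toy.C)
        assert sig.converged and sig.n_iter < 200
        for p in (sig.p_mrna, sig.p_mirna, sig.p_joint):
            assert np.all(p >= 0) and np.all(p <= 1)
            assert np.all(p[toy.C.counts == 0] == 0)
        np.testing.assert_array_equal(sig.p_joint, sig.p_mrna * sig.p_mirna)
        T = 1.3 * toy.x_obs.sum()
        assert abs(sig.x_total_final.sum() - T) / T <= 1e-9

    def test_single_gene_single_mirna_all_one(self):
        C = matrix([[1]])
        pair = ExpressionPair(["g0"], ["m0"], np.array([2.0]), np.array([3.0]))
        sig = fit(pair, C)
        assert sig.p_mrna[0, 0] == 1.0
        assert sig.p_mirna[0, 0] == 1.0
        assert sig.p_joint[0, 0] == 1.0

    def test_all_zero_seed_matrix_trivial_convergence(self):
        with pytest.warns(UserWarning, match="all-zero"):
            C = SeedMatchMatrix(["g0", "g1"], ["m0"], np.zeros((2, 1), int))
        pair = ExpressionPair(["g0", "g1"], ["m0"], np.array([1.0, 2.0]),
                              np.array([3.0]))
        sig = fit(pair, C)
        assert sig.converged and sig.n_iter == 1
        np.testing.assert_array_equal(sig.p_joint, 0.0)

    def test_deterministic_bit_identical(self, rng):
        C, x, z = random_system(rng, 20, 5)
        pair = ExpressionPair(list(C.genes), list(C.mirnas), x, z)
        s1, s2 = fit(pair, C), fit(pair, C)
        np.testing.assert_array_equal(s1.p_mrna, s2.p_mrna)
        np.testing.assert_array_equal(s1.p_mirna, s2.p_mirna)
        assert s1.n_iter == s2.n_iter

    def test_mean_one_rescale_desaturates(self, rng):
        C, x, z = random_system(rng, 30, 5, density=0.8)
        pair = ExpressionPair(list(C.genes), list(C.mirnas), 1e4 * x, 1e4 * z)
        raw = fit(pair, C)
        rescaled = fit(pair, C, ModelConfig(expression_rescale="mean_one"))
        nz = C.counts > 0
        assert np.mean(raw.p_mrna[nz] > 1 - 1e-12) > \
            np.mean(rescaled.p_mrna[nz] > 1 - 1e-12)

    def test_empty_mirna_set_rejected(self):
        C = SeedMatchMatrix(["g0"], [], np.zeros((1, 0), int))
        pair = ExpressionPair(["g0"], [], np.array([1.0]), np.zeros(0))
        with pytest.raises(ValueError):
            fit(pair, C)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_vectorized_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(2, 51))
        M = int(rng.integers(1, 11))
        C, x, z = random_system(rng, N, M, density=0.4)
        # include zero expression entries to hit the degenerate conventions
        x[rng.random(N) < 0.1] = 0.0
        z[rng.random(M) < 0.1] = 0.0
        np.testing.assert_allclose(
            prob_mrna_competition(x, z, C), naive_prob_mrna(x, z, C.counts),
            atol=1e-12)
        np.testing.assert_allclose(
            prob_mirna_competition(x, z, C), naive_prob_mirna(x, z, C.counts),
            atol=1e-12)


class TestMonotonicity:
    def test_mrna_probability_increases_with_mirna_abundance(self):
        C = matrix([[1], [1]])
        x = np.array([1.0, 3.0])
        ps = [prob_mrna_competition(x, np.array([zk]), C)[0, 0]
              for zk in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_mrna_probability_increases_with_own_expression(self):
        C = matrix([[1], [1]])
        z = np.array([1.0])
        ps = [prob_mrna_competition(np.array([xi, 3.0]), z, C)[0, 0]
              for xi in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_mirna_probability_increases_with_gene_expression(self):
        C = matrix([[1, 1]])
        z = np.array([2.0, 3.0])
        ps = [prob_mirna_competition(np.array([xi]), z, C)[0, 0]
              for xi in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_mirna_probability_increases_with_own_abundance(self):
        C = matrix([[1, 1]])
        x = np.array([1.0])
        ps = [prob_mirna_competition(x, np.array([zk, 3.0]), C)[0, 0]
              for zk in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(ps, ps[1:]))


@settings(max_examples=40, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_probability_bounds_property(seed):
    """All three matrices stay within [0, 1] and obey the zero-seed and
    joint-product laws on random valid inputs."""
    rng = np.random.default_rng(seed)
    C, x, z = random_system(rng, 12, 4, density=0.5)
    pair = ExpressionPair(list(C.genes), list(C.mirnas), x, z)
    sig = fit(pair, C, ModelConfig(max_iter=50))
    for p in (sig.p_mrna, sig.p_mirna, sig.p_joint):
        assert np.all((p >= 0) & (p <= 1))
        assert np.all(p[C.counts == 0] == 0)
    np.testing.assert_array_equal(sig.p_joint, sig.p_mrna * sig.p_mirna)


class TestSequenceScoreFusion:
    def base_sig(self):
        C = matrix([[1, 1], [1, 1]])
        pair = ExpressionPair(list(C.genes), list(C.mirnas),
                              np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        return fit(pair, C)

    def test_elementwise_product(self):
        sig = self.base_sig()
        pct = np.full((2, 2), 0.5)
        np.testing.assert_allclose(fuse_with_sequence_score(sig, pct),
                                   0.5 * sig.p_mrna)

    def test_unit_scores_identity(self):
        sig = self.base_sig()
        np.testing.assert_array_equal(
            fuse_with_sequence_score(sig, np.ones((2, 2))), sig.p_mrna)

    def test_missing_scores_zero_the_pair(self):
        sig = self.base_sig()
        pct = np.array([[np.nan, 1.0], [1.0, 1.0]])
        fused = fuse_with_sequence_score(sig, pct)
        assert fused[0, 0] == 0.0

    def test_model_selection(self):
        sig = self.base_sig()
        np.testing.assert_array_equal(
            fuse_with_sequence_score(sig, np.ones((2, 2)), model="joint"),
            sig.p_joint)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            fuse_with_sequence_score(self.base_sig(), np.full((2, 2), 1.5))
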