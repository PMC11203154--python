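import math

import numpy as np
import pytest
from scipy.special import logsumexp

from spikelft.action import (
    ActionParameters,
    CausalityError,
    EnumerationCapError,
    action_value,
    derived_currents,
    enumerate_kernels,
    free_action_functional,
    gibbs_average,
    ground_state_search,
    input_partition,
    lagrangian_split,
    partition_function,
    pulse_kernel,
    sample_gibbs,
    to_spin_parameters,
)
from spikelft.kernelspace import BinaryKernel, MagnetizationKernel, to_spin


def random_params(rng, n, t, lam=1.0, representation="spin", with_input=True):
    a = rng.standard_normal((n, n))
    b = np.tril(rng.standard_normal((t, t)), -1)
    i = rng.standard_normal((n, t)) if with_input else np.zeros((n, t))
    return ActionParameters(a, b, i, lam=lam, representation=representation)


class TestActionParameters:
    def test_causality_enforced(self):
        b = np.zeros((3, 3))
        b[0, 2] = 1.0          # couples bin 0 to the *later* bin 2
        with pytest.raises(CausalityError):
            ActionParameters(np.zeros((2, 2)), b, np.zeros((2, 3)))

    def test_diagonal_kinetic_rejected(self):
        b = np.eye(2)
        with pytest.raises(CausalityError):
            ActionParameters(np.zeros((2, 2)), b, np.zeros((2, 2)))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ActionParameters(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)))

    def test_lam_positive(self):
        with pytest.raises(ValueError):
            ActionParameters.zeros(1, 1, lam=-1.0)

    def test_derived_currents_vanish_for_symmetric(self, rng):
        a = rng.standard_normal((3, 3))
        p = ActionParameters(a + a.T, np.zeros((2, 2)), np.zeros((3, 2)))
        row, col = derived_currents(p, offset=0.3)
        np.testing.assert_allclose(row, 0.0, atol=1e-12)
        np.testing.assert_allclose(col, 0.0)


class TestActionValue:
    def test_zero_parameters(self, random_kernel):
        k = random_kernel()
        p = ActionParameters.zeros(k.n_neurons, k.n_bins, representation="binary")
        assert action_value(k, p) == 0.0

    def test_single_cell(self):
        p = ActionParameters([[2.5]], [[0.0]], [[0.0]], representation="binary")
        assert action_value(BinaryKernel(values=[[1]]), p) == 2.5
        assert action_value(BinaryKernel(values=[[0]]), p) == 0.0

    def test_matches_loop_oracle(self, rng):
        n, t = 2, 2
        for _ in range(20):
            a = rng.integers(-3, 4, (n, n)).astype(float)
            b = np.tril(rng.integers(-3, 4, (t, t)).astype(float), -1)
            i = rng.integers(-3, 4, (n, t)).astype(float)
            p = ActionParameters(a, b, i, representation="binary")
            k = BinaryKernel(values=rng.integers(0, 2, (n, t)))
            phi = k.values.astype(float)
            expected = sum(a[x, y] * phi[x, s] * phi[y, s]
                           for x in range(n) for y in range(n) for s in range(t))
            expected += sum(b[s, u] * phi[x, s] * phi[x, u]
                            for s in range(t) for u in range(t) for x in range(n))
            expected -= float((i * phi).sum())
            assert action_value(k, p) == pytest.approx(expected)

    def test_dimension_mismatch(self, random_kernel):
        p = ActionParameters.zeros(3, 3)
        with pytest.raises(ValueError):
            action_value(random_kernel(n=2, t=2), p)

    def test_binary_spin_equivalence(self, rng):
        for _ in range(10):
            p = random_params(rng, 3, 4, representation="binary")
            p_spin, const = to_spin_parameters(p)
            k = BinaryKernel(values=rng.integers(0, 2, (3, 4)))
            assert action_value(k, p) == pytest.approx(
                action_value(to_spin(k), p_spin) + const)

    def test_max_entropy_reduction(self, rng):
        # B = 0, T = 1: spin action reduces to the pairwise Hamiltonian A/4
        a = rng.standard_normal((4, 4))
        p = ActionParameters(a, np.zeros((1, 1)), np.zeros((4, 1)),
                             representation="binary")
        p_spin, _ = to_spin_parameters(p)
        np.testing.assert_allclose(p_spin.potential, a / 4.0)
        sig = rng.integers(0, 2, (4, 1)) * 2 - 1
        k = MagnetizationKernel(values=sig)
        expected = float(sig[:, 0] @ (a / 4.0) @ sig[:, 0]) \
            + float(p_spin.row_current @ sig[:, 0]) \
            + float(p_spin.col_current[0] * sig[:, 0].sum())
        assert action_value(k, p_spin) == pytest.approx(expected)


class TestLagrangian:
    def test_zero_kinetic(self, rng):
        p = random_params(rng, 3, 4, with_input=False)
        sig = rng.integers(0, 2, (3, 4)) * 2 - 1
        k = MagnetizationKernel(values=sig)
        for alpha in range(4):
            _, kin = lagrangian_split(k, ActionParameters(
                p.potential, np.zeros((4, 4)), np.zeros((3, 4))), alpha)
            assert kin == 0.0

    def test_nearest_step_kinetic(self, rng):
        # B_ab = -B0 for b = a-1: K(alpha) = B0 * N * q_{alpha,alpha-1}
        b0 = 1.7
        n, t = 4, 5
        b = np.zeros((t, t))
        for a in range(1, t):
            b[a, a - 1] = -b0
        p = ActionParameters(np.zeros((n, n)), b, np.zeros((n, t)))
        sig = rng.integers(0, 2, (n, t)) * 2 - 1
        k = MagnetizationKernel(values=sig)
        for alpha in range(1, t):
            q = float(sig[:, alpha] @ sig[:, alpha - 1]) / n
            _, kin = lagrangian_split(k, p, alpha)
            assert kin == pytest.approx(b0 * n * q)

    def test_slice_sum_reproduces_action(self, rng):
        for _ in range(50):
            p = random_params(rng, 3, 4, with_input=False)
            sig = rng.integers(0, 2, (3, 4)) * 2 - 1
            k = MagnetizationKernel(values=sig)
            total = sum(h - kin for h, kin in
                        (lagrangian_split(k, p, a) for a in range(4)))
            assert total == pytest.approx(action_value(k, p))

    def test_free_field_kinetic_equivalence(self, rng):
        # nearest-step overlap Lagrangian differs from the pulse form by -B0*N
        b0 = 0.9
        n, t = 3, 6
        sig = rng.integers(0, 2, (n, t)) * 2 - 1
        k = MagnetizationKernel(values=sig)
        b = np.zeros((t, t))
        for a in range(1, t):
            b[a, a - 1] = -b0
        p = ActionParameters(np.zeros((n, n)), b, np.zeros((n, t)))
        d = pulse_kernel(k).values.astype(float)
        for alpha in range(1, t):
            _, kin = lagrangian_split(k, p, alpha)
            overlap_l = -kin                                # -B0*N*q
            pulse_l = 0.5 * b0 * float(d[:, alpha] @ d[:, alpha]) - b0 * n
            assert overlap_l == pytest.approx(pulse_l)


class TestPulseKernel:
    def test_constant_kernel(self):
        k = MagnetizationKernel(values=np.ones((3, 4), dtype=int))
        assert np.abs(pulse_kernel(k).values).max() == 0

    def test_column_flip(self):
        values = np.ones((3, 4), dtype=int)
        values[:, 2:] = -1
        d = pulse_kernel(MagnetizationKernel(values=values)).values
        assert (d[:, 2] == -2).all()
        assert (d[:, [0, 1, 3]] == 0).all()

    def test_requires_two_bins(self):
        with pytest.raises(ValueError):
            pulse_kernel(MagnetizationKernel(values=[[1], [1]]))

    def test_babylonian_identity_hand(self):
        sig = np.array([[1, 1], [-1, 1], [-1, -1]])
        k = MagnetizationKernel(values=sig)
        d = pulse_kernel(k).values.astype(float)
        norm_sq = float(d[:, 1] @ d[:, 1])
        q = float(sig[:, 1] @ sig[:, 0]) / 3
        assert norm_sq == pytest.approx(4.0)
        assert 2 * 3 * (1 - q) == pytest.approx(4.0)

    def test_babylonian_identity_random(self, rng):
        for _ in range(50):
            n, t = 5, 7
            sig = rng.integers(0, 2, (n, t)) * 2 - 1
            d = pulse_kernel(MagnetizationKernel(values=sig)).values.astype(float)
            for alpha in range(1, t):
                q = float(sig[:, alpha] @ sig[:, alpha - 1]) / n
                assert float(d[:, alpha] @ d[:, alpha]) == pytest.approx(
                    2 * n * (1 - q))


class TestPartitionFunction:
    def test_zero_action_uniform(self):
        gs = partition_function(ActionParameters.zeros(2, 2))
        assert math.exp(gs.log_partition) == pytest.approx(16.0)

    def test_single_spin_field(self):
        lam, h = 1.3, 0.7
        p = ActionParameters([[0.0]], [[0.0]], [[h]], lam=lam)
        gs = partition_function(p)
        assert math.exp(gs.log_partition) == pytest.approx(2 * math.cosh(lam * h))

    def test_replica_factorization(self, rng):
        a = rng.standard_normal((2, 2))
        p_full = ActionParameters(a, np.zeros((3, 3)), np.zeros((2, 3)), lam=0.8)
        p_one = ActionParameters(a, np.zeros((1, 1)), np.zeros((2, 1)), lam=0.8)
        assert partition_function(p_full).log_partition == pytest.approx(
            3 * partition_function(p_one).log_partition)

    def test_enumeration_cap(self):
        p = ActionParameters.zeros(5, 5)
        with pytest.raises(EnumerationCapError):
            partition_function(p)

    def test_mcmc_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            partition_function(ActionParameters.zeros(2, 2), mode="mcmc")

    def test_mcmc_matches_enumeration(self, rng):
        p = random_params(rng, 2, 2, lam=0.5)
        exact = partition_function(p).log_partition
        est = partition_function(p, mode="mcmc", seed=7, n_sweeps=300)
        assert abs(est.log_partition - exact) < max(3 * est.mc_error, 0.1)


class TestGibbsAverage:
    def test_uniform_measure_zero_mean(self, rng):
        p = random_params(rng, 2, 2, lam=1e-12)
        mean, _ = gibbs_average(lambda m: m[0, 0], p)
        assert abs(mean) < 1e-9

    def test_single_spin_tanh(self):
        lam, h = 1.1, 0.4
        p = ActionParameters([[0.0]], [[0.0]], [[h]], lam=lam)
        mean, _ = gibbs_average(lambda m: m[0, 0], p)
        assert mean == pytest.approx(math.tanh(lam * h))

    def test_mcmc_agrees_with_enumeration(self, rng):
        for trial in range(3):
            p = random_params(rng, 2, 3, lam=0.4)
            exact, _ = gibbs_average(lambda m: m[0, 0], p)
            est, se = gibbs_average(lambda m: m[0, 0], p, mode="mcmc",
                                    seed=100 + trial, n_sweeps=3000)
            assert abs(est - exact) < max(3 * se, 0.05)


class TestInputPartition:
    def test_zero_input(self):
        assert math.exp(input_partition(np.zeros((2, 3)), lam=1.0)) == \
            pytest.approx(64.0)

    def test_single_cell(self):
        assert input_partition([[1.0]], lam=1.0) == pytest.approx(
            math.log(2 * math.cosh(1.0)))

    def test_consistency_with_full_partition(self, rng):
        # G(A,B,I) = R(I) * <exp(-lam * A(M|A,B))>_rho by enumeration
        lam = 0.9
        a = rng.standard_normal((2, 2))
        i = rng.standard_normal((2, 2))
        p_full = ActionParameters(a, np.zeros((2, 2)), i, lam=lam)
        p_input_only = ActionParameters(np.zeros((2, 2)), np.zeros((2, 2)), i,
                                        lam=lam)
        log_r = input_partition(i, lam)
        mean, _ = gibbs_average(
            lambda m: math.exp(-lam * float(np.sum(a * (m @ m.T)))),
            p_input_only)
        assert partition_function(p_full).log_partition == pytest.approx(
            log_r + math.log(mean))

    def test_overflow_safe(self):
        val = input_partition([[500.0]], lam=2.0)
        assert val == pytest.approx(1000.0, rel=1e-12)


class TestGibbsBound:
    def test_bound_over_random_test_measures(self, rng):
        p = random_params(rng, 2, 3, lam=0.7)
        psi = partition_function(p).free_action
        for _ in range(100):
            zeta = rng.random((2, 3))
            assert free_action_functional(zeta, p) >= psi - 1e-10

    def test_equality_for_free_field(self):
        # for a pure input action the Gibbs measure is a product measure
        lam, h = 0.8, 0.6
        p = ActionParameters([[0.0]], [[0.0]], [[h]], lam=lam)
        psi = partition_function(p).free_action
        plus = math.exp(lam * h) / (2 * math.cosh(lam * h))
        assert free_action_functional(np.array([[plus]]), p) == pytest.approx(psi)


class TestGroundState:
    def test_exhaustive_minimum(self, rng):
        p = random_params(rng, 2, 3, lam=1.0)
        state, val = ground_state_search(p)
        vals = np.concatenate([
            [action_value(MagnetizationKernel(values=s.astype(int)), p)
             for s in chunk]
            for chunk in enumerate_kernels(2, 3, spin=True)
        ])
        assert val == pytest.approx(vals.min())

    def test_ferromagnetic_ground_state(self):
        a = -np.ones((3, 3))
        p = ActionParameters(a, np.zeros((2, 2)), np.zeros((3, 2)), lam=1.0)
        state, val = ground_state_search(p)
        assert val == pytest.approx(-9.0 * 2)


class TestSampling:
    def test_exact_sampler_reproducible(self, rng):
        p = random_params(rng, 2, 2, lam=0.5)
        s1 = sample_gibbs(p, 5, seed=42)
        s2 = sample_gibbs(p, 5, seed=42)
        assert all((a == b).all() for a, b in zip(s1, s2))

    def test_exact_sampler_single_spin(self):
        lam, h = 1.0, 1.2
        p = ActionParameters([[0.0]], [[0.0]], [[h]], lam=lam)
        samples = sample_gibbs(p, 20000, seed=3)
        m = np.mean([s[0, 0] for s in samples])
        assert m == pytest.approx(math.tanh(lam * h), abs=0.02)
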