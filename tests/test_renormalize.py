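import numpy as np
import pytest
from scipy.special import logsumexp

from spikelft.action import ActionParameters, enumerate_kernels, partition_function
from spikelft.kernelspace import BinaryKernel
from spikelft.renormalize import (
    BlockPartition,
    ElectrodeLattice,
    bin_renormalize,
    coarse_action_value,
    decimate,
    effective_couplings,
    electrode_kernel,
    fine_preimages,
    perturbation_by_enumeration,
    utah96_lattice,
)


class TestBlockPartition:
    def test_shapes(self):
        bp = BlockPartition(3, 2, 4, 5)
        assert bp.fine_shape == (6, 20)
        assert bp.coarse_shape == (3, 4)

    def test_from_block_sizes_exact(self):
        bp = BlockPartition.from_block_sizes(6, 20, space=2, time=5)
        assert (bp.n_blocks_space, bp.n_blocks_time) == (3, 4)

    def test_truncation_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="spikelft.renormalize"):
            bp = BlockPartition.from_block_sizes(7, 21, space=2, time=5)
        assert bp.fine_shape == (6, 20)
        assert "truncating" in caplog.text

    def test_no_truncate_raises(self):
        with pytest.raises(ValueError):
            BlockPartition.from_block_sizes(7, 20, space=2, time=5,
                                            truncate=False)


class TestBinRenormalize:
    def test_single_spike_block(self):
        values = np.zeros((2, 4), dtype=int)
        values[0, 1] = 1
        k = BinaryKernel(values=values)
        coarse = bin_renormalize(k, BlockPartition(1, 2, 2, 2))
        np.testing.assert_array_equal(coarse.values, [[1, 0]])

    def test_zero_block(self):
        k = BinaryKernel(values=np.zeros((2, 2), dtype=int))
        coarse = bin_renormalize(k, BlockPartition(1, 2, 1, 2))
        assert coarse.values[0, 0] == 0

    def test_identity_blocks(self, random_kernel):
        k = random_kernel(n=4, t=6)
        coarse = bin_renormalize(k, BlockPartition(4, 1, 6, 1))
        np.testing.assert_array_equal(coarse.values, k.values)
        assert coarse.tau_ms == k.tau_ms

    def test_tau_scales(self):
        k = BinaryKernel(values=np.zeros((2, 10), dtype=int), tau_ms=1.0)
        coarse = bin_renormalize(k, BlockPartition(2, 1, 2, 5))
        assert coarse.tau_ms == 5.0

    def test_never_creates_activity(self, random_kernel):
        k = random_kernel(n=6, t=12, p=0.2)
        bp = BlockPartition(3, 2, 4, 3)
        coarse = bin_renormalize(k, bp)
        assert coarse.values.sum() <= k.values.sum()
        # a silent block stays silent
        blocks = k.values.reshape(3, 2, 4, 3).sum(axis=(1, 3))
        np.testing.assert_array_equal(coarse.values, (blocks > 0).astype(int))


class TestDecimate:
    def test_constant_kernel(self):
        k = BinaryKernel(values=np.ones((4, 4), dtype=int))
        coarse = decimate(k, BlockPartition(2, 2, 2, 2))
        assert (coarse.values == 1).all()

    def test_checkerboard_takes_even_sites(self):
        values = np.indices((4, 4)).sum(axis=0) % 2
        k = BinaryKernel(values=values)
        coarse = decimate(k, BlockPartition(2, 2, 2, 2))
        np.testing.assert_array_equal(coarse.values, 0)  # even sites are 0

    def test_composition(self, random_kernel):
        k = random_kernel(n=8, t=8)
        twice = decimate(decimate(k, BlockPartition(4, 2, 4, 2)),
                         BlockPartition(2, 2, 2, 2))
        once = decimate(k, BlockPartition(2, 4, 2, 4))
        np.testing.assert_array_equal(twice.values, once.values)

    def test_offset(self):
        values = np.arange(4).reshape(1, 4) % 2
        k = BinaryKernel(values=values)
        coarse = decimate(k, BlockPartition(1, 1, 2, 2), offset=(0, 1))
        np.testing.assert_array_equal(coarse.values, [[1, 1]])


class TestElectrodeKernel:
    def test_utah96_site_count(self):
        lat = utah96_lattice()
        assert lat.n_sites == 96
        assert lat.grid_shape == (10, 10)
        assert not lat.mask[0, 0] and not lat.mask[9, 9]

    def test_one_neuron_per_site_identity(self):
        lat = ElectrodeLattice(grid_shape=(2, 2), mask=np.ones((2, 2), bool),
                               pitch_um=100.0)
        pos = np.array([[0, 0], [100, 0], [0, 100], [100, 100]], dtype=float)
        values = np.eye(4, dtype=int)
        out = electrode_kernel(pos, BinaryKernel(values=values), lat)
        np.testing.assert_array_equal(out.values, values)

    def test_or_of_two_neurons(self):
        lat = ElectrodeLattice(grid_shape=(1, 1), mask=np.ones((1, 1), bool),
                               pitch_um=100.0)
        values = np.array([[1, 0, 0], [0, 1, 0]])
        out = electrode_kernel(np.zeros((2, 2)), BinaryKernel(values=values), lat)
        np.testing.assert_array_equal(out.values, [[1, 1, 0]])

    def test_unassigned_policies(self):
        lat = ElectrodeLattice(grid_shape=(1, 1), mask=np.ones((1, 1), bool),
                               pitch_um=100.0)
        pos = np.array([[0.0, 0.0], [1000.0, 1000.0]])
        k = BinaryKernel(values=np.ones((2, 3), dtype=int))
        out = electrode_kernel(pos, k, lat, on_unassigned="drop")
        assert out.n_neurons == 1
        with pytest.raises(ValueError, match="outside"):
            electrode_kernel(pos, k, lat, on_unassigned="error")

    def test_utah96_output_rows(self):
        lat = utah96_lattice()
        sites = lat.site_order
        pos = np.stack([sites[:, 1] * lat.pitch_um,
                        sites[:, 0] * lat.pitch_um], axis=1)
        k = BinaryKernel(values=np.ones((96, 5), dtype=int))
        out = electrode_kernel(pos, k, lat)
        assert out.n_neurons == 96

    def test_commutes_with_time_binning(self, rng):
        lat = ElectrodeLattice(grid_shape=(2, 2), mask=np.ones((2, 2), bool),
                               pitch_um=100.0)
        pos = np.array([[0, 0], [0, 0], [100, 0], [0, 100], [100, 100],
                        [100, 100]], dtype=float)
        k = BinaryKernel(values=rng.integers(0, 2, (6, 12)))
        bp_fine = BlockPartition(6, 1, 4, 3)
        bp_coarse = BlockPartition(4, 1, 4, 3)
        a = electrode_kernel(pos, bin_renormalize(k, bp_fine), lat)
        b = bin_renormalize(electrode_kernel(pos, k, lat), bp_coarse)
        np.testing.assert_array_equal(a.values, b.values)


class TestEffectiveCouplings:
    def _params(self, rng, n, t, lam=0.7):
        a = rng.standard_normal((n, n))
        b = np.tril(rng.standard_normal((t, t)), -1)
        return ActionParameters(a, b, np.zeros((n, t)), lam=lam,
                                representation="binary")

    def test_trivial_blocks_recover_parameters(self, rng):
        p = self._params(rng, 2, 2)
        bp = BlockPartition(2, 1, 2, 1)
        samples = [rng.integers(0, 2, (2, 2)) for _ in range(5)]
        ec = effective_couplings(p, bp, samples)
        # with 1x1 blocks the block potential is A_ij * phi_i phi_j; the
        # stationary mean over all-ones samples equals A itself
        ones = [np.ones((2, 2), dtype=int)]
        ec1 = effective_couplings(p, bp, ones)
        np.testing.assert_allclose(ec1.a_hat, p.potential)
        assert all(np.abs(d).max() < 1e-12 for d in ec1.delta_a)

    def test_uniform_coupling_block_sum(self):
        # uniform A over 2x1 spatial blocks with a fully active kernel:
        # block sum = sum of intra-block couplings
        n, t = 4, 1
        a = np.ones((n, n))
        p = ActionParameters(a, np.zeros((t, t)), np.zeros((n, t)),
                             representation="binary")
        bp = BlockPartition(2, 2, 1, 1)
        from spikelft.renormalize import block_potential
        full = np.ones((n, t))
        pot = block_potential(full, a, bp)
        np.testing.assert_allclose(pot[:, :, 0], 4.0)   # 2x2 pairs per block pair

    def test_fine_preimages_count(self):
        bp = BlockPartition(1, 2, 1, 2)
        pre = list(fine_preimages(np.array([[1]]), bp))
        assert len(pre) == 15                     # 2^4 - 1 nonzero blocks
        pre0 = list(fine_preimages(np.array([[0]]), bp))
        assert len(pre0) == 1 and pre0[0].sum() == 0

    def test_partition_identity_by_enumeration(self, rng):
        # G(A,B) equals the coarse sum with exact perturbations (bin map)
        p = self._params(rng, 2, 2)
        bp = BlockPartition(1, 2, 1, 2)
        samples = [s.astype(int) for chunk in enumerate_kernels(2, 2, spin=False)
                   for s in chunk]
        ec = effective_couplings(p, bp, samples)
        terms = []
        for coarse_val in (0, 1):
            coarse = np.array([[coarse_val]])
            base = coarse_action_value(coarse, ec.a_hat, ec.b_hat)
            pert = perturbation_by_enumeration(coarse, p, bp, ec.a_hat, ec.b_hat)
            terms.append(-p.lam * (base + pert))
        expected = partition_function(p).log_partition
        assert logsumexp(terms) == pytest.approx(expected)

    def test_partition_identity_two_coarse_cells(self, rng):
        import itertools
        p = self._params(rng, 2, 2, lam=0.5)
        bp = BlockPartition(2, 1, 1, 2)           # coarse shape (2, 1)
        samples = [s.astype(int) for chunk in enumerate_kernels(2, 2, spin=False)
                   for s in chunk]
        ec = effective_couplings(p, bp, samples)
        terms = []
        for bits in itertools.product((0, 1), repeat=2):
            coarse = np.array(bits).reshape(2, 1)
            base = coarse_action_value(coarse, ec.a_hat, ec.b_hat)
            pert = perturbation_by_enumeration(coarse, p, bp, ec.a_hat, ec.b_hat)
            terms.append(-p.lam * (base + pert))
        assert logsumexp(terms) == pytest.approx(
            partition_function(p).log_partition)


def test_binned_pi_pattern_beats_iid_control():
    # qualitative: a raster with 10 ms-scale temporal structure keeps its
    # JS-matrix pattern under 10 ms binning better than an i.i.d. raster
    from spikelft.observables import correlation_set
    rng = np.random.default_rng(44)
    n, t = 30, 400
    slow = np.repeat(rng.random((n, t // 10)) < 0.3, 10, axis=1).astype(int)
    iid = (rng.random((n, t)) < 0.3).astype(int)

    def pattern_corr(values):
        k = BinaryKernel(values=values)
        bp = BlockPartition.from_block_sizes(n, t, time=10)
        fine_pi = correlation_set(k).pi
        coarse_pi = correlation_set(bin_renormalize(k, bp)).pi
        up = np.repeat(np.repeat(coarse_pi, 10, axis=0), 10, axis=1)
        mask = ~np.eye(t, dtype=bool)
        return np.corrcoef(fine_pi[mask], up[mask])[0, 1]

    assert pattern_corr(slow) > pattern_corr(iid)
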