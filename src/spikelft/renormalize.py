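"""Kernel coarse-graining: block binning, decimation, electrode kernels and
effective-coupling bookkeeping.

Blocks are contiguous: fine neuron i = i1 * N2 + i2 belongs to space block
i1, fine bin a = a1 * T2 + a2 to time block a1.  The bin map sets the coarse
cell to 1 iff its block contains any spike; decimation keeps one
representative site per block.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .action import ActionParameters, EnumerationCapError
from .kernelspace import BinaryKernel

__all__ = [
    "BlockPartition",
    "ElectrodeLattice",
    "EffectiveCouplings",
    "bin_renormalize",
    "decimate",
    "electrode_kernel",
    "utah96_lattice",
    "effective_couplings",
    "block_potential",
    "block_kinetic",
    "fine_preimages",
    "coarse_action_value",
    "perturbation_by_enumeration",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockPartition:
    """Joint space/time block partition: N = N1*N2, T = T1*T2."""

    n_blocks_space: int
    block_size_space: int
    n_blocks_time: int
    block_size_time: int

    def __post_init__(self):
        for name in ("n_blocks_space", "block_size_space",
                     "n_blocks_time", "block_size_time"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.n_blocks_space * self.block_size_space,
                self.n_blocks_time * self.block_size_time)

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.n_blocks_space, self.n_blocks_time)

    @classmethod
    def from_block_sizes(cls, n: int, t: int, space: int = 1, time: int = 1,
                         truncate: bool = True) -> "BlockPartition":
        """Partition an N x T kernel with the given block sizes; trailing
        rows/bins that do not fill a block are truncated (with a warning)."""
        if n % space or t % time:
            if not truncate:
                raise ValueError(
                    f"block sizes ({space}, {time}) do not divide ({n}, {t})"
                )
            logger.warning(
                "truncating %d trailing rows and %d trailing bins to fit blocks",
                n % space, t % time,
            )
        return cls(n // space, space, t // time, time)


def _blocked(k: BinaryKernel, bp: BlockPartition) -> np.ndarray:
    """View of the (possibly truncated) kernel as (N1, N2, T1, T2)."""
    n, t = bp.fine_shape
    if k.n_neurons < n or k.n_bins < t:
        raise ValueError(
            f"kernel shape {k.shape} smaller than partition fine shape {(n, t)}"
        )
    v = k.values[:n, :t]
    return v.reshape(bp.n_blocks_space, bp.block_size_space,
                     bp.n_blocks_time, bp.block_size_time)


def bin_renormalize(k: BinaryKernel, bp: BlockPartition) -> BinaryKernel:
    """Any-spike (indicator) coarse-graining; tau scales by the time block size."""
    blocks = _blocked(k, bp)
    coarse = (blocks.sum(axis=(1, 3)) > 0).astype(np.uint8)
    return BinaryKernel(
        values=coarse,
        tau_ms=k.tau_ms * bp.block_size_time,
        time_origin=k.time_origin // bp.block_size_time,
    )


def decimate(k: BinaryKernel, bp: BlockPartition,
             offset: tuple[int, int] = (0, 0)) -> BinaryKernel:
    """Kadanoff decimation: keep the block's representative site (default the
    first site of each block; ``offset`` shifts it within the block)."""
    oi, oa = offset
    if not (0 <= oi < bp.block_size_space and 0 <= oa < bp.block_size_time):
        raise ValueError(f"offset {offset} outside block")
    blocks = _blocked(k, bp)
    coarse = blocks[:, oi, :, oa]
    return BinaryKernel(
        values=coarse,
        tau_ms=k.tau_ms * bp.block_size_time,
        time_origin=k.time_origin // bp.block_size_time,
    )


# ---------------------------------------------------------------------------
# electrode lattice


@dataclass(frozen=True)
class ElectrodeLattice:
    """Planar recording lattice: a boolean site mask on a (rows, cols) grid.

    Site centers sit at ``(row * pitch_um, col * pitch_um)``; a neuron is
    assigned to the nearest active site within ``listening_radius_um``
    (default: half the pitch).  Output sites are ordered row-major.
    """

    grid_shape: tuple[int, int]
    mask: np.ndarray
    pitch_um: float = 400.0
    listening_radius_um: Optional[float] = None
    layer: int = 0

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != tuple(self.grid_shape):
            raise ValueError(
                f"mask shape {mask.shape} != grid shape {self.grid_shape}"
            )
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)
        if self.listening_radius_um is None:
            object.__setattr__(self, "listening_radius_um", self.pitch_um / 2.0)

    @property
    def n_sites(self) -> int:
        return int(self.mask.sum())

    @property
    def site_order(self) -> np.ndarray:
        """(n_sites, 2) array of (row, col) indices in row-major order."""
        return np.argwhere(self.mask)

    def assign(self, positions_um: np.ndarray) -> np.ndarray:
        """Map neuron positions (x, y) in um to site indices (-1 = unassigned)."""
        pos = np.asarray(positions_um, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be (n_neurons, 2)")
        sites = self.site_order
        centers = sites * self.pitch_um          # (row, col) -> (y, x) order
        out = np.full(pos.shape[0], -1, dtype=int)
        for j, (x, y) in enumerate(pos):
            d = np.hypot(centers[:, 1] - x, centers[:, 0] - y)
            i = int(np.argmin(d))
            if d[i] <= self.listening_radius_um:
                out[j] = i
        return out


def utah96_lattice(pitch_um: float = 400.0) -> ElectrodeLattice:
    """The standard 10 x 10 planar array with the four corner sites silent
    (96 recording channels)."""
    mask = np.ones((10, 10), dtype=bool)
    for r, c in ((0, 0), (0, 9), (9, 0), (9, 9)):
        mask[r, c] = False
    return ElectrodeLattice(grid_shape=(10, 10), mask=mask, pitch_um=pitch_um)


def electrode_kernel(neuron_positions_um, raster: BinaryKernel,
                     lattice: ElectrodeLattice,
                     on_unassigned: str = "drop") -> BinaryKernel:
    """Per-site on/off kernel: a site is active at a bin iff any neuron
    assigned to its cell fires there.  Rows follow the mask's row-major
    site order.  ``on_unassigned`` is 'drop' or 'error'."""
    assignment = lattice.assign(neuron_positions_um)
    if len(assignment) != raster.n_neurons:
        raise ValueError("one position per raster row is required")
    if (assignment < 0).any():
        if on_unassigned == "error":
            bad = np.flatnonzero(assignment < 0)
            raise ValueError(f"neurons outside every listening volume: {bad.tolist()}")
        if on_unassigned != "drop":
            raise ValueError(f"unknown on_unassigned policy {on_unassigned!r}")
    out = np.zeros((lattice.n_sites, raster.n_bins), dtype=np.uint8)
    for row, site in enumerate(assignment):
        if site >= 0:
            out[site] |= raster.values[row]
    return BinaryKernel(values=out, tau_ms=raster.tau_ms,
                        time_origin=raster.time_origin)


# ---------------------------------------------------------------------------
# effective couplings


def _expand_potential(a: np.ndarray, bp: BlockPartition) -> np.ndarray:
    """A indexed as (i1, i2, j1, j2)."""
    n1, n2 = bp.n_blocks_space, bp.block_size_space
    return a.reshape(n1, n2, n1, n2)


def _expand_kinetic(b: np.ndarray, bp: BlockPartition) -> np.ndarray:
    """B indexed as (a1, a2, b1, b2)."""
    t1, t2 = bp.n_blocks_time, bp.block_size_time
    return b.reshape(t1, t2, t1, t2)


def block_potential(phi: np.ndarray, a: np.ndarray, bp: BlockPartition,
                    mode: str = "bin") -> np.ndarray:
    """Per-configuration effective potential: (N1, N1, T1) array of block sums
    A-weighted over the fine cells of each (space-block, space-block,
    time-block) triple.  Decimation mode excludes the representative site."""
    phi = np.asarray(phi, dtype=float)
    ax = _expand_potential(np.asarray(a, dtype=float), bp)
    pb = phi.reshape(bp.n_blocks_space, bp.block_size_space,
                     bp.n_blocks_time, bp.block_size_time)
    if mode == "decimate":
        # exclude the representative site (index 0) in both space and time
        if bp.block_size_space <= 1 or bp.block_size_time <= 1:
            return np.zeros((bp.n_blocks_space, bp.n_blocks_space,
                             bp.n_blocks_time))
        return np.einsum("iujv,iuaz,jvaz->ija", ax[:, 1:, :, 1:],
                         pb[:, 1:, :, 1:], pb[:, 1:, :, 1:], optimize=True)
    if mode != "bin":
        raise ValueError(f"unknown mode {mode!r}")
    # sum_{i2, j2} A[(i1,i2),(j1,j2)] * sum_{a2} phi[i1,i2,a1,a2] phi[j1,j2,a1,a2]
    return np.einsum("iujv,iuaz,jvaz->ija", ax, pb, pb, optimize=True)


def block_kinetic(phi: np.ndarray, b: np.ndarray, bp: BlockPartition,
                  mode: str = "bin") -> np.ndarray:
    """Per-configuration effective kinetic term: (N1, T1, T1) array."""
    phi = np.asarray(phi, dtype=float)
    bx = _expand_kinetic(np.asarray(b, dtype=float), bp)
    pb = phi.reshape(bp.n_blocks_space, bp.block_size_space,
                     bp.n_blocks_time, bp.block_size_time)
    if mode == "decimate":
        if bp.block_size_space <= 1 or bp.block_size_time <= 1:
            return np.zeros((bp.n_blocks_space, bp.n_blocks_time,
                             bp.n_blocks_time))
        return np.einsum("azbw,iuaz,iubw->iab", bx[:, 1:, :, 1:],
                         pb[:, 1:, :, 1:], pb[:, 1:, :, 1:], optimize=True)
    if mode != "bin":
        raise ValueError(f"unknown mode {mode!r}")
    # sum_{a2, b2} B[(a1,a2),(b1,b2)] * sum_{i2} phi[i1,i2,a1,a2] phi[i1,i2,b1,b2]
    return np.einsum("azbw,iuaz,iubw->iab", bx, pb, pb, optimize=True)


@dataclass(frozen=True)
class EffectiveCouplings:
    """Stationary renormalized couplings and per-configuration fluctuations.

    ``a_hat`` (N1 x N1) is the stationary mean over samples and time blocks of
    the block potential; ``b_hat`` (T1 x T1) the mean over samples and space
    blocks of the block kinetic term.  ``delta_a`` / ``delta_b`` hold the
    per-sample fluctuation arrays.
    """

    a_hat: np.ndarray
    b_hat: np.ndarray
    delta_a: list
    delta_b: list


def effective_couplings(p: ActionParameters, bp: BlockPartition,
                        samples: Sequence[np.ndarray],
                        mode: str = "bin") -> EffectiveCouplings:
    """Split per-configuration block sums into a stationary renormalized part
    and fluctuations, over the supplied sample kernels (binary matrices)."""
    n, t = bp.fine_shape
    if (p.n_neurons, p.n_bins) != (n, t):
        raise ValueError("parameters and partition disagree on the fine shape")
    pots = [block_potential(s, p.potential, bp, mode=mode) for s in samples]
    kins = [block_kinetic(s, p.kinetic, bp, mode=mode) for s in samples]
    a_hat = np.mean([q.mean(axis=2) for q in pots], axis=0)
    b_hat = np.mean([q.mean(axis=0) for q in kins], axis=0)
    delta_a = [q - a_hat[:, :, None] for q in pots]
    delta_b = [q - b_hat[None, :, :] for q in kins]
    return EffectiveCouplings(a_hat=a_hat, b_hat=b_hat,
                              delta_a=delta_a, delta_b=delta_b)


def coarse_action_value(coarse: np.ndarray, a_hat: np.ndarray,
                        b_hat: np.ndarray) -> float:
    """Action of a coarse binary kernel under the renormalized couplings."""
    x = np.asarray(coarse, dtype=float)
    return float(np.sum(a_hat * (x @ x.T)) + np.sum(b_hat * (x.T @ x)))


def fine_preimages(coarse: np.ndarray, bp: BlockPartition,
                   cap: int = 1 << 20) -> Iterator[np.ndarray]:
    """All fine binary kernels whose bin renormalization equals ``coarse``.

    Active coarse cells range over every nonzero block configuration;
    silent cells force an all-zero block.
    """
    coarse = np.asarray(coarse)
    n1, t1 = bp.coarse_shape
    cell = bp.block_size_space * bp.block_size_time
    active = np.argwhere(coarse != 0)
    n_states = (2 ** cell - 1) ** len(active)
    if n_states > cap:
        raise EnumerationCapError(
            f"{n_states} fine preimages exceed the cap {cap}"
        )
    nonzero_blocks = [
        np.array(bits, dtype=np.uint8).reshape(bp.block_size_space,
                                               bp.block_size_time)
        for bits in itertools.product((0, 1), repeat=cell)
        if any(bits)
    ]
    n, t = bp.fine_shape
    for combo in itertools.product(nonzero_blocks, repeat=len(active)):
        fine = np.zeros((n, t), dtype=np.uint8)
        for (i1, a1), block in zip(active, combo):
            fine[i1 * bp.block_size_space:(i1 + 1) * bp.block_size_space,
                 a1 * bp.block_size_time:(a1 + 1) * bp.block_size_time] = block
        yield fine


def perturbation_by_enumeration(coarse: np.ndarray, p: ActionParameters,
                                bp: BlockPartition, a_hat: np.ndarray,
                                b_hat: np.ndarray) -> float:
    """Exact action perturbation of a coarse configuration:
    -(1/lam) log sum over fine preimages of exp(-lam * Gamma), where Gamma is
    the fluctuation part of the block sums contracted with the coarse kernel."""
    coarse_f = np.asarray(coarse, dtype=float)
    phihat_ij = coarse_f[:, None, :] * coarse_f[None, :, :]       # (N1, N1, T1)
    phihat_ab = coarse_f[:, :, None] * coarse_f[:, None, :]       # (N1, T1, T1)
    log_terms = []
    for fine in fine_preimages(coarse, bp):
        da = block_potential(fine, p.potential, bp) - a_hat[:, :, None]
        db = block_kinetic(fine, p.kinetic, bp) - b_hat[None, :, :]
        gamma = float(np.sum(da * phihat_ij) + np.sum(db * phihat_ab))
        log_terms.append(-p.lam * gamma)
    if not log_terms:
        return 0.0
    from scipy.special import logsumexp
    return float(-logsumexp(log_terms) / p.lam)
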