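"""Generators for every input the toolkit consumes.

All generators take a mandatory seed and are bit-reproducible: identical
arguments and seed give identical rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .action import (
    ActionParameters,
    sample_gibbs,
)
from .ensembles import TrialEnsemble
from .kernelspace import BinaryKernel, MagnetizationKernel
from .renormalize import ElectrodeLattice

__all__ = [
    "GeneratorConfig",
    "generate_refractory_raster",
    "generate_gibbs_raster",
    "generate_columnar_kernel",
    "generate_trial_ensemble",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator settings.

    ``rate_per_bin`` is the per-bin Bernoulli firing probability,
    ``refractory_bins`` the number of silent bins enforced after each spike.
    """

    n_neurons: int = 10
    n_bins: int = 100
    rate_per_bin: float = 0.05
    refractory_bins: int = 0
    tau_ms: float = 1.0

    def __post_init__(self):
        if not 0 < self.rate_per_bin < 1:
            raise ValueError("rate_per_bin must be in (0, 1)")
        if self.refractory_bins < 0 or self.refractory_bins >= self.n_bins:
            raise ValueError("refractory_bins must satisfy 0 <= r < n_bins")
        if self.n_neurons < 1 or self.n_bins < 1:
            raise ValueError("n_neurons and n_bins must be >= 1")


def generate_refractory_raster(cfg: GeneratorConfig, seed: int) -> BinaryKernel:
    """Per-neuron Bernoulli firing with a hard refractory period.

    After each spike the neuron is forced silent for ``refractory_bins``
    bins, so every inter-spike interval exceeds the refractory period.  The
    empirical rate is biased to ~ rate / (1 + rate * r) (renewal process).
    """
    rng = np.random.default_rng(seed)
    n, t, r = cfg.n_neurons, cfg.n_bins, cfg.refractory_bins
    draws = rng.random((n, t)) < cfg.rate_per_bin
    if r == 0:
        values = draws.astype(np.uint8)
    else:
        values = np.zeros((n, t), dtype=np.uint8)
        for i in range(n):
            dead_until = 0
            row = draws[i]
            for a in range(t):
                if a >= dead_until and row[a]:
                    values[i, a] = 1
                    dead_until = a + r + 1
    return BinaryKernel(values=values, tau_ms=cfg.tau_ms)


def generate_gibbs_raster(p: ActionParameters, n_trials: int, seed: int,
                          mode: str = "enumeration", causal: bool = False,
                          burn_in: int = 1000, thin: int = 1,
                          causal_cap: int = 16) -> TrialEnsemble:
    """Draw ``n_trials`` kernels from the Gibbs measure of the action.

    ``causal=True`` samples each time slice sequentially from the
    conditional Gibbs step given the past (the Lagrangian chain); this
    coincides with the global Gibbs measure only for nearest-step kinetic
    couplings with constant normalization.  Requires N <= ``causal_cap``
    for the exact per-slice enumeration.
    """
    if causal:
        mats = _causal_chain_samples(p, n_trials, seed, causal_cap)
    else:
        mats = sample_gibbs(p, n_samples=n_trials, seed=seed, mode=mode,
                            burn_in=burn_in, thin=thin)
    trials = []
    for m in mats:
        phi = (m + 1) / 2 if p.representation == "spin" else m
        trials.append(BinaryKernel(values=phi.astype(np.uint8)))
    return TrialEnsemble(trials=tuple(trials))


def _causal_chain_samples(p: ActionParameters, n_trials: int, seed: int,
                          cap: int) -> list[np.ndarray]:
    """Sequential conditional-Gibbs sampling over time slices."""
    n, t = p.n_neurons, p.n_bins
    if n > cap:
        raise ValueError(f"causal sampler enumerates 2^N slice states; N={n} > {cap}")
    spin = p.representation == "spin"
    rng = np.random.default_rng(seed)
    states = np.array(
        [[(j >> b) & 1 for b in range(n)] for j in range(1 << n)], dtype=float)
    if spin:
        states = 2.0 * states - 1.0
    out = []
    for _ in range(n_trials):
        x = np.empty((n, t))
        for a in range(t):
            # slice energy: potential + kinetic coupling to realized past - input
            e = np.einsum("si,ij,sj->s", states, p.potential, states)
            if a > 0:
                past = x[:, :a] @ p.kinetic[a, :a]   # sum_b B_ab x_ib
                e = e + states @ past
            e = e - states @ p.input_kernel[:, a]
            if p.row_current is not None:
                e = e + states @ p.row_current
            if p.col_current is not None:
                e = e + states.sum(axis=1) * p.col_current[a]
            logw = -p.lam * e
            w = np.exp(logw - logw.max())
            w /= w.sum()
            x[:, a] = states[rng.choice(len(w), p=w)]
        out.append(x)
    return out


def generate_columnar_kernel(lattice: ElectrodeLattice, neurons_per_cell: int,
                             rate_per_bin: float, n_bins: int, seed: int,
                             co_activation: float = 1.0, tau_ms: float = 1.0
                             ) -> tuple[BinaryKernel, np.ndarray]:
    """Multi-neuron-per-cell raster plus neuron positions.

    Each active lattice site hosts ``neurons_per_cell`` neurons at the site
    center.  A cell event occurs per bin with probability ``rate_per_bin``;
    during an event each resident neuron fires with probability
    ``co_activation`` (the first resident always fires, so the site rate
    equals the cell rate).  Ready for :func:`spikelft.renormalize.electrode_kernel`.
    """
    if not 0 < rate_per_bin < 1:
        raise ValueError("rate_per_bin must be in (0, 1)")
    if not 0 <= co_activation <= 1:
        raise ValueError("co_activation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = lattice.site_order
    n = len(sites) * neurons_per_cell
    values = np.zeros((n, n_bins), dtype=np.uint8)
    positions = np.empty((n, 2))
    row = 0
    for (r, c) in sites:
        events = rng.random(n_bins) < rate_per_bin
        for j in range(neurons_per_cell):
            if j == 0:
                fired = events
            else:
                fired = events & (rng.random(n_bins) < co_activation)
            values[row] = fired.astype(np.uint8)
            positions[row] = (c * lattice.pitch_um, r * lattice.pitch_um)
            row += 1
    return BinaryKernel(values=values, tau_ms=tau_ms), positions


def generate_trial_ensemble(base: BinaryKernel, n: int, jitter_range: int,
                            noise_flip_prob: float, seed: int
                            ) -> tuple[TrialEnsemble, np.ndarray]:
    """n jittered noisy copies of a base kernel, with the true jitters returned.

    Each trial embeds the base raster into a recording padded by
    ``jitter_range`` silent bins on both sides, shifted by a uniform random
    integer jitter in [-jitter_range, jitter_range]; cells are then flipped
    independently with ``noise_flip_prob``.  The ensemble window is set so
    that zero shifts recover the unjittered placement.
    """
    if jitter_range < 0:
        raise ValueError("jitter_range must be >= 0")
    if not 0 <= noise_flip_prob < 1:
        raise ValueError("noise_flip_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pad = jitter_range
    t = base.n_bins
    jitters = rng.integers(-jitter_range, jitter_range + 1, size=n)
    trials = []
    for k in range(n):
        rec = np.zeros((base.n_neurons, t + 2 * pad), dtype=np.uint8)
        start = pad + int(jitters[k])
        rec[:, start:start + t] = base.values
        if noise_flip_prob > 0:
            flips = rng.random(rec.shape) < noise_flip_prob
            rec = rec ^ flips.astype(np.uint8)
        trials.append(BinaryKernel(values=rec, tau_ms=base.tau_ms))
    ens = TrialEnsemble(trials=tuple(trials), window_start=pad, window_len=t)
    return ens, jitters
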