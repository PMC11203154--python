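"""Lattice action over kernels, its Lagrangian split, and Gibbs statistics.

The action of a kernel X (binary or spin entries) under parameters
(A, B, I, currents) is::

    A(X) =   sum_ij A_ij sum_a X_ia X_ja        (potential, equal-time)
           + sum_ab B_ab sum_i X_ia X_ib        (kinetic, cross-time, causal)
           - sum_ia I_ia X_ia                   (external input)
           + sum_i c_i sum_a X_ia + sum_a d_a sum_i X_ia   (optional currents)

with the statistical theory defined by the Gibbs weight exp(-lam * A(X)) / G
(the softmax / Gibbs average).  Causality restricts B to couple each time
bin only to strictly earlier bins (B[a, b] nonzero only for b < a).

The binary and spin forms are equivalent: `to_spin_parameters` returns the
transformed parameters (A/4, B/4, adjusted currents) and the additive
constant such that the two evaluations agree exactly.

The per-time-slice split is `lagrangian_split`: potential H(a) and kinetic
K(a) with slice contribution H(a) - K(a) summing to the I=0 action.  (The
canonical Lagrangian is L = -H + K; the sign bookkeeping is chosen so the
slice sum reproduces the action.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import numpy as np
from scipy.special import logsumexp

from .kernelspace import (
    BinaryKernel,
    MagnetizationKernel,
    to_binary,
    to_spin,
)

__all__ = [
    "ActionParameters",
    "PulseKernel",
    "GibbsState",
    "CausalityError",
    "EnumerationCapError",
    "action_value",
    "lagrangian_split",
    "pulse_kernel",
    "partition_function",
    "gibbs_average",
    "input_partition",
    "free_action_functional",
    "to_spin_parameters",
    "derived_currents",
    "sample_gibbs",
    "ground_state_search",
    "enumerate_kernels",
]

ENUMERATION_CAP = 20  # max N*T for exact sums (2^20 ~ 1e6 states)
_CHUNK = 1 << 14


class CausalityError(ValueError):
    """Kinetic matrix couples a time bin to a non-earlier bin."""


class EnumerationCapError(ValueError):
    """Exact enumeration requested beyond the state-count cap."""


@dataclass(frozen=True)
class ActionParameters:
    """Parameters (A, B, I, lam) of the lattice action.

    ``potential`` is N x N, ``kinetic`` is T x T with nonzeros only strictly
    below the diagonal (row index = later bin), ``input_kernel`` is N x T.
    ``lam`` is the inverse Planck constant (plays the role of an inverse
    temperature).  ``representation`` states which kernel type the matrices
    refer to.  Optional ``row_current`` / ``col_current`` are the linear
    offset-induced currents.
    """

    potential: np.ndarray
    kinetic: np.ndarray
    input_kernel: np.ndarray
    lam: float = 1.0
    representation: str = "spin"
    row_current: Optional[np.ndarray] = None
    col_current: Optional[np.ndarray] = None

    def __post_init__(self):
        a = np.asarray(self.potential, dtype=float)
        b = np.asarray(self.kinetic, dtype=float)
        i = np.asarray(self.input_kernel, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"potential must be square, got {a.shape}")
        if b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise ValueError(f"kinetic must be square, got {b.shape}")
        if i.shape != (a.shape[0], b.shape[0]):
            raise ValueError(
                f"input kernel must be N x T = {(a.shape[0], b.shape[0])}, got {i.shape}"
            )
        if np.abs(np.triu(b)).max(initial=0.0) > 0:
            raise CausalityError(
                "kinetic matrix must couple only strictly earlier bins "
                "(nonzeros allowed only for column < row)"
            )
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError(f"lam must be positive and finite, got {self.lam}")
        if self.representation not in ("binary", "spin"):
            raise ValueError(f"unknown representation {self.representation!r}")
        for name, vec, size in (
            ("row_current", self.row_current, a.shape[0]),
            ("col_current", self.col_current, b.shape[0]),
        ):
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if vec.shape != (size,):
                    raise ValueError(f"{name} must have length {size}")
                object.__setattr__(self, name, vec)
        object.__setattr__(self, "potential", a)
        object.__setattr__(self, "kinetic", b)
        object.__setattr__(self, "input_kernel", i)

    @property
    def n_neurons(self) -> int:
        return self.potential.shape[0]

    @property
    def n_bins(self) -> int:
        return self.kinetic.shape[0]

    @classmethod
    def zeros(cls, n: int, t: int, lam: float = 1.0,
              representation: str = "spin") -> "ActionParameters":
        return cls(np.zeros((n, n)), np.zeros((t, t)), np.zeros((n, t)),
                   lam=lam, representation=representation)


def derived_currents(p: ActionParameters, offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Offset-induced currents: antisymmetric parts of A and B scaled by the offset."""
    a, b = p.potential, p.kinetic
    row = offset * (a - a.T).sum(axis=1)
    col = offset * (b - b.T).sum(axis=1)
    return row, col


def _field_matrix(k, representation: str) -> np.ndarray:
    if representation == "binary":
        kb = to_binary(k) if isinstance(k, MagnetizationKernel) else k
        if not isinstance(kb, BinaryKernel):
            raise TypeError(f"expected a kernel, got {type(k).__name__}")
        return kb.values.astype(float)
    ks = to_spin(k) if isinstance(k, BinaryKernel) else k
    if not isinstance(ks, MagnetizationKernel):
        raise TypeError(f"expected a kernel, got {type(k).__name__}")
    return ks.values.astype(float)


def _action_on_matrix(x: np.ndarray, p: ActionParameters) -> float:
    val = float(np.sum(p.potential * (x @ x.T)))
    val += float(np.sum(p.kinetic * (x.T @ x)))
    val -= float(np.sum(p.input_kernel * x))
    if p.row_current is not None:
        val += float(p.row_current @ x.sum(axis=1))
    if p.col_current is not None:
        val += float(p.col_current @ x.sum(axis=0))
    return val


def action_value(k, p: ActionParameters) -> float:
    """Evaluate the action on a kernel (converted to ``p.representation``)."""
    x = _field_matrix(k, p.representation)
    if x.shape != (p.n_neurons, p.n_bins):
        raise ValueError(
            f"kernel shape {x.shape} does not match parameters "
            f"{(p.n_neurons, p.n_bins)}"
        )
    return _action_on_matrix(x, p)


def to_spin_parameters(p: ActionParameters) -> tuple[ActionParameters, float]:
    """Transform binary-representation parameters to the spin form.

    Returns ``(p_spin, constant)`` such that for every binary kernel k,
    ``action_value(k, p) == action_value(to_spin(k), p_spin) + constant``.
    """
    if p.representation != "binary":
        raise ValueError("parameters are already in spin representation")
    a, b, i = p.potential, p.kinetic, p.input_kernel
    n, t = p.n_neurons, p.n_bins
    rc = p.row_current if p.row_current is not None else np.zeros(n)
    cc = p.col_current if p.col_current is not None else np.zeros(t)

    row_spin = 0.5 * rc + 0.25 * (a + a.T).sum(axis=1)
    col_spin = 0.5 * cc + 0.25 * (b + b.T).sum(axis=1)
    const = (0.25 * t * a.sum() + 0.25 * n * b.sum()
             + 0.5 * t * rc.sum() + 0.5 * n * cc.sum() - 0.5 * i.sum())
    p_spin = ActionParameters(
        potential=a / 4.0, kinetic=b / 4.0, input_kernel=i / 2.0,
        lam=p.lam, representation="spin",
        row_current=row_spin, col_current=col_spin,
    )
    return p_spin, const


def lagrangian_split(k: MagnetizationKernel, p: ActionParameters,
                     alpha: int) -> tuple[float, float]:
    """Potential and kinetic parts of the time slice ``alpha``.

    Returns ``(H, K)`` with ``H = sum_ij A_ij s_ia s_ja`` and
    ``K = -N * sum_{b < a} B_ab q_ab``.  The slice contribution to the I=0
    action is ``H - K``; the canonical Lagrangian is ``-H + K``.
    """
    if p.representation != "spin":
        raise ValueError("lagrangian_split requires spin-representation parameters")
    sig = _field_matrix(k, "spin")
    n, t = sig.shape
    if not 0 <= alpha < t:
        raise ValueError(f"alpha out of range [0, {t})")
    s_a = sig[:, alpha]
    h = float(s_a @ p.potential @ s_a)
    if alpha == 0:
        kin = 0.0
    else:
        q_row = (sig[:, :alpha].T @ s_a) / n          # q_{alpha, beta}, beta < alpha
        kin = -n * float(p.kinetic[alpha, :alpha] @ q_row)
    return h, kin


@dataclass(frozen=True)
class PulseKernel:
    """Time-differenced spin kernel; entries in {-2, 0, 2}, first column zero."""

    values: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.values)
        if not np.isin(arr, (-2, 0, 2)).all():
            raise ValueError("pulse kernel entries must be in {-2, 0, 2}")
        arr = arr.astype(np.int8, copy=False)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)


def pulse_kernel(k: MagnetizationKernel) -> PulseKernel:
    """Pulse (momentum) kernel: sigma_ia - sigma_i,a-1 with zero first column."""
    if isinstance(k, BinaryKernel):
        k = to_spin(k)
    if k.n_bins < 2:
        raise ValueError("pulse kernel requires T >= 2")
    sig = k.values.astype(np.int16)
    d = np.zeros_like(sig)
    d[:, 1:] = sig[:, 1:] - sig[:, :-1]
    return PulseKernel(values=d)


# ---------------------------------------------------------------------------
# exact enumeration


def _check_cap(n: int, t: int, cap: int = ENUMERATION_CAP):
    if n * t > cap:
        raise EnumerationCapError(
            f"N*T = {n * t} exceeds the enumeration cap {cap}"
        )


def enumerate_kernels(n: int, t: int, spin: bool = True,
                      cap: int = ENUMERATION_CAP) -> Iterator[np.ndarray]:
    """Yield chunks of all 2^(N*T) kernels as (chunk, N, T) float arrays."""
    _check_cap(n, t, cap)
    l = n * t
    total = 1 << l
    bit = np.arange(l, dtype=np.int64)
    for start in range(0, total, _CHUNK):
        idx = np.arange(start, min(start + _CHUNK, total), dtype=np.int64)
        bits = ((idx[:, None] >> bit[None, :]) & 1).astype(np.float64)
        if spin:
            bits = 2.0 * bits - 1.0
        yield bits.reshape(-1, n, t)


def _batch_action(states: np.ndarray, p: ActionParameters) -> np.ndarray:
    vals = np.einsum("ij,sit,sjt->s", p.potential, states, states,
                     optimize=True)
    vals += np.einsum("ab,sia,sib->s", p.kinetic, states, states,
                      optimize=True)
    vals -= np.einsum("ia,sia->s", p.input_kernel, states, optimize=True)
    if p.row_current is not None:
        vals += states.sum(axis=2) @ p.row_current
    if p.col_current is not None:
        vals += states.sum(axis=1) @ p.col_current
    return vals


@dataclass(frozen=True)
class GibbsState:
    """Result of a partition-function evaluation.

    ``log_partition`` is log G; ``free_action`` is -log G / lam.  In mcmc
    mode ``mc_error`` is the estimated Monte-Carlo standard error on log G.
    """

    log_partition: float
    free_action: float
    mode: str
    mc_error: float = 0.0
    input_log_partition: Optional[float] = None


def partition_function(p: ActionParameters, mode: str = "enumeration",
                       seed: Optional[int] = None,
                       cap: int = ENUMERATION_CAP,
                       n_grid: int = 21, n_sweeps: int = 200,
                       burn_in: int = 1000) -> GibbsState:
    """log G = log sum over kernels of exp(-lam * A).

    ``enumeration`` sums all states exactly (requires N*T <= cap);
    ``mcmc`` uses thermodynamic integration of <A> over a lam grid, with
    Metropolis sampling at each grid point (seed mandatory).
    """
    spin = p.representation == "spin"
    n, t = p.n_neurons, p.n_bins
    if mode == "enumeration":
        parts = [
            logsumexp(-p.lam * _batch_action(chunk, p))
            for chunk in enumerate_kernels(n, t, spin=spin, cap=cap)
        ]
        logg = float(logsumexp(parts))
        return GibbsState(log_partition=logg, free_action=-logg / p.lam,
                          mode="enumeration")
    if mode != "mcmc":
        raise ValueError(f"unknown mode {mode!r}")
    if seed is None:
        raise ValueError("mcmc mode requires a seed")
    rng = np.random.default_rng(seed)
    lams = np.linspace(0.0, p.lam, n_grid)
    means = np.empty(n_grid)
    errs = np.empty(n_grid)
    for j, lam_j in enumerate(lams):
        pj = ActionParameters(p.potential, p.kinetic, p.input_kernel,
                              lam=max(lam_j, 1e-300),
                              representation=p.representation,
                              row_current=p.row_current,
                              col_current=p.col_current)
        vals, _ = _metropolis_series(action_fn=None, p=pj, rng=rng,
                                     n_sweeps=n_sweeps, burn_in=burn_in,
                                     lam=lam_j)
        means[j] = vals.mean()
        errs[j] = vals.std(ddof=1) / math.sqrt(_effective_sample_size(vals))
    integral = float(np.trapezoid(means, lams))
    h = lams[1] - lams[0]
    weights = np.full(n_grid, h)
    weights[0] = weights[-1] = h / 2.0
    err = float(np.sqrt(((weights * errs) ** 2).sum()))
    logg = n * t * math.log(2.0) - integral
    return GibbsState(log_partition=logg, free_action=-logg / p.lam,
                      mode="mcmc", mc_error=err)


def _effective_sample_size(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    n = len(x)
    if n < 4 or x.std() == 0:
        return float(max(n, 1))
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    tau = 1.0
    for k in range(1, min(n // 2, 200)):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return max(n / tau, 1.0)


def _metropolis_series(action_fn, p: ActionParameters, rng, n_sweeps: int,
                       burn_in: int, lam: Optional[float] = None):
    """Run single-cell-flip Metropolis; return per-sweep action values and the
    final state.  ``lam`` overrides p.lam for the acceptance rule (used at
    lam=0 in thermodynamic integration)."""
    n, t = p.n_neurons, p.n_bins
    spin = p.representation == "spin"
    lam_eff = p.lam if lam is None else lam
    x = rng.integers(0, 2, size=(n, t)).astype(float)
    if spin:
        x = 2.0 * x - 1.0
    a_cur = _action_on_matrix(x, p)
    vals = np.empty(n_sweeps)
    cells = n * t
    for sweep in range(burn_in + n_sweeps):
        for _ in range(cells):
            i = rng.integers(n)
            a = rng.integers(t)
            delta = _flip_delta(x, i, a, p, spin)
            if delta <= 0 or rng.random() < math.exp(-lam_eff * delta):
                x[i, a] = -x[i, a] if spin else 1.0 - x[i, a]
                a_cur += delta
        if sweep >= burn_in:
            vals[sweep - burn_in] = a_cur
    return vals, x


def _flip_delta(x: np.ndarray, i: int, a: int, p: ActionParameters,
                spin: bool) -> float:
    """Action change for flipping cell (i, a)."""
    old = x[i, a]
    new = -old if spin else 1.0 - old
    d = new - old
    # potential: sum_j (A_ij + A_ji) x_ja * d, plus diagonal square change
    col = x[:, a]
    lin_a = float((p.potential[i, :] + p.potential[:, i]) @ col) - \
        (p.potential[i, i] + p.potential[i, i]) * old
    quad_a = p.potential[i, i] * (new * new - old * old)
    # kinetic: sum_b (B_ab + B_ba) x_ib * d, plus diagonal square change
    row = x[i, :]
    lin_b = float((p.kinetic[a, :] + p.kinetic[:, a]) @ row) - \
        (p.kinetic[a, a] + p.kinetic[a, a]) * old
    quad_b = p.kinetic[a, a] * (new * new - old * old)
    delta = d * (lin_a + lin_b) + quad_a + quad_b
    delta -= p.input_kernel[i, a] * d
    if p.row_current is not None:
        delta += p.row_current[i] * d
    if p.col_current is not None:
        delta += p.col_current[a] * d
    return delta


def gibbs_average(observable: Callable[[np.ndarray], float],
                  p: ActionParameters, mode: str = "enumeration",
                  seed: Optional[int] = None, cap: int = ENUMERATION_CAP,
                  n_sweeps: int = 2000, burn_in: int = 1000
                  ) -> tuple[float, float]:
    """Gibbs average <O> of ``observable(matrix) -> float`` under exp(-lam A).

    The observable receives the raw field matrix (N x T, in the parameter
    representation).  Returns ``(mean, stderr)``; stderr is 0 in enumeration
    mode and uses the effective sample size in mcmc mode.
    """
    spin = p.representation == "spin"
    n, t = p.n_neurons, p.n_bins
    if mode == "enumeration":
        logw_chunks = []
        obs_chunks = []
        for chunk in enumerate_kernels(n, t, spin=spin, cap=cap):
            logw_chunks.append(-p.lam * _batch_action(chunk, p))
            obs_chunks.append(np.array([observable(s) for s in chunk]))
        logw = np.concatenate(logw_chunks)
        obs = np.concatenate(obs_chunks)
        if not np.isfinite(obs).all():
            raise ValueError("observable returned non-finite values")
        w = np.exp(logw - logsumexp(logw))
        return float(w @ obs), 0.0
    if mode != "mcmc":
        raise ValueError(f"unknown mode {mode!r}")
    if seed is None:
        raise ValueError("mcmc mode requires a seed")
    rng = np.random.default_rng(seed)
    samples = _metropolis_samples(p, rng, n_samples=n_sweeps, burn_in=burn_in)
    vals = np.array([observable(s) for s in samples])
    if not np.isfinite(vals).all():
        raise ValueError("observable returned non-finite values")
    ess = _effective_sample_size(vals)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(ess))


def _metropolis_samples(p: ActionParameters, rng, n_samples: int,
                        burn_in: int, thin: int = 1) -> list[np.ndarray]:
    n, t = p.n_neurons, p.n_bins
    spin = p.representation == "spin"
    x = rng.integers(0, 2, size=(n, t)).astype(float)
    if spin:
        x = 2.0 * x - 1.0
    cells = n * t
    out = []
    for sweep in range(burn_in + n_samples * thin):
        for _ in range(cells):
            i = rng.integers(n)
            a = rng.integers(t)
            delta = _flip_delta(x, i, a, p, spin)
            if delta <= 0 or rng.random() < math.exp(-p.lam * delta):
                x[i, a] = -x[i, a] if spin else 1.0 - x[i, a]
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            out.append(x.copy())
    return out


def sample_gibbs(p: ActionParameters, n_samples: int, seed: int,
                 mode: str = "enumeration", cap: int = ENUMERATION_CAP,
                 burn_in: int = 1000, thin: int = 1) -> list[np.ndarray]:
    """Draw kernels (as field matrices) from the Gibbs measure.

    Enumeration mode samples exactly from the full distribution; mcmc mode
    returns a thinned Metropolis chain.
    """
    rng = np.random.default_rng(seed)
    n, t = p.n_neurons, p.n_bins
    spin = p.representation == "spin"
    if mode == "enumeration":
        logw = np.concatenate([
            -p.lam * _batch_action(chunk, p)
            for chunk in enumerate_kernels(n, t, spin=spin, cap=cap)
        ])
        prob = np.exp(logw - logsumexp(logw))
        idx = rng.choice(len(prob), size=n_samples, p=prob)
        bit = np.arange(n * t, dtype=np.int64)
        bits = ((idx[:, None].astype(np.int64) >> bit[None, :]) & 1).astype(float)
        if spin:
            bits = 2.0 * bits - 1.0
        return [b.reshape(n, t) for b in bits]
    if mode != "mcmc":
        raise ValueError(f"unknown mode {mode!r}")
    return _metropolis_samples(p, rng, n_samples=n_samples,
                               burn_in=burn_in, thin=thin)


def input_partition(input_kernel, lam: float) -> float:
    """log R(I) = sum_ia log(2 cosh(lam * I_ia)) (free spin field in input I)."""
    i = np.asarray(input_kernel, dtype=float)
    if not np.isfinite(i).all():
        raise ValueError("input kernel must be finite")
    # log(2 cosh x) = |x| + log1p(exp(-2|x|)) avoids overflow
    x = np.abs(lam * i)
    return float(np.sum(x + np.log1p(np.exp(-2.0 * x)) ))


def free_action_functional(plus_probs, p: ActionParameters) -> float:
    """Free-action functional F(zeta) = <A>_zeta + (1/lam) <log zeta>_zeta for a
    product test measure on spins; ``plus_probs[i, a]`` = P(sigma_ia = +1).

    The Gibbs bound guarantees F(zeta) >= -log G / lam for every zeta.
    """
    if p.representation != "spin":
        raise ValueError("free_action_functional expects spin parameters")
    q = np.asarray(plus_probs, dtype=float)
    if q.shape != (p.n_neurons, p.n_bins):
        raise ValueError("plus_probs must be N x T")
    if ((q < 0) | (q > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    e = 2.0 * q - 1.0
    # <sum_ij A_ij s_ia s_ja>: independent cells except the i=j diagonal (s^2=1)
    diag_a = np.diag(p.potential)
    diag_b = np.diag(p.kinetic)
    pot = 0.0
    for a in range(p.n_bins):
        ea = e[:, a]
        pot += float(ea @ p.potential @ ea)
        pot += float(diag_a.sum() - (diag_a * ea * ea).sum())
    kin = 0.0
    for i in range(p.n_neurons):
        ei = e[i, :]
        kin += float(ei @ p.kinetic @ ei)
        kin += float(diag_b.sum() - (diag_b * ei * ei).sum())
    mean_a = pot + kin - float(np.sum(p.input_kernel * e))
    if p.row_current is not None:
        mean_a += float(p.row_current @ e.sum(axis=1))
    if p.col_current is not None:
        mean_a += float(p.col_current @ e.sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(q > 0, q * np.log(q), 0.0) + \
            np.where(q < 1, (1 - q) * np.log(1 - q), 0.0)
    return mean_a + float(ent.sum()) / p.lam


def ground_state_search(p: ActionParameters, seed: Optional[int] = None,
                        cap: int = ENUMERATION_CAP,
                        n_anneal_sweeps: int = 2000) -> tuple[np.ndarray, float]:
    """Minimum-action kernel (classical lam -> infinity limit).

    Exhaustive under the enumeration cap, otherwise simulated annealing with
    a geometric temperature ramp (seed required).
    """
    n, t = p.n_neurons, p.n_bins
    spin = p.representation == "spin"
    if n * t <= cap:
        best_val = math.inf
        best = None
        for chunk in enumerate_kernels(n, t, spin=spin, cap=cap):
            vals = _batch_action(chunk, p)
            j = int(np.argmin(vals))
            if vals[j] < best_val:
                best_val = float(vals[j])
                best = chunk[j].copy()
        return best, best_val
    if seed is None:
        raise ValueError("annealing search requires a seed")
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n, t)).astype(float)
    if spin:
        x = 2.0 * x - 1.0
    lam_ramp = np.geomspace(0.1, 50.0, n_anneal_sweeps)
    for lam in lam_ramp:
        for _ in range(n * t):
            i = rng.integers(n)
            a = rng.integers(t)
            delta = _flip_delta(x, i, a, p, spin)
            if delta <= 0 or rng.random() < math.exp(-lam * delta):
                x[i, a] = -x[i, a] if spin else 1.0 - x[i, a]
    return x, _action_on_matrix(x, p)
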