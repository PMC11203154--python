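"""Second-order observables, ergodicity estimators and Wasserstein distances.

Naming convention (docstring note): Phi (N x N) is the space / neuron-pair
correlation matrix and Pi (T x T) the time correlation (joint-spike, JS)
matrix; C and Q are their spin counterparts (Q is the replica-overlap
matrix).  The connected matrices subtract the outer product of the means
(free-field part), and the spin-connected matrices equal 4x the
binary-connected ones entrywise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .kernelspace import (
    BinaryKernel,
    MagnetizationKernel,
    first_order,
    to_binary,
    to_spin,
)

__all__ = [
    "CorrelationSet",
    "AutocorrelationProfile",
    "ErgodicityReport",
    "correlation_set",
    "connected_scaling_check",
    "autocorrelation_profile",
    "ergodicity_report",
    "wasserstein",
    "value_histogram",
]


@dataclass(frozen=True)
class CorrelationSet:
    """Bundle of second-order matrices for one kernel.

    Attributes
    ----------
    phi, pi
        Binary space (N x N) and time (T x T) correlation matrices,
        ``phi = Omega Omega^T / T``, ``pi = Omega^T Omega / N``.
    spin_c, spin_q
        Spin counterparts ``C = M M^T / T``, ``Q = M^T M / N``.
    phi0, pi0, c0, q0
        Free-field (outer-product-of-means) matrices.
    c_star_binary, q_star_binary, c_star_spin, q_star_spin
        Connected matrices (correlation minus free-field part).
    """

    phi: np.ndarray
    pi: np.ndarray
    spin_c: np.ndarray
    spin_q: np.ndarray
    phi0: np.ndarray
    pi0: np.ndarray
    c0: np.ndarray
    q0: np.ndarray
    c_star_binary: np.ndarray
    q_star_binary: np.ndarray
    c_star_spin: np.ndarray
    q_star_spin: np.ndarray


def correlation_set(k: BinaryKernel | MagnetizationKernel) -> CorrelationSet:
    """Compute all second-order matrices (binary and spin, plain and connected)."""
    if isinstance(k, MagnetizationKernel):
        kb = to_binary(k)
    else:
        kb = k
    phi_mat = kb.values.astype(float)
    sig = 2.0 * phi_mat - 1.0
    n, t = phi_mat.shape

    phi = phi_mat @ phi_mat.T / t
    pi = phi_mat.T @ phi_mat / n
    c = sig @ sig.T / t
    q = sig.T @ sig / n

    fo = first_order(kb)
    phi0 = np.outer(fo.row_rates, fo.row_rates)
    pi0 = np.outer(fo.col_activity, fo.col_activity)
    c0 = np.outer(fo.row_means_spin, fo.row_means_spin)
    q0 = np.outer(fo.col_means_spin, fo.col_means_spin)

    return CorrelationSet(
        phi=phi, pi=pi, spin_c=c, spin_q=q,
        phi0=phi0, pi0=pi0, c0=c0, q0=q0,
        c_star_binary=phi - phi0, q_star_binary=pi - pi0,
        c_star_spin=c - c0, q_star_spin=q - q0,
    )


def connected_scaling_check(k: BinaryKernel) -> dict:
    """Verify spin-connected = 4 x binary-connected entrywise.

    Returns a report dict with the max absolute deviation for the C and Q
    families and a boolean ``ok`` at 1e-10 tolerance.
    """
    cs = correlation_set(k)
    dev_c = float(np.abs(cs.c_star_spin - 4.0 * cs.c_star_binary).max())
    dev_q = float(np.abs(cs.q_star_spin - 4.0 * cs.q_star_binary).max())
    dev = max(dev_c, dev_q)
    return {"max_abs_deviation": dev, "dev_c": dev_c, "dev_q": dev_q,
            "ok": dev < 1e-10}


@dataclass(frozen=True)
class AutocorrelationProfile:
    """Lagged autocorrelation/overlap profile of a spin kernel.

    All sums over the time index are truncated to valid pairs
    (alpha >= lag) and normalized by the per-lag pair count T - lag, so the
    identity mean_i chi[i, lag] == mean_alpha q[alpha, alpha-lag] holds
    exactly on the shared index set.
    """

    lags: np.ndarray               # 0..max_lag
    per_neuron: np.ndarray         # chi, shape (N, max_lag+1)
    per_time_overlap: list         # q_{alpha, alpha-k} arrays, one per lag
    delta: np.ndarray              # period-averaged autocorrelation per lag
    delta0: np.ndarray             # free-field part (mu products)
    delta_star: np.ndarray         # connected part (delta - delta0)
    counts: np.ndarray             # valid (alpha, alpha-k) pairs per lag
    stderr: np.ndarray             # per-lag standard error of the overlap mean


def autocorrelation_profile(
    k: MagnetizationKernel | BinaryKernel, max_lag: int
) -> AutocorrelationProfile:
    """Per-lag overlaps q_{alpha,alpha-k}, their averages and connected parts."""
    if isinstance(k, BinaryKernel):
        k = to_spin(k)
    sig = k.values.astype(float)
    n, t = sig.shape
    if not 0 <= max_lag < t:
        raise ValueError(f"max_lag must satisfy 0 <= max_lag < T={t}, got {max_lag}")

    mu = sig.mean(axis=0)
    lags = np.arange(max_lag + 1)
    chi = np.empty((n, max_lag + 1))
    q_by_lag: list[np.ndarray] = []
    delta = np.empty(max_lag + 1)
    delta0 = np.empty(max_lag + 1)
    counts = np.empty(max_lag + 1, dtype=int)
    stderr = np.empty(max_lag + 1)
    for kk in lags:
        a = sig[:, kk:]
        b = sig[:, : t - kk] if kk else sig
        prod = a * b                       # (N, T-k)
        chi[:, kk] = prod.mean(axis=1)
        q = prod.mean(axis=0)              # overlap per valid alpha
        q_by_lag.append(q)
        counts[kk] = t - kk
        delta[kk] = q.mean()
        delta0[kk] = (mu[kk:] * mu[: t - kk]).mean() if kk else (mu * mu).mean()
        stderr[kk] = q.std(ddof=1) / np.sqrt(t - kk) if t - kk > 1 else np.nan
    return AutocorrelationProfile(
        lags=lags, per_neuron=chi, per_time_overlap=q_by_lag,
        delta=delta, delta0=delta0, delta_star=delta - delta0,
        counts=counts, stderr=stderr,
    )


@dataclass(frozen=True)
class ErgodicityReport:
    """Diagnostics for ergodicity in mean / correlation and weak stationarity.

    Ergodicity on average requires every row mean and every column mean to
    coincide, so ``mean_discrepancy`` is the spread (max - min) of the
    combined set of row and column means; it is zero iff the condition
    holds.  ``row_mean_spread`` isolates the part that shrinks as O(1/sqrt(T))
    for i.i.d. activity (the column-mean spread is limited by N, not T).
    """

    mean_discrepancy: float        # spread of {m_i} union {mu_alpha}
    row_mean_spread: float         # max |m_i - offset|
    correlation_discrepancy: float  # max over lags of spread of {chi_ik} u {q}
    col_mean_variance: float       # variance of mu_alpha (stationarity of the mean)
    overlap_alpha_dependence: np.ndarray  # per-lag std of q over alpha


def ergodicity_report(
    k: BinaryKernel | MagnetizationKernel, max_lag: Optional[int] = None
) -> ErgodicityReport:
    """Discrepancy diagnostics: a process is ergodic on average when the row
    and column means coincide, and ergodic in correlation when per-neuron
    autocorrelations match time overlaps at every lag."""
    if isinstance(k, BinaryKernel):
        k = to_spin(k)
    fo = first_order(k)
    m = fo.row_means_spin
    mu = fo.col_means_spin
    combined = np.concatenate([m, mu])
    mean_disc = float(combined.max() - combined.min())

    if max_lag is None:
        max_lag = min(10, k.n_bins - 1)
    prof = autocorrelation_profile(k, max_lag)
    corr_disc = 0.0
    alpha_dep = np.empty(max_lag + 1)
    for kk in prof.lags:
        both = np.concatenate([prof.per_neuron[:, kk],
                               prof.per_time_overlap[kk]])
        corr_disc = max(corr_disc, float(both.max() - both.min()))
        alpha_dep[kk] = prof.per_time_overlap[kk].std()
    return ErgodicityReport(
        mean_discrepancy=mean_disc,
        row_mean_spread=float(np.abs(m - fo.offset_spin).max()),
        correlation_discrepancy=corr_disc,
        col_mean_variance=float(mu.var()),
        overlap_alpha_dependence=alpha_dep,
    )


def wasserstein(a, b, order: int = 1) -> float:
    """Wasserstein distance of the given order between two empirical samples.

    Both samples are represented by their quantile (order-statistics) step
    functions; with equal lengths this pairs sorted values directly, with
    unequal lengths both quantile functions are evaluated on a common grid of
    ``max(len(a), len(b))`` right-continuous steps.  Returns
    ``(mean |a_(i) - b_(i)|^order)^(1/order)``.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("wasserstein requires non-empty samples")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    a = np.sort(a)
    b = np.sort(b)
    if a.size != b.size:
        m = max(a.size, b.size)
        grid = (np.arange(m) + 0.5) / m
        a = a[np.minimum((grid * a.size).astype(int), a.size - 1)]
        b = b[np.minimum((grid * b.size).astype(int), b.size - 1)]
    return float(np.mean(np.abs(a - b) ** order) ** (1.0 / order))


def value_histogram(matrix, bin_width: Optional[float] = None):
    """Histogram of matrix entries (fluctuation distribution).

    Uses the Freedman-Diaconis rule unless ``bin_width`` is given.  Returns
    ``(counts, bin_edges)`` as from :func:`numpy.histogram` with density
    normalization.
    """
    v = np.asarray(matrix, dtype=float).ravel()
    if bin_width is None:
        q75, q25 = np.percentile(v, [75, 25])
        iqr = q75 - q25
        bin_width = 2.0 * iqr / v.size ** (1.0 / 3.0) if iqr > 0 else 0.0
    if bin_width > 0:
        nbins = max(1, int(np.ceil((v.max() - v.min()) / bin_width)))
    else:
        nbins = 10
    return np.histogram(v, bins=nbins, density=True)
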