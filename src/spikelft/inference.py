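"""Closed-form inverse-Ising reconstruction of fields and couplings.

All inverters operate on the *grand covariance*: the L x L covariance of the
spin field over the mixed space-time index l = (i, alpha), L = N*T, together
with the length-L mean vector.  They return the symmetric interaction
matrix J of the exponential family

    P(sigma) propto exp( sum_{l<l'} J_ll' sigma_l sigma_l' + sum_l lam*h_l sigma_l )

(zero diagonal; self-interaction is absorbed into the fields).  The relation
to action parameters F is J = -lam * (F + F^T).

Sign convention: the couplings satisfy J -> -C^{-1} (naive mean field) as the
magnetizations vanish, and the TAP formula reduces to naive MF at m = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kernelspace import BinaryKernel, MagnetizationKernel, to_spin

__all__ = [
    "GrandCovariance",
    "InverseSolution",
    "ReducedCovariances",
    "grand_covariance",
    "callen_invert",
    "invert_naive_mf",
    "invert_tap",
    "invert_independent_pair",
    "invert_sessak_monasson",
    "reduce_nonrelativistic",
    "SingularCovarianceError",
]


class SingularCovarianceError(np.linalg.LinAlgError):
    """Covariance matrix is numerically singular; carries the condition number."""


@dataclass(frozen=True)
class GrandCovariance:
    """Mixed-space covariance C_ll' = <s_l s_l'> - <s_l><s_l'> with means m_l.

    ``shape`` is (N, T); the grand index is row-major, l = i*T + alpha.
    For spin variables the diagonal is 1 - m_l^2.
    """

    values: np.ndarray
    means: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self):
        c = np.asarray(self.values, dtype=float)
        m = np.asarray(self.means, dtype=float)
        n, t = self.shape
        if c.shape != (n * t, n * t):
            raise ValueError(f"covariance must be {(n * t, n * t)}, got {c.shape}")
        if m.shape != (n * t,):
            raise ValueError(f"means must have length {n * t}")
        object.__setattr__(self, "values", (c + c.T) / 2.0)
        object.__setattr__(self, "means", m)

    @property
    def size(self) -> int:
        return self.values.shape[0]


def grand_covariance(samples: Sequence, shape: Optional[tuple[int, int]] = None
                     ) -> GrandCovariance:
    """Estimate the grand covariance across repeated kernels (trials).

    ``samples`` is a sequence of spin kernels, binary kernels or raw N x T
    matrices, all with the same shape; entries are converted to spins.
    The empirical covariance is symmetrized by construction.
    """
    mats = []
    for s in samples:
        if isinstance(s, BinaryKernel):
            s = to_spin(s)
        if isinstance(s, MagnetizationKernel):
            s = s.values
        arr = np.asarray(s, dtype=float)
        if set(np.unique(arr)) <= {0.0, 1.0}:
            arr = 2.0 * arr - 1.0
        mats.append(arr.reshape(-1))
    x = np.stack(mats)                     # (n_trials, L)
    if shape is None:
        raise ValueError("shape (N, T) must be given")
    m = x.mean(axis=0)
    c = (x - m).T @ (x - m) / x.shape[0]
    return GrandCovariance(values=c, means=m, shape=shape)


@dataclass(frozen=True)
class InverseSolution:
    """Reconstructed couplings/fields with per-entry domain-error flags."""

    couplings: np.ndarray
    fields: np.ndarray
    method: str
    field_stderr: Optional[np.ndarray] = None
    flags: Optional[np.ndarray] = None      # True where a fallback/domain issue occurred
    condition_number: Optional[float] = None


def callen_invert(means, n_samples: int) -> InverseSolution:
    """Free-field (Callen) inversion: lam*I_l = atanh(m_l).

    The per-entry error estimate is cosh(lam*I_l) / sqrt(n_samples).
    Saturated means (|m| = 1) raise instead of being silently clipped.
    """
    m = np.asarray(means, dtype=float).ravel()
    if (np.abs(m) >= 1.0).any():
        bad = int(np.argmax(np.abs(m) >= 1.0))
        raise ValueError(
            f"mean at index {bad} is saturated (|m| >= 1): infinite field"
        )
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lam_i = np.arctanh(m)
    stderr = np.cosh(lam_i) / np.sqrt(n_samples)
    return InverseSolution(
        couplings=np.zeros((m.size, m.size)), fields=lam_i,
        method="callen", field_stderr=stderr,
    )


def _inverse(c: np.ndarray, ridge: Optional[float]) -> tuple[np.ndarray, float]:
    l = c.shape[0]
    if ridge is None:
        ridge = 1e-8 * np.trace(c) / l
    creg = c + ridge * np.eye(l)
    cond = float(np.linalg.cond(creg))
    if not np.isfinite(cond) or cond > 1e14:
        raise SingularCovarianceError(
            f"covariance is numerically singular (condition number {cond:.3e})"
        )
    return np.linalg.inv(creg), cond


def _zero_diag(j: np.ndarray) -> np.ndarray:
    np.fill_diagonal(j, 0.0)
    return j


def invert_naive_mf(gc: GrandCovariance, ridge: Optional[float] = None
                    ) -> InverseSolution:
    """Naive mean-field inversion: J = -C^{-1} off-diagonal."""
    cinv, cond = _inverse(gc.values, ridge)
    j = _zero_diag(-cinv.copy())
    j = (j + j.T) / 2.0
    return InverseSolution(couplings=j, fields=np.arctanh(np.clip(gc.means, -1 + 1e-12, 1 - 1e-12)),
                           method="nmf", condition_number=cond)


def invert_tap(gc: GrandCovariance, ridge: Optional[float] = None,
               fallback_to_nmf: bool = True) -> InverseSolution:
    """TAP inversion: J = -2 C^{-1} / (1 + sqrt(1 - 8 m m' C^{-1})) entrywise.

    Entries with negative discriminant are flagged; with
    ``fallback_to_nmf`` they take the naive-MF value, otherwise NaN.
    At m = 0 the formula reduces exactly to naive MF.
    """
    cinv, cond = _inverse(gc.values, ridge)
    m = gc.means
    disc = 1.0 - 8.0 * np.outer(m, m) * cinv
    bad = disc < 0
    disc_safe = np.where(bad, 0.0, disc)
    j = -2.0 * cinv / (1.0 + np.sqrt(disc_safe))
    if fallback_to_nmf:
        j = np.where(bad, -cinv, j)
    else:
        j = np.where(bad, np.nan, j)
    j = _zero_diag((j + j.T) / 2.0)
    np.fill_diagonal(bad, False)
    return InverseSolution(couplings=j, fields=np.arctanh(np.clip(m, -1 + 1e-12, 1 - 1e-12)),
                           method="tap", flags=bad, condition_number=cond)


def _pair_log_ratio(m: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(1/4) log of the pair-marginal probability ratio, with domain flags."""
    mp = m[:, None]
    mq = m[None, :]
    num1 = (1 + mp) * (1 + mq) + c
    num2 = (1 - mp) * (1 - mq) + c
    den1 = (1 + mp) * (1 - mq) - c
    den2 = (1 - mp) * (1 + mq) - c
    bad = (num1 <= 0) | (num2 <= 0) | (den1 <= 0) | (den2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = 0.25 * (np.log(num1) + np.log(num2) - np.log(den1) - np.log(den2))
    val = np.where(bad, np.nan, val)
    return val, bad


def invert_independent_pair(gc: GrandCovariance) -> InverseSolution:
    """Independent-pair inversion from the pair marginals; exact for a true
    two-spin system.  Non-positive log arguments are flagged as NaN."""
    j, bad = _pair_log_ratio(gc.means, gc.values)
    j = _zero_diag(j.copy())
    np.fill_diagonal(bad, False)
    return InverseSolution(couplings=j, fields=np.arctanh(np.clip(gc.means, -1 + 1e-12, 1 - 1e-12)),
                           method="ip", flags=bad)


def invert_sessak_monasson(gc: GrandCovariance, ridge: Optional[float] = None
                           ) -> InverseSolution:
    """Sessak-Monasson small-correlation expansion:
    J = J_IP - C^{-1} - C / ((1 - m^2)(1 - m'^2) - C^2)  off-diagonal."""
    cinv, cond = _inverse(gc.values, ridge)
    m = gc.means
    c = gc.values
    jip, bad = _pair_log_ratio(m, c)
    denom = np.outer(1 - m ** 2, 1 - m ** 2) - c ** 2
    bad = bad | (np.abs(denom) < 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = jip - cinv - c / denom
    j = np.where(bad, np.nan, j)
    j = _zero_diag(((j + j.T) / 2.0).copy())
    np.fill_diagonal(bad, False)
    return InverseSolution(couplings=j, fields=np.arctanh(np.clip(m, -1 + 1e-12, 1 - 1e-12)),
                           method="sm", flags=bad, condition_number=cond)


@dataclass(frozen=True)
class ReducedCovariances:
    """Equal-time N x N and equal-neuron T x T blocks of the grand covariance.

    ``space_cov[i, j]`` = mean over alpha of C_{(i,alpha),(j,alpha)};
    ``time_cov[a, b]`` = mean over i of C_{(i,a),(i,b)}.  This reduces the
    parameter count from (NT)^2 to N*T*(N+T) in the non-relativistic
    approximation (only equal-time or equal-neuron covariances retained).
    """

    space_cov: np.ndarray
    time_cov: np.ndarray


def reduce_nonrelativistic(gc: GrandCovariance) -> ReducedCovariances:
    """Average the equal-time and equal-neuron diagonal blocks of C."""
    n, t = gc.shape
    c4 = gc.values.reshape(n, t, n, t)     # (i, alpha, j, beta)
    space = np.einsum("iaja->ij", c4) / t
    time = np.einsum("iaib->ab", c4) / n
    return ReducedCovariances(space_cov=space, time_cov=time)
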