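"""Coupling-distribution scaling analysis and the PCA-as-lattice-action map.

Couplings are the sum of a stationary and a fluctuating term,

    A_ij = J0 * Lam_ij / g(Lam)  +  J_ij * Lam_ij / sqrt(g(Lam)),

with J0 and J_ij standard Gaussians and g(Lam) the average connectivity
(1/N) sum_ij Lam_ij.  For g = N^alpha the coupling variance is N^(-alpha):
alpha = 1 is the Sherrington-Kirkpatrick regime (variance 1/N), alpha = 1/2
the sub-linear regime.  ``scaling_fit`` recovers alpha as minus the
log-log slope of the fitted variance versus N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConnectivityModel",
    "ScalingFit",
    "generate_couplings",
    "full_connectivity",
    "random_connectivity",
    "scaling_fit",
    "pca_action",
]


@dataclass(frozen=True)
class ConnectivityModel:
    """Binary axon matrix plus coupling-scale bookkeeping.

    ``axon_matrix`` must be symmetric.  Diagonal entries count toward the
    mean connectivity g (the fully connected model has g = N) but never
    produce a coupling: generated matrices are zero on the diagonal.
    ``stationary_per_pair`` draws an independent J0 per pair instead of one
    per matrix.
    """

    axon_matrix: np.ndarray
    stationary_per_pair: bool = False

    def __post_init__(self):
        lam = np.asarray(self.axon_matrix)
        if lam.ndim != 2 or lam.shape[0] != lam.shape[1]:
            raise ValueError("axon matrix must be square")
        if not np.isin(lam, (0, 1)).all():
            raise ValueError("axon matrix entries must be 0/1")
        if (lam != lam.T).any():
            raise ValueError("axon matrix must be symmetric")
        lam = lam.astype(np.uint8, copy=False)
        lam.setflags(write=False)
        object.__setattr__(self, "axon_matrix", lam)

    @property
    def n(self) -> int:
        return self.axon_matrix.shape[0]

    @property
    def mean_connectivity(self) -> float:
        """g(Lam) = (1/N) * number of directed edges."""
        return float(self.axon_matrix.sum()) / self.n


def full_connectivity(n: int) -> ConnectivityModel:
    """Fully connected model: g = N (self-edges count toward g only)."""
    return ConnectivityModel(axon_matrix=np.ones((n, n), dtype=np.uint8))


def random_connectivity(n: int, alpha: float, seed: int) -> ConnectivityModel:
    """Symmetric Erdos-Renyi axon matrix with mean connectivity ~ N^alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    p = min(1.0, n ** alpha / (n - 1.0))
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < p
    lam = np.triu(upper, 1)
    lam = (lam | lam.T).astype(np.uint8)
    return ConnectivityModel(axon_matrix=lam)


def generate_couplings(model: ConnectivityModel, seed: int) -> np.ndarray:
    """Draw a symmetric coupling matrix A = J_tilde + delta_J_tilde.

    Stationary part J0 * Lam / g (J0 drawn once per matrix unless
    ``stationary_per_pair``); fluctuating part J * Lam / sqrt(g) with
    symmetric unit-variance Gaussian J.
    """
    g = model.mean_connectivity
    if g == 0:
        raise ValueError("empty connectivity: g(Lam) = 0")
    rng = np.random.default_rng(seed)
    n = model.n
    lam = model.axon_matrix.astype(float)
    np.fill_diagonal(lam, 0.0)          # self-edges never produce couplings
    if model.stationary_per_pair:
        j0 = rng.standard_normal((n, n))
        j0 = np.triu(j0, 1)
        j0 = j0 + j0.T
    else:
        j0 = float(rng.standard_normal())
    j = rng.standard_normal((n, n))
    j = np.triu(j, 1)
    j = j + j.T
    return (j0 * lam) / g + (j * lam) / math.sqrt(g)


@dataclass(frozen=True)
class ScalingFit:
    """Scaling-exponent fit of coupling variance versus N.

    ``exponent_hat``/``exponent_stderr`` come from the requested fit mode;
    both the Gaussian-ML and moment-based per-N variances are recorded, with
    excess kurtosis as a Gaussianity diagnostic.
    """

    sizes: np.ndarray
    variances_ml: np.ndarray
    variances_moment: np.ndarray
    exponent_hat: float
    exponent_stderr: float
    exponent_hat_moment: float
    exponent_stderr_moment: float
    excess_kurtosis: np.ndarray
    fit_mode: str


def _loglog_slope(sizes: np.ndarray, variances: np.ndarray,
                  sigma_log: Optional[np.ndarray] = None) -> tuple[float, float]:
    """Minus the slope of log(variance) vs log(N) with its standard error.

    When per-point uncertainties of log(variance) are available (replicate
    spread), the fit is weighted and the slope error is propagated from
    them; the residual-based OLS error is the fallback (it reflects only
    non-linearity, not sampling noise).
    """
    x = np.log(sizes)
    y = np.log(variances)
    if sigma_log is not None and np.all(sigma_log > 0):
        w = 1.0 / sigma_log
        coeffs, cov = np.polyfit(x, y, 1, w=w, cov="unscaled")
        return -float(coeffs[0]), float(np.sqrt(cov[0, 0]))
    res = stats.linregress(x, y)
    return -float(res.slope), float(res.stderr)


def scaling_fit(coupling_samples: dict[int, Sequence[np.ndarray]],
                fit_mode: str = "gaussian_fit") -> ScalingFit:
    """Fit the variance-scaling exponent from per-N coupling collections.

    ``coupling_samples`` maps N to a list of coupling matrices (or flat
    sample arrays); off-diagonal entries where couplings exist (nonzero
    pattern union) are pooled per N.  Requires >= 3 distinct N.
    """
    if fit_mode not in ("gaussian_fit", "moment_based"):
        raise ValueError(f"unknown fit mode {fit_mode!r}")
    sizes = np.array(sorted(coupling_samples))
    if len(sizes) < 3:
        raise ValueError("need at least 3 distinct sizes")
    var_ml = np.empty(len(sizes))
    var_mom = np.empty(len(sizes))
    sigma_log = np.empty(len(sizes))
    kurt = np.empty(len(sizes))
    for idx, n in enumerate(sizes):
        rep_ml, rep_mom, pooled = [], [], []
        for mat in coupling_samples[n]:
            arr = np.asarray(mat, dtype=float)
            if arr.ndim == 2:
                mask = ~np.eye(arr.shape[0], dtype=bool)
                vals = arr[mask]
                vals = vals[vals != 0] if (vals == 0).any() else vals
            else:
                vals = arr.ravel()
            # each replicate is one fitted distribution: its own mean is a
            # fit parameter, so the spread is measured about it
            centered = vals - vals.mean()
            pooled.append(centered)
            if centered.size >= 2:
                rep_ml.append(centered.var(ddof=0))
                rep_mom.append(vals.var(ddof=1))
        v = np.concatenate(pooled)
        if v.size < 2 or v.std() == 0 or not rep_ml:
            raise ValueError(f"degenerate samples at N={n}")
        var_ml[idx] = float(np.mean(rep_ml))
        var_mom[idx] = float(np.mean(rep_mom))
        if var_ml[idx] == 0 or var_mom[idx] == 0:
            raise ValueError(f"degenerate samples at N={n}")
        # delta-method error of log(mean variance) from the replicate spread
        if len(rep_ml) >= 2:
            sigma_log[idx] = (np.std(rep_ml, ddof=1)
                              / (var_ml[idx] * math.sqrt(len(rep_ml))))
        else:
            sigma_log[idx] = 0.0
        kurt[idx] = stats.kurtosis(v, fisher=True)
    use_sigma = sigma_log if np.all(sigma_log > 0) else None
    a_ml, se_ml = _loglog_slope(sizes, var_ml, use_sigma)
    a_mom, se_mom = _loglog_slope(sizes, var_mom, use_sigma)
    if fit_mode == "gaussian_fit":
        a, se = a_ml, se_ml
    else:
        a, se = a_mom, se_mom
    return ScalingFit(sizes=sizes, variances_ml=var_ml, variances_moment=var_mom,
                      exponent_hat=a, exponent_stderr=se,
                      exponent_hat_moment=a_mom, exponent_stderr_moment=se_mom,
                      excess_kurtosis=kurt, fit_mode=fit_mode)


def pca_action(k, n_components: int, time_domain: bool = False
               ) -> tuple[np.ndarray, float, np.ndarray]:
    """Principal-subspace action of a kernel.

    Returns ``(basis, action, induced_couplings)``: the top-``n_components``
    orthonormal eigenbasis Y of Omega Omega^T, the action value
    -Tr(Y^T Omega Omega^T Y) = -(sum of the top eigenvalues), and the induced
    potential matrix A_ij = -sum_k y_ik y_jk (symmetric, rank <= n, trace -n).
    The Frobenius projection objective differs from the action by the
    constant Tr(Omega^T Omega).  ``time_domain`` analyzes the transposed
    kernel (the purely kinetic dual: couplings act on time bins).
    """
    values = k.values if hasattr(k, "values") else np.asarray(k)
    x = values.astype(float)
    if time_domain:
        x = x.T
    n = x.shape[0]
    if not 1 <= n_components <= n:
        raise ValueError(f"n_components must be in [1, {n}]")
    gram = x @ x.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1][:n_components]
    y = evecs[:, order]
    # deterministic sign: first entry of largest magnitude made positive
    for col in range(y.shape[1]):
        j = int(np.argmax(np.abs(y[:, col])))
        if y[j, col] < 0:
            y[:, col] = -y[:, col]
    action = -float(evals[order].sum())
    induced = -(y @ y.T)
    return y, action, induced
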