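"""Trial ensembles: windowing, integer time-shift alignment, overlap matrices
and ensemble-averaged hypermatrices.

A :class:`TrialEnsemble` holds n full-length recorded trials (equal N, equal
recorded length) plus a common analysis window; per-trial integer shifts
``nu`` move each trial's window within the recording.  Alignment maximizes
the squared Frobenius norm of the n x n trial-overlap matrix.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .kernelspace import BinaryKernel, first_order

__all__ = [
    "TrialEnsemble",
    "TrialOverlapMatrix",
    "EnsembleHypermatrix",
    "apply_timeshifts",
    "trial_overlap_matrix",
    "align_trials",
    "ensemble_hypermatrix",
    "cut_trials",
]


@dataclass(frozen=True)
class TrialEnsemble:
    """Trials plus a shared analysis window.

    ``trials`` all share N and recorded length; the analysis window of trial
    k is ``[window_start + shifts[k], window_start + shifts[k] + window_len)``
    in that trial's recorded bins.
    """

    trials: tuple
    window_start: int = 0
    window_len: Optional[int] = None
    shifts: Optional[np.ndarray] = None
    alignment_event: str = ""

    def __post_init__(self):
        trials = tuple(self.trials)
        if not trials:
            raise ValueError("ensemble needs at least one trial")
        n = trials[0].n_neurons
        t_rec = trials[0].n_bins
        for k, tr in enumerate(trials):
            if not isinstance(tr, BinaryKernel):
                raise TypeError(f"trial {k} is not a BinaryKernel")
            if tr.n_neurons != n or tr.n_bins != t_rec:
                raise ValueError(f"trial {k} shape {tr.shape} != {(n, t_rec)}")
        object.__setattr__(self, "trials", trials)
        wl = t_rec if self.window_len is None else int(self.window_len)
        object.__setattr__(self, "window_len", wl)
        shifts = (np.zeros(len(trials), dtype=int) if self.shifts is None
                  else np.asarray(self.shifts, dtype=int))
        if shifts.shape != (len(trials),):
            raise ValueError("one shift per trial is required")
        object.__setattr__(self, "shifts", shifts)
        for k in range(len(trials)):
            self._check_window(k, shifts[k])

    def _check_window(self, k: int, nu: int):
        start = self.window_start + nu
        if start < 0 or start + self.window_len > self.trials[k].n_bins:
            raise ValueError(
                f"trial {k}: shifted window [{start}, {start + self.window_len}) "
                f"outside recorded range [0, {self.trials[k].n_bins})"
            )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return self.trials[0].n_neurons

    def windowed(self, k: int) -> np.ndarray:
        """The k-th trial's window (N x window_len binary matrix)."""
        start = self.window_start + int(self.shifts[k])
        return self.trials[k].values[:, start:start + self.window_len]

    def windowed_kernels(self) -> list[BinaryKernel]:
        return [
            BinaryKernel(values=self.windowed(k),
                         tau_ms=self.trials[k].tau_ms,
                         neuron_labels=self.trials[k].neuron_labels)
            for k in range(self.n_trials)
        ]


def cut_trials(trials: Sequence[BinaryKernel], start: int, length: int
               ) -> TrialEnsemble:
    """Build an ensemble from pre-recorded trials with a common window."""
    return TrialEnsemble(trials=tuple(trials), window_start=start,
                         window_len=length)


def apply_timeshifts(e: TrialEnsemble, nu) -> TrialEnsemble:
    """Return the ensemble with per-trial shifts ``nu`` applied (replacing any
    existing shifts).  A positive shift moves the window later in the
    recording, i.e. a spike appears earlier in window coordinates."""
    nu = np.asarray(nu, dtype=int)
    return replace(e, shifts=nu)


@dataclass(frozen=True)
class TrialOverlapMatrix:
    """n x n matrix of binary trial overlaps at the current shifts."""

    values: np.ndarray

    @property
    def norm_sq(self) -> float:
        """Squared Frobenius norm, the alignment objective."""
        return float(np.sum(self.values ** 2))


def trial_overlap_matrix(e: TrialEnsemble) -> TrialOverlapMatrix:
    """Overlaps Q_kk' = mean over cells of phi_k * phi_k' on the shifted
    windows; the diagonal is each trial's activity density."""
    flat = np.stack([e.windowed(k).astype(float).ravel()
                     for k in range(e.n_trials)])
    q = flat @ flat.T / flat.shape[1]
    return TrialOverlapMatrix(values=q)


def _norm_sq_at(e: TrialEnsemble, nu: np.ndarray) -> float:
    return trial_overlap_matrix(apply_timeshifts(e, nu)).norm_sq


def align_trials(e: TrialEnsemble, bounds: Sequence[tuple[int, int]],
                 seed: int = 0, exhaustive_cap: int = 10_000,
                 n_restarts: int = 10) -> np.ndarray:
    """Shift vector maximizing the squared norm of the overlap matrix.

    ``bounds[k] = (lo, hi)`` is the inclusive feasible range for trial k's
    shift.  Exhaustive search when the product of range sizes is within
    ``exhaustive_cap``; otherwise seeded multi-start coordinate ascent.  The
    returned shifts never score below the zero-shift (or feasible-projection)
    baseline.
    """
    if len(bounds) != e.n_trials:
        raise ValueError("one bound pair per trial is required")
    ranges = []
    for k, (lo, hi) in enumerate(bounds):
        lo, hi = int(lo), int(hi)
        if hi < lo:
            raise ValueError(f"empty feasible range for trial {k}")
        feasible = [nu for nu in range(lo, hi + 1)
                    if _window_ok(e, k, nu)]
        if not feasible:
            raise ValueError(f"no feasible shift for trial {k} in [{lo}, {hi}]")
        ranges.append(feasible)

    baseline = np.array([r[np.argmin(np.abs(r))] for r in
                         (np.array(r) for r in ranges)])
    best = baseline.copy()
    best_val = _norm_sq_at(e, best)

    n_comb = math.prod(len(r) for r in ranges)
    if n_comb <= exhaustive_cap:
        for combo in itertools.product(*ranges):
            val = _norm_sq_at(e, np.array(combo))
            if val > best_val:
                best_val = val
                best = np.array(combo)
        return best

    rng = np.random.default_rng(seed)
    for restart in range(n_restarts):
        nu = (baseline.copy() if restart == 0 else
              np.array([r[rng.integers(len(r))] for r in ranges]))
        val = _norm_sq_at(e, nu)
        improved = True
        while improved:
            improved = False
            for k in rng.permutation(e.n_trials):
                best_c, best_cv = int(nu[k]), val
                for cand in ranges[k]:
                    nu[k] = cand
                    v = _norm_sq_at(e, nu)
                    if v > best_cv:
                        best_c, best_cv = cand, v
                nu[k] = best_c
                if best_cv > val:
                    val = best_cv
                    improved = True
        if val > best_val:
            best_val = val
            best = nu.copy()
    return best


def _window_ok(e: TrialEnsemble, k: int, nu: int) -> bool:
    start = e.window_start + nu
    return 0 <= start and start + e.window_len <= e.trials[k].n_bins


@dataclass(frozen=True)
class EnsembleHypermatrix:
    """Trial-averaged kernel and correlation matrices with covariance parts.

    Spin representation: ``mean_kernel`` is the N x T average of 2*phi - 1;
    ``delta_c = <C> - <M><M>^T / T`` and ``delta_q = <Q> - <M>^T<M> / N``
    vanish exactly for a single trial (or identical trials).
    """

    mean_kernel: np.ndarray
    mean_c: np.ndarray
    mean_q: np.ndarray
    delta_c: np.ndarray
    delta_q: np.ndarray
    n_trials: int


def ensemble_hypermatrix(e: TrialEnsemble) -> EnsembleHypermatrix:
    """Average kernel, C, Q over the (aligned) windowed trials, plus the
    ensemble covariance corrections delta_c, delta_q."""
    n = e.n_neurons
    t = e.window_len
    mean_kernel = np.zeros((n, t))
    mean_c = np.zeros((n, n))
    mean_q = np.zeros((t, t))
    for k in range(e.n_trials):
        sig = 2.0 * e.windowed(k).astype(float) - 1.0
        mean_kernel += sig
        mean_c += sig @ sig.T / t
        mean_q += sig.T @ sig / n
    mean_kernel /= e.n_trials
    mean_c /= e.n_trials
    mean_q /= e.n_trials
    return EnsembleHypermatrix(
        mean_kernel=mean_kernel, mean_c=mean_c, mean_q=mean_q,
        delta_c=mean_c - mean_kernel @ mean_kernel.T / t,
        delta_q=mean_q - mean_kernel.T @ mean_kernel / n,
        n_trials=e.n_trials,
    )


def bootstrap_mean_kernel(e: TrialEnsemble, n_boot: int, seed: int) -> np.ndarray:
    """Bootstrap standard error of the mean kernel (per-cell), as a
    convergence diagnostic for the ensemble average."""
    rng = np.random.default_rng(seed)
    sigs = np.stack([2.0 * e.windowed(k).astype(float) - 1.0
                     for k in range(e.n_trials)])
    means = np.empty((n_boot,) + sigs.shape[1:])
    for b in range(n_boot):
        idx = rng.integers(e.n_trials, size=e.n_trials)
        means[b] = sigs[idx].mean(axis=0)
    return means.std(axis=0, ddof=1)
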