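"""Core kernel data types and first-order observables.

A *kernel* is the N x T matrix of neuron activity per clock-time bin: rows
are neurons (index set V, size N), columns are time bins (index set S, size
T, bin width ``tau_ms``).  Two equivalent representations are supported:

* :class:`BinaryKernel` with entries in {0, 1} (lattice-gas picture), and
* :class:`MagnetizationKernel` with entries in {-1, +1} (spin picture),

linked by the entrywise map ``sigma = 2*phi - 1``.

Indices are 0-based internally; time bins are half-open ``[t, t + tau)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BinaryKernel",
    "MagnetizationKernel",
    "IndexMaps",
    "FirstOrderSummary",
    "QuantileSpectrum",
    "InvalidKernelError",
    "to_spin",
    "to_binary",
    "first_order",
    "quantile_spectrum",
    "baseline_activity_order",
    "grand_index",
]


class InvalidKernelError(ValueError):
    """Raised when a kernel matrix violates its value constraints."""


def _as_matrix(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidKernelError(
            f"kernel must be a 2-d matrix with N >= 1, T >= 1; got shape {arr.shape}"
        )
    return arr


def _default_labels(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


@dataclass(frozen=True)
class BinaryKernel:
    """Binary activity kernel: N x T matrix over {0, 1}.

    Parameters
    ----------
    values
        N x T array; every entry must be exactly 0 or 1.
    tau_ms
        Clock time (bin width) in milliseconds; must be positive.
    neuron_labels
        Ordered identifiers for the rows.  Defaults to ``n0, n1, ...``.
    time_origin
        Integer bin index of the alignment event (may lie outside [0, T)).
    """

    values: np.ndarray
    tau_ms: float = 1.0
    neuron_labels: tuple[str, ...] = ()
    time_origin: int = 0

    def __post_init__(self):
        arr = _as_matrix(self.values)
        if not np.isin(arr, (0, 1)).all():
            bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise InvalidKernelError(
                f"non-binary entry {arr[tuple(bad)]!r} at (row={bad[0]}, col={bad[1]})"
            )
        if not (self.tau_ms > 0 and np.isfinite(self.tau_ms)):
            raise InvalidKernelError(f"tau_ms must be positive, got {self.tau_ms}")
        arr = arr.astype(np.uint8, copy=False)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        labels = tuple(self.neuron_labels) or _default_labels(arr.shape[0])
        if len(labels) != arr.shape[0]:
            raise InvalidKernelError(
                f"{len(labels)} labels for {arr.shape[0]} rows"
            )
        object.__setattr__(self, "neuron_labels", labels)
        object.__setattr__(self, "time_origin", int(self.time_origin))

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values, tau_ms: Optional[float] = None) -> "BinaryKernel":
        """Return a copy with new values (and optionally a new clock time)."""
        n = np.asarray(values).shape[0]
        labels = self.neuron_labels if n == self.n_neurons else ()
        return BinaryKernel(
            values=values,
            tau_ms=self.tau_ms if tau_ms is None else tau_ms,
            neuron_labels=labels,
            time_origin=self.time_origin,
        )

    def permute_rows(self, order: Sequence[int]) -> "BinaryKernel":
        order = np.asarray(order, dtype=int)
        if sorted(order.tolist()) != list(range(self.n_neurons)):
            raise ValueError("order must be a permutation of row indices")
        return BinaryKernel(
            values=self.values[order],
            tau_ms=self.tau_ms,
            neuron_labels=tuple(self.neuron_labels[i] for i in order),
            time_origin=self.time_origin,
        )


@dataclass(frozen=True)
class MagnetizationKernel:
    """Spin kernel: N x T matrix over {-1, +1}; same metadata as BinaryKernel."""

    values: np.ndarray
    tau_ms: float = 1.0
    neuron_labels: tuple[str, ...] = ()
    time_origin: int = 0

    def __post_init__(self):
        arr = _as_matrix(self.values)
        if not np.isin(arr, (-1, 1)).all():
            bad = np.argwhere(~np.isin(arr, (-1, 1)))[0]
            raise InvalidKernelError(
                f"non-spin entry {arr[tuple(bad)]!r} at (row={bad[0]}, col={bad[1]})"
            )
        if not (self.tau_ms > 0 and np.isfinite(self.tau_ms)):
            raise InvalidKernelError(f"tau_ms must be positive, got {self.tau_ms}")
        arr = arr.astype(np.int8, copy=False)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        labels = tuple(self.neuron_labels) or _default_labels(arr.shape[0])
        if len(labels) != arr.shape[0]:
            raise InvalidKernelError(f"{len(labels)} labels for {arr.shape[0]} rows")
        object.__setattr__(self, "neuron_labels", labels)
        object.__setattr__(self, "time_origin", int(self.time_origin))

    n_neurons = BinaryKernel.n_neurons
    n_bins = BinaryKernel.n_bins
    shape = BinaryKernel.shape


def to_spin(k: BinaryKernel) -> MagnetizationKernel:
    """Map a binary kernel to the spin representation, sigma = 2*phi - 1."""
    if not isinstance(k, BinaryKernel):
        raise InvalidKernelError(f"expected BinaryKernel, got {type(k).__name__}")
    return MagnetizationKernel(
        values=2 * k.values.astype(np.int8) - 1,
        tau_ms=k.tau_ms,
        neuron_labels=k.neuron_labels,
        time_origin=k.time_origin,
    )


def to_binary(k: MagnetizationKernel) -> BinaryKernel:
    """Inverse of :func:`to_spin`: phi = (sigma + 1) / 2."""
    if not isinstance(k, MagnetizationKernel):
        raise InvalidKernelError(f"expected MagnetizationKernel, got {type(k).__name__}")
    return BinaryKernel(
        values=(k.values.astype(np.int16) + 1) // 2,
        tau_ms=k.tau_ms,
        neuron_labels=k.neuron_labels,
        time_origin=k.time_origin,
    )


@dataclass(frozen=True)
class IndexMaps:
    """Row permutation theta and the bijection between V x S and the mixed space.

    The grand map flattens the double index (i, alpha) into a single index
    l in [0, L) with L = N*T; the default is row-major order l = i*T + alpha.
    """

    n_neurons: int
    n_bins: int
    theta: np.ndarray = None  # permutation of rows; identity by default

    def __post_init__(self):
        theta = (
            np.arange(self.n_neurons)
            if self.theta is None
            else np.asarray(self.theta, dtype=int)
        )
        if sorted(theta.tolist()) != list(range(self.n_neurons)):
            raise ValueError("theta must be a permutation of 0..N-1")
        theta.setflags(write=False)
        object.__setattr__(self, "theta", theta)

    @property
    def theta_inverse(self) -> np.ndarray:
        inv = np.empty_like(self.theta)
        inv[self.theta] = np.arange(self.n_neurons)
        return inv

    @property
    def grand_size(self) -> int:
        return self.n_neurons * self.n_bins

    def to_grand(self, i: int, alpha: int) -> int:
        return int(i) * self.n_bins + int(alpha)

    def from_grand(self, l: int) -> tuple[int, int]:
        return divmod(int(l), self.n_bins)


def grand_index(n_neurons: int, n_bins: int) -> IndexMaps:
    """Convenience constructor for the default (identity-theta) index maps."""
    return IndexMaps(n_neurons=n_neurons, n_bins=n_bins)


@dataclass(frozen=True)
class FirstOrderSummary:
    """First-order observables of a kernel.

    ``offset_binary`` is the global mean of the binary kernel, ``offset_spin``
    its spin counterpart (= 2*offset_binary - 1).  ``row_rates`` (length N) are
    per-neuron firing rates, ``col_activity`` (length T) per-bin population
    activity; ``row_means_spin`` / ``col_means_spin`` are the spin versions.
    """

    offset_binary: float
    offset_spin: float
    row_rates: np.ndarray
    col_activity: np.ndarray
    row_means_spin: np.ndarray
    col_means_spin: np.ndarray


def first_order(k: BinaryKernel | MagnetizationKernel) -> FirstOrderSummary:
    """Compute offsets and row/column averages in both representations.

    The mean of the row averages and the mean of the column averages both
    equal the offset, in either representation.
    """
    if isinstance(k, MagnetizationKernel):
        k = to_binary(k)
    elif not isinstance(k, BinaryKernel):
        raise InvalidKernelError(f"expected a kernel, got {type(k).__name__}")
    phi = k.values.astype(float)
    f = phi.mean(axis=1)
    omega = phi.mean(axis=0)
    offset = float(phi.mean())
    return FirstOrderSummary(
        offset_binary=offset,
        offset_spin=2.0 * offset - 1.0,
        row_rates=f,
        col_activity=omega,
        row_means_spin=2.0 * f - 1.0,
        col_means_spin=2.0 * omega - 1.0,
    )


@dataclass(frozen=True)
class QuantileSpectrum:
    """Empirical quantile (order-statistics) spectrum of a real vector.

    ``sorted_values`` is non-decreasing; the quantile function is the step
    function taking value ``sorted_values[j]`` on the interval
    ``(j/n, (j+1)/n]`` where n = len(sorted_values) (so ``support_step`` is
    1/n).  Its integral over [0, 1] equals the mean of the underlying vector.
    """

    sorted_values: np.ndarray
    support_step: float

    def evaluate(self, s) -> np.ndarray:
        """Right-continuous inverse CDF evaluated at points s in [0, 1]."""
        s = np.asarray(s, dtype=float)
        n = len(self.sorted_values)
        idx = np.clip(np.ceil(s * n).astype(int) - 1, 0, n - 1)
        return self.sorted_values[idx]

    def mean(self) -> float:
        return float(self.sorted_values.mean())


def quantile_spectrum(v, order: int = 1) -> QuantileSpectrum:
    """Order-statistics spectrum of ``v`` (sorted non-decreasing step function).

    ``order`` >= 1 selects the moment order used when the spectrum is fed to a
    distance; it does not change the sorting.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot build a quantile spectrum from an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("quantile spectrum requires finite values")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    return QuantileSpectrum(sorted_values=np.sort(v), support_step=1.0 / v.size)


def baseline_activity_order(k: BinaryKernel, window_ms: float = 250.0) -> np.ndarray:
    """Row order sorting neurons by activity in the first ``window_ms`` of the raster.

    Ties are broken by original index (stable sort).  Returns the permutation
    array usable with :meth:`BinaryKernel.permute_rows` (most active first).
    """
    n_bins = max(1, min(k.n_bins, int(round(window_ms / k.tau_ms))))
    activity = k.values[:, :n_bins].astype(float).mean(axis=1)
    return np.argsort(-activity, kind="stable")
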