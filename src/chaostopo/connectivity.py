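"""Node-interaction (connectivity) matrices from geometry or signals.

A connectivity matrix ``A`` encodes how strongly each pair of nodes in a
spatial network interacts.  Off-diagonal entries are nonnegative kernel
values of the pairwise distance (or absolute Pearson correlations for
signal data); the diagonal is fixed to the negative off-diagonal row sum,
so every row sums to zero.  This is the *negative* graph-Laplacian
convention: ``A = -L`` for the usual positive-semidefinite Laplacian, and
it is exactly the form a diffusively coupled oscillator network consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PointCloud",
    "SignalSet",
    "ConnectivityMatrix",
    "pairwise_distances",
    "connectivity_matrix",
    "correlation_coupling",
]

KERNELS = ("kirchhoff", "exponential", "power")


@dataclass
class PointCloud:
    """N points in n-dimensional space with unique node identifiers."""

    coords: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] < 1:
            raise ValueError("coords must be a non-empty N x n array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if not self.ids:
            self.ids = [str(i) for i in range(self.coords.shape[0])]
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("ids length does not match number of points")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass
class SignalSet:
    """M channels of length-T time series, with optional per-channel labels."""

    signals: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[1] < 3:
            raise ValueError("signals must be M x T with T >= 3")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.signals.shape[0]:
                raise ValueError("labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric zero-row-sum interaction matrix with its kernel provenance."""

    A: np.ndarray
    kernel: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    def laplacian(self) -> np.ndarray:
        """The positive-semidefinite graph Laplacian ``-A``."""
        return -self.A


def pairwise_distances(cloud: PointCloud) -> np.ndarray:
    """Euclidean distance matrix between all node pairs.

    Returns a symmetric N x N matrix with zero diagonal, in the same
    length units as the input coordinates.
    """
    if not np.all(np.isfinite(cloud.coords)):
        raise ValueError("coords contain non-finite values")
    if cloud.n_points == 1:
        return np.zeros((1, 1))
    return squareform(pdist(cloud.coords, metric="euclidean"))


def _zero_row_sum(off: np.ndarray) -> np.ndarray:
    A = off.copy()
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    return A


def connectivity_matrix(
    d: np.ndarray,
    kernel: str = "exponential",
    *,
    sigma: float = 3.0,
    kappa: int = 1,
    nu: float = 2.0,
    cutoff: float | None = None,
) -> ConnectivityMatrix:
    """Build a connectivity matrix from a distance matrix.

    Three kernels map distance to interaction strength:

    ``kirchhoff``
        A_ij = 1 if d_ij <= cutoff else 0 — the hard-cutoff contact matrix
        used by Gaussian network models.
    ``exponential``
        A_ij = exp(-d_ij^kappa / (kappa * sigma^kappa)), a generalized
        exponential with characteristic distance ``sigma`` and order
        ``kappa`` (kappa=1 gives the plain exponential e^{-d/sigma}).
    ``power``
        A_ij = (d_ij / sigma)^{-nu}, nu > 1; undefined at d_ij = 0.

    In all cases the diagonal is the negative off-diagonal row sum, so
    rows sum to zero exactly and the matrix is diagonally dominant.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")
    off_mask = ~np.eye(d.shape[0], dtype=bool)
    if kernel == "kirchhoff":
        if cutoff is None:
            cutoff = sigma
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        off = (d <= cutoff).astype(float)
        params = {"cutoff": float(cutoff)}
    elif kernel == "exponential":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if kappa < 1 or int(kappa) != kappa:
            raise ValueError("kappa must be a positive integer")
        off = np.exp(-(d**kappa) / (kappa * sigma**kappa))
        params = {"sigma": float(sigma), "kappa": int(kappa)}
    else:  # power
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if nu <= 1:
            raise ValueError("power-law exponent nu must exceed 1")
        if np.any(d[off_mask] == 0):
            raise ValueError(
                "power kernel undefined for coincident nodes (d_ij = 0)"
            )
        with np.errstate(divide="ignore"):
            off = np.where(off_mask, (d / sigma) ** (-nu), 0.0)
        params = {"sigma": float(sigma), "nu": float(nu)}
    A = _zero_row_sum(np.where(off_mask, off, 0.0))
    # symmetrize away any float asymmetry from the kernel evaluation
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    return ConnectivityMatrix(A=A, kernel=kernel, params=params)


def correlation_coupling(s: SignalSet, *, absolute: bool = True) -> ConnectivityMatrix:
    """Pearson-correlation coupling matrix between signal channels.

    Off-diagonal weights are |PCC| between channels (signed PCC with
    ``absolute=False``); the diagonal is the negative off-diagonal row
    sum, never the trivial self-correlation of 1.
    """
    X = s.signals
    var = X.var(axis=1)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance channel(s) {dead.tolist()}: Pearson correlation undefined"
        )
    C = np.corrcoef(X)
    if absolute:
        C = np.abs(C)
    off_mask = ~np.eye(C.shape[0], dtype=bool)
    A = _zero_row_sum(np.where(off_mask, C, 0.0))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, -A.sum(axis=1))
    return ConnectivityMatrix(
        A=A, kernel="pearson", params={"absolute": bool(absolute)}
    )
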