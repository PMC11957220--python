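"""Vietoris-Rips complexes and persistent (spectral) Laplacians.

A point cloud at filtration radius alpha induces a simplicial complex:
a q-simplex on q+1 points enters when every pairwise distance is at most
2*alpha (overlapping balls).  Across a nested pair of complexes
K_t ⊆ K_{t+p}, the q-th persistent Laplacian

    L_q^{t,p} = B_{q+1}^{t,p} (B_{q+1}^{t,p})^T + (B_q^t)^T B_q^t

acts on q-chains of K_t, where B_{q+1}^{t,p} represents the boundary
operator restricted to (q+1)-chains of K_{t+p} whose boundary lies in
K_t.  Its kernel dimension is the persistent Betti number beta_q^{t,p},
and its smallest nonzero eigenvalue tracks the homotopic shape evolution
that plain persistent homology cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import networkx as nx
from scipy.linalg import eigh, null_space

from .connectivity import PointCloud, pairwise_distances

__all__ = [
    "SimplicialComplex",
    "PersistentLaplacian",
    "vietoris_rips",
    "boundary_matrix",
    "persistent_laplacian",
    "betti_and_gap",
    "persistent_betti_ranks",
]

MAX_DIM = 3


@dataclass
class SimplicialComplex:
    """Oriented simplicial complex; simplices stored per dimension.

    Vertices within each simplex are sorted ascending (the orientation
    convention) and the simplex lists are sorted lexicographically so
    boundary-matrix column/row order is canonical.
    """

    simplices: dict[int, list[tuple[int, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, list[tuple[int, ...]]] = {}
        for q, simps in self.simplices.items():
            simps = sorted({tuple(sorted(s)) for s in simps})
            if any(len(s) != q + 1 for s in simps):
                raise ValueError(f"dimension-{q} simplex with wrong vertex count")
            if simps:
                clean[q] = simps
        self.simplices = clean
        self._check_closed()

    def _check_closed(self) -> None:
        for q in sorted(self.simplices):
            if q == 0:
                continue
            faces = set(self.simplices.get(q - 1, []))
            for s in self.simplices[q]:
                for i in range(len(s)):
                    if s[:i] + s[i + 1 :] not in faces:
                        raise ValueError(
                            f"complex not closed under faces: {s} misses a face"
                        )

    @property
    def dim(self) -> int:
        return max(self.simplices, default=-1)

    def n_simplices(self, q: int) -> int:
        return len(self.simplices.get(q, []))

    def contains(self, other: "SimplicialComplex") -> bool:
        """True if ``other`` is a subcomplex of self."""
        for q, simps in other.simplices.items():
            mine = set(self.simplices.get(q, []))
            if not set(simps) <= mine:
                return False
        return True


@dataclass
class PersistentLaplacian:
    """L_q^{t,p} with its spectrum and derived topological summaries."""

    q: int
    matrix: np.ndarray
    spectrum: np.ndarray
    betti: int
    lambda_min_nonzero: float | None
    tol: float


def vietoris_rips(
    cloud: PointCloud | np.ndarray,
    alpha: float,
    max_dim: int = 2,
    *,
    diameter_rule: bool = False,
) -> SimplicialComplex:
    """Vietoris-Rips complex of a point cloud at one filtration radius.

    A simplex is included when all pairwise vertex distances are at most
    ``2*alpha`` (balls of radius alpha overlap); ``diameter_rule=True``
    switches to the ``<= alpha`` dialect.  ``max_dim`` caps the simplex
    dimension at 3 (tetrahedra), enough for persistent Laplacians of
    order q in {0, 1, 2}.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if not 1 <= max_dim <= MAX_DIM:
        raise ValueError(f"max_dim must be in 1..{MAX_DIM}")
    if isinstance(cloud, PointCloud):
        d = pairwise_distances(cloud)
    else:
        d = np.asarray(cloud, dtype=float)
    n = d.shape[0]
    reach = alpha if diameter_rule else 2.0 * alpha
    adj = (d <= reach) & ~np.eye(n, dtype=bool)
    simplices: dict[int, list[tuple[int, ...]]] = {0: [(i,) for i in range(n)]}
    g = nx.from_numpy_array(adj.astype(int))
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    if edges:
        simplices[1] = edges
    # higher simplices = cliques in the threshold graph
    for q in range(2, max_dim + 1):
        simps = [
            c
            for c in (
                tuple(sorted(c)) for c in combinations(range(n), q + 1)
            )
            if all(adj[i, j] for i, j in combinations(c, 2))
        ]
        if not simps:
            break
        simplices[q] = simps
    return SimplicialComplex(simplices)


def boundary_matrix(K: SimplicialComplex, q: int) -> np.ndarray:
    """Matrix of the boundary operator from q-chains to (q-1)-chains.

    Column per q-simplex, row per (q-1)-simplex, entries (-1)^i for the
    face omitting vertex i.  For q=0 (or q beyond the stored dimension)
    an empty matrix with the correct row count is returned.
    """
    if q < 1:
        return np.zeros((0, K.n_simplices(0)))
    rows = K.simplices.get(q - 1, [])
    cols = K.simplices.get(q, [])
    B = np.zeros((len(rows), len(cols)))
    index = {s: r for r, s in enumerate(rows)}
    for c, s in enumerate(cols):
        for i in range(len(s)):
            face = s[:i] + s[i + 1 :]
            B[index[face], c] = (-1.0) ** i
    return B


def _persistent_boundary(
    Kt: SimplicialComplex, Ktp: SimplicialComplex, q: int
) -> np.ndarray:
    """Matrix of the (q+1) persistent boundary on an orthonormal basis.

    Returns D with rows indexed by q-simplices of K_t such that the
    persistent up-Laplacian is D @ D.T.  The admissible-chain subspace
    (chains of K_{t+p} whose boundary stays in K_t) is the null space of
    the boundary rows that leave K_t.
    """
    B = boundary_matrix(Ktp, q + 1)
    rows_tp = Ktp.simplices.get(q, [])
    in_t = set(Kt.simplices.get(q, []))
    keep = np.array([s in in_t for s in rows_tp], dtype=bool)
    n_t = Kt.n_simplices(q)
    if B.shape[1] == 0:
        return np.zeros((n_t, 0))
    B_in, B_out = B[keep], B[~keep]
    if B_out.shape[0] == 0:
        Z = np.eye(B.shape[1])
    else:
        Z = null_space(B_out)
    if Z.shape[1] == 0:
        return np.zeros((n_t, 0))
    # reorder rows of B_in to K_t's canonical simplex order
    order = [s for s, k in zip(rows_tp, keep) if k]
    perm = [order.index(s) for s in Kt.simplices.get(q, [])]
    return (B_in @ Z)[perm]


def persistent_laplacian(
    Kt: SimplicialComplex,
    Ktp: SimplicialComplex | None = None,
    q: int = 0,
    *,
    tol: float | None = None,
) -> PersistentLaplacian:
    """q-order persistent Laplacian of the nested pair K_t ⊆ K_{t+p}.

    With ``Ktp=None`` (or ``Ktp is Kt``) this is the ordinary
    combinatorial q-Laplacian of K_t.
    """
    if Ktp is None:
        Ktp = Kt
    if q < 0 or q > 2:
        raise ValueError("q must be in {0, 1, 2}")
    if not Ktp.contains(Kt):
        raise ValueError("K_t is not contained in K_{t+p}")
    n_q = Kt.n_simplices(q)
    D = _persistent_boundary(Kt, Ktp, q)
    Bq = boundary_matrix(Kt, q)
    L = D @ D.T + Bq.T @ Bq
    if n_q == 0:
        return PersistentLaplacian(q, L, np.array([]), 0, None, 0.0)
    evals = eigh(L, eigvals_only=True)
    evals = np.clip(evals, 0.0, None)  # PSD up to round-off
    if tol is None:
        tol = 1e-8 * max(1.0, float(evals[-1]))
    betti, lam = betti_and_gap_from_spectrum(evals, tol)
    return PersistentLaplacian(q, L, evals, betti, lam, tol)


def betti_and_gap_from_spectrum(
    spectrum: np.ndarray, tol: float
) -> tuple[int, float | None]:
    betti = int(np.sum(spectrum <= tol))
    nonzero = spectrum[spectrum > tol]
    return betti, (float(nonzero.min()) if nonzero.size else None)


def betti_and_gap(
    pl: PersistentLaplacian, tol: float | None = None
) -> tuple[int, float | None]:
    """Betti number (kernel dimension) and smallest nonzero eigenvalue.

    ``tol`` defaults to the scale-aware zero tolerance stored on the
    persistent Laplacian at construction.
    """
    if tol is None:
        tol = pl.tol
    return betti_and_gap_from_spectrum(pl.spectrum, tol)


def persistent_betti_ranks(
    Kt: SimplicialComplex, Ktp: SimplicialComplex, q: int
) -> int:
    """Persistent Betti number via rank-nullity on boundary matrices.

    beta_q^{t,p} = dim ker d_q^t  -  dim( im d_{q+1}^{t+p} ∩ C_q(K_t) ),
    with the subspace intersection computed by the rank identity
    dim(U ∩ W) = rk U + rk W - rk [U W].  Independent of the
    persistent-Laplacian construction; used as a cross-check oracle.
    """
    if not Ktp.contains(Kt):
        raise ValueError("K_t is not contained in K_{t+p}")
    n_q_t = Kt.n_simplices(q)
    Bq_t = boundary_matrix(Kt, q)
    rank_Bq = np.linalg.matrix_rank(Bq_t) if min(Bq_t.shape) else 0
    dim_ker = n_q_t - rank_Bq
    B = boundary_matrix(Ktp, q + 1)
    if B.shape[1] == 0 or B.shape[0] == 0:
        return dim_ker
    rows_tp = Ktp.simplices.get(q, [])
    in_t = set(Kt.simplices.get(q, []))
    keep = np.array([s in in_t for s in rows_tp], dtype=bool)
    E = np.eye(len(rows_tp))[:, keep]  # basis of C_q(K_t) inside C_q(K_{t+p})
    rk_B = np.linalg.matrix_rank(B)
    rk_E = int(keep.sum())
    rk_joint = np.linalg.matrix_rank(np.hstack([B, E])) if rk_E else rk_B
    dim_inter = rk_B + rk_E - rk_joint
    return dim_ker - dim_inter
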