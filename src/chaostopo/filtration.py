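"""Laplacian filtration: a multiscale family of coupling matrices.

Instead of filtering a simplicial complex, the weighted (zero-row-sum)
interaction matrix itself is thresholded at ``p`` evenly spaced levels
between the smallest and largest off-diagonal weight.  At level k the
edges whose weight exceeds ``(k/p)*(l_max - l_min) + l_min`` are retained
with weight -1 (positive-semidefinite Laplacian convention: positive
diagonal), so the edge sets are nested and shrink as k grows; the last
level is always the empty graph.  Each level's matrix, negated, is the
coupling matrix of one coupled chaotic system.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "FiltrationFamily",
    "laplacian_filtration",
    "radius_filtration",
    "coupling_matrices",
]


@dataclass
class FiltrationFamily:
    """Ordered sequence of thresholded Laplacians L^1 .. L^p."""

    matrices: list[np.ndarray]
    thresholds: np.ndarray
    l_min: float
    l_max: float
    p: int
    weighted: bool = False
    mode: str = "weight"  # "weight" (threshold on l_ij) or "radius" (on d_ij)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def edge_sets(self) -> list[set[tuple[int, int]]]:
        """Retained (i<j) edge pairs at each level."""
        out = []
        for L in self.matrices:
            i, j = np.nonzero(np.triu(L, k=1))
            out.append(set(zip(i.tolist(), j.tolist())))
        return out

    def to_dir(self, path: str | Path) -> None:
        """Serialize to a directory of CSV matrices plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for k, L in enumerate(self.matrices, start=1):
            np.savetxt(path / f"L{k:03d}.csv", L, delimiter=",")
        manifest = {
            "p": self.p,
            "thresholds": np.asarray(self.thresholds).tolist(),
            "l_min": self.l_min,
            "l_max": self.l_max,
            "weighted": self.weighted,
            "mode": self.mode,
            "meta": self.meta,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "FiltrationFamily":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        mats = [
            np.loadtxt(path / f"L{k:03d}.csv", delimiter=",", ndmin=2)
            for k in range(1, manifest["p"] + 1)
        ]
        return cls(
            matrices=mats,
            thresholds=np.asarray(manifest["thresholds"], dtype=float),
            l_min=manifest["l_min"],
            l_max=manifest["l_max"],
            p=manifest["p"],
            weighted=manifest["weighted"],
            mode=manifest["mode"],
            meta=manifest.get("meta", {}),
        )


def _assemble(mask: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    """Laplacian with off-diagonal -1 (or -w_ij) on masked edges."""
    off = -mask.astype(float) if weights is None else -weights * mask
    np.fill_diagonal(off, 0.0)
    off = 0.5 * (off + off.T)
    np.fill_diagonal(off, -off.sum(axis=1))
    return off


def laplacian_filtration(
    L: np.ndarray, p: int = 10, *, weighted: bool = False
) -> FiltrationFamily:
    """Threshold a weighted zero-row-sum matrix at p accumulation levels.

    Parameters
    ----------
    L
        Symmetric matrix with zero row sums; off-diagonal entries are the
        edge weights (typically a :class:`ConnectivityMatrix` ``A``, whose
        off-diagonals are nonnegative kernel values).
    p
        Number of filtration levels.  Level k keeps edges with weight
        strictly above ``(k/p)*(l_max-l_min) + l_min``; level p is empty.
    weighted
        If True, retained edges keep their original weight (negated)
        instead of the binary -1.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1]:
        raise ValueError("L must be square")
    if p < 1:
        raise ValueError("p must be >= 1")
    n = L.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    w = np.where(off_mask, L, 0.0)
    offvals = w[off_mask]
    l_min = float(offvals.min()) if offvals.size else 0.0
    l_max = float(offvals.max()) if offvals.size else 0.0
    d = l_max - l_min
    thresholds = np.array([(k / p) * d + l_min for k in range(1, p + 1)])
    # the last threshold is l_max by definition; pin it so no edge survives
    # the final level through round-off in l_min + d
    thresholds[-1] = l_max
    if d == 0.0:
        warnings.warn(
            "all off-diagonal weights are equal: degenerate filtration, "
            "returning an all-zero family",
            RuntimeWarning,
        )
        mats = [np.zeros((n, n)) for _ in range(p)]
        return FiltrationFamily(mats, thresholds, l_min, l_max, p, weighted)
    mats = []
    for thr in thresholds:
        mask = off_mask & (w > thr)
        mats.append(_assemble(mask, w if weighted else None))
    return FiltrationFamily(mats, thresholds, l_min, l_max, p, weighted)


def radius_filtration(
    d: np.ndarray,
    radii,
    *,
    weights: np.ndarray | None = None,
    diameter_rule: bool = False,
) -> FiltrationFamily:
    """Threshold on pairwise *distance* instead of edge weight.

    At filtration radius alpha an edge (i, j) is retained when the balls
    of radius alpha around both nodes overlap, i.e. ``d_ij <= 2*alpha``
    (``d_ij <= alpha`` with ``diameter_rule=True``).  Larger radii retain
    more edges, so the family grows along the radius grid — the natural
    direction for a geometric filtration.
    """
    d = np.asarray(d, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = d.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    scale = 1.0 if diameter_rule else 2.0
    mats = []
    for alpha in radii:
        mask = off_mask & (d <= scale * alpha)
        mats.append(_assemble(mask, weights))
    offvals = d[off_mask]
    return FiltrationFamily(
        matrices=mats,
        thresholds=radii,
        l_min=float(offvals.min()) if offvals.size else 0.0,
        l_max=float(offvals.max()) if offvals.size else 0.0,
        p=len(mats),
        weighted=weights is not None,
        mode="radius",
        meta={"diameter_rule": diameter_rule},
    )


def coupling_matrices(fam: FiltrationFamily, *, attractive: bool = True):
    """Coupling matrices G^k = -L^k consumed by the dynamics module.

    The filtration stores positive-semidefinite Laplacians (positive
    diagonal); diffusive coupling with positive strength synchronizes when
    the coupling matrix is the *negative* Laplacian, so the default negates.
    """
    sign = -1.0 if attractive else 1.0
    return [sign * L for L in fam.matrices]
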