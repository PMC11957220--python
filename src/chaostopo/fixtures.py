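"""Synthetic inputs exercising the full pipeline without any downloads.

Generators cover the geometry classes and data shapes the pipeline is
designed for: regular polygons (homogeneous oscillator rings), folded /
partially folded / unfolded 120-node chains (synchronization-regime
fixtures), labeled Gaussian point clouds (sample-classification tasks),
class-structured signal sets (correlation-coupling tasks), and a
synthetic protein-like chain with a planted flexibility profile
(parameter-recovery surrogate for B-factor prediction).  Every generator
is pure in (parameters, seed): identical calls give bitwise-identical
output.
"""

from __future__ import annotations

import numpy as np

from .connectivity import PointCloud, SignalSet, pairwise_distances

__all__ = [
    "regular_polygon",
    "chain_cloud",
    "labeled_blobs",
    "class_signals",
    "synthetic_protein",
]


def regular_polygon(n_nodes: int = 16, circumradius: float = 1.0) -> PointCloud:
    """Vertices of a regular n-gon in the z=0 plane.

    The 16-node hexadecagon (the default) is the canonical homogeneous
    toy geometry for the synchronization-transition demonstrations.
    """
    if n_nodes < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    theta = 2.0 * np.pi * np.arange(n_nodes) / n_nodes
    coords = np.column_stack(
        [circumradius * np.cos(theta), circumradius * np.sin(theta),
         np.zeros(n_nodes)]
    )
    return PointCloud(coords=coords)


def _compact_coil(n: int, rng: np.random.Generator, spacing: float) -> np.ndarray:
    """Self-avoiding-ish random walk confined to a compact ball.

    Step length = ``spacing``; the confinement radius scales as n^(1/3)
    so the mean density (contacts per node) is size-independent.
    """
    radius = max(1.5, 0.55 * n ** (1.0 / 3.0)) * spacing
    pts = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(64):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = pts[i - 1] + spacing * u
            if np.linalg.norm(cand) <= radius and (
                i < 2 or np.min(np.linalg.norm(pts[: i - 1] - cand, axis=1))
                > 0.5 * spacing
            ):
                break
        else:  # fall back: pull toward the center
            direction = -pts[i - 1]
            nrm = np.linalg.norm(direction)
            u = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
            cand = pts[i - 1] + spacing * u
        pts[i] = cand
    return pts


def chain_cloud(
    n_nodes: int = 120,
    fold_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    *,
    spacing: float = 1.0,
) -> PointCloud:
    """Chain with a compactly coiled (folded) part and an extended tail.

    The first ``round(fold_fraction * n_nodes)`` nodes form a compact
    coil with dense pairwise contacts; the remainder extends away as a
    nearly straight segment with only chain-neighbor contacts.  The
    default 120 nodes at fold_fraction 2/3 gives the 80-folded /
    40-unfolded partially folded conformation; fractions 1 and 0 give
    the fully folded and fully unfolded ones.
    """
    if not 0.0 <= fold_fraction <= 1.0:
        raise ValueError("fold_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_fold = int(round(fold_fraction * n_nodes))
    n_free = n_nodes - n_fold
    parts = []
    if n_fold:
        parts.append(_compact_coil(n_fold, rng, spacing))
    if n_free:
        # extend radially away from the coil center with small jitter
        if n_fold:
            start = parts[0][-1]
            nrm = np.linalg.norm(start)
            direction = start / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        else:
            start = np.zeros(3)
            direction = np.array([1.0, 0.0, 0.0])
        steps = np.arange(1, n_free + 1)[:, None] * spacing * direction
        jitter = 0.05 * spacing * rng.normal(size=(n_free, 3))
        parts.append(start + steps + jitter)
    coords = np.vstack(parts)
    return PointCloud(coords=coords)


def labeled_blobs(
    n_samples: int = 300,
    n_classes: int = 3,
    separation: float = 10.0,
    dim: int = 3,
    seed: int = 0,
) -> tuple[PointCloud, np.ndarray]:
    """Isotropic unit-variance Gaussian clusters with controlled separation.

    Centroids sit on a regular simplex, so *every* pair of class centers
    is exactly ``separation`` apart (in cluster-standard-deviation
    units), then the whole constellation gets a seeded random rotation.
    Class sizes honor equal proportions exactly (remainders go to the
    first classes).  ``separation=0`` collapses all centroids to the
    origin, making classes statistically indistinguishable.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if dim < n_classes - 1:
        raise ValueError("dim must be at least n_classes - 1 for a simplex")
    rng = np.random.default_rng(seed)
    sizes = [n_samples // n_classes] * n_classes
    for i in range(n_samples - sum(sizes)):
        sizes[i] += 1
    # regular simplex: centered basis vectors have pairwise distance
    # sqrt(2); express in its (n_classes-1)-dim span and scale
    simplex = np.eye(n_classes) - 1.0 / n_classes
    U, svals, _ = np.linalg.svd(simplex)
    coords = U[:, : n_classes - 1] * svals[: n_classes - 1]
    centers = np.zeros((n_classes, dim))
    centers[:, : n_classes - 1] = (separation / np.sqrt(2.0)) * coords
    Q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
    centers = centers @ Q.T
    coords, labels = [], []
    for k, (size, c) in enumerate(zip(sizes, centers)):
        coords.append(c + rng.normal(size=(size, dim)))
        labels.extend([k] * size)
    return (
        PointCloud(coords=np.vstack(coords)),
        np.asarray(labels, dtype=int),
    )


def class_signals(
    n_channels_per_class: int = 100,
    n_classes: int = 3,
    length: int = 512,
    seed: int = 0,
    *,
    snr: float = 2.0,
) -> SignalSet:
    """Signal channels whose classes share a common latent waveform.

    Each class k has a latent narrow-band waveform (class-specific
    carrier frequency plus band-limited noise); every channel is the
    latent plus independent noise at the requested signal-to-noise
    ratio, so within-class Pearson correlations are strong and
    between-class ones are near zero — the block structure a
    correlation-coupling pipeline feeds on.
    """
    if length < 64:
        raise ValueError("length must be at least 64")
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    signals, labels = [], []
    for k in range(n_classes):
        freq = 0.02 * (k + 1) + 0.005
        carrier = np.sin(2.0 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        drift = np.cumsum(rng.normal(size=length))
        drift = (drift - drift.mean()) / max(drift.std(), 1e-12)
        latent = carrier + 0.5 * drift
        latent = (latent - latent.mean()) / latent.std()
        for _ in range(n_channels_per_class):
            noise = rng.normal(size=length)
            ch = snr * latent + noise
            signals.append(ch)
            labels.append(k)
    return SignalSet(
        signals=np.asarray(signals), labels=np.asarray(labels, dtype=int)
    )


def synthetic_protein(
    n_residues: int = 100, seed: int = 0
) -> tuple[PointCloud, np.ndarray]:
    """Synthetic protein-like chain with a planted flexibility profile.

    A compact self-avoiding coil with 3.8 Å virtual bonds stands in for
    a C-alpha trace.  The planted per-residue "B-factor" is a smooth
    (chain-window-averaged) decreasing function of local contact
    density, mimicking the empirical anticorrelation between packing
    and thermal motion: loosely packed termini and surface segments get
    high values, the buried core low ones.  Any sound flexibility
    method should recover this profile.
    """
    if n_residues < 20:
        raise ValueError("need at least 20 residues")
    rng = np.random.default_rng(seed)
    spacing = 3.8
    n_tail = 3  # dangling residues at each terminus
    core = _compact_coil(n_residues - 2 * n_tail, rng, spacing)
    # termini dangle radially outward from the coil surface, as chain ends
    # of globular proteins typically do
    def _tail(anchor: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(anchor)
        u = anchor / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        pts = anchor + np.outer(np.arange(1, n_tail + 1) * spacing, u)
        return pts + 0.1 * spacing * rng.normal(size=pts.shape)

    head = _tail(core[0])[::-1]
    tail = _tail(core[-1])
    coords = np.vstack([head, core, tail])
    cloud = PointCloud(coords=coords)
    d = pairwise_distances(cloud)
    # local packing: exponential contact density at the 3 A characteristic
    # distance used by the downstream kernel-free of self-contacts
    density = np.exp(-d / 3.0).sum(axis=1) - 1.0
    flexibility = 1.0 / density
    # light chain smoothing (3-residue window): neighbors share mobility,
    # but the profile stays dominated by local packing
    kernel = np.array([0.2, 0.6, 0.2])
    padded = np.pad(flexibility, 1, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    # scale to a realistic crystallographic range
    lo, hi = smooth.min(), smooth.max()
    true_b = 5.0 + 45.0 * (smooth - lo) / (hi - lo) if hi > lo else np.full_like(smooth, 20.0)
    return cloud, true_b
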