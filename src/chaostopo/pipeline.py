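"""End-to-end pipelines: data -> connectivity -> filtration -> chaos ->
features -> prediction, driven by a single RunConfig."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .connectivity import (
    PointCloud,
    SignalSet,
    connectivity_matrix,
    correlation_coupling,
    pairwise_distances,
)
from .features import FeatureMatrix, multiscale_features
from .filtration import FiltrationFamily, laplacian_filtration
from .learn import EvaluationReport, bfactor_regression, crossval_classify

__all__ = [
    "filtration_from_cloud",
    "filtration_from_signals",
    "chaos_features",
    "classify_cloud",
    "classify_signals",
    "predict_bfactors",
]


def filtration_from_cloud(
    cloud: PointCloud, config: RunConfig
) -> FiltrationFamily:
    """Distance kernel + Laplacian filtration for a point cloud."""
    d = pairwise_distances(cloud)
    conn = connectivity_matrix(
        d,
        config.kernel,
        sigma=config.sigma,
        kappa=config.kappa,
        nu=config.nu,
        cutoff=config.cutoff,
    )
    return laplacian_filtration(conn.A, config.p, weighted=config.weighted)


def filtration_from_signals(
    s: SignalSet, config: RunConfig
) -> FiltrationFamily:
    """Pearson-correlation coupling + Laplacian filtration for signals."""
    conn = correlation_coupling(s, absolute=config.absolute_pcc)
    return laplacian_filtration(conn.A, config.p, weighted=config.weighted)


def chaos_features(fam: FiltrationFamily, config: RunConfig) -> FeatureMatrix:
    """Multiscale chaotic-trajectory statistics for a filtration family."""
    return multiscale_features(
        fam,
        spec=config.oscillator_spec(),
        mode=config.mode,
        epsilon=config.epsilon,
        h=config.h,
        n_steps=config.n_steps,
        transient=config.transient,
        scheme=config.scheme,
        stats=tuple(config.stats),
        seed=config.seed,
        attractive=config.attractive,
    )


def classify_cloud(
    cloud: PointCloud, labels: np.ndarray, config: RunConfig
) -> tuple[FeatureMatrix, EvaluationReport]:
    """Sample classification from a labeled point cloud.

    Features are computed transductively on the full coupled system
    before cross-validation splits (the coupling ties samples together,
    so per-fold recomputation would change every sample's features).
    """
    fam = filtration_from_cloud(cloud, config)
    X = chaos_features(fam, config)
    report = crossval_classify(
        X, labels, model=config.ml_model, folds=config.folds,
        seeds=tuple(config.seeds),
    )
    return X, report


def classify_signals(
    s: SignalSet, config: RunConfig
) -> tuple[FeatureMatrix, EvaluationReport]:
    """Channel classification from a labeled signal set."""
    if s.labels is None:
        raise ValueError("signal set has no labels")
    fam = filtration_from_signals(s, config)
    X = chaos_features(fam, config)
    report = crossval_classify(
        X, s.labels, model=config.ml_model, folds=config.folds,
        seeds=tuple(config.seeds),
    )
    return X, report


def predict_bfactors(
    cloud: PointCloud, bfactors: np.ndarray, config: RunConfig
) -> tuple[FeatureMatrix, np.ndarray, float]:
    """Per-residue flexibility regression on a C-alpha trace.

    Exponential-kernel connectivity, Laplacian filtration, perturbative
    chaotic features per residue, then in-sample ordinary least squares
    against the experimental B-factors; returns (features, fitted, PCC).
    """
    fam = filtration_from_cloud(cloud, config)
    X = chaos_features(fam, config)
    fitted, pcc = bfactor_regression(X, bfactors)
    return X, fitted, pcc
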