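"""Normalization and sample-level quality control.

Counts are depth-corrected with the median-of-ratios method: per sample j,

    s_j = median_g ( K_gj / (prod_j' K_gj')^(1/m) )

over reference genes g with all-positive counts. A log2-like variance
stabilization ``log2(K_gj / s_j + 1)`` then feeds PCA (samples as
observations, genes as variables, centered and unit-scaled) and pairwise
Pearson correlation with average-linkage clustering on 1 - r.

The transform is a stand-in labeled ``log2-norm-pseudocount`` in its
provenance tag: it preserves the log2-like scale used downstream without
reimplementing a fitted dispersion-mean trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .cluster3p import CountMatrix

logger = logging.getLogger(__name__)

TRANSFORM_NAME = "log2-norm-pseudocount"


@dataclass
class SizeFactors:
    """Per-sample positive scale factors."""

    factors: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass
class TransformedMatrix:
    """Log2-like genes x samples matrix with a provenance tag."""

    values: pd.DataFrame
    transform: str = TRANSFORM_NAME
    params: dict | None = None


@dataclass
class PCAResult:
    """Per-sample component scores and explained-variance fractions."""

    scores: pd.DataFrame          # samples x k
    explained_fraction: np.ndarray
    n_dropped_zero_variance: int = 0


def filter_low_expression(
    matrix: CountMatrix, min_count: int = 5, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with >= min_count counts in >= min_samples samples."""
    n = matrix.counts.shape[1]
    if min_samples > n:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {n}"
        )
    keep = (matrix.counts >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(counts=matrix.counts.loc[keep].copy(),
                       samples=matrix.samples)


def estimate_size_factors(matrix: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors over all-positive reference genes."""
    counts = matrix.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has positive counts in every sample; relax the "
            "low-expression filter or check the input matrix"
        )
    logc = np.log(counts[ref])
    log_geomean = logc.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logc - log_geomean, axis=0))
    return SizeFactors(pd.Series(s, index=matrix.counts.columns,
                                 name="size_factor"))


def vst_transform(matrix: CountMatrix, factors: SizeFactors) -> TransformedMatrix:
    """Variance-mitigating log2 transform of depth-normalized counts.

    t_gj = log2(count_gj / s_j + 1); monotone in counts for fixed s_j.
    """
    norm = matrix.counts.div(factors.factors, axis=1)
    return TransformedMatrix(
        values=np.log2(norm + 1.0),
        transform=TRANSFORM_NAME,
        params={"pseudocount": 1.0},
    )


def run_pca(
    matrix: TransformedMatrix,
    center: bool = True,
    scale: bool = True,
    k: int | None = None,
) -> PCAResult:
    """PCA with samples as observations and genes as variables.

    Zero-variance genes are dropped before scaling (their count is logged
    and recorded); explained-variance fractions come from squared singular
    values of the centered/scaled matrix.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    if k is None:
        k = n_samples - 1
    if k > n_samples - 1:
        raise ValueError(f"k={k} exceeds n_samples-1={n_samples - 1}")

    var = X.var(axis=0)
    nz = var > 0
    n_dropped = int((~nz).sum())
    if n_dropped:
        logger.info("dropping %d zero-variance genes before PCA", n_dropped)
    X = X[:, nz]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0)

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
        explained_fraction=pca.explained_variance_ratio_,
        n_dropped_zero_variance=n_dropped,
    )


def sample_correlation(
    matrix: TransformedMatrix,
) -> Tuple[pd.DataFrame, List[str]]:
    """All-pairs Pearson correlation of samples with clustering leaf order.

    Returns (correlation matrix, leaf-ordered sample list); the order comes
    from average-linkage hierarchical clustering on the 1 - r distance.
    A zero-variance sample makes r undefined and is a fatal error.
    """
    X = matrix.values.to_numpy(dtype=float)
    sample_ids = list(matrix.values.columns)
    if len(sample_ids) < 2:
        raise ValueError("correlation requires at least 2 samples")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [s for s, z in zip(sample_ids, sd == 0) if z]
        raise ValueError(f"zero-variance sample(s): {bad}")
    r = np.corrcoef(X.T)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(r, index=sample_ids, columns=sample_ids)

    dist = 1.0 - r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    order = leaves_list(average(squareform(dist, checks=False)))
    return corr, [sample_ids[i] for i in order]
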