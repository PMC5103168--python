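"""Upper-quartile count normalization, log2(x + offset) transform, PCA QC.

Library-size correction divides each sample by the 75th percentile of its
nonzero count distribution and rescales to a fixed reference, so that
multiplying any sample's counts by any positive constant leaves the
normalized matrix exactly unchanged.  The subsequent log2(x + 32) transform
damps the variance of low-count genes towards a constant.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io_model import CountMatrix, RunConfig

#: fixed reference scale: a sample's upper-quartile nonzero count maps to this
#: value after normalization.  A constant (rather than a data-driven mean of
#: quantiles) keeps normalization exactly invariant to per-sample scaling.
UQ_REFERENCE = 256.0


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def sample_quantiles(counts: CountMatrix | pd.DataFrame, quantile: float = 0.75) -> pd.Series:
    """Per-sample quantile of the nonzero count distribution.

    Uses linear interpolation between order statistics.  A sample with no
    nonzero count is an error (its library size is undefined).
    """
    df = _as_frame(counts)
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    values = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if (v < 0).any():
            raise ValueError(f"sample {col!r} has negative values")
        nz = v[v > 0]
        if nz.size == 0:
            raise ValueError(f"sample {col!r} has all-zero counts; cannot normalize")
        values[col] = float(np.quantile(nz, quantile, method="linear"))
    return pd.Series(values, name=f"q{quantile:g}")


def upper_quartile_factors(
    counts: CountMatrix | pd.DataFrame, quantile: float = 0.75
) -> pd.Series:
    """Per-sample scale factors, centred so their geometric mean is 1.

    factor_j = Q(quantile, nonzero counts of sample j) / G with G the
    geometric mean of the per-sample quantiles; dimensionless, > 0.
    """
    q = sample_quantiles(counts, quantile)
    gmean = float(np.exp(np.mean(np.log(q.to_numpy()))))
    factors = q / gmean
    factors.name = "uq_factor"
    return factors


def normalize(
    counts: CountMatrix | pd.DataFrame,
    quantile: float = 0.75,
    reference: float = UQ_REFERENCE,
) -> pd.DataFrame:
    """Rescale each sample onto the fixed upper-quartile reference scale.

    value(g, j) = count(g, j) * reference / Q(quantile, nonzero counts of j).
    Zeros stay zero, and scaling any sample by a positive constant cancels
    exactly.  ``reference`` only sets the common output scale (it interacts
    with the additive offset of :func:`log_transform`).
    """
    df = _as_frame(counts)
    q = sample_quantiles(df, quantile)
    if reference <= 0:
        raise ValueError("reference must be positive")
    return df.astype(float) * (reference / q)


def log_transform(values: pd.DataFrame, offset: float = 32.0) -> pd.DataFrame:
    """Elementwise log2(value + offset); values must be >= 0 and offset > 0.

    Output is bounded below by log2(offset) and strictly monotone in the
    input, so rank-based statistics downstream see the same gene ordering.
    """
    if offset <= 0:
        raise ValueError(f"offset must be positive, got {offset}")
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative value at gene {values.index[i]!r}, sample "
            f"{values.columns[j]!r}; normalized counts must be >= 0"
        )
    return pd.DataFrame(
        np.log2(arr + offset), index=values.index, columns=values.columns
    )


def expression_matrix(cm: CountMatrix, config: RunConfig | None = None) -> pd.DataFrame:
    """Full normalization chain: upper-quartile rescale then log2(x + offset)."""
    config = config or RunConfig()
    return log_transform(normalize(cm, config.quantile), config.log_offset)


def pca_qc(
    em: pd.DataFrame, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA of a (genes x samples) expression matrix, for QC only.

    Genes are centred (not scaled).  Returns per-sample coordinates on
    PC1..PCk and the variance-explained fractions (non-increasing, sum <= 1).
    """
    n_samples = em.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 1 <= n_components < n_samples:
        raise ValueError(
            f"n_components must be in [1, n_samples); got {n_components} "
            f"with {n_samples} samples"
        )
    X = em.to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("expression matrix is constant per gene; PCA is degenerate")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    frame = pd.DataFrame(
        coords,
        index=em.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    frame.index.name = "sample_id"
    return frame, pca.explained_variance_ratio_.copy()
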