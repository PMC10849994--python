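"""Per-sample normalization and optional log transform.

Normalization is *across features within each sample column*: after
:func:`normalize_samples`, every sample ``j`` satisfies

    sum_i x_ij  = 0
    sum_i x_ij2 = N

where ``N`` is the number of features.  (The sums run over features,
not samples — the transposed reading is a common mistake.)  The
dispersion uses the N-denominator (population) form so that the
second constraint holds exactly.
"""

from __future__ import annotations

import numpy as np

from .exceptions import NormalizationError
from .io_expression import ExpressionMatrix


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Replace values by ``log2(value + pseudocount)``.

    Requires all values to be non-negative and the pseudocount to be
    positive.  Monotone within each sample, so within-sample rank order
    is preserved.
    """
    if pseudocount <= 0:
        raise NormalizationError(f"pseudocount must be positive, got {pseudocount}")
    if np.any(matrix.values < 0):
        raise NormalizationError("log transform requires non-negative values")
    return ExpressionMatrix(
        feature_ids=list(matrix.feature_ids),
        sample_ids=list(matrix.sample_ids),
        values=np.log2(matrix.values + pseudocount),
    )


def normalize_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each sample column to the zero-sum / N-sum-of-squares constraints.

    ``x'_ij = (x_ij - mean_i x_ij) / s_j`` with
    ``s_j = sqrt(sum_i (x_ij - mean)^2 / N)``.
    """
    x = matrix.values
    n = matrix.n_features
    if n < 2:
        raise NormalizationError("need at least 2 features to normalize")
    mean = x.mean(axis=0, keepdims=True)
    centered = x - mean
    scale = np.sqrt((centered**2).mean(axis=0, keepdims=True))
    zero = np.flatnonzero(scale.ravel() == 0)
    if zero.size:
        bad = [matrix.sample_ids[j] for j in zero]
        raise NormalizationError(f"constant sample column(s): {bad}")
    return ExpressionMatrix(
        feature_ids=list(matrix.feature_ids),
        sample_ids=list(matrix.sample_ids),
        values=centered / scale,
    )


def check_normalized(values: np.ndarray, rtol: float = 1e-6) -> bool:
    """True if every column satisfies both normalization constraints."""
    n = values.shape[0]
    sums = values.sum(axis=0)
    sq = (values**2).sum(axis=0)
    return bool(
        np.all(np.abs(sums) <= rtol * n) and np.all(np.abs(sq - n) <= rtol * n)
    )
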