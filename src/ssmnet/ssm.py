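"""Scaled Subprofile Model core: log transform, double-centering, PCA.

The SSM treats a participants x regions matrix of strictly positive metric
values as log(value) = grand mean + subject offset + region profile +
residual covariance structure. Natural log transformation followed by
removal of row (subject) means and column (region) means isolates the
residual "subject residual profile" matrix, whose principal components are
regional covariance patterns (loadings over tracts) with per-participant
expression scores. The log + double-centering step is what makes the model
invariant to a global multiplicative scaling factor per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .data import MetricMatrix


@dataclass
class CenteringOffsets:
    """Centering terms from :func:`log_double_center`, kept so the pattern
    can be applied to new participants on the same scale."""

    column_means: np.ndarray      # per-tract mean of the log matrix
    row_means_removed: np.ndarray  # per-participant mean offset (log scale)
    grand_mean: float

    def apply_to_new(self, values: np.ndarray) -> np.ndarray:
        """Center new rows (participants) with their own row means and the
        stored column profile."""
        values = np.asarray(values, dtype=float)
        if np.any(values <= 0):
            raise ValueError("non-positive value: log transform undefined")
        L = np.log(values)
        row_means = L.mean(axis=1, keepdims=True)
        return L - row_means - self.column_means + self.grand_mean


def log_double_center(matrix: MetricMatrix | np.ndarray) -> tuple[np.ndarray, CenteringOffsets]:
    """Natural log, then full double-centering.

    C = ln(X) - row means - column means + grand mean. Every row mean and
    column mean of C is zero to machine precision; additive row/column
    structure on the log scale (in particular a per-subject global scaling
    of the raw values) maps exactly to zero.
    """
    values = matrix.values if isinstance(matrix, MetricMatrix) else np.asarray(matrix, dtype=float)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        bad = np.argwhere(~(np.isfinite(values) & (values > 0)))[0]
        if isinstance(matrix, MetricMatrix):
            raise ValueError(
                f"non-positive or non-finite value at participant "
                f"{matrix.participant_ids[bad[0]]}, tract {matrix.tract_labels[bad[1]]}")
        raise ValueError(f"non-positive or non-finite value at cell {tuple(bad)}")
    L = np.log(values)
    row_means = L.mean(axis=1)
    col_means = L.mean(axis=0)
    grand = L.mean()
    C = L - row_means[:, None] - col_means[None, :] + grand
    offsets = CenteringOffsets(column_means=col_means,
                               row_means_removed=row_means,
                               grand_mean=float(grand))
    return C, offsets


@dataclass
class SSMDecomposition:
    """PCA of the double-centered log matrix.

    loadings
        (tracts, components), orthonormal columns; the regional covariance
        patterns.
    scores
        (participants, components); scores = C @ loadings, so the variance of
        score column c equals eigenvalue c.
    eigenvalues
        per-component variance of scores (singular value^2 / (n-1)),
        non-increasing.
    """

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    offsets: CenteringOffsets | None = None
    tract_labels: list[str] | None = None
    participant_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        idx = self.tract_labels if self.tract_labels is not None else None
        return pd.DataFrame(self.loadings, index=idx, columns=cols)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        idx = self.participant_ids if self.participant_ids is not None else None
        return pd.DataFrame(self.scores, index=idx, columns=cols)


def _orient_components(loadings: np.ndarray, scores: np.ndarray) -> None:
    # deterministic sign: largest-|loading| entry of each component positive
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0


def decompose(centered: np.ndarray,
              offsets: CenteringOffsets | None = None,
              tract_labels: list[str] | None = None,
              participant_ids: list[str] | None = None,
              rtol: float | None = None) -> SSMDecomposition:
    """SVD-based PCA of a double-centered matrix.

    Components with singular values below ``rtol * s_max`` (default
    ``max(n, p) * eps``) are treated as numerically zero and dropped; a
    double-centered n x p matrix has rank at most min(n-1, p-1). An all-zero
    matrix yields an empty (zero-component) decomposition.
    """
    C = np.asarray(centered, dtype=float)
    n, p = C.shape
    U, s, Vt = linalg.svd(C, full_matrices=False)
    if rtol is None:
        rtol = max(n, p) * np.finfo(float).eps
    smax = s[0] if s.size else 0.0
    k = int(np.sum(s > rtol * smax)) if smax > 0 else 0
    k = min(k, n - 1, p - 1) if k > 0 else 0
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    eigenvalues = (s[:k] ** 2) / (n - 1) if n > 1 else s[:k] ** 2
    _orient_components(loadings, scores)
    return SSMDecomposition(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        offsets=offsets,
        tract_labels=tract_labels,
        participant_ids=participant_ids,
    )


def decompose_metric(matrix: MetricMatrix) -> SSMDecomposition:
    """Convenience: log + double-center + PCA of one metric matrix."""
    C, offsets = log_double_center(matrix)
    return decompose(C, offsets=offsets,
                     tract_labels=list(matrix.tract_labels),
                     participant_ids=list(matrix.participant_ids))
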