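"""PCA-based circular pre-sorting and cosinor data augmentation.

For data dominated by sinusoidal genes, the first two principal components
of the sample cloud form an orthogonal cosine/sine basis, so samples fall on
an (approximate) circle in the PC1-PC2 plane.  The pre-sort angle

    theta_i = atan2(PC2_i, PC1_i)  in [0, 2*pi)

orders samples around that circle (up to a global rotation and a possible
reflection, both unresolvable without external time labels).  Augmentation
then replaces each gene row by its fitted period-24 cosinor curve over a
pseudo-time axis, denoising the matrix handed to the deep model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .cosinor import _design
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["PreSortedMatrix", "AugmentedMatrix", "pca_presort", "augment"]


class DegenerateEmbeddingError(ValueError):
    """Raised when the sample cloud has rank < 2 and no circle exists."""


@dataclass
class PreSortedMatrix:
    """Samples reordered by their PCA circle angle."""

    data: pd.DataFrame  # genes x samples, columns in pre-sort order
    sort_order: np.ndarray  # permutation: position k holds original index
    presort_angles: np.ndarray  # theta in [0, 2*pi), in sorted order
    pc_scores: np.ndarray  # (N, 2) PC1/PC2 coordinates, in sorted order
    true_times: np.ndarray | None = None  # reordered alongside, if known

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def pseudo_times_h(self) -> np.ndarray:
        """Pre-sort angles converted to hours in [0, 24)."""
        return self.presort_angles * 24.0 / (2.0 * np.pi)


@dataclass
class AugmentedMatrix:
    """Per-gene fitted cosinor curves over the pseudo-time axis."""

    data: pd.DataFrame  # genes x samples (same order as the pre-sort)
    pseudo_times: np.ndarray  # hours, abscissa used for the fits
    residual_sd: np.ndarray  # per gene
    cosinor_params: np.ndarray  # (genes, 3): mesor, beta_cos, beta_sin
    period_h: float = 24.0


def pca_presort(matrix: ExpressionMatrix) -> PreSortedMatrix:
    """Embed samples on the PCA circle and reorder them by angle."""
    if matrix.n_samples < 4:
        raise ValueError("pre-sorting needs at least 4 samples")
    X = matrix.values.T  # samples as observations, genes as features
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(X)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < 2 or np.any(
        pca.explained_variance_ <= 1e-12
    ):
        raise DegenerateEmbeddingError(
            "sample cloud has rank < 2; no circular embedding exists"
        )
    theta = np.mod(np.arctan2(scores[:, 1], scores[:, 0]), 2.0 * np.pi)
    theta[theta >= 2.0 * np.pi] = 0.0  # guard the -eps mod 2*pi edge case
    order = np.argsort(theta, kind="stable")
    true_times = (
        matrix.true_times[order] if matrix.true_times is not None else None
    )
    return PreSortedMatrix(
        data=matrix.data.iloc[:, order],
        sort_order=order,
        presort_angles=theta[order],
        pc_scores=scores[order],
        true_times=true_times,
    )


def augment(
    presorted: PreSortedMatrix,
    period_h: float = 24.0,
    abscissa: str = "uniform",
) -> AugmentedMatrix:
    """Replace each gene row by its fitted cosinor curve.

    ``abscissa`` chooses the pseudo-time axis for the per-gene fits:
    ``"uniform"`` uses N equally spaced points on [0, 24) in pre-sort order,
    ``"angle"`` uses the pre-sort angles themselves converted to hours
    (which preserves non-uniform spacing and partial-cycle arcs).
    """
    n = presorted.n_samples
    if n < 4:
        raise ValueError("augmentation needs at least 4 samples")
    if abscissa == "uniform":
        t = np.arange(n) * (period_h / n)
    elif abscissa == "angle":
        t = presorted.presort_angles * period_h / (2.0 * np.pi)
    else:
        raise ValueError(f"unknown abscissa {abscissa!r}")

    Z = presorted.data.to_numpy(dtype=float)
    X = _design(t, period_h)
    beta, _, rank, _ = np.linalg.lstsq(X, Z.T, rcond=None)
    if rank < 3:
        raise DegenerateEmbeddingError(
            "pseudo-time design is rank-deficient; cannot fit cosinor curves"
        )
    Y = (X @ beta).T
    resid = Z - Y
    residual_sd = resid.std(axis=1, ddof=1) if n > 1 else np.zeros(len(Z))
    out = pd.DataFrame(Y, index=presorted.data.index, columns=presorted.data.columns)
    return AugmentedMatrix(
        data=out,
        pseudo_times=t,
        residual_sd=residual_sd,
        cosinor_params=beta.T,
        period_h=period_h,
    )
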