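"""Bray-Curtis dissimilarity between chemical fingerprints.

d_ij = sum_m |x_im - x_jm| / sum_m (x_im + x_jm), in [0, 1] for nonnegative
data: 0 for identical profiles, 1 for profiles with disjoint compound sets.
Computed here on log(x+1)-transformed relative abundances by default.
Bray-Curtis is not Euclidean-embeddable in general, which matters downstream
(negative PCoA eigenvalues); :func:`is_euclidean_embeddable` diagnoses this.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import AbundanceMatrix, FingerprintError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "sample_ids", list(self.sample_ids))
        n = len(self.sample_ids)
        if D.shape != (n, n):
            raise FingerprintError(f"distance matrix shape {D.shape} != ({n}, {n})")
        if not np.allclose(D, D.T, atol=1e-12):
            raise FingerprintError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise FingerprintError("distance matrix diagonal is not zero")
        if np.any(D < 0):
            raise FingerprintError("negative dissimilarity")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, indices: np.ndarray) -> "DistanceMatrix":
        indices = np.asarray(indices)
        return DistanceMatrix([self.sample_ids[i] for i in indices],
                              self.D[np.ix_(indices, indices)])

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


def bray_curtis(matrix: AbundanceMatrix, require_log: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    By default insists on ``unit_state == "log_relative"`` (the study's
    analysis scale); pass ``require_log=False`` to run on any nonnegative
    matrix.
    """
    if require_log and matrix.unit_state != "log_relative":
        raise FingerprintError(
            f"bray_curtis expects log_relative abundances, got {matrix.unit_state!r} "
            "(pass require_log=False to override)"
        )
    X = matrix.values
    zero_rows = np.nonzero(X.sum(axis=1) == 0)[0]
    if zero_rows.size >= 2:
        a, b = zero_rows[:2]
        raise FingerprintError(
            "Bray-Curtis undefined for all-zero sample pair "
            f"({matrix.sample_ids[a]!r}, {matrix.sample_ids[b]!r})"
        )
    D = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(matrix.sample_ids, D)


def gower_center(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower double-centering G = J (-1/2 D^2) J with J = I - 11'/n.

    Converts squared dissimilarities into an inner-product-like matrix whose
    trace is the total sum of squares of the distance decomposition.
    """
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    A = -0.5 * Dm ** 2
    row_mean = A.mean(axis=1, keepdims=True)
    col_mean = A.mean(axis=0, keepdims=True)
    return A - row_mean - col_mean + A.mean()


def is_euclidean_embeddable(D: DistanceMatrix, tol: float = 1e-10) -> tuple[bool, float]:
    """Whether the Gower-centered matrix of D is PSD, plus its minimum eigenvalue."""
    G = gower_center(D)
    eigvals = np.linalg.eigvalsh((G + G.T) / 2)
    lam_min = float(eigvals[0])
    scale = max(float(eigvals[-1]), 1.0)
    return lam_min >= -tol * scale, lam_min
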