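"""Ordination: principal coordinates analysis and non-metric MDS.

PCoA eigendecomposes the Gower-centered matrix of a distance matrix.  For
non-Euclidean dissimilarities such as Bray-Curtis some eigenvalues are
negative; the corresponding "imaginary" axes are kept (with |lambda|) because
the dispersion-homogeneity test needs them to correct squared distances.

NMDS finds a k-dimensional configuration whose inter-point distances best
preserve the *rank order* of the input dissimilarities, by minimizing
Kruskal stress-1

    stress = sqrt( sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2 )

where d are the configuration distances and dhat their monotone (isotonic)
regression on the ranks of the input.  Optimization alternates isotonic fits
with Guttman-transform configuration updates, restarted from several random
starts; the first start is the PCoA solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist

from .dissimilarity import DistanceMatrix, gower_center
from .io import FingerprintError

_EIG_TOL = 1e-9


@dataclass(frozen=True)
class PcoaResult:
    """Eigendecomposition of the Gower-centered matrix.

    ``eigenvalues`` are all eigenvalues in descending order (negatives
    allowed; values within +-1e-9 of zero dropped).  ``real_axes`` holds
    coordinates on positive-eigenvalue axes scaled by sqrt(lambda);
    ``imaginary_axes`` those on negative-eigenvalue axes scaled by
    sqrt(|lambda|).
    """

    eigenvalues: np.ndarray
    real_axes: np.ndarray
    imaginary_axes: np.ndarray
    sample_ids: list[str]

    @property
    def trace(self) -> float:
        return float(self.eigenvalues.sum())


def pcoa(D: DistanceMatrix) -> PcoaResult:
    """Principal coordinates analysis of a distance matrix."""
    if D.n < 2:
        raise FingerprintError("pcoa needs at least 2 samples")
    G = gower_center(D)
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0)
    keep = np.abs(eigvals) > _EIG_TOL * scale
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    pos = eigvals > 0
    real_axes = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag_axes = eigvecs[:, ~pos] * np.sqrt(-eigvals[~pos])
    return PcoaResult(eigvals, real_axes, imag_axes, list(D.sample_ids))


@dataclass(frozen=True)
class NmdsResult:
    k: int
    coordinates: np.ndarray
    stress: float
    converged: bool
    restart_stresses: list[float]
    stress_trace: list[float] = field(default_factory=list)
    sample_ids: list[float] | None = None


def _disparities(config_d: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Monotone (PAVA) fit of configuration distances along the target order."""
    fitted = np.empty_like(config_d)
    fitted[order] = isotonic_regression(config_d[order]).x
    return fitted


def stress(coordinates: np.ndarray, D: DistanceMatrix) -> float:
    """Kruskal stress-1 of a configuration, isotonic fit recomputed.

    Ties in the target dissimilarities are handled by Kruskal's primary
    approach: tied values impose no order constraint between their fits
    (implemented by breaking ties with the configuration distances).
    """
    target = D.condensed()
    config_d = pdist(np.asarray(coordinates, dtype=float))
    if config_d.shape != target.shape:
        raise FingerprintError("coordinate and distance-matrix sizes disagree")
    order = np.lexsort((config_d, target))
    dhat = _disparities(config_d, order)
    denom = float((config_d ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((config_d - dhat) ** 2).sum() / denom))


def _guttman_update(X: np.ndarray, config_d: np.ndarray, dhat: np.ndarray,
                    iu: tuple) -> np.ndarray:
    n = X.shape[0]
    ratio = np.zeros_like(config_d)
    nz = config_d > 0
    ratio[nz] = dhat[nz] / config_d[nz]
    B = np.zeros((n, n))
    B[iu] = -ratio
    B += B.T
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def _run_start(X: np.ndarray, target: np.ndarray, max_iter: int,
               tol: float) -> tuple[np.ndarray, float, bool, list[float]]:
    n = X.shape[0]
    iu = np.triu_indices(n, 1)
    config_d = pdist(X)
    order = np.lexsort((config_d, target))
    dhat = _disparities(config_d, order)
    s = np.sqrt(((config_d - dhat) ** 2).sum() / (config_d ** 2).sum())
    trace = [float(s)]
    converged = False
    for _ in range(max_iter):
        X_new = _guttman_update(X, config_d, dhat, iu)
        config_d_new = pdist(X_new)
        if config_d_new.max() == 0:  # collapsed configuration
            break
        order = np.lexsort((config_d_new, target))
        dhat_new = _disparities(config_d_new, order)
        s_new = np.sqrt(((config_d_new - dhat_new) ** 2).sum() / (config_d_new ** 2).sum())
        if s_new > s:  # keep the stress trace monotone: reject and stop
            converged = True
            break
        X, config_d, dhat = X_new, config_d_new, dhat_new
        trace.append(float(s_new))
        if s - s_new < tol:
            s = s_new
            converged = True
            break
        s = s_new
    return X, float(s), converged, trace


def nmds(D: DistanceMatrix, k: int = 2, restarts: int = 20, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-6) -> NmdsResult:
    """Best-of-``restarts`` non-metric MDS embedding in k dimensions.

    The first start is the PCoA configuration; the remaining starts are
    random Gaussian configurations drawn from ``seed``.  The returned
    coordinates are centered and scaled so the RMS inter-point distance
    is 1 (stress-1 is scale-invariant, so this is cosmetic).
    """
    n = D.n
    if n < k + 2:
        raise FingerprintError(f"nmds needs at least k+2={k + 2} samples, got {n}")
    target = D.condensed()
    if np.ptp(target) == 0:
        raise FingerprintError("degenerate ranks: all dissimilarities are equal")
    rng = np.random.default_rng(seed)

    p = pcoa(D)
    X0 = p.real_axes[:, :k]
    if X0.shape[1] < k:
        X0 = np.hstack([X0, rng.standard_normal((n, k - X0.shape[1])) * 1e-3])
    starts = [X0] + [rng.standard_normal((n, k)) for _ in range(max(restarts - 1, 0))]

    best = None
    restart_stresses: list[float] = []
    for X_init in starts:
        X, s, conv, trace = _run_start(X_init.copy(), target, max_iter, tol)
        restart_stresses.append(s)
        if best is None or s < best[1]:
            best = (X, s, conv, trace)
    X, s, conv, trace = best
    X = X - X.mean(axis=0)
    rms = np.sqrt((pdist(X) ** 2).mean())
    if rms > 0:
        X = X / rms
    return NmdsResult(k=k, coordinates=X, stress=s, converged=conv,
                      restart_stresses=restart_stresses, stress_trace=trace,
                      sample_ids=list(D.sample_ids))
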