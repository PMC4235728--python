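"""Principal coordinate analysis and Procrustes comparison of ordinations.

PCoA (classical metric multidimensional scaling) eigendecomposes the
Gower-centered matrix B = -1/2 * J D^2 J (J the centering projector).
Coordinates are eigenvector * sqrt(eigenvalue) for positive eigenvalues
only; semi-metric inputs such as Bray-Curtis may produce negative
eigenvalues, which are counted and their axes dropped (no Lingoes/Cailliez
correction). A deterministic sign convention (the largest-magnitude
loading of each axis is made positive) keeps output bit-stable.

Procrustes superimposition centers both configurations, scales each to
unit Frobenius norm (symmetric scaling), and finds the orthogonal rotation
(reflections allowed) minimizing the residual sum of squares. The
goodness of fit is

    M^2 = 1 - (sum of singular values of X_c^T Y_c)^2

which is symmetric in its arguments. Significance is Monte-Carlo: rows of
one configuration are relabeled and p = (1 + #{M2_perm <= M2_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import JoinError, ValidationError
from .io import DistanceMatrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9  # relative tolerance for calling an eigenvalue zero


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray          # samples x positive axes
    eigenvalues: np.ndarray          # descending, positive axes only
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class ProcrustesResult:
    m_squared: float
    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def pcoa(D: DistanceMatrix, n_axes: int = 3) -> OrdinationResult:
    """Principal coordinate analysis of a distance matrix.

    Returns at most ``n_axes`` coordinate axes; fewer (with a warning) when
    the matrix has fewer positive eigenvalues.
    """
    if n_axes < 2:
        raise ValidationError("n_axes must be >= 2")
    n = D.n
    D2 = D.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0  # enforce exact symmetry for eigh
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    scale = max(abs(eigvals[0]), 1.0) if n else 1.0
    tol = _EIG_TOL * scale
    positive = eigvals > tol
    n_negative = int((eigvals < -tol).sum())

    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    # sign convention: largest-magnitude entry of each axis positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col

    if coords.shape[1] > n_axes:
        coords = coords[:, :n_axes]
        pos_vals_kept = pos_vals[:n_axes]
    else:
        pos_vals_kept = pos_vals
        if coords.shape[1] < n_axes:
            logger.warning("only %d positive axes available (requested %d)",
                           coords.shape[1], n_axes)
    total_pos = pos_vals.sum() if pos_vals.size else 1.0
    prop = pos_vals_kept / total_pos if pos_vals.size else np.array([])
    return OrdinationResult(list(D.labels), coords, pos_vals_kept, prop, n_negative)


def _configuration(ord_res: OrdinationResult, n_axes: int) -> np.ndarray:
    """Coordinates padded with zero columns up to n_axes when needed."""
    X = ord_res.coordinates[:, :n_axes]
    if X.shape[1] < n_axes:
        logger.warning("zero-padding configuration from %d to %d axes",
                       X.shape[1], n_axes)
        X = np.hstack([X, np.zeros((X.shape[0], n_axes - X.shape[1]))])
    return X


def _procrustes(X: np.ndarray, Y: np.ndarray) -> ProcrustesResult:
    muX = X.mean(axis=0)
    muY = Y.mean(axis=0)
    Xc = X - muX
    Yc = Y - muY
    normX = np.linalg.norm(Xc)
    normY = np.linalg.norm(Yc)
    if normX == 0 or normY == 0:
        raise ValidationError("degenerate configuration: all points coincide")
    Xc /= normX
    Yc /= normY
    U, s, Vt = np.linalg.svd(Xc.T @ Yc)
    R = Vt.T @ U.T  # applied to Y: Yc @ R approximates Xc
    traceTA = s.sum()
    m2 = max(0.0, 1.0 - traceTA ** 2)
    return ProcrustesResult(float(m2), R, float(traceTA), muX - muY)


def procrustes_fit(
    X: OrdinationResult, Y: OrdinationResult, n_axes: int = 3
) -> ProcrustesResult:
    """Least-squares superimposition of two ordinations of the same samples."""
    if X.labels != Y.labels:
        raise JoinError("ordinations have different sample labels")
    return _procrustes(_configuration(X, n_axes), _configuration(Y, n_axes))


def procrustes_monte_carlo(
    X: OrdinationResult,
    Y: OrdinationResult,
    n_axes: int = 3,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ProcrustesResult:
    """Procrustes fit with Monte-Carlo significance by sample relabeling.

    The null distribution is obtained by randomly permuting the rows of the
    second configuration ``n_perm`` times (default 1000).
    """
    if X.labels != Y.labels:
        raise JoinError("ordinations have different sample labels")
    A = _configuration(X, n_axes)
    B = _configuration(Y, n_axes)
    obs = _procrustes(A, B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        if _procrustes(A, B[perm]).m_squared <= obs.m_squared + 1e-12:
            count += 1
    obs.p = (1 + count) / (1 + n_perm)
    obs.n_permutations = n_perm
    obs.seed = seed
    return obs
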