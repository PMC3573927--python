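"""Shared numerical primitives: column scaling, PCA block reduction, and the
regularized CCA solver used by every Granger-causality operation.

All canonical correlations are computed on the correlation scale.  Ridge
regularization with parameter ``lam`` replaces each within-block correlation
matrix R by (R + lam*I) and rescales the whitened cross-block by (1 + lam),
so that a pair of univariate blocks always yields exactly the absolute
Pearson correlation, for any ``lam``.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

_EIG_TOL = 1e-10


class SingularCovarianceError(np.linalg.LinAlgError):
    """A within-block covariance matrix is numerically singular."""


def center_columns(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return m - m.mean(axis=0, keepdims=True)


def unit_columns(m: np.ndarray) -> np.ndarray:
    """Center columns and scale them to unit Euclidean norm.

    Raises on constant columns (zero variance), which carry no correlation
    information and would otherwise produce NaNs downstream.
    """
    c = center_columns(m)
    norms = np.linalg.norm(c, axis=0)
    if np.any(norms <= 0):
        raise SingularCovarianceError(
            "constant column(s) in sample block; remove constant series"
        )
    return c / norms


def pca_scores(
    m: np.ndarray, var_threshold: float = 0.05, noise_floor: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component score time series of a (time x variables) block.

    Returns ``(scores, fractions)`` where columns of ``scores`` are the PC
    projections for every component whose variance fraction exceeds
    ``var_threshold`` (at least one component is always kept), and
    ``fractions`` are the retained variance fractions.  With
    ``noise_floor=True`` the threshold is floored at the average
    eigenvalue (1 / number of components), so that wide blocks whose
    genuine structure falls below ``var_threshold`` per component are not
    truncated to noise.
    """
    c = center_columns(m)
    u, s, _ = np.linalg.svd(c, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        # all-constant block: a single zero score column
        return np.zeros((m.shape[0], 1)), np.ones(1)
    frac = var / total
    thr = min(var_threshold, 1.0 / var.size) if noise_floor else var_threshold
    keep = frac > thr
    if not keep.any():
        keep[0] = True
    scores = u[:, keep] * s[keep]
    return scores, frac[keep]


def maybe_reduce_block(
    m: np.ndarray, n_eff: int, var_threshold: float = 0.05
) -> np.ndarray:
    """PCA-reduce a sample block when its width threatens singularity.

    A block whose dimension is at least half the effective sample size is
    replaced by its principal-component scores retaining components with
    more than ``var_threshold`` of the variance.  Narrow blocks pass
    through unchanged.
    """
    if m.ndim == 1:
        m = m[:, None]
    if m.shape[1] < n_eff / 2:
        return m
    scores, _ = pca_scores(m, var_threshold)
    return scores


def _inv_sqrt_psd(r: np.ndarray, lam: float) -> np.ndarray:
    """(R + lam*I)^{-1/2} for a symmetric PSD correlation matrix R."""
    w, v = np.linalg.eigh(r)
    if lam == 0 and w.min() < _EIG_TOL * max(w.max(), 1.0):
        raise SingularCovarianceError(
            "singular within-block covariance; raise the ridge shrinkage or "
            "enable PCA reduction of the block"
        )
    w = np.maximum(w + lam, _EIG_TOL)
    return (v / np.sqrt(w)) @ v.T


def canonical_correlations(
    left: np.ndarray, right: np.ndarray, shrinkage: float = 0.0
) -> np.ndarray:
    """All canonical correlations between two sample blocks, descending.

    ``left`` and ``right`` are (n x m) and (n x q) sample matrices sharing
    rows (observations).  ``shrinkage`` is the ridge parameter ``lam``
    applied on the correlation scale as described in the module docstring.
    Values are clipped to [0, 1].
    """
    left = np.atleast_2d(np.asarray(left, dtype=float))
    right = np.atleast_2d(np.asarray(right, dtype=float))
    if left.ndim == 2 and left.shape[0] == 1:
        left = left.T
    if right.ndim == 2 and right.shape[0] == 1:
        right = right.T
    if left.shape[0] != right.shape[0]:
        raise ValueError(
            f"sample blocks must share observations: {left.shape[0]} != {right.shape[0]}"
        )
    if shrinkage < 0:
        raise ValueError("shrinkage must be >= 0")
    nx = unit_columns(left)
    ny = unit_columns(right)
    rxx = nx.T @ nx
    ryy = ny.T @ ny
    rxy = nx.T @ ny
    wx = _inv_sqrt_psd(rxx, shrinkage)
    wy = _inv_sqrt_psd(ryy, shrinkage)
    k = (1.0 + shrinkage) * (wx @ rxy @ wy)
    sv = np.linalg.svd(k, compute_uv=False)
    return np.clip(sv, 0.0, 1.0)


def rho_uni_vs_block(
    targets: np.ndarray, block: np.ndarray, shrinkage: float = 0.0
) -> np.ndarray:
    """Largest canonical correlation of each univariate target with a block.

    Vectorized special case of :func:`canonical_correlations` with a
    univariate left side: for unit-norm target y and block N with
    correlation matrix R and cross-vector r = N'y,

        rho^2 = (1 + lam) * r' (R + lam*I)^{-1} r.

    ``targets`` is (n x t); returns a length-t vector of rhos.
    """
    nt = unit_columns(targets if targets.ndim == 2 else targets[:, None])
    nb = unit_columns(block)
    rbb = nb.T @ nb
    lam = float(shrinkage)
    if lam == 0:
        w = np.linalg.eigvalsh(rbb)
        if w.min() < _EIG_TOL * max(w.max(), 1.0):
            raise SingularCovarianceError(
                "singular within-block covariance; raise the ridge shrinkage or "
                "enable PCA reduction of the block"
            )
    cross = nb.T @ nt  # (q x t)
    sol = sla.solve(rbb + lam * np.eye(rbb.shape[0]), cross, assume_a="pos")
    rho2 = (1.0 + lam) * np.einsum("qt,qt->t", cross, sol)
    return np.sqrt(np.clip(rho2, 0.0, 1.0))


def residualize(y: np.ndarray, z: np.ndarray | None, shrinkage: float = 0.0) -> np.ndarray:
    """Residuals of the columns of ``y`` after regression on block ``z``.

    Both blocks are column-centered first (an implicit intercept).  With a
    positive ``shrinkage`` the regression is ridge-regularized on the
    correlation scale, which keeps the projection defined even when ``z``
    has more columns than rows.
    """
    yc = center_columns(y if y.ndim == 2 else y[:, None])
    if z is None or z.size == 0 or z.shape[1] == 0:
        return yc
    nz = unit_columns(z)
    if shrinkage == 0:
        if z.shape[1] >= z.shape[0]:
            raise SingularCovarianceError(
                "conditioning block has column rank >= sample size; "
                "use a positive shrinkage or reduce the block"
            )
        beta, *_ = np.linalg.lstsq(nz, yc, rcond=None)
        return yc - nz @ beta
    rzz = nz.T @ nz + shrinkage * np.eye(nz.shape[1])
    beta = sla.solve(rzz, nz.T @ yc, assume_a="pos")
    return yc - nz @ beta
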