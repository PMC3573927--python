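"""Choosing the number of sub-networks: a Granger-causality cluster index
and a two-segment regression breakpoint rule.

For each series i with assigned sub-network A, ``a(i) = dist(x_i, A)`` is
the set-level Granger-causality distance of the series to its own cluster
and ``b(i)`` the smallest such distance to any other cluster (the neighbor
cluster).  The cluster index is ``s(i) = (b(i) - a(i)) / max(a(i), b(i))``
in [-1, 1].  Scanned over cluster counts k, the mean index is nearly flat
while k is at or below the adequate number of sub-networks and drops
abruptly once a genuine sub-network is split in two; the adequate k is
located by fitting two least-squares lines to the mean index versus k and
picking the split with the smallest total squared error.

Two numerical choices make the index comparable across cluster counts
(details in the package methods note):

* every multi-series set entering a distance is first summarized by its
  principal-component score series, keeping components above 5% of the
  variance or above the average eigenvalue (the noise floor) for wide
  sets -- so a merged double-cluster keeps its structure instead of being
  truncated by a size-dependent threshold;
* squared canonical correlations are degrees-of-freedom adjusted
  (Ezekiel's correction) before entering the distance, removing the
  mechanical inflation of a sample CCA with block width, which would
  otherwise make distances to wide sets look systematically smaller.

``dist(x_i, A)`` is evaluated with x_i kept inside its own cluster's set:
the lag in the CCA makes the quantity well defined, and the own-past
anchor keeps a(i) stable across cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from . import core
from ._linalg import pca_scores, unit_columns
from .clustering import (
    AdjacencyModel,
    ClusterAssignment,
    build_adjacency,
    functional_cluster,
)

__all__ = [
    "SilhouetteProfile",
    "KScanResult",
    "series_cluster_dissimilarity",
    "silhouette",
    "detect_breakpoint",
    "select_num_clusters",
]

DEFAULT_SHRINKAGE = 0.01


@dataclass
class SilhouetteProfile:
    """Per-series cluster indices s(i) with their a(i)/b(i) components.

    ``a`` is NaN for a series alone in its cluster (its s(i) is defined as
    0, the neutral value, since own-cluster cohesion is undefined there).
    """

    per_series_s: np.ndarray
    a: np.ndarray
    b: np.ndarray
    mean_s: float


@dataclass
class KScanResult:
    """Mean cluster index over a range of cluster counts, with the selection."""

    ks: np.ndarray
    mean_s_per_k: np.ndarray
    assignments: list[ClusterAssignment]
    selected_k: int
    breakpoint_q: int
    profiles: list[SilhouetteProfile] = field(default_factory=list)


def _adjust_rho(rho: np.ndarray, d: int, n: int) -> np.ndarray:
    """Degrees-of-freedom adjusted canonical correlation magnitude.

    Applies Ezekiel's correction to the squared correlation,
    ``1 - (1 - rho^2) (n - 1) / (n - d - 1)``, clipping at zero.  Under
    independence the raw squared correlation of a univariate target with a
    d-dimensional block inflates like d/n; the adjustment removes that
    bias so distances to blocks of different widths are comparable.
    """
    denom = max(n - d - 1, 1)
    r2 = 1.0 - (1.0 - np.asarray(rho) ** 2) * (n - 1) / denom
    return np.sqrt(np.clip(r2, 0.0, 1.0))


def _set_scores(values_t: np.ndarray, var_threshold: float) -> np.ndarray:
    """Summarize a (time x members) set block by its PC score series.

    Retention threshold is ``min(var_threshold, 1/n_components)``: the 5%
    temporal-variance rule, floored at the average eigenvalue for sets
    wide enough that genuine structure falls below 5% per component.
    Univariate sets pass through unchanged.
    """
    if values_t.shape[1] <= 1:
        return values_t
    scores, _ = pca_scores(values_t, var_threshold, noise_floor=True)
    return scores


def _rho_block(targets: np.ndarray, block: np.ndarray, lam: float) -> np.ndarray:
    """rho of each unit-norm target column with a unit-norm column block."""
    rbb = block.T @ block + lam * np.eye(block.shape[1])
    cross = block.T @ targets
    sol = sla.solve(rbb, cross, assume_a="pos")
    rho2 = (1.0 + lam) * np.einsum("qt,qt->t", cross, sol)
    return np.sqrt(np.clip(rho2, 0.0, 1.0))


def _dissimilarity_matrix(
    tsm: core.TimeSeriesMatrix,
    labels: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    pca_threshold: float = 0.05,
    adjusted: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """dist(x_i, cluster_c) for every series and cluster, vectorized.

    Each cluster is summarized once by its PC score series; the two
    directional univariate-vs-set CCAs of all p series against that block
    share one Gram factorization.  The own-cluster entry of a singleton
    cluster is NaN (no cohesion defined).  Returns (p x k matrix, cluster
    labels).
    """
    lag = tsm.lag_order
    n = tsm.n_eff
    lam = float(shrinkage)
    cur = unit_columns(tsm.values[:, lag:].T)  # n x p
    lagm = unit_columns(tsm.values[:, :-lag].T)
    clusters = np.unique(labels)
    out = np.full((tsm.n_series, clusters.size), np.nan)
    for c_pos, c in enumerate(clusters):
        members = np.flatnonzero(labels == c)
        block = _set_scores(tsm.values[members].T, pca_threshold)
        d = block.shape[1]
        bl = unit_columns(block[:-lag])
        bc = unit_columns(block[lag:])
        r_in = _rho_block(cur, bl, lam)  # CCA(x_i(t), C(t-1))
        r_out = _rho_block(lagm, bc, lam)  # CCA(C(t), x_i(t-1))
        if adjusted:
            r_in = _adjust_rho(r_in, d, n)
            r_out = _adjust_rho(r_out, d, n)
        out[:, c_pos] = 1.0 - (r_in + r_out) / 2.0
        if members.size == 1:
            out[members[0], c_pos] = np.nan
    return out, clusters


def series_cluster_dissimilarity(
    tsm: core.TimeSeriesMatrix,
    i: int,
    cluster,
    shrinkage: float = DEFAULT_SHRINKAGE,
    pca_threshold: float = 0.05,
    adjusted: bool = True,
) -> float:
    """Granger-causality distance between series i and one cluster.

    The building block of the cluster index: one minus the average of the
    two directional CCA magnitudes between the series and the cluster's
    PC summary, with the df adjustment of the module docstring.  With
    ``adjusted=False`` and a cluster not containing i this coincides with
    :func:`grangerclust.core.gc_distance` up to the set-summarization
    convention (exactly, for singleton clusters).  Returns NaN when the
    cluster is the singleton {i}.
    """
    idx = core._as_indices(cluster, tsm.n_series)
    if idx.size == 1 and idx[0] == int(i):
        return float("nan")
    lag = tsm.lag_order
    lam = float(shrinkage)
    cur = unit_columns(tsm.values[i, lag:][:, None])
    lagv = unit_columns(tsm.values[i, :-lag][:, None])
    block = _set_scores(tsm.values[idx].T, pca_threshold)
    d = block.shape[1]
    bl = unit_columns(block[:-lag])
    bc = unit_columns(block[lag:])
    r_in = _rho_block(cur, bl, lam)
    r_out = _rho_block(lagv, bc, lam)
    if adjusted:
        r_in = _adjust_rho(r_in, d, tsm.n_eff)
        r_out = _adjust_rho(r_out, d, tsm.n_eff)
    return float(1.0 - (r_in[0] + r_out[0]) / 2.0)


def silhouette(
    tsm: core.TimeSeriesMatrix,
    assign: ClusterAssignment,
    shrinkage: float = DEFAULT_SHRINKAGE,
    pca_threshold: float = 0.05,
    adjusted: bool = True,
) -> SilhouetteProfile:
    """Cluster index s(i) for every series under an assignment.

    Requires at least two clusters (the neighbor distance b(i) is undefined
    otherwise).  ``mean_s`` is the unweighted mean over all series.
    """
    if assign.k < 2:
        raise ValueError("the cluster index requires more than one sub-network")
    labels = assign.labels
    d, clusters = _dissimilarity_matrix(
        tsm, labels, shrinkage, pca_threshold, adjusted
    )
    pos = {c: j for j, c in enumerate(clusters)}
    p = labels.size
    a = np.empty(p)
    b = np.empty(p)
    s = np.empty(p)
    for i in range(p):
        own = pos[labels[i]]
        a[i] = d[i, own]
        b[i] = np.nanmin(np.delete(d[i], own))
        if np.isnan(a[i]):
            s[i] = 0.0  # singleton cluster: neutral index
        else:
            denom = max(a[i], b[i])
            s[i] = 0.0 if denom <= 0 else (b[i] - a[i]) / denom
    return SilhouetteProfile(per_series_s=s, a=a, b=b, mean_s=float(s.mean()))


def detect_breakpoint(ks, mean_s_per_k) -> tuple[int, int]:
    """Two-segment least-squares breakpoint on the mean index curve.

    Fits an ordinary least-squares line to the first q points and another
    to the remaining points, for every q leaving at least two points per
    segment, and returns the q with the smallest total squared error (ties
    break toward the smallest q).  The selected number of clusters is the
    last scanned k of the first segment -- the last k before the abrupt
    drop.  Returns ``(q, selected_k)``.
    """
    ks = np.asarray(ks, dtype=float)
    y = np.asarray(mean_s_per_k, dtype=float)
    n = ks.size
    if n < 4:
        raise ValueError("breakpoint detection needs at least 4 scanned k values")
    if ks.size != y.size or np.any(np.diff(ks) <= 0):
        raise ValueError("ks must be strictly increasing and match mean_s_per_k")

    def _sse(x: np.ndarray, t: np.ndarray) -> float:
        coef = np.polyfit(x, t, 1)
        r = t - np.polyval(coef, x)
        return float(r @ r)

    best_q, best_sse = None, np.inf
    for q in range(2, n - 1):
        sse = _sse(ks[:q], y[:q]) + _sse(ks[q:], y[q:])
        if sse < best_sse - 1e-15:
            best_q, best_sse = q, sse
    return best_q, int(ks[best_q - 1])


def select_num_clusters(
    tsm: core.TimeSeriesMatrix,
    k_min: int = 2,
    k_max: int | None = None,
    degree_mode: str = "cca_degree",
    eig_order: str = "smallest",
    shrinkage: float = DEFAULT_SHRINKAGE,
    n_init: int = 100,
    seed: int | None = 0,
    adjacency: AdjacencyModel | None = None,
    keep_profiles: bool = False,
) -> KScanResult:
    """Scan cluster counts, score each with the mean cluster index, and
    select the count at the breakpoint.

    The default scan is k = 2..7 (capped at p - 1): the upper end must
    exceed the largest plausible sub-network count by enough points for
    the second regression segment to see the post-drop behavior.  The
    similarity graph does not depend on k and is built once.
    """
    p = tsm.n_series
    if k_max is None:
        k_max = min(7, p - 1)
    if not 2 <= k_min < k_max <= p - 1:
        raise ValueError("need 2 <= k_min < k_max <= p - 1")
    if k_max - k_min + 1 < 4:
        raise ValueError("scan at least 4 values of k for the breakpoint rule")
    adj = adjacency if adjacency is not None else build_adjacency(
        tsm, degree_mode=degree_mode, shrinkage=shrinkage
    )
    ks = np.arange(k_min, k_max + 1)
    assignments: list[ClusterAssignment] = []
    profiles: list[SilhouetteProfile] = []
    means = np.empty(ks.size)
    for j, k in enumerate(ks):
        assign = functional_cluster(
            tsm,
            int(k),
            eig_order=eig_order,
            shrinkage=shrinkage,
            n_init=n_init,
            seed=seed,
            adjacency=adj,
        )
        prof = silhouette(tsm, assign, shrinkage=shrinkage)
        assignments.append(assign)
        means[j] = prof.mean_s
        if keep_profiles:
            profiles.append(prof)
    q, selected_k = detect_breakpoint(ks, means)
    return KScanResult(
        ks=ks,
        mean_s_per_k=means,
        assignments=assignments,
        selected_k=selected_k,
        breakpoint_q=q,
        profiles=profiles,
    )
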