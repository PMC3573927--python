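"""Cluster-level Granger-causality network inference.

Each cluster is summarized by its eigen-time series: the principal-
component score series of the cluster's expression matrix, keeping every
component that explains more than 5% of the temporal variance.  For every
ordered cluster pair (j -> i) the edge weight is the partial CCA between
cluster i's eigen-series at time t and cluster j's eigen-series at time
t-1, conditioning on the lag-1 eigen-series of every other cluster
(including, for i != j, cluster i's own past -- the Granger requirement
that j's past must add predictive information beyond everything else's).
Edges are tested for zero canonical correlation and flagged at the 0.05
(solid) and 0.10 (dashed) levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import pca_scores, residualize
from .clustering import ClusterAssignment
from .core import TimeSeriesMatrix, cca_max, gc_test

__all__ = [
    "EigenSeriesSet",
    "GCEdge",
    "ClusterNetwork",
    "extract_eigen_series",
    "infer_network",
]


@dataclass
class EigenSeriesSet:
    """Per-cluster principal-component time series.

    ``series[c]`` is a (T x r_c) matrix of orthogonal eigen-time series for
    cluster c; ``variance_fractions[c]`` are the corresponding retained
    variance fractions (each above the retention threshold, at least one
    component per cluster).
    """

    series: dict[int, np.ndarray]
    variance_fractions: dict[int, np.ndarray]
    n_timepoints: int
    lag_order: int = 1

    @property
    def clusters(self) -> list[int]:
        return sorted(self.series)


@dataclass
class GCEdge:
    """A directed cluster-to-cluster Granger-causality test result."""

    from_cluster: int
    to_cluster: int
    rho_hat: float
    p_value: float
    statistic: float = float("nan")


@dataclass
class ClusterNetwork:
    """All pairwise cluster-level tests at the two significance levels."""

    nodes: list[int]
    edges: list[GCEdge]
    self_edges: list[GCEdge] = field(default_factory=list)
    alpha_solid: float = 0.05
    alpha_dashed: float = 0.10

    def significant(self, alpha: float | None = None) -> list[GCEdge]:
        a = self.alpha_solid if alpha is None else alpha
        return [e for e in self.edges if e.p_value < a]

    def edge(self, from_cluster: int, to_cluster: int) -> GCEdge:
        pool = self.self_edges if from_cluster == to_cluster else self.edges
        for e in pool:
            if e.from_cluster == from_cluster and e.to_cluster == to_cluster:
                return e
        raise KeyError((from_cluster, to_cluster))


def extract_eigen_series(
    tsm: TimeSeriesMatrix,
    assign: ClusterAssignment,
    var_threshold: float = 0.05,
) -> EigenSeriesSet:
    """PCA summarization of each cluster into its eigen-time series.

    The PCA treats time points as observations and the cluster's series as
    variables; components with a variance fraction above ``var_threshold``
    are retained (always at least one).
    """
    series: dict[int, np.ndarray] = {}
    fractions: dict[int, np.ndarray] = {}
    for c in range(1, assign.k + 1):
        members = assign.members(c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        scores, frac = pca_scores(tsm.values[members].T, var_threshold)
        series[c] = scores
        fractions[c] = frac
    return EigenSeriesSet(
        series=series,
        variance_fractions=fractions,
        n_timepoints=tsm.n_timepoints,
        lag_order=tsm.lag_order,
    )


def infer_network(
    eigs: EigenSeriesSet,
    method: str = "asymptotic",
    shrinkage: float = 0.0,
    alpha_solid: float = 0.05,
    alpha_dashed: float = 0.10,
    n_permutations: int = 199,
    seed: int | None = None,
) -> ClusterNetwork:
    """Partial-CCA Granger-causality tests between all ordered cluster pairs.

    For the pair (j -> i) the conditioning block is the lag-1 eigen-series
    of every cluster except j.  The diagonal entries (a cluster's
    dependence on its own past given all other clusters) are reported
    separately in ``self_edges``.
    """
    clusters = eigs.clusters
    if len(clusters) < 2:
        raise ValueError("network inference needs at least two clusters")
    lag = eigs.lag_order
    cur = {c: eigs.series[c][lag:] for c in clusters}
    past = {c: eigs.series[c][:-lag] for c in clusters}
    edges: list[GCEdge] = []
    self_edges: list[GCEdge] = []
    for j in clusters:  # source
        cond_cols = [past[c] for c in clusters if c != j]
        z = np.hstack(cond_cols) if cond_cols else None
        for i in clusters:  # target
            y = residualize(cur[i], z, shrinkage)
            x = residualize(past[j], z, shrinkage)
            res = cca_max(y, x, shrinkage)
            res.n_conditioned = 0 if z is None else z.shape[1]
            test = gc_test(
                res, method=method, n_permutations=n_permutations, seed=seed
            )
            edge = GCEdge(
                from_cluster=int(j),
                to_cluster=int(i),
                rho_hat=test.rho_hat,
                p_value=test.p_value,
                statistic=test.statistic,
            )
            (self_edges if i == j else edges).append(edge)
    return ClusterNetwork(
        nodes=[int(c) for c in clusters],
        edges=edges,
        self_edges=self_edges,
        alpha_solid=alpha_solid,
        alpha_dashed=alpha_dashed,
    )
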