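"""Granger-causality primitives for sets of time series.

A set of time series Y Granger-causes a set X when the past of Y improves
the prediction of X beyond all other available information.  In the linear
first-order autoregressive setting this is equivalent to a nonzero largest
canonical correlation between X at time t and Y at time t-1, partialized on
the remaining information.  This module provides the building blocks:

* :func:`lagged_cca` -- largest canonical correlation between one set's
  present and another set's past (directional information flow);
* :func:`partial_cca` -- the same after regressing out a conditioning set;
* :func:`gc_distance` -- the symmetric dissimilarity
  ``1 - (|CCA(i<-j)| + |CCA(j<-i)|) / 2``;
* :func:`series_degree` / :func:`set_degree` -- total information flow
  entering/leaving a vertex or sub-network;
* :func:`gc_test` -- asymptotic (Bartlett-Lawley) or permutation test of
  zero canonical correlation.

All reported correlations are magnitudes in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy import stats

from ._linalg import (
    SingularCovarianceError,
    canonical_correlations,
    center_columns,
    maybe_reduce_block,
    residualize,
)

__all__ = [
    "TimeSeriesMatrix",
    "SeriesSet",
    "CcaResult",
    "GCTestResult",
    "SingularCovarianceError",
    "standardize",
    "cca_max",
    "lagged_cca",
    "partial_cca",
    "gc_distance",
    "series_degree",
    "set_degree",
    "gc_test",
]

DegreeMode = Literal["in", "out", "total"]
TestMethod = Literal["asymptotic", "permutation"]


@dataclass
class TimeSeriesMatrix:
    """A universe of p time series observed at T uniformly spaced points.

    ``values`` has one row per series and one column per time point, in
    temporal order.  ``lag_order`` is the autoregressive order assumed by
    the Granger-causality operations (the method is developed for order 1).
    """

    values: np.ndarray
    series_ids: list[str]
    lag_order: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (series x time) array")
        if self.lag_order < 1:
            raise ValueError("lag_order must be a positive integer")
        p, t = self.values.shape
        if len(self.series_ids) != p:
            raise ValueError("series_ids length must match the number of rows")
        if len(set(self.series_ids)) != p:
            raise ValueError("series_ids must be unique")
        if t < self.lag_order + 3:
            raise ValueError(
                f"need at least lag_order + 3 = {self.lag_order + 3} time points, got {t}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_eff(self) -> int:
        """Aligned sample size of a lagged regression, T - lag_order."""
        return self.n_timepoints - self.lag_order


class SeriesSet:
    """An ordered set of row indices into a :class:`TimeSeriesMatrix`.

    Candidate clusters / sub-networks are represented this way.  Any
    sequence of unique non-negative integers is accepted wherever a
    SeriesSet is expected.
    """

    def __init__(self, indices: Iterable[int]):
        idx = [int(i) for i in indices]
        if len(idx) == 0:
            raise ValueError("a SeriesSet must be non-empty")
        if len(set(idx)) != len(idx):
            raise ValueError("SeriesSet indices must be unique")
        if min(idx) < 0:
            raise ValueError("SeriesSet indices must be non-negative")
        self.indices = np.asarray(idx, dtype=int)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __repr__(self) -> str:
        return f"SeriesSet({list(self.indices)})"


def _as_indices(s, p: int) -> np.ndarray:
    if isinstance(s, SeriesSet):
        idx = s.indices
    elif np.isscalar(s):
        idx = np.asarray([int(s)])
    else:
        idx = SeriesSet(s).indices
    if idx.max() >= p:
        raise IndexError(f"series index {idx.max()} out of range for p={p}")
    return idx


def _check_disjoint(a: np.ndarray, b: np.ndarray) -> None:
    if np.intersect1d(a, b).size:
        raise ValueError("the two series sets must be disjoint")


@dataclass
class CcaResult:
    """Largest canonical correlation between two sample blocks.

    ``rho`` is the leading canonical correlation in [0, 1]; ``rhos`` holds
    all canonical roots (used by the joint significance test).  ``dim_left``
    and ``dim_right`` are the block dimensions after any PCA reduction, and
    ``n_conditioned`` the number of conditioning columns regressed out
    (both enter the degrees of freedom of the asymptotic test).
    """

    rho: float
    dim_left: int
    dim_right: int
    n_eff: int
    rhos: np.ndarray = field(default_factory=lambda: np.zeros(0))
    shrinkage: float = 0.0
    n_conditioned: int = 0
    # centered sample blocks retained for the permutation test
    _left: np.ndarray | None = field(default=None, repr=False)
    _right: np.ndarray | None = field(default=None, repr=False)


@dataclass
class GCTestResult:
    """Outcome of the zero-canonical-correlation (Granger non-causality) test."""

    rho_hat: float
    statistic: float
    p_value: float
    method: str
    df: int = 0


def standardize(tsm: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Return a copy with every series scaled to mean 0 and unit variance.

    CCA is invariant to affine rescaling of individual series, so this only
    stabilizes the numerics; constant series are rejected because they
    carry no dynamic information.
    """
    v = tsm.values
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() <= 0)
    if bad.size:
        names = ", ".join(tsm.series_ids[i] for i in bad[:5])
        raise ValueError(f"constant series cannot be standardized: {names}")
    return TimeSeriesMatrix((v - mu) / sd, list(tsm.series_ids), tsm.lag_order)


def cca_max(
    left: np.ndarray, right: np.ndarray, shrinkage: float = 0.0
) -> CcaResult:
    """Largest canonical correlation between two sample matrices.

    Rows are shared observations, columns are variables.  With both sides
    univariate the result equals the absolute Pearson correlation for any
    shrinkage.  A singular within-block covariance with ``shrinkage=0``
    raises :class:`SingularCovarianceError`.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.ndim == 1:
        left = left[:, None]
    if right.ndim == 1:
        right = right[:, None]
    rhos = canonical_correlations(left, right, shrinkage)
    return CcaResult(
        rho=float(rhos[0]),
        dim_left=left.shape[1],
        dim_right=right.shape[1],
        n_eff=left.shape[0],
        rhos=rhos,
        shrinkage=shrinkage,
        _left=center_columns(left),
        _right=center_columns(right),
    )


def _set_block(
    tsm: TimeSeriesMatrix,
    indices: np.ndarray,
    pca_threshold: float = 0.05,
    reduce: bool = True,
) -> np.ndarray:
    """(T x m) sample block for a series set, PCA-reduced when wide.

    A set whose size reaches half the effective sample size is replaced by
    its principal-component score series (components above
    ``pca_threshold`` of the variance), the same redundancy-removal rule
    used when extracting cluster eigen-time series.
    """
    block = tsm.values[indices].T
    if reduce:
        block = maybe_reduce_block(block, tsm.n_eff, pca_threshold)
    return block


def lagged_cca(
    tsm: TimeSeriesMatrix,
    from_set,
    to_set,
    lag: int | None = None,
    shrinkage: float = 0.01,
    pca_threshold: float = 0.05,
) -> CcaResult:
    """CCA between ``to_set`` at time t and ``from_set`` at time t-lag.

    This is the (unconditional) Granger causality from ``from_set`` to
    ``to_set``: the largest canonical correlation between the target set's
    present and the source set's past, on the aligned sample of size
    T - lag.
    """
    lag = tsm.lag_order if lag is None else int(lag)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if tsm.n_timepoints - lag < 3:
        raise ValueError("too few time points for the requested lag")
    src = _as_indices(from_set, tsm.n_series)
    dst = _as_indices(to_set, tsm.n_series)
    _check_disjoint(src, dst)
    y = _set_block(tsm, dst, pca_threshold)[lag:]
    x = _set_block(tsm, src, pca_threshold)[:-lag]
    return cca_max(y, x, shrinkage)


def partial_cca(
    tsm: TimeSeriesMatrix,
    target,
    predictor_lagged,
    conditioning=None,
    lag: int | None = None,
    shrinkage: float = 0.01,
    pca_threshold: float = 0.05,
) -> CcaResult:
    """CCA between target(t) and predictor(t-lag) given a conditioning set.

    The lag-1 values of the conditioning series are regressed out of both
    blocks before the CCA; with an empty conditioning set this reduces to
    :func:`lagged_cca`.  The conditioning block enters at its full width,
    so with ``shrinkage=0`` it must have fewer columns than the aligned
    sample size.
    """
    lag = tsm.lag_order if lag is None else int(lag)
    tgt = _as_indices(target, tsm.n_series)
    src = _as_indices(predictor_lagged, tsm.n_series)
    _check_disjoint(tgt, src)
    y = _set_block(tsm, tgt, pca_threshold)[lag:]
    x = _set_block(tsm, src, pca_threshold)[:-lag]
    z = None
    n_cond = 0
    if conditioning is not None:
        cond = _as_indices(conditioning, tsm.n_series)
        if cond.size:
            z = tsm.values[cond].T[:-lag]
            n_cond = z.shape[1]
    yr = residualize(y, z, shrinkage)
    xr = residualize(x, z, shrinkage)
    res = cca_max(yr, xr, shrinkage)
    res.n_conditioned = n_cond
    return res


def gc_distance(
    tsm: TimeSeriesMatrix,
    set_i,
    set_j,
    shrinkage: float = 0.01,
    pca_threshold: float = 0.05,
) -> float:
    """Granger-causality distance between two disjoint (sets of) series.

    ``1 - (|CCA(i(t), j(t-1))| + |CCA(j(t), i(t-1))|) / 2``: the stronger
    the information flow in either direction, the closer the sets.
    Symmetric by construction and contained in [0, 1].
    """
    a = lagged_cca(tsm, set_j, set_i, shrinkage=shrinkage, pca_threshold=pca_threshold)
    b = lagged_cca(tsm, set_i, set_j, shrinkage=shrinkage, pca_threshold=pca_threshold)
    return float(1.0 - (a.rho + b.rho) / 2.0)


def _degree_blocks(tsm: TimeSeriesMatrix, pca_threshold: float) -> np.ndarray:
    """The whole-universe block used as the opposite side of degree CCAs."""
    return _set_block(tsm, np.arange(tsm.n_series), pca_threshold)


def set_degree(
    tsm: TimeSeriesMatrix,
    s,
    mode: DegreeMode = "total",
    shrinkage: float = 0.01,
    pca_threshold: float = 0.05,
    exclude_self_flow: bool = False,
) -> float:
    """Granger-causality degree of a sub-network.

    The in-degree is the largest canonical correlation between the set's
    present and the lagged whole network; the out-degree swaps the roles;
    the total degree is their average.  The whole-network block is
    PCA-reduced when wider than half the effective sample, which keeps the
    computation defined for p close to (or above) T.

    By definition the lagged network includes the set itself, so the
    degree counts within-set flow (a tightly coupled sub-network has a
    *high* degree).  With ``exclude_self_flow=True`` the opposite side is
    the set's complement instead, giving the cross-boundary flow — the
    quantity that is *low* for a well-separated functional cluster.
    """
    idx = _as_indices(s, tsm.n_series)
    if idx.size >= tsm.n_series:
        raise ValueError("degree of the full universe is undefined (empty complement)")
    lag = tsm.lag_order
    if exclude_self_flow:
        other = np.setdiff1d(np.arange(tsm.n_series), idx)
        universe = _set_block(tsm, other, pca_threshold)
    else:
        universe = _degree_blocks(tsm, pca_threshold)
    own = _set_block(tsm, idx, pca_threshold)

    def _in() -> float:
        return cca_max(own[lag:], universe[:-lag], shrinkage).rho

    def _out() -> float:
        return cca_max(universe[lag:], own[:-lag], shrinkage).rho

    if mode == "in":
        return _in()
    if mode == "out":
        return _out()
    if mode == "total":
        return (_in() + _out()) / 2.0
    raise ValueError(f"unknown degree mode: {mode!r}")


def series_degree(
    tsm: TimeSeriesMatrix,
    i: int,
    mode: DegreeMode = "total",
    shrinkage: float = 0.01,
    pca_threshold: float = 0.05,
) -> float:
    """Degree of a single series: total information flow through vertex i."""
    if tsm.n_series < 2:
        raise ValueError("degree requires at least two series")
    return set_degree(tsm, [int(i)], mode, shrinkage, pca_threshold)


def gc_test(
    result: CcaResult,
    method: TestMethod = "asymptotic",
    n_permutations: int = 199,
    seed: int | None = None,
) -> GCTestResult:
    """Test H0: all canonical correlations are zero (Granger non-causality).

    The asymptotic method is the Bartlett-Lawley chi-square approximation
    on the canonical roots,

        -(n' - 1 - (m + q + 1)/2) * sum_k log(1 - rho_k^2)  ~  chi2(m*q),

    with n' the aligned sample size minus the number of conditioning
    columns regressed out.  The permutation method re-estimates the leading
    correlation on circularly time-shifted predictor blocks and returns the
    empirical upper-tail p-value (1 + #{rho_perm >= rho_hat}) / (B + 1),
    which stays valid at small samples.
    """
    m, q = result.dim_left, result.dim_right
    n_adj = result.n_eff - result.n_conditioned
    if method == "asymptotic":
        if n_adj <= m + q + 2:
            raise ValueError(
                "effective sample too small for the asymptotic test; "
                "use method='permutation'"
            )
        rhos = np.clip(result.rhos, 0.0, 1.0 - 1e-12)
        stat = -(n_adj - 1 - (m + q + 1) / 2.0) * np.log(1.0 - rhos**2).sum()
        stat = float(max(stat, 0.0))
        df = m * q
        p = float(stats.chi2.sf(stat, df))
        return GCTestResult(result.rho, stat, p, "asymptotic", df)
    if method == "permutation":
        if result._left is None or result._right is None:
            raise ValueError("permutation test needs the sample blocks on the result")
        rng = np.random.default_rng(seed)
        n = result._left.shape[0]
        count = 0
        for _ in range(n_permutations):
            shift = int(rng.integers(1, n))
            perm = np.roll(result._right, shift, axis=0)
            rho_b = canonical_correlations(result._left, perm, result.shrinkage)[0]
            if rho_b >= result.rho - 1e-12:
                count += 1
        p = (1.0 + count) / (n_permutations + 1.0)
        return GCTestResult(result.rho, result.rho, float(p), "permutation", m * q)
    raise ValueError(f"unknown test method: {method!r}")
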