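"""Reading and writing the package's exchange formats.

Expression matrices travel as TSV/CSV with one row per gene/series (first
column the identifier, remaining columns time-ordered values), the common
shape of time-course expression tables.  All other artifacts (cluster
labels, k-scan curves, edge lists, configs) are small TSV/YAML files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterAssignment
from .core import TimeSeriesMatrix
from .model_selection import KScanResult
from .network import ClusterNetwork

__all__ = [
    "AnalysisConfig",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "write_kscan",
    "write_edge_list",
]


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters, serializable to/from YAML."""

    lag_order: int = 1
    shrinkage: float = 0.01
    k_min: int = 2
    k_max: int | None = None
    n_init: int = 100
    eig_order: str = "smallest"
    degree_mode: str = "cca_degree"
    pca_variance_threshold: float = 0.05
    alpha_solid: float = 0.05
    alpha_dashed: float = 0.10
    test_method: str = "asymptotic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag_order < 1:
            raise ValueError("lag_order must be >= 1")
        if self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")
        if not 0 < self.pca_variance_threshold < 1:
            raise ValueError("pca_variance_threshold must be in (0, 1)")
        for a in (self.alpha_solid, self.alpha_dashed):
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")
        if self.eig_order not in ("smallest", "largest"):
            raise ValueError("eig_order must be 'smallest' or 'largest'")
        if self.degree_mode not in ("cca_degree", "row_sum"):
            raise ValueError("degree_mode must be 'cca_degree' or 'row_sum'")
        if self.test_method not in ("asymptotic", "permutation"):
            raise ValueError("test_method must be 'asymptotic' or 'permutation'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_expression_matrix(
    path, sep: str | None = None, log2: bool = False, lag_order: int = 1
) -> TimeSeriesMatrix:
    """Load a genes x time-points expression table into a TimeSeriesMatrix.

    The first column holds series identifiers; remaining columns are
    numeric and time-ordered.  Rows with missing or non-numeric values
    and duplicated identifiers are rejected with the offending series
    named.  ``log2`` applies a log2(x + 1) transform.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 5:
        raise ValueError(
            f"{path.name}: need at least 5 time points, found {df.shape[1]}"
        )
    ids = [str(i) for i in df.index]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path.name}: duplicated series id(s): {', '.join(dup[:5])}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        names = ", ".join(ids[i] for i in bad[:5])
        raise ValueError(f"{path.name}: missing/non-numeric values in: {names}")
    if log2:
        if (values < 0).any():
            raise ValueError(f"{path.name}: negative values under log2 transform")
        values = np.log2(values + 1.0)
    return TimeSeriesMatrix(values, ids, lag_order)


def write_expression_matrix(tsm: TimeSeriesMatrix, path) -> None:
    df = pd.DataFrame(
        tsm.values,
        index=pd.Index(tsm.series_ids, name="series_id"),
        columns=[f"t{j + 1}" for j in range(tsm.n_timepoints)],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_labels(tsm: TimeSeriesMatrix, assign: ClusterAssignment, path) -> None:
    """Two-column TSV: series_id, cluster_label."""
    pd.DataFrame(
        {"series_id": tsm.series_ids, "cluster_label": assign.labels}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"series_id", "cluster_label"}
    if not need <= set(df.columns):
        raise ValueError(f"labels file must have columns {sorted(need)}")
    return df


def write_kscan(scan: KScanResult, path) -> None:
    """TSV of the scanned curve: k, mean_s, selected flag."""
    pd.DataFrame(
        {
            "k": scan.ks,
            "mean_s": scan.mean_s_per_k,
            "selected": (scan.ks == scan.selected_k).astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_edge_list(net: ClusterNetwork, path, include_self: bool = True) -> None:
    """Edge-list TSV with rho, p-value and the two significance flags."""
    rows = []
    pool = net.edges + (net.self_edges if include_self else [])
    for e in pool:
        rows.append(
            {
                "from": e.from_cluster,
                "to": e.to_cluster,
                "rho_hat": e.rho_hat,
                "p_value": e.p_value,
                f"significant_{net.alpha_solid:g}": int(e.p_value < net.alpha_solid),
                f"significant_{net.alpha_dashed:g}": int(e.p_value < net.alpha_dashed),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
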