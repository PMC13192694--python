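"""Optional post-hoc analyses on processed trace matrices.

Agglomerative hierarchical clustering groups traces by shape under a
choice of distance (euclidean, correlation, cosine) and linkage
(average, complete, or ward for euclidean); per-condition averaged
traces with pointwise dispersion support the classic mean-trace plot;
the dendrogram leaf order gives a heatmap-ready row ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .errors import DegenerateInputError, ParameterError
from .traces import TraceMatrix

__all__ = ["ClusterResult", "trace_distance", "cluster_traces", "average_trace"]

METRICS = ("euclidean", "correlation", "cosine")
LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-trace cluster index in 1..k
    metric: str
    linkage: str
    k: int
    cophenetic_order: np.ndarray  # trace ordering for heatmap display


def trace_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Distance between two fully observed, equal-length traces."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("traces must be 1-D and of equal length")
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "correlation":
        if np.std(x) == 0 or np.std(y) == 0:
            raise DegenerateInputError(
                "correlation distance undefined for a zero-variance trace"
            )
        r = float(np.corrcoef(x, y)[0, 1])
        return 1.0 - r
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise DegenerateInputError("cosine distance undefined for a zero trace")
        return 1.0 - float(np.dot(x, y) / (nx * ny))
    raise ParameterError(f"unknown metric {metric!r}")


def cluster_traces(
    tm: TraceMatrix, metric: str = "euclidean", linkage_method: str = "average", k: int = 2
) -> ClusterResult:
    """Agglomerative clustering of traces, cut at k clusters.

    Deterministic for fixed inputs. Cluster labels are renumbered by
    first occurrence so they are stable under permutation of traces.
    """
    if metric not in METRICS:
        raise ParameterError(f"unknown metric {metric!r}")
    if linkage_method not in LINKAGES:
        raise ParameterError(f"unknown linkage {linkage_method!r}")
    if linkage_method == "ward" and metric != "euclidean":
        raise ParameterError("ward linkage requires the euclidean metric")
    n = tm.n_cells
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} must be in 1..n_traces={n}")
    data = tm.values.T  # one row per trace
    if metric == "correlation" and np.any(np.std(data, axis=1) == 0):
        raise DegenerateInputError("correlation clustering with a zero-variance trace")
    if n == 1:
        return ClusterResult(
            labels=np.array([1]), metric=metric, linkage=linkage_method, k=1,
            cophenetic_order=np.array([0]),
        )
    dmat = pdist(data, metric=metric)
    Z = linkage(dmat, method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # canonical relabeling by first occurrence
    mapping: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    return ClusterResult(
        labels=labels,
        metric=metric,
        linkage=linkage_method,
        k=int(labels.max()),
        cophenetic_order=np.asarray(leaves_list(Z)),
    )


def average_trace(
    tm: TraceMatrix, condition_labels: list[str] | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and standard deviation of traces per condition.

    Returns ``{condition: (mean, sd)}`` with vectors of length n_time.
    With no labels, all traces form one condition named "all".
    """
    labels = condition_labels or tm.condition_labels
    if labels is None:
        labels = ["all"] * tm.n_cells
    if len(labels) != tm.n_cells:
        raise ParameterError("condition labels must cover all traces")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond in dict.fromkeys(labels):  # preserve first-seen order
        cols = [j for j, lab in enumerate(labels) if lab == cond]
        block = tm.values[:, cols]
        out[cond] = (block.mean(axis=1), block.std(axis=1, ddof=0))
    return out
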