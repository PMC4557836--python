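"""Nodal graph-theory measures on non-directed weighted connectivity matrices.

Four measures are computed per node:

* **degree** — number of links with strictly positive weight.
* **strength** — sum of incident weights (the standard weighted degree).
* **clustering** — Onnela weighted clustering coefficient: with weights
  normalized by the global maximum, ``C_i = (1/(k_i (k_i-1))) *
  sum_{j,h} (w_ij w_ih w_jh)^(1/3)`` over ordered neighbor pairs; 0 when a
  node has fewer than two neighbors.
* **betweenness** — shortest-path betweenness with edge length 1/weight
  (zero weight = no edge), fractional counting of tied geodesics, and the
  ``2/((n-1)(n-2))`` normalization so values lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import ConnectivityMatrix

METRIC_NAMES = ("degree", "strength", "clustering", "betweenness")


@dataclass
class NodalMetricVector:
    """One value per ROI for a single nodal measure, with provenance."""

    metric_name: str
    values: np.ndarray
    subject_id: str | None = None
    session_id: str | None = None
    method: str | None = None
    roi_keys: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")
        self.values = np.asarray(self.values, dtype=float)


def _provenance(matrix: ConnectivityMatrix) -> dict:
    return {
        "subject_id": matrix.subject_id,
        "session_id": matrix.session_id,
        "method": matrix.method,
        "roi_keys": matrix.roi_table.keys,
    }


def degree(matrix: ConnectivityMatrix) -> NodalMetricVector:
    """Count of strictly positive incident weights per node."""
    k = (matrix.weights > 0).sum(axis=1)
    return NodalMetricVector("degree", k.astype(float), **_provenance(matrix))


def strength(matrix: ConnectivityMatrix) -> NodalMetricVector:
    """Sum of incident weights per node (weighted degree)."""
    return NodalMetricVector("strength", matrix.weights.sum(axis=1), **_provenance(matrix))


def clustering_coefficient(matrix: ConnectivityMatrix) -> NodalMetricVector:
    """Onnela weighted clustering coefficient per node.

    Vectorized as ``cyc3 = diag((W^(1/3))^3)`` on the max-normalized weight
    matrix, divided by ``k_i (k_i - 1)``; nodes with degree < 2 get 0.
    """
    w = matrix.weights
    wmax = w.max()
    if wmax == 0:
        return NodalMetricVector("clustering", np.zeros(w.shape[0]), **_provenance(matrix))
    w_hat = (w / wmax) ** (1.0 / 3.0)
    cyc3 = np.diagonal(w_hat @ w_hat @ w_hat)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc3 / denom, 0.0)
    return NodalMetricVector("clustering", c, **_provenance(matrix))


def betweenness(matrix: ConnectivityMatrix) -> NodalMetricVector:
    """Normalized weighted shortest-path betweenness centrality per node.

    Edge length is the reciprocal weight; ties among equal-length geodesics
    are split fractionally (Brandes accumulation, via networkx).
    """
    w = matrix.weights
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(w, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / w[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    vals = np.array([bc[i] for i in range(n)])
    return NodalMetricVector("betweenness", vals, **_provenance(matrix))


_METRIC_FUNCS = {
    "degree": degree,
    "strength": strength,
    "clustering": clustering_coefficient,
    "betweenness": betweenness,
}


def compute_metric(matrix: ConnectivityMatrix, metric_name: str) -> NodalMetricVector:
    """Dispatch a nodal metric by name, caching per matrix (weights are
    immutable after construction)."""
    if metric_name not in _METRIC_FUNCS:
        raise ValueError(
            f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}"
        )
    cache = getattr(matrix, "_metric_cache", None)
    if cache is None:
        cache = {}
        matrix._metric_cache = cache
    if metric_name not in cache:
        cache[metric_name] = _METRIC_FUNCS[metric_name](matrix)
    return cache[metric_name]
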