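"""Weighted graph metrics: strength, degree, path length, clustering.

Conventions (deliberately those of the source-network literature this
pipeline serves, some of which differ from common toolbox defaults):

* node strength S_i = (1/N) sum_j w_ij — note the 1/N normalization; the
  classic unnormalized sum is available via ``normalized=False``;
* network values SA, DA, LA, CA are plain means over all N nodes;
* path lengths use edge lengths 1/w_ij, and an unreachable pair contributes
  L_ij = 0 to the average (which makes sparser graphs look "shorter" — a
  convention, kept deliberately);
* the clustering coefficient is the geometric-mean (Onnela) form with
  weights first normalized by the network's maximum weight, so C_i is in
  [0, 1] and reduces to the unweighted clustering coefficient on binary
  graphs.

Metrics are computed on the positive-connection subnetwork by default
(``edge_policy="positive"``); absolute-value weighting is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .bands import BandDefinition
from .connectivity import ThresholdedNetwork

__all__ = [
    "GraphMetricsResult",
    "node_strength",
    "network_strength",
    "network_degree",
    "path_length_matrix",
    "average_path_length",
    "clustering_coefficient",
    "network_clustering",
    "compute_metrics",
    "metrics_table",
]


@dataclass
class GraphMetricsResult:
    """Network-level metrics (with per-node vectors) for one subject x band."""

    SA: float
    DA: float
    LA: float
    CA: float
    Si: np.ndarray
    di: np.ndarray
    Ci: np.ndarray
    band: BandDefinition | str
    subject_id: str | int | None = None


def _weights(net: ThresholdedNetwork | np.ndarray, edge_policy: str) -> np.ndarray:
    if isinstance(net, ThresholdedNetwork):
        W = net.weight_matrix(edge_policy)
    else:
        W = np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if (W < 0).any():
        raise ValueError("graph metrics require non-negative weights (use edge_policy 'positive' or 'absolute')")
    return W


def node_strength(
    net: ThresholdedNetwork | np.ndarray,
    node: int | None = None,
    edge_policy: str = "positive",
    normalized: bool = True,
) -> float | np.ndarray:
    """S_i = (1/N) sum_j w_ij (or the raw sum with ``normalized=False``)."""
    W = _weights(net, edge_policy)
    s = W.sum(axis=1)
    if normalized:
        s = s / W.shape[0]
    return float(s[node]) if node is not None else s


def network_strength(net: ThresholdedNetwork | np.ndarray, edge_policy: str = "positive", normalized: bool = True) -> float:
    """SA: mean node strength."""
    W = _weights(net, edge_policy)
    if W.shape[0] == 0:
        return 0.0
    return float(np.mean(node_strength(W, edge_policy=edge_policy, normalized=normalized)))


def _degrees(W: np.ndarray) -> np.ndarray:
    return (W > 0).sum(axis=1).astype(float)


def network_degree(net: ThresholdedNetwork | np.ndarray, edge_policy: str = "positive") -> float:
    """DA: mean over nodes of the count of incident retained edges."""
    W = _weights(net, edge_policy)
    if W.shape[0] == 0:
        return 0.0
    return float(np.mean(_degrees(W)))


def path_length_matrix(net: ThresholdedNetwork | np.ndarray, edge_policy: str = "positive") -> np.ndarray:
    """Shortest-path distances with edge lengths 1/w; 0 when unreachable or i=j."""
    W = _weights(net, edge_policy)
    n = W.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    D = dijkstra(lengths, directed=False, unweighted=False)
    D[~np.isfinite(D)] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


def average_path_length(net: ThresholdedNetwork | np.ndarray, edge_policy: str = "positive") -> float:
    """LA = (1/(N(N-1))) sum_{i != j} L_ij, unreachable pairs counted as 0."""
    D = path_length_matrix(net, edge_policy)
    n = D.shape[0]
    if n < 2:
        return 0.0
    return float(D.sum() / (n * (n - 1)))


def clustering_coefficient(
    net: ThresholdedNetwork | np.ndarray, node: int | None = None, edge_policy: str = "positive"
) -> float | np.ndarray:
    """Geometric-mean weighted clustering, weights max-normalized.

    C_i = (1/(d_i (d_i - 1))) * sum_{j,k} (w'_ij w'_jk w'_ki)^(1/3) over
    ordered neighbor pairs, with w' = w / max(w); C_i = 0 when d_i < 2.
    """
    W = _weights(net, edge_policy)
    n = W.shape[0]
    if n == 0:
        return np.zeros(0) if node is None else 0.0
    wmax = W.max()
    Wn = W / wmax if wmax > 0 else W
    M = np.cbrt(Wn)
    num = np.diagonal(M @ M @ M).copy()
    d = _degrees(W)
    denom = d * (d - 1)
    Ci = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return float(Ci[node]) if node is not None else Ci


def network_clustering(net: ThresholdedNetwork | np.ndarray, edge_policy: str = "positive") -> float:
    """CA: mean clustering coefficient over all nodes."""
    W = _weights(net, edge_policy)
    if W.shape[0] == 0:
        return 0.0
    return float(np.mean(clustering_coefficient(W, edge_policy=edge_policy)))


def compute_metrics(
    net: ThresholdedNetwork,
    subject_id: str | int | None = None,
    edge_policy: str = "positive",
    normalized_strength: bool = True,
) -> GraphMetricsResult:
    """All four network metrics plus per-node vectors for one network."""
    W = net.weight_matrix(edge_policy)
    Si = node_strength(W, edge_policy=edge_policy, normalized=normalized_strength)
    Ci = clustering_coefficient(W, edge_policy=edge_policy)
    return GraphMetricsResult(
        SA=float(np.mean(Si)) if len(Si) else 0.0,
        DA=network_degree(W, edge_policy),
        LA=average_path_length(W, edge_policy),
        CA=float(np.mean(Ci)) if len(Ci) else 0.0,
        Si=Si,
        di=_degrees(W),
        Ci=Ci,
        band=net.band,
        subject_id=subject_id,
    )


def metrics_table(results: list[tuple[GraphMetricsResult, str]]) -> pd.DataFrame:
    """One row per subject x band: subject_id, group, band, SA, DA, LA, CA."""
    rows = []
    for res, group in results:
        band = res.band.name if hasattr(res.band, "name") else str(res.band)
        rows.append(
            {
                "subject_id": res.subject_id,
                "group": group,
                "band": band,
                "SA": res.SA,
                "DA": res.DA,
                "LA": res.LA,
                "CA": res.CA,
            }
        )
    return pd.DataFrame(rows)
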