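"""Correlation networks thresholded by a t-type statistic.

For each pair of source signals the Pearson correlation

    R(Xa, Xb) = C(Xa, Xb) / (S_Xa S_Xb)

is computed over the clean analysis window (C the sample covariance, S the
sample standard deviations), then transformed to the t-type statistic

    TP = R * sqrt(K - 2) / sqrt(1 - R^2)

with K the number of samples. An edge is retained when |TP| exceeds the
two-sided Student-t critical value at significance alpha (default .01) with
K - 2 degrees of freedom; retained edges carry weight |R| and the sign of R
(positive vs negative connections).

Note on degrees of freedom: K is the raw sample count by default, matching
the thresholding rule as published. Band-limited signals are autocorrelated,
so the nominal K overstates the effective degrees of freedom; an optional
Bartlett-type (Pyper-Peterman) effective-K correction is exposed via
``k_policy="bartlett"`` and is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import stats

from .bands import BandDefinition
from .preprocessing import CleanSegment

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "pairwise_correlation",
    "tp_statistic",
    "tp_critical",
    "effective_sample_size",
    "threshold_network",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric pairwise correlation matrix with its sample count."""

    R: np.ndarray
    K: int
    band: BandDefinition | str
    node_labels: list[str]
    node_roles: list[str] = field(default_factory=list)
    K_eff: np.ndarray | None = None  # per-pair effective sample counts

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if np.abs(R).max() > 1 + 1e-12:
            raise ValueError("|R| must not exceed 1")
        self.R = R

    @property
    def n_nodes(self) -> int:
        return self.R.shape[0]


@dataclass
class ThresholdedNetwork:
    """Signed weighted graph of significant connections.

    ``edges`` rows are (i, j, weight, sign, tp) with i < j, weight = |R| and
    sign in {+1, -1}.
    """

    N: int
    edges: list[tuple[int, int, float, int, float]]
    tp_crit: float
    alpha: float
    K: int
    band: BandDefinition | str
    node_labels: list[str]
    node_roles: list[str] = field(default_factory=list)

    @property
    def k_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        pairs = self.N * (self.N - 1) / 2
        return self.k_edges / pairs if pairs else 0.0

    def weight_matrix(self, edge_policy: str = "positive") -> np.ndarray:
        """N x N weight matrix under an edge-selection policy.

        ``positive`` keeps only positive connections (default for graph
        metrics), ``absolute`` keeps all with weight |R|, ``signed`` keeps
        all with signed weight R.
        """
        W = np.zeros((self.N, self.N))
        for i, j, w, sign, _ in self.edges:
            if edge_policy == "positive":
                if sign > 0:
                    W[i, j] = W[j, i] = w
            elif edge_policy == "absolute":
                W[i, j] = W[j, i] = w
            elif edge_policy == "signed":
                W[i, j] = W[j, i] = sign * w
            else:
                raise ValueError(f"unknown edge_policy {edge_policy!r}")
        return W


def pairwise_correlation(seg: CleanSegment) -> ConnectivityMatrix:
    """Pearson correlation of every node pair over the analysis window."""
    x = np.asarray(seg.data, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need K >= 3 samples")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [seg.node_labels[i] for i in dead]
        raise ValueError(f"zero-variance channel(s): {names}")
    R = np.corrcoef(x, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return ConnectivityMatrix(
        R=R,
        K=x.shape[0],
        band=seg.band,
        node_labels=list(seg.node_labels),
        node_roles=list(getattr(seg, "node_roles", []) or []),
    )


def tp_statistic(R: float | np.ndarray, K: int | np.ndarray):
    """t-type transform of a correlation: TP = R sqrt(K-2) / sqrt(1-R^2).

    |R| = 1 maps to signed infinity. Scalar or array arguments.
    """
    R_arr = np.asarray(R, dtype=float)
    K_arr = np.asarray(K, dtype=float)
    if np.any(K_arr < 3):
        raise ValueError("K must be >= 3")
    if np.any(np.abs(R_arr) > 1):
        raise ValueError("|R| must not exceed 1")
    with np.errstate(divide="ignore"):
        out = R_arr * np.sqrt(K_arr - 2) / np.sqrt(1.0 - R_arr**2)
    out = np.where(np.abs(R_arr) == 1.0, np.where(R_arr > 0, np.inf, -np.inf), out)
    return float(out) if np.isscalar(R) and np.isscalar(K) else out


def tp_critical(alpha: float = 0.01, K: int | np.ndarray = 3):
    """Two-sided Student-t critical value at *alpha* with K-2 df."""
    K_arr = np.asarray(K, dtype=float)
    if np.any(K_arr < 3):
        raise ValueError("K must be >= 3")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    crit = stats.t.ppf(1.0 - alpha / 2.0, K_arr - 2)
    return float(crit) if np.isscalar(K) else crit


def effective_sample_size(seg: CleanSegment, max_lag: int | None = None) -> np.ndarray:
    """Pyper-Peterman effective sample counts for every node pair.

    1/K_eff = 1/K + (2/K) * sum_l (1 - l/K) r_a(l) r_b(l), with per-channel
    autocorrelations r(l) estimated by FFT and the sum truncated at
    ``max_lag`` (default min(K-3, 10 * K**0.5)). Values clipped to [3, K].
    """
    x = np.asarray(seg.data, dtype=float)
    K, m = x.shape
    if max_lag is None:
        max_lag = int(min(K - 3, 10 * math.sqrt(K)))
    xc = x - x.mean(axis=0)
    nfft = sp_fft.next_fast_len(K + max_lag + 1)
    spec = sp_fft.rfft(xc, n=nfft, axis=0)
    acov = sp_fft.irfft(np.abs(spec) ** 2, n=nfft, axis=0)[: max_lag + 1]
    acorr = acov / acov[0]
    w = 1.0 - np.arange(1, max_lag + 1) / K
    A = acorr[1:] * np.sqrt(w)[:, None]  # split taper symmetrically across the pair product
    S = A.T @ A
    inv_keff = (1.0 + 2.0 * S) / K
    K_eff = np.clip(1.0 / inv_keff, 3.0, K)
    np.fill_diagonal(K_eff, K)
    return K_eff


def threshold_network(
    cm: ConnectivityMatrix, alpha: float = 0.01, k_policy: str = "nominal"
) -> ThresholdedNetwork:
    """Retain edge (i, j) iff |TP(R_ij, K)| exceeds the critical value.

    ``k_policy="nominal"`` uses the raw sample count for every pair (the
    rule as published); ``"bartlett"`` uses per-pair effective sample counts
    (requires ``cm.K_eff``).
    """
    if k_policy == "nominal":
        K_pair = np.full_like(cm.R, float(cm.K))
    elif k_policy == "bartlett":
        if cm.K_eff is None:
            raise ValueError("k_policy='bartlett' requires cm.K_eff (see effective_sample_size)")
        K_pair = np.asarray(cm.K_eff, dtype=float)
    else:
        raise ValueError(f"unknown k_policy {k_policy!r}")
    tp = tp_statistic(cm.R, K_pair)
    crit = tp_critical(alpha, K_pair)
    edges = []
    for i in range(cm.n_nodes):
        for j in range(i + 1, cm.n_nodes):
            if np.abs(tp[i, j]) > crit[i, j]:
                r = cm.R[i, j]
                edges.append((i, j, abs(float(r)), 1 if r > 0 else -1, float(tp[i, j])))
    return ThresholdedNetwork(
        N=cm.n_nodes,
        edges=edges,
        tp_crit=float(tp_critical(alpha, cm.K)),
        alpha=alpha,
        K=cm.K,
        band=cm.band,
        node_labels=list(cm.node_labels),
        node_roles=list(cm.node_roles),
    )
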