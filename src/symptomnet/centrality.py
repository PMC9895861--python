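"""Centrality indices on weighted correlation networks.

Three node-importance indices are computed on the absolute-weight graph:

* **strength** -- sum of absolute incident edge weights;
* **closeness** -- harmonic-free classic closeness on shortest-path distances
  with edge length d = 1/|r|, multiplied by the reachable-fraction penalty
  (n_reachable - 1)/(n - 1) so disconnected graphs stay on the [0, 1] scale;
* **betweenness** -- shortest-path betweenness with fractional (Brandes)
  credit over tied geodesics, normalized by (n-1)(n-2)/2.

Reported values are standardized to [0, 1].  Two standardization modes exist
because published analyses are ambiguous between them: ``"theoretical-max"``
divides strength by (n - 1) (valid since |r| <= 1; closeness and normalized
betweenness are already <= 1), while ``"observed-max"`` divides each index by
its maximum over nodes so the top node scores exactly 1.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import MissingItemError
from .network import SpearmanNetwork

__all__ = [
    "weight_to_distance",
    "shortest_paths",
    "strength",
    "closeness",
    "betweenness",
    "standardize",
    "rank_nodes",
    "NetworkCentrality",
]

MODES = ("theoretical-max", "observed-max")
_TIE_TOL = 1e-12


def weight_to_distance(r):
    """Edge length for a correlation weight: d = 1/|r|, no edge for r = 0.

    Stronger association means shorter distance; since |r| <= 1 every finite
    distance is >= 1.  Scalar or array input; zero weight maps to +inf.
    """
    r = np.abs(np.asarray(r, dtype=float))
    if np.any(r > 1.0 + 1e-12):
        raise ValueError("|r| must be <= 1")
    with np.errstate(divide="ignore"):
        d = np.where(r > 0.0, 1.0 / np.where(r > 0.0, r, 1.0), np.inf)
    return d if d.ndim else float(d)


def _coerce(network) -> tuple[list[str], np.ndarray]:
    """Accept SpearmanNetwork / DataFrame / ndarray / nx.Graph -> (nodes, W)."""
    if isinstance(network, SpearmanNetwork):
        df = network.correlation_
        return list(df.columns), df.to_numpy(dtype=float)
    if isinstance(network, pd.DataFrame):
        return [str(c) for c in network.columns], network.to_numpy(dtype=float)
    if isinstance(network, nx.Graph):
        nodes = list(network.nodes)
        W = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
        return [str(n) for n in nodes], W
    W = np.asarray(network, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    return [str(i) for i in range(W.shape[0])], W


def _abs_weights(W: np.ndarray) -> np.ndarray:
    A = np.abs(np.asarray(W, dtype=float)).copy()
    np.fill_diagonal(A, 0.0)
    return A


def _graph(nodes: Sequence[str], A: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0.0:
                G.add_edge(nodes[i], nodes[j], distance=1.0 / A[i, j])
    return G


def shortest_paths(network) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs shortest-path distances and geodesic counts.

    Distances use edge length 1/|r|; unreachable pairs are +inf with a count
    of 0.  Counts accumulate over all tied geodesics (ties resolved within
    1e-12 relative tolerance), the bookkeeping betweenness fractions need.
    """
    nodes, W = _coerce(network)
    A = _abs_weights(W)
    G = _graph(nodes, A)
    n = len(nodes)
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(nodes)}
    for s in nodes:
        dist = nx.single_source_dijkstra_path_length(G, s, weight="distance")
        order = sorted(dist, key=dist.get)
        sigma = {s: 1.0}
        for v in order:
            if v == s:
                continue
            sigma[v] = 0.0
            for u in G.neighbors(v):
                du = dist.get(u)
                if du is None:
                    continue
                if abs(du + G[u][v]["distance"] - dist[v]) <= _TIE_TOL * max(
                    1.0, dist[v]
                ):
                    sigma[v] += sigma.get(u, 0.0)
        i = idx[s]
        for v, d in dist.items():
            D[i, idx[v]] = d
            S[i, idx[v]] = sigma[v]
        D[i, i] = 0.0
        S[i, i] = 1.0
    return (
        pd.DataFrame(D, index=nodes, columns=nodes),
        pd.DataFrame(S, index=nodes, columns=nodes),
    )


def _strength_all(A: np.ndarray) -> np.ndarray:
    return A.sum(axis=1)


def _closeness_all(nodes: Sequence[str], A: np.ndarray) -> np.ndarray:
    G = _graph(nodes, A)
    c = nx.closeness_centrality(G, distance="distance", wf_improved=True)
    return np.array([c[v] for v in nodes])


def _betweenness_all(nodes: Sequence[str], A: np.ndarray) -> np.ndarray:
    G = _graph(nodes, A)
    b = nx.betweenness_centrality(G, weight="distance", normalized=True)
    return np.array([b[v] for v in nodes])


def _single(network, node, fn):
    nodes, W = _coerce(network)
    if node not in nodes:
        raise MissingItemError(f"unknown node {node!r}")
    return float(fn(nodes, _abs_weights(W))[nodes.index(node)])


def strength(network, node) -> float:
    """Raw strength of one node: sum of absolute incident weights."""
    return _single(network, node, lambda nodes, A: _strength_all(A))


def closeness(network, node) -> float:
    """Raw (component-penalized) closeness of one node; isolated node -> 0."""
    return _single(network, node, _closeness_all)


def betweenness(network, node) -> float:
    """Normalized shortest-path betweenness of one node."""
    return _single(network, node, _betweenness_all)


def standardize(report: pd.DataFrame, mode: str = "theoretical-max") -> pd.DataFrame:
    """Add standardized columns ``r_s``, ``r_c``, ``r_b`` to a raw report.

    ``report`` must carry ``strength_raw``, ``closeness_raw``,
    ``betweenness_raw`` columns, one row per node, plus the node count context
    implied by its length.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    out = report.copy()
    n = len(out)
    if mode == "theoretical-max":
        out["r_s"] = out["strength_raw"] / max(n - 1, 1)
        out["r_c"] = out["closeness_raw"]
        out["r_b"] = out["betweenness_raw"]
    else:
        for raw, std in (
            ("strength_raw", "r_s"),
            ("closeness_raw", "r_c"),
            ("betweenness_raw", "r_b"),
        ):
            mx = out[raw].max()
            if mx == 0.0:
                warnings.warn(
                    f"all-zero {raw}: observed-max standardization yields zeros",
                    UserWarning,
                    stacklevel=2,
                )
                out[std] = 0.0
            else:
                out[std] = out[raw] / mx
    return out


def _competition_rank(values: pd.Series) -> pd.Series:
    """Descending rank 1..n, ties broken lexicographically by node id."""
    order = sorted(values.index, key=lambda v: (-values[v], str(v)))
    return pd.Series({v: i + 1 for i, v in enumerate(order)}, name=values.name)


def rank_nodes(report: pd.DataFrame) -> pd.DataFrame:
    """Per-index descending rankings plus a mean-rank consensus.

    Adds ``rank_strength``, ``rank_closeness``, ``rank_betweenness`` (1 =
    most central, ties lexicographic), ``mean_rank`` and ``consensus_rank``
    (ranking of the mean rank, ties lexicographic).
    """
    out = report.copy()
    out["rank_strength"] = _competition_rank(out["r_s"])
    out["rank_closeness"] = _competition_rank(out["r_c"])
    out["rank_betweenness"] = _competition_rank(out["r_b"])
    out["mean_rank"] = out[
        ["rank_strength", "rank_closeness", "rank_betweenness"]
    ].mean(axis=1)
    out["consensus_rank"] = _competition_rank(-out["mean_rank"])
    return out


class NetworkCentrality(BaseEstimator):
    """Estimator computing raw and standardized centrality indices.

    Accepts a fitted :class:`~symptomnet.network.SpearmanNetwork`, a symmetric
    weight DataFrame/array, or a networkx Graph with ``weight`` attributes.

    Parameters
    ----------
    mode : {"theoretical-max", "observed-max"}, default "theoretical-max"
        Standardization of the reported r_S / r_C / r_B values.

    Attributes
    ----------
    report_ : pandas.DataFrame
        One row per node: ``strength_raw``, ``closeness_raw``,
        ``betweenness_raw``, ``r_s``, ``r_c``, ``r_b`` and rank columns.
    strength_, closeness_, betweenness_ : pandas.Series
        Raw indices by node.
    r_s_, r_c_, r_b_ : pandas.Series
        Standardized indices by node.
    mode_ : str
        The standardization mode actually applied.
    """

    def __init__(self, mode: str = "theoretical-max"):
        self.mode = mode

    def fit(self, X, y=None) -> "NetworkCentrality":
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        nodes, W = _coerce(X)
        if np.max(np.abs(W - W.T)) > 1e-10:
            raise ValueError("weight matrix must be symmetric")
        A = _abs_weights(W)
        raw = pd.DataFrame(
            {
                "strength_raw": _strength_all(A),
                "closeness_raw": _closeness_all(nodes, A),
                "betweenness_raw": _betweenness_all(nodes, A),
            },
            index=pd.Index(nodes, name="node"),
        )
        report = rank_nodes(standardize(raw, self.mode))
        self.nodes_ = nodes
        self.report_ = report
        self.strength_ = report["strength_raw"]
        self.closeness_ = report["closeness_raw"]
        self.betweenness_ = report["betweenness_raw"]
        self.r_s_ = report["r_s"]
        self.r_c_ = report["r_c"]
        self.r_b_ = report["r_b"]
        self.mode_ = self.mode
        return self

    def top_nodes(self, k: int = 3) -> list[str]:
        """The k most central nodes by consensus rank."""
        return list(self.report_.sort_values("consensus_rank").index[:k])
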