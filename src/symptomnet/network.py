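"""Spearman correlation networks over symptoms and symptom clusters.

The network is a weighted undirected graph whose nodes are the instrument's 40
items (single-symptom network) or the six cluster sum composites plus the four
standalone items (cluster network), and whose edge weights are pairwise
Spearman rank correlations computed on raw ordinal scores with mid-rank tie
handling.  No thresholding or regularization is applied by default: every
pairwise correlation is retained as a weighted edge, matching the plain
estimation the analysis describes; an optional ``min_abs_weight`` zeroes weak
edges for display.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import UndefinedCorrelationError
from .instrument import InstrumentConfig
from .scoring import cluster_score

__all__ = [
    "spearman_rho",
    "SpearmanNetwork",
    "correlation_matrix",
    "build_cluster_nodes",
    "top_edges",
]

logger = logging.getLogger(__name__)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average (mid) ranks.  Requires equal-length vectors with at
    least 3 observations; a constant vector has no defined rank correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("rank correlation of a constant vector")
    return float(stats.spearmanr(x, y).statistic)


class SpearmanNetwork(BaseEstimator):
    """Estimator of a Spearman correlation network from a response matrix.

    Parameters
    ----------
    min_abs_weight : float, default 0.0
        Edges with \\|rho\\| below this are set to zero (the network stays fully
        estimated; this is a sparsification of the stored weights).
    on_constant : {"raise", "drop"}, default "raise"
        Constant columns have undefined rank correlations.  ``"drop"`` removes
        the offending nodes (recorded in ``dropped_nodes_``) with a warning;
        ``"raise"`` fails.

    Attributes
    ----------
    nodes_ : list of str
        Node ids, in input column order (minus dropped nodes).
    correlation_ : pandas.DataFrame
        Symmetric matrix of Spearman rho with unit diagonal.
    dropped_nodes_ : list of str
        Constant columns removed when ``on_constant="drop"``.
    n_samples_ : int
        Number of participants the network was estimated from.
    threshold_applied_ : tuple(bool, float)
        Whether ``min_abs_weight`` zeroed any stored weights, and its value.
    """

    def __init__(self, min_abs_weight: float = 0.0, on_constant: str = "raise"):
        self.min_abs_weight = min_abs_weight
        self.on_constant = on_constant

    def fit(self, X, y=None) -> "SpearmanNetwork":
        if self.on_constant not in ("raise", "drop"):
            raise ValueError("on_constant must be 'raise' or 'drop'")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        if X.isna().any().any():
            raise ValueError("response matrix contains missing values; "
                             "apply exclude_incomplete first")
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least 2 items")
        if n < 3:
            raise ValueError("need at least 3 participants")

        values = X.to_numpy(dtype=float)
        constant = [c for j, c in enumerate(X.columns)
                    if np.all(values[:, j] == values[0, j])]
        if constant:
            if self.on_constant == "raise":
                raise UndefinedCorrelationError(
                    f"constant columns {constant} have undefined rank correlations"
                )
            warnings.warn(
                f"dropping constant columns {constant}", UserWarning, stacklevel=2
            )
            X = X.drop(columns=constant)
            values = X.to_numpy(dtype=float)
            p = values.shape[1]
            if p < 2:
                raise UndefinedCorrelationError(
                    "fewer than 2 nonconstant columns remain"
                )
        self.dropped_nodes_ = constant

        if p == 2:
            r = stats.spearmanr(values[:, 0], values[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
        else:
            rho = np.asarray(stats.spearmanr(values).statistic)
        rho = (rho + rho.T) / 2.0
        np.fill_diagonal(rho, 1.0)
        thresholded = False
        if self.min_abs_weight > 0.0:
            mask = np.abs(rho) < self.min_abs_weight
            np.fill_diagonal(mask, False)
            thresholded = bool(mask.any())
            rho[mask] = 0.0
        self.threshold_applied_ = (thresholded, float(self.min_abs_weight))
        self.nodes_ = list(X.columns)
        self.correlation_ = pd.DataFrame(rho, index=self.nodes_, columns=self.nodes_)
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    # -- views -------------------------------------------------------------
    def to_graph(self) -> nx.Graph:
        """networkx Graph with ``weight`` (rho) and ``distance`` (1/|rho|) attrs."""
        W = self.correlation_.to_numpy()
        G = nx.Graph()
        G.add_nodes_from(self.nodes_)
        for i in range(len(self.nodes_)):
            for j in range(i + 1, len(self.nodes_)):
                w = W[i, j]
                if w != 0.0:
                    G.add_edge(
                        self.nodes_[i],
                        self.nodes_[j],
                        weight=float(w),
                        distance=1.0 / abs(float(w)),
                    )
        return G

    def edge_list(self) -> pd.DataFrame:
        return top_edges(self.correlation_, k=None)

    def top_edges(self, k: int) -> pd.DataFrame:
        return top_edges(self.correlation_, k)


def correlation_matrix(X, **kwargs) -> SpearmanNetwork:
    """Fit and return a :class:`SpearmanNetwork` (thin functional wrapper)."""
    return SpearmanNetwork(**kwargs).fit(X)


def build_cluster_nodes(
    matrix: pd.DataFrame, instrument: InstrumentConfig
) -> pd.DataFrame:
    """Composite matrix for the cluster-level network.

    One column per cluster (sum of member items, in the instrument's cluster
    order) followed by the standalone item columns -- ten columns for the
    canonical configuration.
    """
    cols = [
        cluster_score(matrix, instrument, c) for c in instrument.cluster_names
    ] + [matrix[i] for i in instrument.standalone_items]
    return pd.concat(cols, axis=1)


def top_edges(weights, k: int | None = 3) -> pd.DataFrame:
    """Edges ranked by \\|rho\\| descending, ties lexicographic by node pair.

    ``weights`` is a symmetric DataFrame (or a fitted :class:`SpearmanNetwork`).
    Zero-weight pairs are not edges.  ``k=None`` returns the full list; ``k``
    beyond the edge count returns the whole (truncated) list with a warning.
    """
    if isinstance(weights, SpearmanNetwork):
        weights = weights.correlation_
    W = weights.to_numpy() if isinstance(weights, pd.DataFrame) else np.asarray(weights)
    nodes = (
        list(weights.columns)
        if isinstance(weights, pd.DataFrame)
        else [str(i) for i in range(W.shape[0])]
    )
    records = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if W[i, j] != 0.0:
                a, b = sorted((nodes[i], nodes[j]))
                records.append((a, b, float(W[i, j])))
    records.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    if k is not None and k > len(records):
        warnings.warn(
            f"requested top {k} edges but only {len(records)} exist",
            UserWarning,
            stacklevel=2,
        )
    if k is not None:
        records = records[:k]
    return pd.DataFrame(records, columns=["node_a", "node_b", "r"])
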