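"""Force-directed (Fruchterman-Reingold) placement of network nodes.

Nodes repel like charged particles (k^2 / d) and connected nodes attract in
proportion to the absolute edge weight (w * d^2 / k), with k = sqrt(area / n)
the ideal pairwise spacing.  Displacements are capped by a linearly cooling
temperature, so strongly inter-correlated nodes settle near the centre of the
figure.  Initial positions are seeded uniform draws; the final configuration
is centred on its centroid and uniformly rescaled so the layout fits in
[-1, 1]^2.  The uniform (rather than per-axis) rescaling keeps pairwise
distances equivariant under rotations of the initial placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .centrality import _coerce

__all__ = ["LayoutResult", "FruchtermanReingoldLayout", "fruchterman_reingold"]


@dataclass(frozen=True)
class LayoutResult:
    """2-D node coordinates plus the reproducibility parameters that made them."""

    coordinates: pd.DataFrame  # index node, columns x, y
    iterations: int
    seed: int


class FruchtermanReingoldLayout(BaseEstimator):
    """Weighted Fruchterman-Reingold embedding into [-1, 1]^2.

    Parameters
    ----------
    iterations : int, default 500
        Number of cooling steps.
    seed : int, default 0
        Seed for the uniform initial placement.
    area : float, default 1.0
        Notional layout area; sets the ideal spacing k = sqrt(area / n).
    temperature_schedule : "linear" or callable, default "linear"
        Maximum displacement at step i.  ``"linear"`` is
        t0 * (1 - i / iterations) with t0 = 0.1 * sqrt(area); a callable
        receives (i, iterations) and returns the temperature.
    init : ndarray of shape (n, 2), optional
        Explicit initial positions (overrides the seeded draw); used e.g. to
        verify rotation equivariance.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, 2)
        Final normalized coordinates.
    nodes_ : list of str
    """

    def __init__(
        self,
        iterations: int = 500,
        seed: int = 0,
        area: float = 1.0,
        temperature_schedule: str | Callable[[int, int], float] = "linear",
        init: np.ndarray | None = None,
    ):
        self.iterations = iterations
        self.seed = seed
        self.area = area
        self.temperature_schedule = temperature_schedule
        self.init = init

    def _temperature(self, i: int) -> float:
        if callable(self.temperature_schedule):
            return float(self.temperature_schedule(i, self.iterations))
        if self.temperature_schedule == "linear":
            return 0.1 * np.sqrt(self.area) * (1.0 - i / self.iterations)
        raise ValueError("temperature_schedule must be 'linear' or a callable")

    def fit(self, X, y=None) -> "FruchtermanReingoldLayout":
        nodes, W = _coerce(X)
        n = len(nodes)
        A = np.abs(W).astype(float)
        np.fill_diagonal(A, 0.0)
        if n == 1:
            self.nodes_, self.embedding_ = nodes, np.zeros((1, 2))
            return self
        if self.init is not None:
            pos = np.array(self.init, dtype=float)
            if pos.shape != (n, 2):
                raise ValueError(f"init must have shape ({n}, 2)")
        else:
            rng = np.random.default_rng(self.seed)
            half = 0.5 * np.sqrt(self.area)
            pos = rng.uniform(-half, half, size=(n, 2))
        k = np.sqrt(self.area / n)
        for i in range(self.iterations):
            t = self._temperature(i)
            delta = pos[:, None, :] - pos[None, :, :]
            dist = np.linalg.norm(delta, axis=-1)
            np.fill_diagonal(dist, 1.0)
            dist = np.maximum(dist, 1e-9)
            # net per-pair force along delta: repulsion k^2/d minus attraction w d^2/k
            coeff = k * k / dist**2 - A * dist / k
            disp = (delta * coeff[:, :, None]).sum(axis=1)
            length = np.maximum(np.linalg.norm(disp, axis=1), 1e-12)
            pos = pos + disp / length[:, None] * np.minimum(length, t)[:, None]
        pos = pos - pos.mean(axis=0)
        scale = np.linalg.norm(pos, axis=1).max()
        if scale > 0.0:
            pos = pos / scale
        self.nodes_ = nodes
        self.embedding_ = pos
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).embedding_


def fruchterman_reingold(
    network,
    seed: int = 0,
    iterations: int = 500,
    temperature_schedule: str | Callable[[int, int], float] = "linear",
) -> LayoutResult:
    """Functional wrapper returning a :class:`LayoutResult`."""
    est = FruchtermanReingoldLayout(
        iterations=iterations, seed=seed, temperature_schedule=temperature_schedule
    ).fit(network)
    coords = pd.DataFrame(
        est.embedding_, index=pd.Index(est.nodes_, name="node"), columns=["x", "y"]
    )
    return LayoutResult(coordinates=coords, iterations=iterations, seed=seed)
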