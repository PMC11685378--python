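"""Multiplex core-periphery decomposition, coreness, and the disruption index.

The analysis characterizes where each brain region sits on the core-periphery
axis of a multiplex (multi-layer, node-aligned) network:

1. **Density sweep.**  Each layer is filtered at every density ``d`` in a
   grid by keeping its ``m = round(d * N(N-1)/2)`` strongest edges (weights
   retained, not binarized).
2. **Multiplex richness.**  At each density, node richness is the linear
   combination of the node's strengths across filtered layers,
   ``mu_i = sum_a c_a * s_i^a``, with per-layer coefficients ``c_a``
   (default 0.5 each).
3. **Rich core.**  Nodes are ranked by decreasing richness; for each node
   the richer-neighbor strength ``mu_plus`` (strength restricted to nodes
   ranked above it) is computed, and the core boundary is placed at the rank
   where ``mu_plus`` peaks.  Nodes at or above the boundary form the core.
4. **Coreness.**  A node's coreness is the fraction of densities at which it
   falls inside the core — the probability of core membership over the sweep,
   in [0, 1] and an exact multiple of ``1/len(grid)``.
5. **Coreness disruption index (kappa).**  Given a reference coreness profile
   (the HC group mean), kappa is the OLS slope of ``subject - reference``
   regressed on ``reference``.  kappa < 0 means high-coreness (hub) nodes
   lose proportionally more coreness than peripheral ones — the signature of
   a targeted rather than random attack on the network.

Deterministic tie rules (documented, not arbitrary at run time): edges tied
at a density cutoff are kept in ascending (i, j) lexicographic order;
richness ties rank the lower node index first; boundary ties pick the
smallest rank (smallest core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .layers import ConnectivityLayer, MultiplexNetwork

__all__ = [
    "DensityGrid",
    "LayerCoefficients",
    "RichnessVector",
    "CorenessProfile",
    "KappaResult",
    "threshold_layer",
    "multiplex_richness",
    "rich_core",
    "coreness",
    "kappa",
    "group_kappa",
    "CorenessExtractor",
    "CorenessDisruption",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """Strictly increasing edge densities in (0, 1]."""

    densities: np.ndarray = field(
        default_factory=lambda: np.arange(1, 101) / 100.0
    )

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float).ravel()
        if d.size == 0:
            raise ValueError("density grid is empty")
        if np.any(d <= 0) or np.any(d > 1):
            raise ValueError("densities must lie in (0, 1]")
        if np.any(np.diff(d) <= 0):
            raise ValueError("densities must be strictly increasing")
        self.densities = d

    @classmethod
    def from_range(cls, start: float = 0.01, stop: float = 1.0, step: float = 0.01):
        n = int(round((stop - start) / step)) + 1
        return cls(densities=start + step * np.arange(n))

    def __len__(self) -> int:
        return self.densities.size


@dataclass
class LayerCoefficients:
    """Per-layer nonnegative mixing coefficients for multiplex richness."""

    c: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5, 0.5]))

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float).ravel()
        if np.any(c < 0):
            raise ValueError("layer coefficients must be nonnegative")
        if not np.any(c > 0):
            raise ValueError("at least one layer coefficient must be positive")
        self.c = c


@dataclass
class RichnessVector:
    mu: np.ndarray
    mu_plus: np.ndarray


@dataclass
class CorenessProfile:
    coreness: np.ndarray
    grid: DensityGrid
    coefficients: LayerCoefficients
    domain: str = "multiplex"
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.coreness, dtype=float)
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("coreness values must lie in [0, 1]")
        self.coreness = c


@dataclass
class KappaResult:
    """OLS fit of delta-coreness on reference coreness."""

    kappa: float
    intercept: float
    r_squared: float
    delta: np.ndarray
    reference: np.ndarray


# ---------------------------------------------------------------------------
# density filtering
# ---------------------------------------------------------------------------

def _edge_order(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by (-weight, i, j); returns (i, j, order)."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu, ju, order


def _edge_count(density: float, n: int) -> int:
    # round-half-up for a platform-independent edge count
    return int(np.floor(density * (n * (n - 1) // 2) + 0.5))


def threshold_layer(weights: np.ndarray, density: float) -> np.ndarray:
    """Keep the ``m = round(density * N(N-1)/2)`` strongest edges of a layer.

    Retained edges keep their weights; all others are zeroed.  Ties at the
    cutoff are resolved by ascending (i, j) lexicographic order.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    iu, ju, order = _edge_order(w)
    m = _edge_count(density, n)
    keep = order[:m]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = w[iu[keep], ju[keep]]
    out += out.T
    return out


# ---------------------------------------------------------------------------
# richness and rich core
# ---------------------------------------------------------------------------

def _as_weight_list(multiplex) -> list[np.ndarray]:
    if isinstance(multiplex, MultiplexNetwork):
        return multiplex.weight_arrays()
    if isinstance(multiplex, ConnectivityLayer):
        return [multiplex.weights]
    if isinstance(multiplex, np.ndarray):
        return [multiplex]
    return [lay.weights if isinstance(lay, ConnectivityLayer) else np.asarray(lay, float)
            for lay in multiplex]


def _combined(layers: list[np.ndarray], coefficients: LayerCoefficients) -> np.ndarray:
    c = coefficients.c
    if c.size != len(layers):
        raise ValueError(f"{c.size} coefficients for {len(layers)} layers")
    out = np.zeros_like(layers[0])
    for ci, w in zip(c, layers):
        out += ci * w
    return out


def _ranking(mu: np.ndarray) -> np.ndarray:
    """Node indices in decreasing-richness order; ties by ascending index."""
    return np.lexsort((np.arange(mu.size), -mu))


def _mu_plus_ranked(W: np.ndarray, order: np.ndarray) -> np.ndarray:
    """mu_plus, in rank order, from the combined weighted matrix."""
    P = W[np.ix_(order, order)]
    return np.tril(P, k=-1).sum(axis=1)


def multiplex_richness(
    filtered_multiplex,
    coefficients: LayerCoefficients | Sequence[float] = None,
    ranking: Sequence[int] | None = None,
) -> RichnessVector:
    """Multiplex richness ``mu`` and richer-neighbor strength ``mu_plus``.

    ``ranking`` is a strict total order of node indices (rank 0 = richest)
    used to restrict ``mu_plus``; by default the richness ranking itself.
    """
    layers = _as_weight_list(filtered_multiplex)
    if coefficients is None:
        coefficients = LayerCoefficients(np.full(len(layers), 0.5))
    elif not isinstance(coefficients, LayerCoefficients):
        coefficients = LayerCoefficients(np.asarray(coefficients, float))
    W = _combined(layers, coefficients)
    mu = W.sum(axis=1)
    order = np.asarray(ranking, int) if ranking is not None else _ranking(mu)
    mp_ranked = _mu_plus_ranked(W, order)
    mu_plus = np.empty_like(mu)
    mu_plus[order] = mp_ranked
    return RichnessVector(mu=mu, mu_plus=mu_plus)


def rich_core(filtered_multiplex, coefficients=None) -> np.ndarray:
    """Core node indices of a filtered multiplex.

    Nodes are ranked by decreasing richness; the boundary ``r*`` is the rank
    with maximal ``mu_plus`` (first such rank on ties) and the core is ranks
    ``0..r*``.  An edgeless multiplex (all ``mu_plus`` zero) has an empty core.
    """
    layers = _as_weight_list(filtered_multiplex)
    if coefficients is None:
        coefficients = LayerCoefficients(np.full(len(layers), 0.5))
    elif not isinstance(coefficients, LayerCoefficients):
        coefficients = LayerCoefficients(np.asarray(coefficients, float))
    W = _combined(layers, coefficients)
    mu = W.sum(axis=1)
    order = _ranking(mu)
    mp = _mu_plus_ranked(W, order)
    if mp.max(initial=0.0) <= 0.0:
        return np.array([], dtype=int)
    r_star = int(np.argmax(mp))
    return np.sort(order[: r_star + 1])


# ---------------------------------------------------------------------------
# coreness over the density sweep
# ---------------------------------------------------------------------------

def coreness(
    multiplex_or_layer,
    grid: DensityGrid | None = None,
    coefficients: LayerCoefficients | Sequence[float] | None = None,
    domain: str = "multiplex",
) -> CorenessProfile:
    """Fraction of densities at which each node belongs to the rich core.

    Layers are filtered independently at each density.  The sweep is run
    incrementally: edges enter in the same deterministic order the
    per-density filter would select them, so the cumulative network at each
    grid point equals ``threshold_layer`` applied at that density.
    """
    if grid is None:
        grid = DensityGrid()
    layers = _as_weight_list(multiplex_or_layer)
    if coefficients is None:
        coefficients = LayerCoefficients(np.full(len(layers), 0.5))
    elif not isinstance(coefficients, LayerCoefficients):
        coefficients = LayerCoefficients(np.asarray(coefficients, float))
    c = coefficients.c
    if c.size != len(layers):
        raise ValueError(f"{c.size} coefficients for {len(layers)} layers")

    n = layers[0].shape[0]
    labels = (
        multiplex_or_layer.node_labels
        if isinstance(multiplex_or_layer, (MultiplexNetwork, ConnectivityLayer))
        else []
    )
    orders = []
    for w in layers:
        iu, ju, order = _edge_order(w)
        orders.append((iu[order], ju[order], w[iu[order], ju[order]]))

    counts = np.zeros(n)
    W = np.zeros((n, n))
    prev_m = 0
    for d in grid.densities:
        m = _edge_count(float(d), n)
        if m > prev_m:
            for ci, (ei, ej, ew) in zip(c, orders):
                ii, jj, ww = ei[prev_m:m], ej[prev_m:m], ci * ew[prev_m:m]
                W[ii, jj] += ww
                W[jj, ii] += ww
            prev_m = m
        mu = W.sum(axis=1)
        order = _ranking(mu)
        mp = _mu_plus_ranked(W, order)
        if mp.max(initial=0.0) > 0.0:
            counts[order[: int(np.argmax(mp)) + 1]] += 1
    return CorenessProfile(
        coreness=counts / len(grid),
        grid=grid,
        coefficients=coefficients,
        domain=domain,
        node_labels=list(labels),
    )


# ---------------------------------------------------------------------------
# coreness disruption index
# ---------------------------------------------------------------------------

def kappa(subject_coreness, reference_coreness) -> KappaResult:
    """OLS (with intercept) of ``subject - reference`` on ``reference``."""
    s = np.asarray(subject_coreness, dtype=float).ravel()
    r = np.asarray(reference_coreness, dtype=float).ravel()
    if s.size != r.size:
        raise ValueError("subject and reference coreness differ in length")
    if np.ptp(r) == 0:
        raise ValueError("constant reference coreness: slope undefined")
    delta = s - r
    rc = r - r.mean()
    slope = float(rc @ (delta - delta.mean()) / (rc @ rc))
    intercept = float(delta.mean() - slope * r.mean())
    fitted = intercept + slope * r
    ss_res = float(((delta - fitted) ** 2).sum())
    ss_tot = float(((delta - delta.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return KappaResult(
        kappa=slope, intercept=intercept, r_squared=r2, delta=delta, reference=r
    )


def group_kappa(group_coreness_matrix, reference_coreness) -> KappaResult:
    """kappa of the column-wise mean coreness of a group of subjects."""
    m = np.atleast_2d(np.asarray(group_coreness_matrix, dtype=float))
    if m.shape[0] < 1:
        raise ValueError("group must contain at least one subject")
    return kappa(m.mean(axis=0), reference_coreness)


# ---------------------------------------------------------------------------
# estimator facades
# ---------------------------------------------------------------------------

class CorenessExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: multiplex networks -> per-node coreness rows.

    Parameters mirror the sweep: ``grid`` (DensityGrid or None for the
    default 0.01..1.00 step 0.01), ``coefficients`` (per-layer, default 0.5
    each), and ``domain`` ('multiplex' or a single layer kind 'MC'/'SC'/'FC',
    in which case the named layer is extracted with unit coefficient).
    """

    def __init__(self, grid=None, coefficients=None, domain: str = "multiplex"):
        self.grid = grid
        self.coefficients = coefficients
        self.domain = domain

    def fit(self, X: Iterable, y=None):
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        rows = []
        for mx in X:
            if self.domain == "multiplex":
                prof = coreness(mx, self.grid, self.coefficients, domain=self.domain)
            else:
                if isinstance(mx, MultiplexNetwork):
                    idx = [lay.kind for lay in mx.layers].index(self.domain)
                    target = mx.layers[idx]
                else:
                    target = mx
                prof = coreness(target, self.grid, [1.0], domain=self.domain)
            rows.append(prof.coreness)
        return np.vstack(rows)


class CorenessDisruption(BaseEstimator):
    """Coreness disruption index relative to a fitted reference profile.

    ``fit`` takes the HC coreness matrix (subjects x nodes) and stores its
    column mean as the reference; ``transform`` maps any coreness matrix to a
    per-subject kappa vector.
    """

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 1:
            raise ValueError("need at least one reference subject")
        self.reference_ = X.mean(axis=0)
        if np.ptp(self.reference_) == 0:
            raise ValueError("constant reference coreness: slope undefined")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "reference_"):
            raise ValueError("CorenessDisruption is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([kappa(row, self.reference_).kappa for row in X])

    def kappa_result(self, subject_coreness) -> KappaResult:
        if not hasattr(self, "reference_"):
            raise ValueError("CorenessDisruption is not fitted")
        return kappa(subject_coreness, self.reference_)

    def group_kappa(self, X) -> KappaResult:
        if not hasattr(self, "reference_"):
            raise ValueError("CorenessDisruption is not fitted")
        return group_kappa(X, self.reference_)
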