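"""Residual linear graph convolution over the herb-target bipartite graph.

The training-split interactions define a bipartite adjacency A (herbs then
targets in node order).  Propagation is purely linear:

    E^{k+1} = S E^k W^k,      S = D~^{-1/2} (A + I) D~^{-1/2},

with no nonlinearity between layers, and the final node representation is the
residual sum e = E^0 + E^1 + ... + E^K (or E^K alone in the ablated
last-layer mode).  With identity layer weights this is the parameter-free
LightGCN-style propagation; learnable per-layer linear maps are optional.
Pair scores are plain dot products of the final herb and target vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .kg_data import HTIDataset

__all__ = [
    "BipartiteGraph",
    "PropagationState",
    "build_bipartite",
    "normalize",
    "propagate",
    "residual_aggregate",
    "score",
]


@dataclass(frozen=True)
class BipartiteGraph:
    """Herb-target training graph with fixed node order (herbs, then targets)."""

    herbs: tuple[str, ...]
    targets: tuple[str, ...]
    adjacency: sp.csr_matrix  # (n x n), 0/1, symmetric, bipartite

    @property
    def n_nodes(self) -> int:
        return len(self.herbs) + len(self.targets)

    @property
    def n_herbs(self) -> int:
        return len(self.herbs)

    def node_ids(self) -> tuple[str, ...]:
        return self.herbs + self.targets

    def herb_index(self, herb: str) -> int:
        return self.herbs.index(herb)

    def target_index(self, target: str) -> int:
        return self.n_herbs + self.targets.index(target)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class PropagationState:
    """Per-layer embeddings E^0..E^K plus the layer weights used."""

    layers: list[np.ndarray]
    weights: list[np.ndarray] | None  # None => identity at every layer

    @property
    def n_layers(self) -> int:
        return len(self.layers) - 1


def build_bipartite(dataset: HTIDataset, use_split: str = "train") -> BipartiteGraph:
    """Assemble the bipartite adjacency from one split's positive pairs.

    Only the requested split's edges enter the graph; held-out pairs are
    structurally invisible to propagation.  Node order is sorted herbs
    followed by sorted targets.
    """
    herbs = tuple(sorted(dataset.herbs))
    targets = tuple(sorted(dataset.targets))
    pairs = dataset.pairs_in_split(use_split)
    if not pairs:
        raise ValueError(f"split {use_split!r} has no pairs; cannot build graph")
    h_idx = {h: i for i, h in enumerate(herbs)}
    t_idx = {t: len(herbs) + j for j, t in enumerate(targets)}
    n = len(herbs) + len(targets)
    rows, cols = [], []
    for h, t in pairs:
        i, j = h_idx[h], t_idx[t]
        rows += [i, j]
        cols += [j, i]
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    A.data[:] = 1.0  # duplicates collapse to 0/1
    return BipartiteGraph(herbs=herbs, targets=targets, adjacency=A)


def normalize(graph: BipartiteGraph, mode: str = "sqrt") -> sp.csr_matrix:
    """Degree-normalize the self-loop-augmented adjacency.

    ``mode="sqrt"`` (canonical): S = D~^{-1/2} (A+I) D~^{-1/2}, the symmetric
    normalization standard in linear GCNs; entries are
    (A+I)[i,j] / sqrt(d~_i d~_j) with d~ the degree of A+I.

    ``mode="product"``: the per-node coefficient scheme with self term
    1/d~_i and neighbour term a_ij/(d~_i d~_j); kept as a configurable
    alternative reading of the per-node propagation rule (asymmetric).
    """
    A = graph.adjacency
    n = A.shape[0]
    A_tilde = (A + sp.identity(n, format="csr")).tocsr()
    d = np.asarray(A_tilde.sum(axis=1)).ravel()
    if mode == "sqrt":
        inv_sqrt = 1.0 / np.sqrt(d)
        D = sp.diags(inv_sqrt)
        return (D @ A_tilde @ D).tocsr()
    if mode == "product":
        inv = 1.0 / d
        S = sp.diags(inv) @ A @ sp.diags(inv) + sp.diags(inv)
        return S.tocsr()
    raise ValueError(f"unknown normalization mode {mode!r}; use 'sqrt' or 'product'")


def propagate(
    S: sp.spmatrix,
    E0: np.ndarray,
    K: int,
    weights: Sequence[np.ndarray] | None = None,
) -> PropagationState:
    """Run K layers of linear message passing E^{k+1} = S E^k W^k.

    ``weights=None`` uses the identity at every layer, in which case E^K is
    exactly the dense product S^K E^0.  K = 0 returns a state holding E^0
    alone.
    """
    E0 = np.asarray(E0, dtype=float)
    if E0.shape[0] != S.shape[0]:
        raise ValueError(f"E0 has {E0.shape[0]} rows but S is {S.shape[0]}x{S.shape[1]}")
    if K < 0:
        raise ValueError("K must be >= 0")
    if weights is not None:
        if len(weights) != K:
            raise ValueError(f"need {K} weight matrices, got {len(weights)}")
        for W in weights:
            if W.shape != (E0.shape[1], E0.shape[1]):
                raise ValueError(f"weight shape {W.shape} incompatible with dim {E0.shape[1]}")
    layers = [E0]
    for k in range(K):
        E = S @ layers[-1]
        if weights is not None:
            E = E @ weights[k]
        layers.append(E)
    return PropagationState(layers=layers, weights=list(weights) if weights is not None else None)


def residual_aggregate(
    state: PropagationState, mode: str = "residual"
) -> np.ndarray:
    """Fuse per-layer embeddings into final node representations.

    ``residual`` sums all K+1 layer matrices (unweighted), so the initial
    features survive arbitrarily deep propagation; ``last_layer`` is the
    ablation that keeps only E^K.
    """
    if mode == "residual":
        return np.sum(state.layers, axis=0)
    if mode == "last_layer":
        return state.layers[-1]
    raise ValueError(f"unknown aggregation mode {mode!r}; use 'residual' or 'last_layer'")


def score(e_h: np.ndarray, e_t: np.ndarray) -> float:
    """Dot-product affinity of a herb and a target representation."""
    e_h = np.asarray(e_h, dtype=float)
    e_t = np.asarray(e_t, dtype=float)
    if e_h.shape != e_t.shape:
        raise ValueError(f"dimension mismatch: {e_h.shape} vs {e_t.shape}")
    return float(e_h @ e_t)
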