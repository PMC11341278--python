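"""Knowledge-graph embedding pre-training.

Three backends produce an entity -> dense-vector map used as the initial
node features of the downstream graph convolution:

* ``deepwalk`` — uniform random walks over the (undirected, type-blind)
  knowledge graph fed to a skip-gram objective with negative sampling,
  so each entity's vector predicts its windowed walk context;
* ``node2vec`` — the same pipeline with second-order biased walks
  (return parameter ``p``, in-out parameter ``q``); ``p = q = 1`` recovers
  the uniform walk law exactly;
* ``hope`` — truncated SVD factorization of the Katz proximity matrix
  ``S = (I - beta*A)^{-1} beta*A``, concatenating source and target factors
  scaled by square roots of the singular values.

``none`` returns seeded standard-normal vectors scaled by 1/sqrt(dim) — the
no-pre-training ablation.  Relation types and edge directions are ignored
throughout: proximity, not semantics, is what the downstream ranker consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .kg_data import KnowledgeGraph, ParseError

__all__ = [
    "WalkConfig",
    "HopeConfig",
    "WalkCorpus",
    "EmbeddingMatrix",
    "generate_walks",
    "train_skipgram",
    "hope_embed",
    "katz_matrix",
    "pretrain",
    "write_embeddings",
    "read_embeddings",
    "EMBED_METHODS",
]

logger = logging.getLogger(__name__)

EMBED_METHODS = ("deepwalk", "node2vec", "hope", "none")
_UNSUPPORTED = ("line", "grarep")


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk and skip-gram hyper-parameters.

    Defaults follow common DeepWalk practice (10 walks of length 40 per node,
    window 5, 5 negative samples, 5 epochs); every field is configurable.
    ``p``/``q`` are the node2vec return and in-out parameters; 1/1 gives
    uniform first-order walks.
    """

    num_walks_per_node: int = 10
    walk_length: int = 40
    window_size: int = 5
    dimension: int = 64
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.025
    p: float = 1.0
    q: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass(frozen=True)
class HopeConfig:
    """Katz-proximity factorization parameters.

    ``dimension`` must be even (half for the source factor, half for the
    target factor); ``beta`` must satisfy ``beta * spectral_radius(A) < 1``
    for the Katz series to converge.
    """

    dimension: int = 64
    beta: float = 0.05

    def __post_init__(self) -> None:
        if self.dimension <= 0 or self.dimension % 2:
            raise ValueError(f"dimension must be a positive even integer, got {self.dimension}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class WalkCorpus:
    """A list of entity-id walk sequences; consecutive ids are KG edges."""

    walks: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.walks)


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Ordered entity ids with one embedding row each."""

    ids: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError(
                f"vectors must be ({len(self.ids)}, dim), got {self.vectors.shape}"
            )
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def dimension(self) -> int:
        return int(self.vectors.shape[1])

    def index(self) -> dict[str, int]:
        return {e: i for i, e in enumerate(self.ids)}

    def lookup(self, ids: Sequence[str]) -> np.ndarray:
        idx = self.index()
        missing = [e for e in ids if e not in idx]
        if missing:
            raise KeyError(f"entities absent from embedding matrix: {missing[:5]}")
        return self.vectors[[idx[e] for e in ids]]


# ---------------------------------------------------------------------------
# Random walks
# ---------------------------------------------------------------------------

def _adjacency_lists(kg: KnowledgeGraph) -> dict[str, list[str]]:
    nbrs: dict[str, set[str]] = {e: set() for e in kg.entity_ids}
    for a, b in kg.undirected_edges():
        nbrs[a].add(b)
        nbrs[b].add(a)
    return {v: sorted(ns) for v, ns in nbrs.items()}


def generate_walks(kg: KnowledgeGraph, cfg: WalkConfig) -> WalkCorpus:
    """Run ``num_walks_per_node`` seeded walks from every entity.

    The graph is walked as undirected and unlabeled.  With ``p = q = 1`` the
    next node is uniform over neighbours; otherwise the node2vec second-order
    law applies (weight 1/p to return, 1 to nodes at distance one from the
    previous node, 1/q to nodes further out).  A node with no neighbours
    yields a length-1 walk.
    """
    nodes = list(kg.entity_ids)
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in nodes]
    nbr_lists: dict[int, list[int]] = {i: [] for i in range(len(nodes))}
    for a, b in kg.undirected_edges():
        ia, ib = index[a], index[b]
        nbr_lists[ia].append(ib)
        nbr_lists[ib].append(ia)
    for i, ns in nbr_lists.items():
        adj[i] = np.asarray(sorted(ns), dtype=np.int64)

    rng = np.random.default_rng(cfg.seed)
    walks: list[tuple[str, ...]] = []
    isolated_logged = False
    for _ in range(cfg.num_walks_per_node):
        order = rng.permutation(len(nodes))
        for start in order:
            if adj[start].size == 0:
                if not isolated_logged:
                    logger.info("isolated entity %s: emitting length-1 walks", nodes[start])
                    isolated_logged = True
                walks.append((nodes[start],))
                continue
            walk = [int(start)]
            while len(walk) < cfg.walk_length:
                options = adj[walk[-1]]
                if options.size == 0:
                    break
                if len(walk) == 1:
                    nxt = options[rng.integers(options.size)]
                else:
                    # second-order law; with p = q = 1 the weights are equal
                    # and this reduces to the uniform first-order walk
                    prev = walk[-2]
                    w = np.where(
                        np.isin(options, adj[prev], assume_unique=True), 1.0, 1.0 / cfg.q
                    )
                    w[options == prev] = 1.0 / cfg.p
                    cw = np.cumsum(w)
                    nxt = options[np.searchsorted(cw, rng.random() * cw[-1], side="right")]
                walk.append(int(nxt))
            walks.append(tuple(nodes[i] for i in walk))
    return WalkCorpus(walks=tuple(walks))


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling
# ---------------------------------------------------------------------------

def train_skipgram(
    corpus: WalkCorpus,
    cfg: WalkConfig,
    all_entities: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Fit skip-gram embeddings on a walk corpus by negative sampling.

    The windowed context likelihood ``prod_j Pr(v_j | Phi(v_i))`` over
    ``j in [i-w, i+w], j != i`` is maximized via the standard SGNS surrogate:
    for each (center, context) pair, the context is pushed up and
    ``negative_samples`` draws from the unigram^0.75 noise distribution are
    pushed down through a log-sigmoid.  Optimization is mini-batched SGD with
    a linearly decaying step size; the context window is fixed (not randomly
    shrunk) so a fixed seed reproduces the matrix exactly.

    Entities in ``all_entities`` that never occur in the corpus receive seeded
    random vectors (scaled like the initialization) rather than failing.
    """
    if not corpus.walks:
        raise ValueError("walk corpus is empty")
    rng = np.random.default_rng([cfg.seed, 104729])
    vocab: dict[str, int] = {}
    counts: list[int] = []
    encoded: list[np.ndarray] = []
    for walk in corpus.walks:
        row = np.empty(len(walk), dtype=np.int64)
        for k, v in enumerate(walk):
            if v not in vocab:
                vocab[v] = len(vocab)
                counts.append(0)
            row[k] = vocab[v]
            counts[vocab[v]] += 1
        encoded.append(row)
    n_vocab = len(vocab)
    dim = cfg.dimension

    centers_l: list[np.ndarray] = []
    contexts_l: list[np.ndarray] = []
    w = cfg.window_size
    for row in encoded:
        L = len(row)
        if L < 2:
            continue
        for off in range(1, w + 1):
            if off >= L:
                break
            centers_l.append(row[:-off])
            contexts_l.append(row[off:])
            centers_l.append(row[off:])
            contexts_l.append(row[:-off])
    if not centers_l:
        raise ValueError("corpus has no co-occurring pairs (all walks length 1)")
    centers = np.concatenate(centers_l)
    contexts = np.concatenate(contexts_l)

    noise = np.asarray(counts, dtype=float) ** 0.75
    noise /= noise.sum()

    W_in = (rng.random((n_vocab, dim)) - 0.5) / dim
    W_out = np.zeros((n_vocab, dim))

    n_pairs = len(centers)
    batch = 1024
    total_steps = cfg.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch):
            sel = order[lo : lo + batch]
            c = centers[sel]
            pos = contexts[sel]
            neg = rng.choice(n_vocab, size=(len(sel), cfg.negative_samples), p=noise)
            lr = cfg.learning_rate * max(1.0 - step / total_steps, 1e-4)
            step += 1

            vc = W_in[c]                            # (b, d)
            vp = W_out[pos]                         # (b, d)
            vn = W_out[neg]                         # (b, neg, d)
            s_pos = expit(np.einsum("bd,bd->b", vc, vp))
            s_neg = expit(-np.einsum("bd,bnd->bn", vc, vn))
            g_pos = (1.0 - s_pos)[:, None]          # push positives up
            g_neg = -(1.0 - s_neg)[..., None]       # push negatives down
            grad_c = g_pos * vp + np.einsum("bnd->bd", g_neg * vn)
            np.add.at(W_in, c, lr * grad_c)
            np.add.at(W_out, pos, lr * g_pos * vc)
            np.add.at(
                W_out,
                neg.ravel(),
                lr * (g_neg * vc[:, None, :]).reshape(-1, dim),
            )

    ids = list(vocab)
    vectors = W_in[: n_vocab]
    if all_entities is not None:
        missing = [e for e in all_entities if e not in vocab]
        if missing:
            logger.info("%d entities absent from walks; assigning random vectors", len(missing))
            extra = (rng.random((len(missing), dim)) - 0.5) / dim
            ids = ids + missing
            vectors = np.vstack([vectors, extra])
    return EmbeddingMatrix(ids=tuple(ids), vectors=vectors)


# ---------------------------------------------------------------------------
# HOPE (Katz-proximity factorization)
# ---------------------------------------------------------------------------

def katz_matrix(kg: KnowledgeGraph, beta: float) -> tuple[np.ndarray, tuple[str, ...]]:
    """Dense Katz proximity ``(I - beta*A)^{-1} beta*A`` of the undirected KG.

    Raises ``ValueError`` (reporting the spectral radius) when the series
    does not converge for the requested ``beta``.
    """
    ids = kg.entity_ids
    index = {e: i for i, e in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for a, b in kg.undirected_edges():
        A[index[a], index[b]] = 1.0
        A[index[b], index[a]] = 1.0
    if A.any():
        radius = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    else:
        radius = 0.0
    if beta * radius >= 1.0:
        raise ValueError(
            f"Katz series diverges: beta={beta} * spectral_radius={radius:.4f} >= 1"
        )
    S = np.linalg.solve(np.eye(n) - beta * A, beta * A)
    return S, ids


def hope_embed(kg: KnowledgeGraph, cfg: HopeConfig) -> EmbeddingMatrix:
    """Embed entities by truncated SVD of the Katz proximity matrix.

    The rank-``dimension/2`` SVD ``S ~ U diag(s) V^T`` yields source factors
    ``U sqrt(s)`` and target factors ``V sqrt(s)``, concatenated per entity.
    An edgeless graph gives all-zero embeddings.
    """
    S, ids = katz_matrix(kg, cfg.beta)
    half = cfg.dimension // 2
    n = len(ids)
    if not S.any():
        return EmbeddingMatrix(ids=ids, vectors=np.zeros((n, cfg.dimension)))
    U, s, Vt = np.linalg.svd(S)
    k = min(half, n)
    scale = np.sqrt(s[:k])
    src = U[:, :k] * scale
    dst = Vt[:k].T * scale
    vectors = np.zeros((n, cfg.dimension))
    vectors[:, :k] = src
    vectors[:, half : half + k] = dst
    return EmbeddingMatrix(ids=ids, vectors=vectors)


# ---------------------------------------------------------------------------
# Dispatch and I/O
# ---------------------------------------------------------------------------

def pretrain(
    kg: KnowledgeGraph,
    method: str = "deepwalk",
    walk_config: WalkConfig | None = None,
    hope_config: HopeConfig | None = None,
    dimension: int | None = None,
    seed: int | None = None,
) -> EmbeddingMatrix:
    """Pre-train entity embeddings with the chosen backend.

    ``method="none"`` returns seeded standard-normal vectors scaled by
    ``1/sqrt(dimension)`` — the ablation that skips pre-training entirely.
    """
    method = method.lower()
    if method in _UNSUPPORTED:
        raise ValueError(
            f"backend {method!r} is not supported; choose one of {EMBED_METHODS}"
        )
    if method not in EMBED_METHODS:
        raise ValueError(
            f"unknown embedding method {method!r}; supported: {EMBED_METHODS}"
        )
    if method == "none":
        cfg = walk_config or WalkConfig()
        dim = dimension or cfg.dimension
        sd = cfg.seed if seed is None else seed
        rng = np.random.default_rng([sd, 15485863])
        vectors = rng.standard_normal((kg.n_entities(), dim)) / np.sqrt(dim)
        return EmbeddingMatrix(ids=kg.entity_ids, vectors=vectors)
    if method == "hope":
        cfg = hope_config or HopeConfig()
        if dimension is not None:
            cfg = replace(cfg, dimension=dimension)
        return hope_embed(kg, cfg)
    cfg = walk_config or WalkConfig()
    if dimension is not None:
        cfg = replace(cfg, dimension=dimension)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if method == "deepwalk":
        cfg = replace(cfg, p=1.0, q=1.0)
    corpus = generate_walks(kg, cfg)
    return train_skipgram(corpus, cfg, all_entities=kg.entity_ids)


def write_embeddings(emb: EmbeddingMatrix, path: str | Path) -> None:
    """Write the word2vec-style text format: ``count dim`` header, then
    ``entity v1 ... vdim`` rows at 8 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.ids)} {emb.dimension}\n")
        for e, row in zip(emb.ids, emb.vectors):
            fh.write(e + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def read_embeddings(path: str | Path) -> EmbeddingMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}:1: malformed header {header!r}")
        count, dim = int(header[0]), int(header[1])
        ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != dim + 1:
                raise ParseError(
                    f"{path}:{lineno}: entity {parts[0]!r} has {len(parts) - 1} values, expected {dim}"
                )
            ids.append(parts[0])
            rows.append(np.asarray(parts[1:], dtype=float))
    if len(ids) != count:
        raise ParseError(f"{path}: header declares {count} rows, found {len(ids)}")
    return EmbeddingMatrix(ids=tuple(ids), vectors=np.vstack(rows) if rows else np.zeros((0, dim)))
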