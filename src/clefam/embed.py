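"""Graph embedding of the similarity network and diffusion-based 2D maps.

The similarity graph is vectorized by biased random walks whose windowed
co-occurrence statistics are factorized through a shifted positive PMI
matrix and truncated SVD — the closed-form equivalent of skip-gram
training, chosen for determinism.  A kNN graph over the embedding feeds
the paralog label-propagation stage, and a diffusion-potential projection
(adaptive-bandwidth kernel, Markov diffusion, potential distances, MDS)
gives a 2D map preserving local and global structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .graph import SimilarityGraph

log = logging.getLogger(__name__)


@dataclass
class WalkConfig:
    """Random-walk settings.

    Desk-scale defaults (length 80, 20 walks/node, window 10) keep small
    simulated families fast; ``large_scale()`` returns the heavy settings
    (length 200, 600 walks/node, window 100) used for genome-scale
    networks.  ``return_p`` and ``inout_q`` are node2vec second-order
    biases; both default to 1 (first-order walks).
    """

    walk_length: int = 80
    walks_per_node: int = 20
    context_window: int = 10
    return_p: float = 1.0
    inout_q: float = 1.0
    seed: int = 0

    @classmethod
    def large_scale(cls, seed: int = 0) -> "WalkConfig":
        return cls(walk_length=200, walks_per_node=600, context_window=100, seed=seed)

    def validate(self) -> None:
        if self.walk_length < 1 or self.walks_per_node < 1 or self.context_window < 1:
            raise ValueError("walk counts must be positive")
        if self.context_window > self.walk_length:
            raise ValueError("context_window must be <= walk_length")
        if self.return_p <= 0 or self.inout_q <= 0:
            raise ValueError("walk biases must be positive")


@dataclass
class Embedding:
    """Dense vectors per gene, row-aligned with ``ids``."""

    ids: list[str]
    vectors: np.ndarray                # (n, dims)
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.ids)}
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def dims(self) -> int:
        return self.vectors.shape[1]

    def vector(self, gene_id: str) -> np.ndarray:
        return self.vectors[self.index[gene_id]]


# ---------------------------------------------------------------------------
# walks


def random_walks(graph: SimilarityGraph, cfg: WalkConfig) -> list[list[str]]:
    """node2vec-style second-order random walks over edge weights.

    Transition weight to a candidate next node x from current v with
    previous t is w(v,x)/p if x == t, w(v,x) if x neighbors t, and
    w(v,x)/q otherwise.  Isolated nodes produce singleton walks.
    """
    cfg.validate()
    if len(graph) == 0:
        raise ValueError("empty graph")
    rng = np.random.default_rng(cfg.seed)
    nodes = sorted(graph.nodes)
    nbrs = {n: sorted(graph.neighbors(n).items()) for n in nodes}
    nbr_names = {n: [x for x, _ in v] for n, v in nbrs.items()}
    nbr_w = {n: np.array([w for _, w in v]) for n, v in nbrs.items()}
    nbr_set = {n: set(nbr_names[n]) for n in nodes}
    first_order = cfg.return_p == 1.0 and cfg.inout_q == 1.0
    cum1 = {}
    for n in nodes:
        if len(nbr_w[n]):
            c = np.cumsum(nbr_w[n])
            cum1[n] = c / c[-1]

    walks: list[list[str]] = []
    for node in nodes:
        for _ in range(cfg.walks_per_node):
            walk = [node]
            if not nbr_names[node]:
                walks.append(walk)
                continue
            while len(walk) < cfg.walk_length:
                cur = walk[-1]
                names = nbr_names[cur]
                if not names:
                    break
                if first_order or len(walk) == 1:
                    idx = int(np.searchsorted(cum1[cur], rng.random()))
                else:
                    prev = walk[-2]
                    w = nbr_w[cur].copy()
                    for i, x in enumerate(names):
                        if x == prev:
                            w[i] /= cfg.return_p
                        elif x not in nbr_set[prev]:
                            w[i] /= cfg.inout_q
                    c = np.cumsum(w)
                    idx = int(np.searchsorted(c / c[-1], rng.random()))
                walk.append(names[idx])
            walks.append(walk)
    return walks


# ---------------------------------------------------------------------------
# PPMI + SVD factorization


def embed_walks(walks: list[list[str]], dims: int = 128,
                context_window: int = 10) -> Embedding:
    """Factorize windowed walk co-occurrences into node vectors.

    Symmetric co-occurrence counts within ``context_window`` are
    transformed to positive pointwise mutual information and decomposed by
    truncated SVD; vectors are rows of U * sqrt(S) with a deterministic
    sign convention.  ``dims`` is reduced with a warning when it exceeds
    the node count.
    """
    if not walks:
        raise ValueError("empty walk corpus")
    nodes = sorted({n for w in walks for n in w})
    V = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    if dims > V:
        log.warning("requested dims %d > node count %d; reducing", dims, V)
        dims = V
    C = np.zeros((V, V))
    for walk in walks:
        enc = [idx[n] for n in walk]
        for i, a in enumerate(enc):
            for j in range(i + 1, min(i + 1 + context_window, len(enc))):
                b = enc[j]
                C[a, b] += 1.0
                C[b, a] += 1.0
    total = C.sum()
    if total == 0:
        # corpus of singleton walks only: all-zero vectors
        return Embedding(ids=nodes, vectors=np.zeros((V, dims)))
    row = C.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(C * total / (row @ row.T))
    pmi[~np.isfinite(pmi)] = 0.0
    ppmi = np.clip(pmi, 0.0, None)
    U, S, _ = np.linalg.svd(ppmi, full_matrices=False)
    U, S = U[:, :dims], S[:dims]
    # sign convention: largest-magnitude loading of each component positive
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    vecs = (U * signs) * np.sqrt(S)
    if vecs.shape[1] < dims:
        vecs = np.pad(vecs, ((0, 0), (0, dims - vecs.shape[1])))
    return Embedding(ids=nodes, vectors=vecs)


# ---------------------------------------------------------------------------
# kNN graph


def knn_graph(emb: Embedding, k: int) -> SimilarityGraph:
    """Union-symmetrized k-nearest-neighbour graph on embedding vectors;
    edge weight 1 / (1 + Euclidean distance)."""
    n = len(emb.ids)
    if k >= n:
        raise ValueError("k must be smaller than the node count")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb.vectors)
    dist, ind = nn.kneighbors(emb.vectors)
    g = SimilarityGraph(emb.ids)
    for i in range(n):
        added = 0
        for d, j in zip(dist[i], ind[i]):
            if j == i:
                continue
            g.add_edge(emb.ids[i], emb.ids[int(j)], 1.0 / (1.0 + float(d)))
            added += 1
            if added == k:
                break
    return g


# ---------------------------------------------------------------------------
# diffusion projection


def _von_neumann_entropy(eigvals: np.ndarray, t: int) -> float:
    lam = np.abs(eigvals) ** t
    s = lam.sum()
    if s == 0:
        return 0.0
    p = lam / s
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def project_2d(emb: Embedding, t: int | str = "auto", knn_bandwidth: int = 5,
               alpha: float = 2.0, max_t: int = 40) -> dict[str, tuple[float, float]]:
    """Diffusion-potential 2D projection of the embedding.

    Builds an adaptive-bandwidth kernel exp(-(d/sigma_i)^alpha) with
    sigma_i the distance to the ``knn_bandwidth``-th neighbour, symmetrizes
    and row-normalizes it into a Markov matrix, diffuses ``t`` steps
    ("auto" picks the von Neumann entropy knee), takes -log potential
    distances between diffusion profiles and maps them to the plane by
    classical MDS.  Output is defined up to a rigid transform.
    """
    n = len(emb.ids)
    if n < 3:
        raise ValueError("need at least 3 nodes to project")
    X = emb.vectors
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    kth = min(knn_bandwidth, n - 1)
    sigma = np.sort(D, axis=1)[:, kth]
    sigma[sigma == 0] = 1e-12
    with np.errstate(over="ignore"):
        K = np.exp(-((D / sigma[:, None]) ** alpha))
    K = 0.5 * (K + K.T)
    P = K / K.sum(axis=1, keepdims=True)

    if t == "auto":
        eigvals = np.linalg.eigvals(P)
        ents = np.array([_von_neumann_entropy(eigvals, s) for s in range(1, max_t + 1)])
        # knee: farthest point from the line joining the entropy endpoints
        ts = np.arange(1, max_t + 1, dtype=float)
        v = np.array([ts[-1] - ts[0], ents[-1] - ents[0]])
        v = v / (np.linalg.norm(v) + 1e-12)
        d = np.abs((ts - ts[0]) * v[1] - (ents - ents[0]) * v[0])
        t = int(ts[int(np.argmax(d))])
    Pt = np.linalg.matrix_power(P, int(t))
    U = -np.log(Pt + 1e-12)
    pot = np.sqrt(((U[:, None, :] - U[None, :, :]) ** 2).sum(axis=2))

    # classical MDS on potential distances
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (pot**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    coords = V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    signs = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    coords = coords * signs
    return {g: (float(coords[i, 0]), float(coords[i, 1])) for i, g in enumerate(emb.ids)}
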