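"""All-by-all peptide similarity network with E-value-like edge weights.

Pairwise precursor similarity is scored by exact Smith-Waterman local
alignment with affine gaps (BLOSUM62, open 11, extend 1) and converted to
a -log10 pseudo-E-value through a Karlin-Altschul-style transform, giving
a deterministic, dependency-free analogue of a reciprocal BLASTp network.
Each node's edge set can then be pruned to its strongest connections.
"""

from __future__ import annotations

import heapq

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import aa
from .graph import SimilarityGraph
from .synthdata import GeneRecord

# Karlin-Altschul-style scale defaults for BLOSUM62 with affine gaps.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


def _aligner(matrix_name: str = "BLOSUM62", gap_open: float = DEFAULT_GAP_OPEN,
             gap_extend: float = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix_name)
    al.open_gap_score = -gap_open
    al.extend_gap_score = -gap_extend
    return al


def _check_protein(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    for i, ch in enumerate(seq):
        if ch not in aa.AA_INDEX:
            raise ValueError(f"invalid residue symbol {ch!r} at position {i + 1}")


def align_pair(a: str, b: str, matrix: str = "BLOSUM62",
               gap_open: float = DEFAULT_GAP_OPEN,
               gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Optimal Smith-Waterman local alignment score with affine gaps.

    The score floor is 0 (empty local alignment).  Gap penalties are
    passed as positive costs.
    """
    _check_protein(a)
    _check_protein(b)
    al = _aligner(matrix, gap_open, gap_extend)
    return max(0.0, float(al.score(a, b)))


def score_to_weight(score: float, m: int, n: int,
                    lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K) -> float:
    """-log10 of the Karlin-Altschul pseudo-E-value, clipped below at 0.

    E = K * m * n * exp(-lam * score); the weight is max(0, -log10 E),
    strictly increasing in the score above the clip point.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence and database sizes must be positive")
    if score < 0:
        raise ValueError("alignment score must be >= 0")
    log10_e = (np.log(K) + np.log(m) + np.log(n) - lam * score) / np.log(10.0)
    return max(0.0, float(-log10_e))


def build_graph(genes: list[GeneRecord], min_weight: float = 0.0,
                lam: float = DEFAULT_LAMBDA, K: float = DEFAULT_K,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> SimilarityGraph:
    """All-by-all precursor similarity network.

    The database size of the E-value transform is the summed residue count
    of all precursors.  Edges with weight below ``min_weight`` are dropped;
    all genes remain as nodes.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_id in input")
    db_size = sum(len(g.precursor) for g in genes)
    al = _aligner(gap_open=gap_open, gap_extend=gap_extend)
    for g in genes:
        _check_protein(g.precursor)
    graph = SimilarityGraph(ids)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            score = max(0.0, float(al.score(genes[i].precursor, genes[j].precursor)))
            w = score_to_weight(score, len(genes[i].precursor), db_size, lam, K)
            if w >= min_weight and w > 0.0:
                graph.add_edge(ids[i], ids[j], w)
    return graph


def prune_top_k(graph: SimilarityGraph, k: int = 500) -> SimilarityGraph:
    """Keep each edge iff it ranks within the k heaviest edges of either
    endpoint (union semantics); ties broken by lexicographic partner id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep: set[tuple[str, str]] = set()
    for node in graph.nodes:
        nbrs = graph.neighbors(node)
        # heaviest first; ties resolved toward the lexicographically
        # smaller partner id
        top = heapq.nsmallest(k, nbrs.items(), key=lambda kv: (-kv[1], kv[0]))
        for partner, _ in top:
            keep.add(tuple(sorted((node, partner))))
    out = SimilarityGraph(graph.nodes)
    for u, v, w in graph.edges():
        if (u, v) in keep:
            out.add_edge(u, v, w)
    return out
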