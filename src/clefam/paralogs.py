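"""Promoter-similarity networks and semi-supervised paralog grouping.

Shared regulatory sequence is detected by containment Jaccard of
canonical promoter k-mers, which captures a conserved noncoding block
retained (possibly asymmetrically) by both members of a paralog pair.
Genes connected at high promoter similarity seed joint groups that are
then extended over the embedding kNN graph by clamped, synchronous label
propagation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import SimilarityGraph
from .synthdata import GeneRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Strand-canonical k-mer set (lexicographic min of k-mer and its
    reverse complement)."""
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i: i + k]
        out.add(min(kmer, _revcomp(kmer)))
    return out


def promoter_similarity(a: str, b: str, k: int = 12) -> float:
    """Containment Jaccard of canonical k-mer sets:
    |K(a) & K(b)| / min(|K(a)|, |K(b)|), in [0, 1]."""
    if len(a) < k or len(b) < k:
        raise ValueError(f"promoter shorter than k-mer size {k}")
    ka, kb = canonical_kmers(a, k), canonical_kmers(b, k)
    denom = min(len(ka), len(kb))
    if denom == 0:
        return 0.0
    return len(ka & kb) / denom


@dataclass
class PromoterNetwork:
    """Symmetric promoter-similarity graph with values in [0, 1]."""

    graph: SimilarityGraph

    @property
    def nodes(self) -> set[str]:
        return self.graph.nodes

    def similarity(self, u: str, v: str) -> float:
        return self.graph.weight(u, v) if self.graph.has_edge(u, v) else 0.0


def build_promoter_network(genes: list[GeneRecord], min_sim: float = 0.0,
                           k: int = 12) -> PromoterNetwork:
    """All-pairs promoter similarity; edges below ``min_sim`` dropped.

    Genes without a promoter (or with one shorter than ``k``) are excluded
    from the network with a warning.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    usable = []
    for g in genes:
        if len(g.promoter) < k:
            log.warning("gene %s has no usable promoter; excluded", g.gene_id)
            continue
        usable.append(g)
    net = SimilarityGraph(g.gene_id for g in usable)
    kmers = {g.gene_id: canonical_kmers(g.promoter, k) for g in usable}
    ids = sorted(kmers)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            ka, kb = kmers[ids[i]], kmers[ids[j]]
            denom = min(len(ka), len(kb))
            sim = len(ka & kb) / denom if denom else 0.0
            if sim >= min_sim and sim > 0.0:
                net.add_edge(ids[i], ids[j], sim)
    return PromoterNetwork(graph=net)


@dataclass
class LabelState:
    """Propagation result: labels, confidences, and the clamped seed set."""

    labels: dict[str, str | None]
    confidence: dict[str, float]
    seeded: set[str] = field(default_factory=set)


def propagate_labels(knn: SimilarityGraph, seeds: dict[str, str],
                     max_iter: int = 100) -> LabelState:
    """Clamped synchronous label propagation by weighted majority vote.

    Seed nodes keep their labels forever (confidence 1).  Each round
    every unseeded node adopts the label with the largest summed neighbor
    weight; exact ties leave the node unlabeled for that round and are
    broken lexicographically at termination.  Confidence is the winning
    label's weight share.  Stops at a fixed point or ``max_iter``.
    """
    if not seeds:
        raise ValueError("at least one seed is required")
    for s in seeds:
        if s not in knn.nodes:
            raise ValueError(f"seed node {s!r} not in graph")
    labels: dict[str, str | None] = {n: seeds.get(n) for n in knn.nodes}
    confidence = {n: 1.0 if n in seeds else 0.0 for n in knn.nodes}
    order = sorted(knn.nodes)

    def vote(n: str, current: dict[str, str | None]):
        scores: dict[str, float] = {}
        for nbr, w in knn.neighbors(n).items():
            lab = current[nbr]
            if lab is not None:
                scores[lab] = scores.get(lab, 0.0) + w
        if not scores:
            return None, 0.0, False
        best = max(scores.values())
        winners = sorted(lab for lab, s in scores.items() if s >= best - 1e-12)
        share = best / sum(scores.values())
        return winners[0], share, len(winners) > 1

    for _ in range(max_iter):
        new_labels = dict(labels)
        changed = False
        for n in order:
            if n in seeds:
                continue
            lab, share, tied = vote(n, labels)
            new = None if tied else lab
            if new != labels[n]:
                changed = True
            new_labels[n] = new
            confidence[n] = 0.0 if tied or lab is None else share
        labels = new_labels
        if not changed:
            break

    # terminal lexicographic tie-break for still-tied nodes
    for n in order:
        if n not in seeds and labels[n] is None:
            lab, share, tied = vote(n, labels)
            if lab is not None:
                labels[n] = lab
                confidence[n] = share
    return LabelState(labels=labels, confidence=confidence, seeded=set(seeds))


def assign_paralog_groups(genes: list[GeneRecord], knn: SimilarityGraph,
                          promoter_net: PromoterNetwork,
                          sim_seed_threshold: float = 0.5,
                          max_iter: int = 100) -> dict[str, str | None]:
    """Group genes by shared promoters, extended over the kNN graph.

    Connected components of the promoter network restricted to edges with
    similarity >= ``sim_seed_threshold`` become seed groups (singletons
    included); label propagation then assigns the remaining kNN nodes.
    """
    thresholded = SimilarityGraph(promoter_net.nodes)
    for u, v, w in promoter_net.graph.edges():
        if w >= sim_seed_threshold:
            thresholded.add_edge(u, v, w)
    seeds: dict[str, str] = {}
    for comp in sorted(thresholded.connected_components(), key=min):
        group = f"group_{min(comp)}"
        for g in comp:
            if g in knn.nodes:
                seeds[g] = group
    state = propagate_labels(knn, seeds, max_iter=max_iter)
    return {g.gene_id: state.labels.get(g.gene_id) for g in genes
            if g.gene_id in knn.nodes}
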