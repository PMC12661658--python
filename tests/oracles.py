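"""Independent brute-force oracles shared by unit and acceptance tests.

Each oracle re-derives a quantity by exhaustive enumeration or a direct
textbook algorithm, deliberately sharing no code with the package.
"""

import itertools

import numpy as np

from clefam import aa, codons
from clefam.hierarchy import Partition, cpm_quality, reconciliation_cost


def set_partitions(items):
    """All set partitions of a list (restricted-growth-string order)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


def cpm_optimum(graph, gamma):
    """Exhaustive CPM maximum over all partitions (n <= 8)."""
    nodes = sorted(graph.nodes)
    best = -np.inf
    for part in set_partitions(nodes):
        assignment = {}
        for c, block in enumerate(part):
            for n in block:
                assignment[n] = c
        best = max(best, cpm_quality(graph, assignment, gamma))
    return best


def reconciliation_optimum(partitions: list[Partition]) -> int:
    """Minimum total membership disagreement over every leaf partition
    with at most as many leaves as the finest input layer has communities
    (the reconciler's model class; unconstrained, singletons trivially
    reach 0)."""
    genes = sorted(partitions[0].assignment)
    max_leaves = len(set(partitions[-1].assignment.values()))
    best = None
    for blocks in set_partitions(genes):
        if len(blocks) > max_leaves:
            continue
        leaf_of = {}
        for c, block in enumerate(blocks):
            for g in block:
                leaf_of[g] = c
        cost = reconciliation_cost(leaf_of, partitions)
        best = cost if best is None else min(best, cost)
    return best


def sw_affine(a, b, open_cost=11.0, extend_cost=1.0):
    """Gotoh local alignment DP over BLOSUM62; gap of length g costs
    open_cost + (g - 1) * extend_cost."""
    B = aa.blosum62()
    xa, xb = aa.encode(a), aa.encode(b)
    n, m = len(xa), len(xb)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - extend_cost)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - extend_cost)
            H[i, j] = max(0.0,
                          H[i - 1, j - 1] + B[xa[i - 1], xb[j - 1]],
                          E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def codon_syn_pathways(a, b):
    """Pathway-averaged synonymous difference count for one codon pair,
    enumerated directly; stop-crossing pathways are excluded."""
    table = codons.codon_to_aa()
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, ok = a, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if table[nxt] == "*":
                ok = False
                break
            sd += table[nxt] == table[cur]
            cur = nxt
        if ok:
            results.append(sd)
    if not results:
        return 0.0
    return float(np.mean(results))


def entropy_objective(groups_by_shape, motifs_by_child):
    """Total member-weighted positional entropy of a nested-tuple shape."""
    def node_entropy(members):
        X = np.array([aa.encode(m) for m in members])
        total = 0.0
        for i in range(X.shape[1]):
            counts = np.bincount(X[:, i], minlength=aa.A).astype(float)
            p = counts / len(members)
            p = p[p > 0]
            total += -float((p * np.log(p)).sum()) * len(members)
        return total

    def rec(shape):
        if isinstance(shape, str):
            return 0.0, list(motifs_by_child[shape])
        lo, lm = rec(shape[0])
        ro, rm = rec(shape[1])
        members = lm + rm
        return lo + ro + node_entropy(members), members

    return rec(groups_by_shape)[0]


def polytomy_optimum(motifs_by_child):
    """Exhaustive minimum entropy objective over all rooted binary shapes,
    built by a different enumeration (iterative pair merging with memo)."""
    ids = sorted(motifs_by_child)

    def shapes(subset):
        subset = tuple(subset)
        if len(subset) == 1:
            yield subset[0]
            return
        fixed, rest = subset[0], subset[1:]
        for k in range(len(rest)):
            for left_rest in itertools.combinations(rest, k):
                left = (fixed, *left_rest)
                right = tuple(x for x in rest if x not in left_rest)
                for ls in shapes(left):
                    for rs in shapes(right):
                        yield (ls, rs)

    return min(entropy_objective(s, motifs_by_child) for s in shapes(ids))


def label_prop_fixed_point(adj, seeds, max_iter=100):
    """Direct synchronous clamped weighted-majority propagation.

    ``adj`` maps node -> {neighbor: weight}.  Mirrors the documented rule:
    ties leave a node unlabeled for the round and break lexicographically
    at termination.
    """
    labels = {n: seeds.get(n) for n in adj}

    def vote(n, current):
        scores = {}
        for nbr, w in adj[n].items():
            lab = current[nbr]
            if lab is not None:
                scores[lab] = scores.get(lab, 0.0) + w
        if not scores:
            return None, False
        best = max(scores.values())
        winners = sorted(lab for lab, s in scores.items() if s >= best - 1e-12)
        return winners[0], len(winners) > 1

    for _ in range(max_iter):
        new = dict(labels)
        changed = False
        for n in sorted(adj):
            if n in seeds:
                continue
            lab, tied = vote(n, labels)
            val = None if tied else lab
            if val != labels[n]:
                changed = True
            new[n] = val
        labels = new
        if not changed:
            break
    for n in sorted(adj):
        if n not in seeds and labels[n] is None:
            lab, _ = vote(n, labels)
            if lab is not None:
                labels[n] = lab
    return labels
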