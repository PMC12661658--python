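"""Multi-resolution community hierarchy over the similarity network.

Communities are detected at an ascending ladder of resolutions with the
Leiden algorithm under the constant-Potts-model (CPM) objective

    Q(gamma) = sum_c [ w_in(c) - gamma * n_c (n_c - 1) / 2 ],

reconciled into a strictly nested tree by alternating
plurality-containment labelling and member reassignment, then refined at
the leaves: sister leaves that a random-forest permutation test cannot
distinguish on their dodecapeptides are merged, and polytomies can be
resolved into binary subtrees by parsimonious entropy minimization on
motif composition.
"""

from __future__ import annotations

import copy
import itertools
import json
import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg as la
import numpy as np

from . import aa
from ._rf import forest_oob_accuracy
from .graph import SimilarityGraph

log = logging.getLogger(__name__)


@dataclass
class Partition:
    """One flat community assignment at a given resolution."""

    resolution: float
    assignment: dict[str, int]

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for g, c in self.assignment.items():
            out.setdefault(c, set()).add(g)
        return out


@dataclass
class TreeNode:
    node_id: str
    level: int
    members: frozenset[str]
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class HierarchyTree:
    """Strictly nested multi-resolution partition tree over genes."""

    root: TreeNode
    resolutions: list[float] = field(default_factory=list)
    n_reassignments: int = 0

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(n: TreeNode) -> None:
            if n.is_leaf():
                out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    def validate_nested(self) -> None:
        def rec(n: TreeNode) -> None:
            if n.children:
                union: set[str] = set()
                for c in n.children:
                    if c.level <= n.level:
                        raise ValueError("child level must exceed parent level")
                    if union & c.members:
                        raise ValueError("sibling member sets overlap")
                    union |= c.members
                    rec(c)
                if union != set(n.members):
                    raise ValueError("children do not partition the parent")

        rec(self.root)

    # -- serialization -------------------------------------------------
    def to_newick(self) -> str:
        def label(n: TreeNode) -> str:
            return f"L{n.level}_C{n.node_id}"

        def rec(n: TreeNode) -> str:
            if n.is_leaf():
                return label(n)
            inner = ",".join(rec(c) for c in sorted(n.children, key=lambda c: c.node_id))
            return f"({inner}){label(n)}"

        return rec(self.root) + ";"

    def to_json(self) -> str:
        def rec(n: TreeNode) -> dict:
            return {
                "node_id": n.node_id,
                "level": n.level,
                "members": sorted(n.members),
                "children": [rec(c) for c in sorted(n.children, key=lambda c: c.node_id)],
            }

        return json.dumps({"resolutions": self.resolutions, "tree": rec(self.root)})


# ---------------------------------------------------------------------------
# Leiden / CPM


def _to_igraph(graph: SimilarityGraph) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    edges, weights = [], []
    for u, v, w in graph.edges():
        edges.append((idx[u], idx[v]))
        weights.append(w)
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def cpm_quality(graph: SimilarityGraph, assignment: dict[str, int],
                gamma: float) -> float:
    """CPM objective of a partition: within-community weight minus
    gamma times the number of within-community node pairs."""
    comms: dict[int, set[str]] = {}
    for g, c in assignment.items():
        comms.setdefault(c, set()).add(g)
    q = 0.0
    for members in comms.values():
        n = len(members)
        q -= gamma * n * (n - 1) / 2.0
    for u, v, w in graph.edges():
        if assignment[u] == assignment[v]:
            q += w
    return q


def multires_communities(graph: SimilarityGraph, resolutions: list[float],
                         seed: int = 0, n_restarts: int = 5) -> list[Partition]:
    """Leiden/CPM partitions at each resolution, best of seeded restarts.

    Communities are connected by construction; tie-breaking is seeded and
    the best-quality restart is kept, so output is deterministic for a
    fixed seed.
    """
    if not resolutions:
        raise ValueError("need at least one resolution")
    g, nodes = _to_igraph(graph)
    out = []
    for gamma in resolutions:
        best_assign, best_q = None, -np.inf
        for r in range(n_restarts):
            part = la.find_partition(
                g, la.CPMVertexPartition,
                weights="weight" if g.ecount() else None,
                resolution_parameter=gamma,
                seed=seed + r, n_iterations=-1,
            )
            assign = {nodes[i]: int(m) for i, m in enumerate(part.membership)}
            q = cpm_quality(graph, assign, gamma)
            if q > best_q + 1e-12:
                best_q, best_assign = q, assign
        out.append(Partition(resolution=float(gamma), assignment=best_assign))
    return out


def default_resolution_ladder(graph: SimilarityGraph, n: int = 6) -> list[float]:
    """Geometric ladder of resolutions spanning the edge-weight scale."""
    weights = [w for _, _, w in graph.edges()]
    if not weights:
        return list(np.geomspace(1e-3, 1.0, n))
    lo = max(min(weights) / 10.0, 1e-6)
    hi = max(weights) * 2.0
    return list(np.geomspace(lo, hi, n))


# ---------------------------------------------------------------------------
# reconciliation


def reconciliation_cost(leaf_of: dict[str, int],
                        partitions: list[Partition]) -> int:
    """Total membership disagreement of a leaf assignment: for each leaf
    and each layer, members outside the leaf's plurality label count one
    reassignment each."""
    leaves: dict[int, list[str]] = {}
    for g, leaf in leaf_of.items():
        leaves.setdefault(leaf, []).append(g)
    cost = 0
    for members in leaves.values():
        for p in partitions:
            labels = [p.assignment[g] for g in members]
            counts: dict[int, int] = {}
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
            cost += len(members) - max(counts.values())
    return cost


def _plurality(labels: list[int]) -> int:
    counts: dict[int, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def reconcile_tree(partitions: list[Partition], max_iter: int = 50) -> HierarchyTree:
    """Reconcile coarse-to-fine partitions into a strictly nested tree.

    Leaves start as the finest partition's communities.  Alternating
    steps (a) label each leaf at every layer with the plurality community
    of its members and (b) reassign each gene to the leaf whose label
    vector disagrees least with the gene's own input labels, iterated to
    a fixed point, perform coordinate descent on the total number of
    membership reassignments.  The prefix structure of the converged
    label vectors defines the nested tree, which is valid even for
    non-nested inputs.
    """
    if not partitions:
        raise ValueError("empty partition list")
    genes = sorted(partitions[0].assignment)
    for p in partitions:
        if sorted(p.assignment) != genes:
            raise ValueError("partitions must cover the same gene set")
    R = len(partitions)

    leaf_of = {g: partitions[-1].assignment[g] for g in genes}
    for _ in range(max_iter):
        members: dict[int, list[str]] = {}
        for g in genes:
            members.setdefault(leaf_of[g], []).append(g)
        vec = {
            leaf: tuple(_plurality([p.assignment[g] for g in mem]) for p in partitions)
            for leaf, mem in members.items()
        }
        changed = False
        for g in genes:
            own = tuple(p.assignment[g] for p in partitions)
            cur = leaf_of[g]
            cur_cost = sum(a != b for a, b in zip(vec[cur], own))
            best_leaf, best_cost = cur, cur_cost
            for leaf in sorted(vec):
                c = sum(a != b for a, b in zip(vec[leaf], own))
                if c < best_cost:
                    best_leaf, best_cost = leaf, c
            if best_leaf != cur:
                leaf_of[g] = best_leaf
                changed = True
        if not changed:
            break

    # build the prefix tree from converged label vectors
    members = {}
    for g in genes:
        members.setdefault(leaf_of[g], []).append(g)
    vec = {
        leaf: tuple(_plurality([p.assignment[g] for g in mem]) for p in partitions)
        for leaf, mem in members.items()
    }
    gene_vec = {g: vec[leaf_of[g]] for g in genes}

    root = TreeNode(node_id="root", level=0, members=frozenset(genes))

    def build(node: TreeNode, gene_set: list[str], depth: int) -> None:
        if depth == R:
            return
        groups: dict[tuple, list[str]] = {}
        for g in gene_set:
            groups.setdefault(gene_vec[g][: depth + 1], []).append(g)
        if len(groups) == 1 and depth > 0:
            # no further split at this layer; recurse in place
            build(node, gene_set, depth + 1)
            return
        for prefix in sorted(groups):
            child = TreeNode(
                node_id="_".join(str(x) for x in prefix),
                level=depth + 1,
                members=frozenset(groups[prefix]),
            )
            node.children.append(child)
            build(child, groups[prefix], depth + 1)

    build(root, genes, 0)
    tree = HierarchyTree(
        root=root,
        resolutions=[p.resolution for p in partitions],
        n_reassignments=reconciliation_cost(leaf_of, partitions),
    )
    tree = _collapse_redundant(tree)
    tree.validate_nested()
    return tree


def _collapse_redundant(tree: HierarchyTree) -> HierarchyTree:
    """Collapse single-child chains with identical member sets."""

    def rec(n: TreeNode) -> TreeNode:
        while len(n.children) == 1 and n.children[0].members == n.members:
            child = n.children[0]
            n.children = child.children
        n.children = [rec(c) for c in n.children]
        return n

    tree.root = rec(tree.root)
    return tree


# ---------------------------------------------------------------------------
# random-forest sister pruning


def sister_separation_pvalue(motifs_a: list[str], motifs_b: list[str],
                             n_perm: int = 199, seed: int = 0,
                             n_estimators: int = 100) -> float:
    """Permutation p-value for separability of two sibling leaves.

    Members' dodecapeptides are one-hot encoded over 12 categorical
    positions; the observed statistic is the out-of-bag accuracy of a
    bootstrap random forest separating the leaves, and the null
    distribution comes from refitting on leaf-label permutations.
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    X = np.array([_one_hot(m) for m in motifs_a + motifs_b])
    y = np.array([0] * len(motifs_a) + [1] * len(motifs_b))
    rng = np.random.default_rng(seed)

    obs = forest_oob_accuracy(X, y, n_estimators, int(rng.integers(2**31 - 1)))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if forest_oob_accuracy(X, perm, n_estimators,
                               int(rng.integers(2**31 - 1))) >= obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def _one_hot(motif: str) -> np.ndarray:
    x = aa.encode(motif)
    out = np.zeros(len(x) * aa.A)
    out[np.arange(len(x)) * aa.A + x] = 1.0
    return out


def prune_sisters_rf(tree: HierarchyTree, motifs: dict[str, str],
                     n_perm: int = 199, alpha: float = 0.05, seed: int = 0,
                     n_estimators: int = 100) -> HierarchyTree:
    """Merge sister leaves that the permutation test cannot distinguish.

    Sister leaf pairs are tested pairwise in deterministic order; a pair
    merges when its separation p-value exceeds ``alpha`` (alpha >= 1
    degenerates to merging every pair).  Leaves with fewer than two
    members are untrainable and merge automatically with a logged note.
    Passes repeat until no merge occurs.
    """
    tree = copy.deepcopy(tree)
    rng = np.random.default_rng(seed)

    def sister_pairs(node: TreeNode):
        leaves_here = [c for c in node.children if c.is_leaf()]
        leaves_here.sort(key=lambda n: n.node_id)
        for a, b in itertools.combinations(leaves_here, 2):
            yield node, a, b
        for c in node.children:
            yield from sister_pairs(c)

    merged_any = True
    while merged_any:
        merged_any = False
        for parent, a, b in list(sister_pairs(tree.root)):
            if a not in parent.children or b not in parent.children:
                continue
            if len(a.members) < 2 or len(b.members) < 2:
                log.info("auto-merging untrainable sister pair %s/%s",
                         a.node_id, b.node_id)
                merge = True
            elif alpha >= 1.0:
                merge = True
            else:
                p = sister_separation_pvalue(
                    [motifs[g] for g in sorted(a.members)],
                    [motifs[g] for g in sorted(b.members)],
                    n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                    n_estimators=n_estimators,
                )
                merge = p > alpha
            if merge:
                new = TreeNode(
                    node_id=f"{a.node_id}+{b.node_id}",
                    level=max(a.level, b.level),
                    members=a.members | b.members,
                )
                parent.children = [c for c in parent.children if c not in (a, b)]
                parent.children.append(new)
                merged_any = True
    tree = _collapse_redundant(tree)
    tree.validate_nested()
    return tree


# ---------------------------------------------------------------------------
# entropy-based polytomy resolution


def _weighted_entropy(motifs: list[str]) -> float:
    """Member-weighted Shannon entropy summed over the 12 positions."""
    X = np.array([aa.encode(m) for m in motifs])
    n, L = X.shape
    total = 0.0
    for i in range(L):
        counts = np.bincount(X[:, i], minlength=aa.A).astype(float)
        p = counts / n
        p = p[p > 0]
        total += -float((p * np.log(p)).sum()) * n
    return total


def _tree_objective(shape, groups: dict[str, list[str]]) -> tuple[float, list[str]]:
    """Total weighted entropy over internal nodes of a nested-tuple shape."""
    if isinstance(shape, str):
        return 0.0, list(groups[shape])
    lo, lm = _tree_objective(shape[0], groups)
    ro, rm = _tree_objective(shape[1], groups)
    members = lm + rm
    return lo + ro + _weighted_entropy(members), members


def _all_shapes(ids: list[str]):
    """All rooted binary tree shapes over labelled children."""
    if len(ids) == 1:
        yield ids[0]
        return
    first, rest = ids[0], ids[1:]
    for k in range(1, len(rest) + 1):
        for combo in itertools.combinations(rest, k - 1):
            left = [first, *combo]
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for ls in _all_shapes(left):
                for rs in _all_shapes(right):
                    yield (ls, rs)


def _canonical(shape):
    if isinstance(shape, str):
        return shape
    a, b = _canonical(shape[0]), _canonical(shape[1])
    return (a, b) if str(a) <= str(b) else (b, a)


def resolve_polytomy_entropy(children: dict[str, list[str]],
                             exhaustive_limit: int = 6):
    """Binary subtree over >2 children minimizing total motif entropy.

    ``children`` maps child id to the member dodecapeptides.  Merging two
    groups costs the member-weighted positional Shannon entropy of the
    merged residue distribution; the objective is the sum over internal
    nodes.  All (2m-3)!! rooted shapes are searched exhaustively for
    m <= ``exhaustive_limit``; beyond that, greedy agglomeration picks
    the cheapest merge at each step.  Ties break lexicographically by
    child id, making the output deterministic.  Returns
    ``(nested-tuple topology, objective value)``.
    """
    m = len(children)
    if m < 3:
        raise ValueError("polytomy resolution needs at least 3 children")
    ids = sorted(children)
    if m <= exhaustive_limit:
        best_shape, best_obj = None, np.inf
        for shape in _all_shapes(ids):
            obj, _ = _tree_objective(shape, children)
            cshape = _canonical(shape)
            if obj < best_obj - 1e-12 or (
                abs(obj - best_obj) <= 1e-12
                and best_shape is not None
                and str(cshape) < str(best_shape)
            ):
                best_shape, best_obj = cshape, obj
        return best_shape, float(best_obj)

    # greedy agglomeration
    forest: dict[str, tuple] = {i: i for i in ids}
    members: dict[str, list[str]] = {i: list(children[i]) for i in ids}
    entropy: dict[str, float] = {i: _weighted_entropy(children[i]) for i in ids}
    total = 0.0
    while len(forest) > 1:
        best = None
        for x, y in itertools.combinations(sorted(forest), 2):
            inc = _weighted_entropy(members[x] + members[y]) - entropy[x] - entropy[y]
            if best is None or inc < best[0] - 1e-12:
                best = (inc, x, y)
        _, x, y = best
        new_id = f"{x}+{y}"
        merged = members[x] + members[y]
        h = _weighted_entropy(merged)
        total += h
        forest[new_id] = _canonical((forest.pop(x), forest.pop(y)))
        members[new_id] = merged
        entropy[new_id] = h
        del members[x], members[y], entropy[x], entropy[y]
    shape = next(iter(forest.values()))
    return shape, float(total)
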