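"""Compiled random forest for the sister-leaf permutation test.

A minimal bootstrap forest over binary (one-hot) features with Gini
splits, sqrt-feature sampling per node and out-of-bag accuracy scoring.
Permutation testing refits the forest hundreds of times per leaf pair on
a handful of samples, a regime where a compiled implementation is
orders of magnitude faster than general-purpose libraries.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_NODES = 512


@njit(cache=True)
def _build_tree(X, y, order, lo_hi_stack, feat_arr, left_arr, right_arr,
                pred_arr, mtry):
    """Grow one tree on the index window ``order[0:n]``; arrays are
    preallocated.  Features are binary, split threshold is 0.5."""
    n, f = X.shape
    n_nodes = 1
    lo_hi_stack[0, 0] = 0
    lo_hi_stack[0, 1] = len(order)
    lo_hi_stack[0, 2] = 0          # node id
    sp = 1
    while sp > 0:
        sp -= 1
        lo = lo_hi_stack[sp, 0]
        hi = lo_hi_stack[sp, 1]
        node = lo_hi_stack[sp, 2]
        n1 = 0
        for i in range(lo, hi):
            n1 += y[order[i]]
        m = hi - lo
        pred_arr[node] = 1 if 2 * n1 > m else 0
        feat_arr[node] = -1
        if n1 == 0 or n1 == m or m < 2 or n_nodes + 2 > _MAX_NODES:
            continue
        parent_gini = 1.0 - ((n1 / m) ** 2 + ((m - n1) / m) ** 2)
        best_gain = 1e-12
        best_feat = -1
        for _ in range(mtry):
            j = np.random.randint(0, f)
            lm = 0
            l1 = 0
            for i in range(lo, hi):
                if X[order[i], j] <= 0.5:
                    lm += 1
                    l1 += y[order[i]]
            if lm == 0 or lm == m:
                continue
            r1 = n1 - l1
            rm = m - lm
            gl = 1.0 - ((l1 / lm) ** 2 + ((lm - l1) / lm) ** 2)
            gr = 1.0 - ((r1 / rm) ** 2 + ((rm - r1) / rm) ** 2)
            gain = parent_gini - (lm * gl + rm * gr) / m
            if gain > best_gain:
                best_gain = gain
                best_feat = j
        if best_feat < 0:
            continue
        # partition in place
        mid = lo
        for i in range(lo, hi):
            if X[order[i], best_feat] <= 0.5:
                tmp = order[mid]
                order[mid] = order[i]
                order[i] = tmp
                mid += 1
        feat_arr[node] = best_feat
        left_arr[node] = n_nodes
        right_arr[node] = n_nodes + 1
        lo_hi_stack[sp, 0] = lo
        lo_hi_stack[sp, 1] = mid
        lo_hi_stack[sp, 2] = n_nodes
        lo_hi_stack[sp + 1, 0] = mid
        lo_hi_stack[sp + 1, 1] = hi
        lo_hi_stack[sp + 1, 2] = n_nodes + 1
        sp += 2
        n_nodes += 2
    return n_nodes


@njit(cache=True)
def _predict_one(X, i, feat_arr, left_arr, right_arr, pred_arr):
    node = 0
    while feat_arr[node] >= 0:
        if X[i, feat_arr[node]] <= 0.5:
            node = left_arr[node]
        else:
            node = right_arr[node]
    return pred_arr[node]


@njit(cache=True)
def oob_accuracy(X, y, n_trees, seed):
    """Mean out-of-bag vote share for each sample's own class.

    A soft accuracy in [0, 1] (0.5 under no signal) whose fine
    granularity avoids the tie-induced conservativeness a hard 0/1
    accuracy would give the permutation test; 0.5 if no sample is ever
    out of bag (vanishingly rare for usual forest sizes)."""
    np.random.seed(seed)
    n, f = X.shape
    mtry = max(1, int(np.sqrt(f)))
    votes = np.zeros((n, 2), dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    inbag = np.empty(n, dtype=np.bool_)
    stack = np.empty((_MAX_NODES, 3), dtype=np.int64)
    feat_arr = np.empty(_MAX_NODES, dtype=np.int64)
    left_arr = np.empty(_MAX_NODES, dtype=np.int64)
    right_arr = np.empty(_MAX_NODES, dtype=np.int64)
    pred_arr = np.empty(_MAX_NODES, dtype=np.int64)
    for _ in range(n_trees):
        inbag[:] = False
        for k in range(n):
            order[k] = np.random.randint(0, n)
            inbag[order[k]] = True
        _build_tree(X, y, order, stack, feat_arr, left_arr, right_arr,
                    pred_arr, mtry)
        for i in range(n):
            if not inbag[i]:
                votes[i, _predict_one(X, i, feat_arr, left_arr, right_arr,
                                      pred_arr)] += 1
    score = 0.0
    counted = 0
    for i in range(n):
        tot = votes[i, 0] + votes[i, 1]
        if tot > 0:
            counted += 1
            score += votes[i, y[i]] / tot
    if counted == 0:
        return 0.5
    return score / counted


def forest_oob_accuracy(X: np.ndarray, y: np.ndarray, n_trees: int = 100,
                        seed: int = 0) -> float:
    """Python entry point; casts inputs and bounds the seed."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.int64)
    return float(oob_accuracy(X, y, n_trees, int(seed) % (2**31 - 1)))
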