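"""Independent brute-force oracle for parsimony reconstruction.

Enumerates every assignment of states to internal nodes (and to
missing-data leaves, which are free) over a small alphabet, scores each by
counting state changes on edges, and reports the minimum length, the exact
MPR sets, and the maximum summed depth of change edges over all
most-parsimonious labelings.  Vectorized with numpy but conceptually a
plain exhaustive search; entirely independent of the package's dynamic
program.
"""

from __future__ import annotations

import numpy as np

from apoclass.alignment import is_missing
from apoclass.tree import RootedTree


def enumerate_site(tree: RootedTree, leaf_states: dict[str, str | None],
                   alphabet: list[str]):
    """Exhaustive parsimony over all labelings.

    leaf_states maps leaf label -> state or None (missing, free).
    Returns (length, mpr_sets: node_id -> frozenset, max_change_depth,
    optimal_labelings: array over free nodes, free_ids).
    """
    nodes = list(tree.preorder())
    free = [n for n in nodes
            if (not n.is_leaf) or leaf_states[n.label] is None]
    free_ids = [n.id for n in free]
    free_pos = {nid: i for i, nid in enumerate(free_ids)}
    na = len(alphabet)
    aidx = {s: i for i, s in enumerate(alphabet)}

    n_lab = na ** len(free)
    # all labelings: rows = labelings, cols = free nodes
    grids = np.indices((na,) * len(free)).reshape(len(free), n_lab).T

    depth = {n.id: tree.depth(n) for n in nodes}
    cost = np.zeros(n_lab, dtype=np.int64)
    depth_sum = np.zeros(n_lab, dtype=np.int64)

    def column(node):
        if node.id in free_pos:
            return grids[:, free_pos[node.id]]
        return np.full(n_lab, aidx[leaf_states[node.label]])

    for node in nodes:
        if node.parent is None:
            continue
        diff = column(node) != column(node.parent)
        cost += diff
        depth_sum += diff * depth[node.id]

    length = int(cost.min())
    optimal = cost == length
    mpr = {}
    for node in nodes:
        col = column(node)[optimal]
        mpr[node.id] = frozenset(alphabet[i] for i in np.unique(col))
    max_depth = int(depth_sum[optimal].max())
    return length, mpr, max_depth, grids[optimal], free_ids


def oracle_alphabet(leaf_states: dict[str, str | None],
                    extra: str = "Z") -> list[str]:
    """Observed states plus one never-observed state, to verify that
    unobserved states never enter an MPR."""
    observed = sorted({s for s in leaf_states.values() if s is not None})
    return observed + [extra]


def leaf_states_of(tree, matrix, site):
    return {
        leaf.label: (None if is_missing(matrix.cell(leaf.label, site))
                     else matrix.cell(leaf.label, site))
        for leaf in tree.leaves()
    }


def subtree_costs(tree: RootedTree, node, leaf_states, alphabet):
    """Minimum change count inside the subtree of ``node`` for each pinned
    root state, by exhaustive (vectorized) enumeration of subtree
    labelings."""
    sub_nodes = []
    stack = [node]
    while stack:
        n = stack.pop()
        sub_nodes.append(n)
        stack.extend(n.children)
    na = len(alphabet)
    aidx = {s: i for i, s in enumerate(alphabet)}
    if node.is_leaf and leaf_states[node.label] is not None:
        pinned = aidx[leaf_states[node.label]]
        return {
            s: (0 if aidx[s] == pinned else 10 ** 6) for s in alphabet
        }
    free = [n for n in sub_nodes
            if (not n.is_leaf) or leaf_states[n.label] is None]
    free_pos = {n.id: i for i, n in enumerate(free)}
    n_lab = na ** len(free)
    grids = np.indices((na,) * len(free)).reshape(len(free), n_lab).T

    def column(n):
        if n.id in free_pos:
            return grids[:, free_pos[n.id]]
        return np.full(n_lab, aidx[leaf_states[n.label]])

    cost = np.zeros(n_lab, dtype=np.int64)
    for n in sub_nodes:
        if n is node:
            continue
        cost += column(n) != column(n.parent)
    root_col = column(node)
    return {
        alphabet[s]: int(cost[root_col == s].min()) for s in range(na)
    }


def oracle_deltran(tree: RootedTree, leaf_states, alphabet, outgroup_states):
    """DELTRAN finals derived from enumeration only: exact MPR sets and
    subtree-optimal sets by brute force, then the documented resolution —
    the root takes the alphabetically smallest MPR state present in the
    outgroup (else smallest), every other node inherits its parent's state
    when its MPR set allows, else the smallest member of (MPR ∩
    subtree-optimal), else the smallest MPR state."""
    _, mpr, _, _, _ = enumerate_site(tree, leaf_states, alphabet)
    prelim = {}
    for n in tree.preorder():
        costs = subtree_costs(tree, n, leaf_states, alphabet)
        m = min(costs.values())
        prelim[n.id] = frozenset(s for s, c in costs.items() if c == m)
    finals = {}
    for n in tree.preorder():
        if n.is_leaf:
            s = leaf_states[n.label]
            finals[n.id] = s if s is not None else finals[n.parent.id]
            continue
        cand = mpr[n.id]
        if n.parent is None:
            anchored = sorted(cand & outgroup_states)
            finals[n.id] = anchored[0] if anchored else min(cand)
        else:
            p = finals[n.parent.id]
            if p in cand:
                finals[n.id] = p
            else:
                inter = cand & prelim[n.id]
                finals[n.id] = min(inter) if inter else min(cand)
    return finals


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> str:
    """Random binary topology as newick over leaves a, b, c, ..."""
    labels = [chr(ord("a") + i) for i in range(n_leaves)]
    pool = list(labels)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        pool.append(f"({a},{b})")
    return pool[0] + ";"
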