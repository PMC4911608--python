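"""Parsimony reconstruction with DELTRAN optimization on a fixed topology.

For every alignment column this module computes, under unweighted (Fitch)
parsimony with the reference topology held fixed:

* the tree length *s* (minimum number of state changes),
* per-node MPR sets — the exact set of states a node takes in at least one
  most-parsimonious reconstruction,
* a single DELTRAN ("delayed transformation") assignment that pushes changes
  as far toward the tips as the MPR sets allow, resolved deterministically,
* the resulting per-edge change list (the "apolist"), and
* the consistency index CI = (k - 1)/s, with k the number of distinct
  non-missing states at the column (Kluge-Farris minimum conceivable
  changes for an unordered character).

Missing symbols (X, -, ?) are non-constraining: a missing leaf can take any
state at zero cost and therefore never contributes to tree length.

Lengths and MPR sets are computed by the exact unit-cost dynamic program
(inside cost + outside cost), which coincides with Fitch's set operations on
bifurcations and with Hartigan's generalization on polytomies; exactness at
polytomies is why the DP is used rather than iterated pairwise Fitch sets.

DELTRAN is resolved in pre-order: the root takes the alphabetically smallest
MPR state that also occurs among the outgroup leaves at the column (falling
back to the smallest MPR state); every other node inherits its parent's
state whenever that state is in its own MPR set, otherwise it takes the
alphabetically smallest member of (MPR set ∩ down-pass set), falling back to
the smallest MPR state.  Inheriting whenever possible delays changes toward
the tips; the alphabetical rule makes the output fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .alignment import AminoAcidMatrix, GenePartition, is_missing
from .tree import Node, RootedTree

_INF = 10 ** 9


@dataclass
class Reconstruction:
    """Per-site parsimony reconstruction on the fixed tree."""

    site: int
    length: int
    alphabet: tuple[str, ...]
    #: down-pass (subtree-optimal) state sets per node id
    preliminary: dict[int, frozenset[str]]
    #: states realized in at least one most-parsimonious reconstruction
    mpr: dict[int, frozenset[str]]
    #: DELTRAN final state per node id (None when the column is all-missing)
    final: dict[int, Optional[str]]
    #: node id -> MPR set larger than one state
    ambiguous: dict[int, bool]


@dataclass(frozen=True)
class SiteChange:
    """One inferred state change on an edge; the child node is the clade
    diagnosed by the change."""

    site: int
    gene: str
    parent_node: int
    child_node: int
    from_state: str
    to_state: str
    ambiguous: bool
    ci: float
    k: int           # distinct non-missing states at the site
    length: int      # tree length of the site

    @property
    def ci_exact(self) -> Fraction:
        return Fraction(self.k - 1, self.length)


def _leaf_state(matrix: AminoAcidMatrix, leaf: Node, site: int) -> Optional[str]:
    s = matrix.cell(leaf.label, site)
    return None if is_missing(s) else s


def reconstruct(tree: RootedTree, matrix: AminoAcidMatrix, site: int) -> Reconstruction:
    """Full per-site reconstruction: length, preliminary and MPR sets, and
    DELTRAN final states."""
    if not 1 <= site <= matrix.columns:
        raise IndexError(f"site {site} out of range 1..{matrix.columns}")

    nodes = list(tree.preorder())
    leaf_obs = {
        n.id: _leaf_state(matrix, n, site) for n in nodes if n.is_leaf
    }
    observed = sorted({s for s in leaf_obs.values() if s is not None})

    if len(observed) <= 1:
        state = observed[0] if observed else None
        single = frozenset([state]) if state else frozenset()
        return Reconstruction(
            site=site,
            length=0,
            alphabet=tuple(observed),
            preliminary={n.id: single for n in nodes},
            mpr={n.id: single for n in nodes},
            final={n.id: state for n in nodes},
            ambiguous={n.id: False for n in nodes},
        )

    alphabet = tuple(observed)
    aidx = {s: i for i, s in enumerate(alphabet)}
    na = len(alphabet)

    # -- inside (down) pass: cost[v][s] = min changes in subtree(v) given v=s
    cost: dict[int, list[int]] = {}
    # min(cost[v][t], m_v + 1) per state: the cheapest way to attach subtree
    # v under a parent in state t
    attach: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            obs = leaf_obs[node.id]
            if obs is None:
                c = [0] * na
            else:
                c = [_INF] * na
                c[aidx[obs]] = 0
        else:
            c = [0] * na
            for child in node.children:
                ac = attach[child.id]
                for i in range(na):
                    c[i] += ac[i]
        m = min(c)
        attach[node.id] = [min(c[i], m + 1) for i in range(na)]
        cost[node.id] = c

    length = min(cost[tree.root.id])

    # -- outside (up) pass: above[v][s] = min changes outside subtree(v)
    # given v=s
    above: dict[int, list[int]] = {tree.root.id: [0] * na}
    for node in nodes:
        if node.is_leaf:
            continue
        au = above[node.id]
        for child in node.children:
            # E[t] = outside cost of u plus the attachment of all siblings
            e = list(au)
            for sib in node.children:
                if sib is child:
                    continue
                ac = attach[sib.id]
                for i in range(na):
                    e[i] += ac[i]
            me = min(e)
            above[child.id] = [min(e[i], me + 1) for i in range(na)]

    preliminary = {}
    mpr = {}
    for node in nodes:
        c = cost[node.id]
        mc = min(c)
        preliminary[node.id] = frozenset(
            alphabet[i] for i in range(na) if c[i] == mc
        )
        a = above[node.id]
        mpr[node.id] = frozenset(
            alphabet[i] for i in range(na) if c[i] + a[i] == length
        )

    # -- DELTRAN resolution (pre-order)
    final: dict[int, Optional[str]] = {}
    out_states = {
        s
        for leaf, s in (
            (n, leaf_obs[n.id]) for n in nodes if n.is_leaf and n.label in tree.outgroup
        )
        if s is not None
    }
    for node in nodes:
        if node.is_leaf:
            obs = leaf_obs[node.id]
            final[node.id] = obs if obs is not None else final[node.parent.id]
            continue
        cand = mpr[node.id]
        if node.parent is None:
            anchored = sorted(cand & out_states)
            final[node.id] = anchored[0] if anchored else min(cand)
        else:
            pstate = final[node.parent.id]
            if pstate in cand:
                final[node.id] = pstate
            else:
                inter = cand & preliminary[node.id]
                final[node.id] = min(inter) if inter else min(cand)

    ambiguous = {
        n.id: (len(mpr[n.id]) > 1) if not n.is_leaf
        else (leaf_obs[n.id] is None)
        for n in nodes
    }
    # rooting on the outgroup polarizes the root: when the outgroup states
    # pin a unique member of the root's MPR set, the root is resolved
    root = tree.root
    if ambiguous[root.id] and len(mpr[root.id] & out_states) == 1:
        ambiguous[root.id] = False
    return Reconstruction(
        site=site,
        length=length,
        alphabet=alphabet,
        preliminary=preliminary,
        mpr=mpr,
        final=final,
        ambiguous=ambiguous,
    )


def fitch_down_pass(
    tree: RootedTree, matrix: AminoAcidMatrix, site: int
) -> tuple[dict[int, frozenset[str]], int]:
    """Down-pass state sets and tree length for one site.

    Returns the subtree-optimal state set per node id and the parsimony
    length.  Leaves with missing data never contribute to length.
    """
    rec = reconstruct(tree, matrix, site)
    return rec.preliminary, rec.length


def mpr_sets(
    tree: RootedTree, matrix: AminoAcidMatrix, site: int
) -> dict[int, frozenset[str]]:
    """Exact MPR set per node id: states assignable in at least one
    most-parsimonious reconstruction."""
    return reconstruct(tree, matrix, site).mpr


def deltran_resolve(tree: RootedTree, matrix: AminoAcidMatrix, site: int) -> dict[int, Optional[str]]:
    """DELTRAN final state per node id for one site."""
    return reconstruct(tree, matrix, site).final


def site_changes(
    tree: RootedTree,
    reconstruction: Reconstruction,
    matrix: AminoAcidMatrix,
    partition: GenePartition | None = None,
) -> list[SiteChange]:
    """Per-edge changes of the DELTRAN assignment, in pre-order edge order.

    Edges into nodes containing outgroup taxa are excluded: only ingroup
    clades are apomorphy candidates.  A change is flagged ambiguous when
    either endpoint's MPR set holds more than one state.
    """
    rec = reconstruction
    if rec.length == 0:
        return []
    ci = Fraction(len(rec.alphabet) - 1, rec.length)
    gene = partition.gene_of(rec.site) if partition else GenePartition.UNASSIGNED
    changes: list[SiteChange] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        if not tree.is_ingroup_node(node):
            continue
        f_child = rec.final[node.id]
        f_parent = rec.final[node.parent.id]
        if f_child is None or f_parent is None or f_child == f_parent:
            continue
        if node.is_leaf and is_missing(matrix.cell(node.label, rec.site)):
            continue  # missing leaves inherit silently; never a change
        changes.append(
            SiteChange(
                site=rec.site,
                gene=gene,
                parent_node=node.parent.id,
                child_node=node.id,
                from_state=f_parent,
                to_state=f_child,
                ambiguous=bool(
                    rec.ambiguous.get(node.parent.id) or
                    (not node.is_leaf and rec.ambiguous.get(node.id))
                ),
                ci=float(ci),
                k=len(rec.alphabet),
                length=rec.length,
            )
        )
    return changes


def consistency_index(matrix: AminoAcidMatrix, site: int, length: int) -> float:
    """CI = (k - 1) / length with k the distinct non-missing states.

    Undefined (raises) for invariant sites, which carry no apomorphies.
    """
    if length < 1:
        raise ValueError("CI undefined for invariant sites (length 0)")
    k = len(matrix.observed_states(site))
    return float(Fraction(k - 1, length))


def apomorphy_list(
    tree: RootedTree,
    matrix: AminoAcidMatrix,
    partition: GenePartition | None = None,
    sites: Sequence[int] | None = None,
) -> list[SiteChange]:
    """Concatenated change lists over all variable sites (the apolist).

    Deterministic order: by site, then pre-order edge order within a site.
    """
    if partition is not None:
        partition.validate_against(matrix.columns)
    out: list[SiteChange] = []
    for site in sites if sites is not None else range(1, matrix.columns + 1):
        if len(matrix.observed_states(site)) < 2:
            continue  # invariant or all-missing: no apomorphies
        rec = reconstruct(tree, matrix, site)
        out.extend(site_changes(tree, rec, matrix, partition))
    return out
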