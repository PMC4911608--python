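"""Screening and selection of diagnostic apomorphies per clade.

Every candidate passes through four checks before it may become a clade
code:

a. *sister overlap* — the derived state must not occur in the clade's
   sister group (otherwise it could be a plesiomorphy);
b. *missing data* — the sister group and the basal child lineage of the
   clade must not be entirely missing at the site, and the fraction of
   clade leaves missing at the site must not exceed a configured cap;
c. *uniqueness* — states unique in the whole matrix rank highest
   ("unique"), then states unique relative to the sister group with
   uniform carriers ("clade_unique"), then binary states whose two
   variants are each uniform within one child subclade
   ("multistate_trend", rendered |T/V|); scattered multistate patterns are
   rejected;
d. *gene economy* — genes with broad taxon coverage are preferred, and on
   exact ties genes already used by other clades are favoured, so the
   final code set involves as few markers as practical.

Clades sampled with fewer leaves than ``min_clade_taxa`` are never coded:
an apomorphy observed in a single sampled taxon cannot be shown to be
shared by the clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import AminoAcidMatrix, GenePartition, is_missing
from .mining import ApomorphyCandidate
from .tree import Node, RootedTree

logger = logging.getLogger(__name__)

REJECTION_REASONS = (
    "sister_overlap",
    "sister_or_basal_missing",
    "clade_missing_excess",
    "singleton_clade",
    "low_coverage",
    "inconsistent_multistate",
)

PRIORITY_CLASSES = ("unique", "clade_unique", "multistate_trend")
_CLASS_RANK = {c: i for i, c in enumerate(PRIORITY_CLASSES)}


@dataclass
class ScreeningConfig:
    max_missing_fraction: float = 0.5
    min_clade_taxa: int = 2
    allow_multistate: bool = True
    codes_per_clade: int = 1

    def __post_init__(self):
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.min_clade_taxa < 2:
            raise ValueError("min_clade_taxa must be >= 2")
        if self.codes_per_clade < 1:
            raise ValueError("codes_per_clade must be >= 1")


@dataclass
class ScreeningDecision:
    candidate: ApomorphyCandidate
    verdict: str                      # "accepted" | "rejected"
    reason: Optional[str] = None      # rejection reason
    priority_class: Optional[str] = None
    states: tuple[str, ...] = ()      # 1 state, or 2 for a binary code
    #: for binary codes: child node id -> the uniform state of that subclade
    state_by_child: dict = field(default_factory=dict)


@dataclass
class ScreeningReport:
    decisions: list[ScreeningDecision] = field(default_factory=list)

    def accepted(self) -> list[ScreeningDecision]:
        return [d for d in self.decisions if d.verdict == "accepted"]

    def rejected(self, reason: Optional[str] = None) -> list[ScreeningDecision]:
        out = [d for d in self.decisions if d.verdict == "rejected"]
        if reason is not None:
            out = [d for d in out if d.reason == reason]
        return out


# ---------------------------------------------------------------------------
# individual criteria


def sister_group_leaves(tree: RootedTree, node: Node) -> tuple[str, ...]:
    """Leaves of the sister group: the union of the parent's other children
    (hard polytomies included)."""
    if node.parent is None:
        raise ValueError("the root has no sister group and is never coded")
    leaves: list[str] = []
    for sib in node.parent.children:
        if sib is not node:
            leaves.extend(sorted(tree.leafset(sib)))
    return tuple(leaves)


def sister_overlap(
    candidate: ApomorphyCandidate, tree: RootedTree, matrix: AminoAcidMatrix
) -> bool:
    """True (reject) when the derived state occurs in any sister-group leaf
    at the site; missing sister leaves do not count as overlap."""
    node = tree.nodes[candidate.clade]
    for taxon in sister_group_leaves(tree, node):
        s = matrix.cell(taxon, candidate.site)
        if not is_missing(s) and s == candidate.to_state:
            return True
    return False


def _basal_child(tree: RootedTree, node: Node) -> Optional[Node]:
    """The basal (smallest, ties broken by child order) child lineage of an
    internal clade; None for leaves."""
    if node.is_leaf:
        return None
    return min(node.children, key=lambda c: (len(tree.leafset(c)),
                                             node.children.index(c)))


def missing_check(
    candidate: ApomorphyCandidate,
    tree: RootedTree,
    matrix: AminoAcidMatrix,
    config: ScreeningConfig,
) -> Optional[str]:
    """Rejection reason from the missing-data criteria, or None to pass."""
    node = tree.nodes[candidate.clade]
    sisters = sister_group_leaves(tree, node)
    if sisters and all(is_missing(matrix.cell(t, candidate.site)) for t in sisters):
        return "sister_or_basal_missing"
    basal = _basal_child(tree, node)
    if basal is not None:
        basal_leaves = sorted(tree.leafset(basal))
        if all(is_missing(matrix.cell(t, candidate.site)) for t in basal_leaves):
            return "sister_or_basal_missing"
    if candidate.clade_taxa:
        frac = len(candidate.missing_leaves) / len(candidate.clade_taxa)
        if frac > config.max_missing_fraction:
            return "clade_missing_excess"
    return None


def uniqueness_class(
    candidate: ApomorphyCandidate, matrix: AminoAcidMatrix, tree: RootedTree
) -> tuple[Optional[str], tuple[str, ...]]:
    """Priority class and the code's state set.

    Returns (None, states) when the carrier pattern is an inconsistent
    multistate (rejected).
    """
    node = tree.nodes[candidate.clade]
    clade = set(candidate.clade_taxa)
    site = candidate.site

    outside_states = {
        matrix.cell(t, site)
        for t in matrix.taxa
        if t not in clade and not is_missing(matrix.cell(t, site))
    }
    clade_states = {
        matrix.cell(t, site)
        for t in clade
        if not is_missing(matrix.cell(t, site))
    }

    if len(clade_states) <= 1:
        # uniform carriers
        if candidate.to_state not in outside_states:
            return "unique", (candidate.to_state,)
        return "clade_unique", (candidate.to_state,)

    # several states within the clade: accept only a binary pattern that is
    # uniform within each child subclade (a consistent evolutionary trend)
    if len(clade_states) == 2 and not node.is_leaf:
        for child in node.children:
            child_states = {
                matrix.cell(t, site)
                for t in tree.leafset(child)
                if not is_missing(matrix.cell(t, site))
            }
            if len(child_states) > 1:
                return None, tuple(sorted(clade_states))
        return "multistate_trend", tuple(sorted(clade_states))
    return None, tuple(sorted(clade_states))


def screen_candidate(
    candidate: ApomorphyCandidate,
    tree: RootedTree,
    matrix: AminoAcidMatrix,
    config: ScreeningConfig,
) -> ScreeningDecision:
    """Run criteria (a)-(c) on one candidate."""
    node = tree.nodes[candidate.clade]
    if len(candidate.clade_taxa) < config.min_clade_taxa:
        reason = "singleton_clade" if len(candidate.clade_taxa) == 1 else "low_coverage"
        return ScreeningDecision(candidate, "rejected", reason)
    if node.parent is None:
        raise ValueError("the root clade is never coded")
    if sister_overlap(candidate, tree, matrix):
        return ScreeningDecision(candidate, "rejected", "sister_overlap")
    reason = missing_check(candidate, tree, matrix, config)
    if reason:
        return ScreeningDecision(candidate, "rejected", reason)
    cls, states = uniqueness_class(candidate, matrix, tree)
    if cls is None or (cls == "multistate_trend" and not config.allow_multistate):
        return ScreeningDecision(candidate, "rejected", "inconsistent_multistate",
                                 states=states)
    state_by_child: dict = {}
    if cls == "multistate_trend":
        for child in node.children:
            child_states = {
                matrix.cell(t, candidate.site)
                for t in tree.leafset(child)
                if not is_missing(matrix.cell(t, candidate.site))
            }
            if child_states:
                state_by_child[child.id] = child_states.pop()
    return ScreeningDecision(candidate, "accepted", priority_class=cls,
                             states=states, state_by_child=state_by_child)


# ---------------------------------------------------------------------------
# ranking and selection


def gene_breadth(matrix: AminoAcidMatrix, partition: GenePartition | None,
                 gene: str) -> int:
    """Number of matrix taxa with at least one non-missing residue in the
    gene; the whole matrix counts as one gene when unpartitioned."""
    if partition is None or gene == GenePartition.UNASSIGNED:
        span = (1, matrix.columns)
    else:
        span = partition.span(gene)
    start, end = span
    count = 0
    for t in matrix.taxa:
        row = matrix.row(t)[start - 1:end]
        if any(not is_missing(ch) for ch in row):
            count += 1
    return count


def _rank_key(decision: ScreeningDecision, breadths: dict[str, int]):
    c = decision.candidate
    return (
        _CLASS_RANK[decision.priority_class],
        len(c.missing_leaves),
        -breadths.get(c.gene, 0),
        c.gene,
        c.site,
    )


def rank_candidates(
    accepted: Sequence[ScreeningDecision],
    matrix: AminoAcidMatrix,
    partition: GenePartition | None = None,
) -> list[ScreeningDecision]:
    """Deterministic priority order within a clade: unique > clade_unique >
    multistate_trend, then fewer missing leaves, broader genes, and finally
    lexicographic (gene, site)."""
    breadths = {
        d.candidate.gene: gene_breadth(matrix, partition, d.candidate.gene)
        for d in accepted
    }
    return sorted(accepted, key=lambda d: _rank_key(d, breadths))


def select_codes(
    tree: RootedTree,
    candidates: Sequence[ApomorphyCandidate],
    config: ScreeningConfig,
    matrix: AminoAcidMatrix,
    partition: GenePartition | None = None,
) -> tuple[dict[int, list[ScreeningDecision]], ScreeningReport]:
    """Choose up to ``codes_per_clade`` apomorphies per qualifying clade.

    Clades are visited in pre-order; on exact ranking ties a gene already
    chosen for another clade wins (gene economy).  Clades left with no
    accepted candidate are logged and stay uncoded.
    """
    report = ScreeningReport()
    by_clade: dict[int, list[ScreeningDecision]] = {}
    for cand in candidates:
        decision = screen_candidate(cand, tree, matrix, config)
        report.decisions.append(decision)
        if decision.verdict == "accepted":
            by_clade.setdefault(cand.clade, []).append(decision)

    breadth_cache: dict[str, int] = {}

    def breadth(gene: str) -> int:
        if gene not in breadth_cache:
            breadth_cache[gene] = gene_breadth(matrix, partition, gene)
        return breadth_cache[gene]

    selection: dict[int, list[ScreeningDecision]] = {}
    used_genes: set[str] = set()
    for node in tree.preorder():
        decisions = by_clade.get(node.id)
        if not decisions:
            continue
        breadths = {d.candidate.gene: breadth(d.candidate.gene) for d in decisions}
        remaining = sorted(decisions, key=lambda d: _rank_key(d, breadths))
        chosen: list[ScreeningDecision] = []
        while remaining and len(chosen) < config.codes_per_clade:
            best_key = _rank_key(remaining[0], breadths)[:3]
            tied = [d for d in remaining
                    if _rank_key(d, breadths)[:3] == best_key]
            preferred = [d for d in tied if d.candidate.gene in used_genes]
            pick = (preferred or tied)[0]
            chosen.append(pick)
            used_genes.add(pick.candidate.gene)
            remaining.remove(pick)
        selection[node.id] = chosen

    uncoded = [
        n.id for n in tree.preorder()
        if not n.is_leaf and n.parent is not None and tree.is_ingroup_node(n)
        and len(tree.leafset(n)) >= config.min_clade_taxa
        and n.id not in selection
    ]
    if uncoded:
        logger.info("%d qualifying clades received no code: %s",
                    len(uncoded), uncoded)
    return selection, report
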