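"""Candidate filtering and sub-dataset assembly.

The raw apolist is thinned in two steps: changes whose endpoints had
ambiguous (multi-state) MPR sets are dropped, then a consistency-index
threshold is applied (the stringent 1.0 / 0.9 / 0.8 scheme).  Surviving
changes become :class:`ApomorphyCandidate` records annotated with the
leaves of the diagnosed clade, the leaves actually carrying the derived
state, and the leaves missing at the site.  The union of candidate sites
forms a filtered sub-dataset of the original matrix.

Candidate counts refer to changes, not sites: one site can diagnose several
clades.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .alignment import AminoAcidMatrix, is_missing
from .parsimony import SiteChange
from .tree import RootedTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ApomorphyCandidate:
    """A screened state change that may diagnose its clade."""

    change: SiteChange
    clade_taxa: tuple[str, ...]      # ingroup leaves under the diagnosed clade
    carriers: tuple[str, ...]        # clade leaves actually showing to_state
    missing_leaves: tuple[str, ...]  # clade leaves missing at the site

    @property
    def site(self) -> int:
        return self.change.site

    @property
    def gene(self) -> str:
        return self.change.gene

    @property
    def clade(self) -> int:
        return self.change.child_node

    @property
    def to_state(self) -> str:
        return self.change.to_state

    @property
    def from_state(self) -> str:
        return self.change.from_state

    @property
    def ci(self) -> float:
        return self.change.ci


def _as_fraction(threshold: float) -> Fraction:
    return Fraction(str(threshold))


def annotate(change: SiteChange, tree: RootedTree, matrix: AminoAcidMatrix) -> ApomorphyCandidate:
    node = tree.nodes[change.child_node]
    clade_taxa = tuple(sorted(tree.leafset(node)))
    carriers = []
    missing = []
    for taxon in clade_taxa:
        s = matrix.cell(taxon, change.site)
        if is_missing(s):
            missing.append(taxon)
        elif s == change.to_state:
            carriers.append(taxon)
    return ApomorphyCandidate(
        change=change,
        clade_taxa=clade_taxa,
        carriers=tuple(carriers),
        missing_leaves=tuple(missing),
    )


def filter_candidates(
    apolist: Sequence[SiteChange],
    ci_threshold: float,
    tree: RootedTree,
    matrix: AminoAcidMatrix,
) -> list[ApomorphyCandidate]:
    """Keep unambiguous changes with CI >= ``ci_threshold`` (exact rational
    comparison) and annotate them for screening."""
    if not 0 < ci_threshold <= 1:
        raise ValueError("ci_threshold must be in (0, 1]")
    thr = _as_fraction(ci_threshold)
    dropped_ambiguous = sum(1 for c in apolist if c.ambiguous)
    if dropped_ambiguous:
        logger.info("dropping %d ambiguous changes", dropped_ambiguous)
    kept = [
        c for c in apolist
        if not c.ambiguous and c.ci_exact >= thr
    ]
    return [annotate(c, tree, matrix) for c in kept]


def build_subdataset(
    matrix: AminoAcidMatrix, candidates: Sequence[ApomorphyCandidate]
) -> tuple[AminoAcidMatrix, dict]:
    """Matrix restricted to the sorted union of candidate sites.

    Returns the sub-matrix and a report with the candidate (change) count
    and the distinct site count.
    """
    if not candidates:
        raise ValueError("no candidates: cannot build an empty sub-dataset")
    sites = sorted({c.site for c in candidates})
    sub = matrix.restrict(sites)
    report = {
        "n_candidates": len(candidates),
        "n_sites": len(sites),
        "sites": sites,
    }
    return sub, report
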