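"""Query identification: tree-climbing barcode matching with missing-state
descent.

A query is reduced to a :class:`QueryObservation`: one token per database
code — an amino acid, ``X`` (the site is missing inside a sequenced gene)
or ``?`` (the whole gene is absent).  Identification then walks the code
trie from the root:

* a child clade is *matched* when the observed token at its code belongs to
  the code's state set;
* it is *excluded* when the token is an amino acid outside the state set
  (no fuzzy matching: a single contradicting residue vetoes the branch);
* when the token is missing the walk looks past the code and lets deeper
  codes discriminate: a branch stays viable while nothing downstream
  contradicts it, and a positive match deeper inside confirms it.

The assigned clade is the deepest node whose own code was matched
non-missing with no non-missing mismatch anywhere on its path.  Against a
truth label the outcome is categorized as in the query test: *positive*
(right terminal), *false_positive* (wrong terminal), *false_negative*
(stopped above the terminal because of missing states on the remaining
path) or *negative* (stopped by state mismatches).

With code redundancy (several codes per clade) a clade is judged matched
when at least half of its non-missing codes match, and missing only when
all of them are missing.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment import (
    GAP,
    MISSING_GENE,
    MISSING_RESIDUE,
    AminoAcidMatrix,
    GenePartition,
    is_missing,
)
from .coding import Barcode, CodeDatabase

MATCH = "match"
MISMATCH = "mismatch"
MISSING = "missing"

CATEGORIES = ("positive", "false_positive", "false_negative", "negative",
              "unassigned_truth_unknown")


@dataclass(frozen=True)
class QueryObservation:
    """One observed token per database code ID.

    IDs absent from ``tokens`` are unknown (off-lineage in fixture mode);
    they can never confirm a clade but do not exclude it either.
    """

    tokens: Mapping[str, str]

    def token(self, ident: str) -> Optional[str]:
        return self.tokens.get(ident)

    @property
    def n_missing_residue(self) -> int:
        return sum(1 for t in self.tokens.values() if t == MISSING_RESIDUE)

    @property
    def n_missing_gene(self) -> int:
        return sum(1 for t in self.tokens.values() if t == MISSING_GENE)


@dataclass
class QueryResult:
    assigned: Optional[object]        # database node key, or None
    assigned_name: Optional[str]
    stop_reason: str                  # terminal | exhausted_mismatch | unresolved_missing
    category: Optional[str] = None
    complete_match: bool = False
    match_log: list = field(default_factory=list)
    n_missing_residue: int = 0
    n_missing_gene: int = 0


def observation_from_barcode(barcode: Barcode | str) -> QueryObservation:
    """Observation from a generated barcode string (fixture mode)."""
    from .coding import parse_barcode

    if isinstance(barcode, str):
        barcode = parse_barcode(barcode, kind="generated")
    return QueryObservation(dict((i, s) for s, i in barcode.pairs))


def extract_states(
    db: CodeDatabase,
    query_genes: Mapping[str, str],
    partition: GenePartition,
) -> QueryObservation:
    """Read the query symbol at every database code.

    ``query_genes`` maps gene name -> the query's row in that gene's
    alignment (same column space as the database alignment's gene block).
    Genes absent from the mapping yield ``?`` at all their codes; gaps and
    undetermined residues yield ``X``.
    """
    tokens: dict[str, str] = {}
    for code in db.codes:
        if code.gene is None or code.site is None:
            raise ValueError(f"code {code.id} lacks gene/site provenance")
        if code.gene not in query_genes:
            tokens[code.id] = MISSING_GENE
            continue
        start, end = partition.span(code.gene)
        seq = query_genes[code.gene].upper()
        if len(seq) != end - start + 1:
            raise ValueError(
                f"query row for gene {code.gene!r} has length {len(seq)}, "
                f"expected {end - start + 1}"
            )
        symbol = seq[code.site - start]
        if symbol == MISSING_GENE:
            tokens[code.id] = MISSING_GENE
        elif symbol == GAP or symbol == MISSING_RESIDUE or is_missing(symbol):
            tokens[code.id] = MISSING_RESIDUE
        else:
            tokens[code.id] = symbol
    return QueryObservation(tokens)


def observation_from_matrix_row(
    db: CodeDatabase, matrix: AminoAcidMatrix, taxon: str
) -> QueryObservation:
    """Observation for a database taxon's own row (self-identification)."""
    tokens: dict[str, str] = {}
    for code in db.codes:
        symbol = matrix.cell(taxon, code.site)
        if symbol == MISSING_GENE:
            tokens[code.id] = MISSING_GENE
        elif is_missing(symbol):
            tokens[code.id] = MISSING_RESIDUE
        else:
            tokens[code.id] = symbol
    return QueryObservation(tokens)


# ---------------------------------------------------------------------------
# matching


def _judge(db: CodeDatabase, key, obs: QueryObservation) -> str:
    """Match status of one coded node, with majority rule over redundant
    codes."""
    codes = db.nodes[key].codes
    statuses = []
    for code in codes:
        token = obs.token(code.id)
        if token is None or token in (MISSING_RESIDUE, MISSING_GENE, GAP):
            statuses.append(MISSING)
        elif code.matches(token):
            statuses.append(MATCH)
        else:
            statuses.append(MISMATCH)
    informative = [s for s in statuses if s != MISSING]
    if not informative:
        return MISSING
    n_match = sum(1 for s in informative if s == MATCH)
    return MATCH if n_match >= math.ceil(len(informative) / 2) else MISMATCH


def _deepest_confirmed(db: CodeDatabase, key, obs: QueryObservation,
                       log: list) -> Optional[object]:
    """Deepest node in the subtree at ``key`` whose code matched non-missing,
    reachable without crossing a non-missing mismatch; None if nothing in the
    subtree is confirmed."""
    status = _judge(db, key, obs)
    log.append((key, status))
    if status == MISMATCH:
        return None
    own = key if status == MATCH else None
    confirmed_below = []
    for child in db.nodes[key].children:
        deep = _deepest_confirmed(db, child, obs, log)
        if deep is not None:
            confirmed_below.append(deep)
    if len(confirmed_below) == 1:
        return confirmed_below[0]
    # zero or conflicting confirmations below: stop at the node itself
    return own


def assign(db: CodeDatabase, obs: QueryObservation) -> QueryResult:
    """Root-to-leaf identification of one observation."""
    log: list = []
    confirmed = []
    for root in db.roots:
        deep = _deepest_confirmed(db, root, obs, log)
        if deep is not None:
            confirmed.append(deep)
    assigned = confirmed[0] if len(confirmed) == 1 else None

    if assigned is not None and db.is_terminal(assigned):
        reason = "terminal"
    else:
        frontier = db.nodes[assigned].children if assigned is not None else db.roots
        statuses = [_judge(db, c, obs) for c in frontier]
        if statuses and all(s == MISMATCH for s in statuses):
            reason = "exhausted_mismatch"
        else:
            reason = "unresolved_missing"

    return QueryResult(
        assigned=assigned,
        assigned_name=db.name_of(assigned) if assigned is not None else None,
        stop_reason=reason,
        match_log=log,
        n_missing_residue=obs.n_missing_residue,
        n_missing_gene=obs.n_missing_gene,
    )


def categorize(
    db: CodeDatabase,
    result: QueryResult,
    truth_terminal,
    obs: QueryObservation,
) -> str:
    """Query-test category of a result against the true terminal."""
    if truth_terminal is None:
        return "unassigned_truth_unknown"
    if result.assigned == truth_terminal:
        return "positive"
    if result.assigned is not None and db.is_terminal(result.assigned):
        return "false_positive"
    # stopped above terminal level: blame a mismatch if one exists on the
    # true path, otherwise missing states
    for key in db.path(truth_terminal):
        if _judge(db, key, obs) == MISMATCH:
            return "negative"
    return "false_negative"


def _complete_match(db: CodeDatabase, truth_terminal, obs: QueryObservation) -> bool:
    return all(
        _judge(db, key, obs) == MATCH for key in db.path(truth_terminal)
    )


@dataclass
class EvaluationRow:
    name: str
    result: QueryResult
    truth: object
    category: str
    complete_match: bool


def evaluate(
    db: CodeDatabase,
    queries: Sequence[tuple[str, QueryObservation, object]],
) -> tuple[list[EvaluationRow], Counter]:
    """Assign and categorize a batch of (name, observation, truth-terminal)
    queries; returns per-row results and category counts."""
    rows: list[EvaluationRow] = []
    counts: Counter = Counter()
    for name, obs, truth in queries:
        res = assign(db, obs)
        cat = categorize(db, res, truth, obs)
        complete = (
            cat == "positive" and truth is not None
            and _complete_match(db, truth, obs)
        )
        res.category = cat
        res.complete_match = complete
        rows.append(EvaluationRow(name, res, truth, cat, complete))
        counts[cat] += 1
        if complete:
            counts["complete_match"] += 1
    return rows, counts


def missingness_report(
    observations: Iterable[QueryObservation],
) -> dict:
    """Fractions of missing tokens attributable to missing residues (X)
    versus missing genes (?), over all queries."""
    n_x = 0
    n_q = 0
    per_query = []
    for obs in observations:
        x, q = obs.n_missing_residue, obs.n_missing_gene
        per_query.append({"n_X": x, "n_question": q})
        n_x += x
        n_q += q
    total = n_x + n_q
    return {
        "n_X": n_x,
        "n_question": n_q,
        "n_missing": total,
        "fraction_X": (n_x / total) if total else None,
        "fraction_question": (n_q / total) if total else None,
        "per_query": per_query,
    }
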