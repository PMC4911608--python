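"""Clade codes, sequential IDs, the code database and barcode serialization.

Each coded internal node carries a *code*: the derived amino-acid state(s)
of its selected apomorphy plus a sequential two-character base-36 ID
("00", "01", ..., "0Z", "10", ...), optionally with a one-letter dataset
prefix for secondary databases ("S01" style).  IDs follow a pre-order
traversal of the coded nodes, so along any root-to-leaf path they are
strictly increasing.

The complete description of a terminal category is its *designed barcode*:
the concatenation of the (state, ID) codes on its root-to-terminal path,
serialized ``T_00_I_02_G_03_...``.  An ancestor's barcode is always a
prefix of its descendants' barcodes; the barcode minus its final pair is
the clade's *lineage prefix*.  Binary codes (two states, each uniform in
one child subclade) display compactly as ``|T/V|``.

Generated (observed) barcodes use the same serialization but may contain
``X`` (missing residue) or ``?`` (missing gene) state tokens.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .selection import ScreeningDecision
from .tree import RootedTree

logger = logging.getLogger(__name__)

_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_ID_RE = re.compile(r"^([A-Z]?)([0-9A-Z]{2})$")
_BINARY_RE = re.compile(r"^\|[A-Z?X](?:/[A-Z?X])+\|$")


def base36_id(index: int, prefix: str = "") -> str:
    """Two-character base-36 token for ``index`` (0 -> "00", 36 -> "10")."""
    if not 0 <= index < 36 * 36:
        raise ValueError("id index out of base-36 range")
    return f"{prefix}{_B36[index // 36]}{_B36[index % 36]}"


def id_sort_key(token: str) -> tuple[str, int]:
    """Sort key: dataset prefix first, then base-36 value."""
    m = _ID_RE.match(token)
    if not m:
        raise ValueError(f"malformed id token: {token!r}")
    prefix, digits = m.groups()
    return prefix, _B36.index(digits[0]) * 36 + _B36.index(digits[1])


# ---------------------------------------------------------------------------
# barcodes


@dataclass(frozen=True)
class Barcode:
    """An ordered sequence of (state token, code ID) pairs.

    ``kind`` is "designed" (database truth) or "generated" (observed from a
    query; may contain X/? tokens).
    """

    pairs: tuple[tuple[str, str], ...]
    kind: str = "designed"

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i for _, i in self.pairs)

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.pairs)

    def compact(self) -> str:
        """Concatenated state tokens, e.g. ``TIGERSINNNAY``."""
        return "".join(self.states)

    def drop_last(self) -> "Barcode":
        return Barcode(self.pairs[:-1], self.kind)

    def __len__(self) -> int:
        return len(self.pairs)


def format_barcode(barcode: Barcode) -> str:
    """Serialize as ``<state>_<id>_`` repeated (trailing underscore kept)."""
    return "".join(f"{s}_{i}_" for s, i in barcode.pairs)


def parse_barcode(text: str, kind: str = "designed") -> Barcode:
    """Exact inverse of :func:`format_barcode` on well-formed strings.

    One known typographical variant is normalized: a single-character ID
    token is missing its leading "1" and is restored (logged), so
    ``X_A_E_1C`` parses as (X, 1A), (E, 1C).
    """
    tokens = [t for t in text.strip().split("_") if t != ""]
    if len(tokens) % 2 != 0:
        raise ValueError(f"odd token count in barcode at offset {len(text)}: {text!r}")
    pairs = []
    for pos in range(0, len(tokens), 2):
        state, ident = tokens[pos], tokens[pos + 1]
        if not (len(state) == 1 or _BINARY_RE.match(state)):
            raise ValueError(
                f"malformed state token {state!r} at pair {pos // 2} of {text!r}"
            )
        if len(ident) == 1 and ident in _B36:
            logger.warning(
                "barcode %r: single-character id %r normalized to %r",
                text, ident, "1" + ident,
            )
            ident = "1" + ident
        if not _ID_RE.match(ident):
            raise ValueError(
                f"malformed id token {ident!r} at pair {pos // 2} of {text!r}"
            )
        pairs.append((state, ident))
    return Barcode(tuple(pairs), kind)


# ---------------------------------------------------------------------------
# codes and the database


@dataclass(frozen=True)
class CladeCode:
    """The diagnostic code of one clade: state set, ID and provenance."""

    id: str                           # base-36 token, optional prefix letter
    states: tuple[str, ...]           # 1 state, or 2 for a binary code
    plesiomorphic: Optional[str] = None
    site: Optional[int] = None
    gene: Optional[str] = None
    #: for binary codes built from a tree: child node id -> that lineage's state
    state_by_child: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.states or len(self.states) > 2:
            raise ValueError("a code carries one or two states")
        if self.plesiomorphic is not None and self.plesiomorphic in self.states:
            raise ValueError("plesiomorphic state cannot be an apomorphic state")

    def display_state(self) -> str:
        if len(self.states) == 1:
            return self.states[0]
        return "|" + "/".join(self.states) + "|"

    def matches(self, token: str) -> bool:
        """A generated state matches a binary code iff it is in the state set."""
        return token in self.states


@dataclass
class CodedNode:
    key: object                       # tree node id (int) or primary ID (str)
    name: Optional[str]
    codes: list[CladeCode]
    parent: Optional[object] = None
    children: list = field(default_factory=list)

    @property
    def primary_id(self) -> str:
        return self.codes[0].id


class CodeDatabase:
    """The ordered clade codes plus the lineage trie of coded nodes.

    Terminal categories are coded nodes without coded descendants; each has
    a designed barcode, the concatenation of the codes on its root-to-
    terminal path, and the prefix property holds for every ancestor/
    descendant pair by construction.
    """

    def __init__(self, nodes: Mapping[object, CodedNode],
                 designed: Optional[Mapping[object, Barcode]] = None):
        self.nodes: dict[object, CodedNode] = dict(nodes)
        ids = [c.id for n in self.nodes.values() for c in n.codes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate code ids: {dupes}")
        self.roots = [k for k, n in self.nodes.items() if n.parent is None]
        for n in self.nodes.values():
            n.children.sort(key=lambda k: id_sort_key(self.nodes[k].primary_id))
        self.terminals = [k for k, n in self.nodes.items() if not n.children]
        self._designed: dict[object, Barcode] = dict(designed or {})
        for t in self.terminals:
            if t not in self._designed:
                self._designed[t] = self._materialize(t)
        self._check_preorder_ids()

    # -- construction ---------------------------------------------------------

    @classmethod
    def from_selection(
        cls,
        selection: Mapping[int, Sequence[ScreeningDecision]],
        tree: RootedTree,
        prefix: str = "",
        names: Optional[Mapping[int, str]] = None,
    ) -> "CodeDatabase":
        """Build the database from per-clade selected apomorphies.

        IDs are dense, assigned over codes in pre-order of the coded nodes.
        """
        coded = {k: v for k, v in selection.items() if v}
        if not coded:
            raise ValueError("empty selection: no coded clades")
        names = dict(names or {})
        nodes: dict[object, CodedNode] = {}
        decisions_at: dict[int, Sequence[ScreeningDecision]] = {}
        counter = 0
        ancestry: dict[int, Optional[int]] = {}
        for node in tree.preorder():
            parent_key = ancestry.get(node.parent.id) if node.parent else None
            if node.id in coded:
                codes = []
                for dec in coded[node.id]:
                    c = dec.candidate
                    codes.append(
                        CladeCode(
                            id=base36_id(counter, prefix),
                            states=tuple(dec.states),
                            plesiomorphic=c.from_state,
                            site=c.site,
                            gene=c.gene,
                        )
                    )
                    counter += 1
                name = names.get(node.id) or tree.nodes[node.id].name
                nodes[node.id] = CodedNode(node.id, name, codes, parent_key)
                decisions_at[node.id] = coded[node.id]
                if parent_key is not None:
                    nodes[parent_key].children.append(node.id)
                ancestry[node.id] = node.id
            else:
                ancestry[node.id] = parent_key

        # resolve binary codes per coded child: find the direct tree child
        # each coded descendant hangs from, whose subclade state is uniform
        for key, coded_node in nodes.items():
            decs = decisions_at[key]
            if not any(d.state_by_child for d in decs):
                continue
            child_route: dict[object, int] = {}
            for ck in coded_node.children:
                walker = tree.nodes[ck]
                while walker.parent is not None and walker.parent.id != key:
                    walker = walker.parent
                child_route[ck] = walker.id
            coded_node.codes = [
                CladeCode(
                    id=code.id,
                    states=code.states,
                    plesiomorphic=code.plesiomorphic,
                    site=code.site,
                    gene=code.gene,
                    state_by_child={
                        ck: dec.state_by_child[route]
                        for ck, route in child_route.items()
                        if route in dec.state_by_child
                    },
                )
                for code, dec in zip(coded_node.codes, decs)
            ]
        return cls(nodes)

    @classmethod
    def from_designed_barcodes(
        cls,
        barcodes: Mapping[str, str | Barcode],
        clade_names: Optional[Mapping[str, str]] = None,
    ) -> "CodeDatabase":
        """Build the trie from terminal categories' designed barcode strings.

        Keys of ``barcodes`` name the terminal categories; ``clade_names``
        optionally names internal IDs.  Sparse ID numbering is accepted.
        """
        if not barcodes:
            raise ValueError("no designed barcodes given")
        clade_names = dict(clade_names or {})
        parsed: dict[str, Barcode] = {}
        for name, bc in barcodes.items():
            parsed[name] = bc if isinstance(bc, Barcode) else parse_barcode(bc)

        states: dict[str, set[str]] = {}
        parent_of: dict[str, Optional[str]] = {}
        for name, bc in parsed.items():
            prev: Optional[str] = None
            for state, ident in bc.pairs:
                states.setdefault(ident, set()).add(state)
                if ident in parent_of and parent_of[ident] != prev:
                    raise ValueError(
                        f"inconsistent trie: id {ident} has parents "
                        f"{parent_of[ident]!r} and {prev!r}"
                    )
                parent_of.setdefault(ident, prev)
                prev = ident

        terminal_name: dict[str, str] = {}
        for name, bc in parsed.items():
            terminal_name[bc.ids[-1]] = name

        nodes: dict[object, CodedNode] = {}
        for ident, st in states.items():
            name = terminal_name.get(ident) or clade_names.get(ident)
            code = CladeCode(id=ident, states=tuple(sorted(st)))
            nodes[ident] = CodedNode(ident, name, [code], parent_of[ident])
        for ident, parent in parent_of.items():
            if parent is not None:
                nodes[parent].children.append(ident)
        designed = {parsed[name].ids[-1]: parsed[name] for name in parsed}
        return cls(nodes, designed)

    # -- invariants -----------------------------------------------------------

    def _check_preorder_ids(self) -> None:
        for t in self.terminals:
            keys = [id_sort_key(self.nodes[k].primary_id) for k in self.path(t)]
            if keys != sorted(keys):
                raise ValueError(
                    f"ids not pre-order sorted on path to {t!r}"
                )

    # -- accessors ------------------------------------------------------------

    @property
    def codes(self) -> list[CladeCode]:
        """All codes in database (ID) order."""
        out = [c for n in self.nodes.values() for c in n.codes]
        return sorted(out, key=lambda c: id_sort_key(c.id))

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.codes]

    def path(self, key) -> list:
        """Coded nodes from the root to ``key`` (inclusive)."""
        out = []
        k = key
        while k is not None:
            out.append(k)
            k = self.nodes[k].parent
        return out[::-1]

    def is_terminal(self, key) -> bool:
        return not self.nodes[key].children

    def name_of(self, key) -> str:
        n = self.nodes[key]
        return n.name or f"clade_{n.primary_id}"

    def find(self, name: str):
        for k, n in self.nodes.items():
            if n.name == name:
                return k
        raise KeyError(name)

    def _materialize(self, terminal) -> Barcode:
        pairs: list[tuple[str, str]] = []
        path = self.path(terminal)
        for pos, key in enumerate(path):
            nxt = path[pos + 1] if pos + 1 < len(path) else None
            for code in self.nodes[key].codes:
                if len(code.states) == 1:
                    token = code.states[0]
                elif nxt is not None and nxt in code.state_by_child:
                    token = code.state_by_child[nxt]
                else:
                    token = code.display_state()
                pairs.append((token, code.id))
        return Barcode(tuple(pairs), "designed")

    def barcode_of(self, key) -> Barcode:
        """Designed barcode: lineage prefix plus the clade's own code(s)."""
        if key not in self.nodes:
            raise KeyError(key)
        if key in self._designed:
            return self._designed[key]
        pairs: list[tuple[str, str]] = []
        for k in self.path(key):
            for code in self.nodes[k].codes:
                pairs.append((code.display_state() if len(code.states) > 1
                              else code.states[0], code.id))
        return Barcode(tuple(pairs), "designed")

    def lineage_prefix(self, key) -> Barcode:
        """The barcode of ``key`` without the clade's own code(s)."""
        own = len(self.nodes[key].codes)
        bc = self.barcode_of(key)
        return Barcode(bc.pairs[:-own], bc.kind)

    def code_location(self, ident: str):
        """(key, CladeCode) for a code ID."""
        for k, n in self.nodes.items():
            for c in n.codes:
                if c.id == ident:
                    return k, c
        raise KeyError(ident)

    # -- outputs --------------------------------------------------------------

    def export_table(self) -> pd.DataFrame:
        """Two-dimensional table: rows = terminal categories, columns = IDs
        in database order, cells = the state at that ID when the ID lies on
        the row's lineage, else blank."""
        ids = self.ids
        rows = {}
        for t in sorted(self.terminals,
                        key=lambda k: id_sort_key(self.nodes[k].primary_id)):
            bc = self.barcode_of(t)
            present = dict((i, s) for s, i in bc.pairs)
            rows[self.name_of(t)] = [present.get(i, "") for i in ids]
        return pd.DataFrame.from_dict(rows, orient="index", columns=ids)

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {
                    "key": str(n.key),
                    "name": n.name,
                    "parent": None if n.parent is None else str(n.parent),
                    "codes": [
                        {
                            "id": c.id,
                            "states": list(c.states),
                            "plesiomorphic": c.plesiomorphic,
                            "site": c.site,
                            "gene": c.gene,
                        }
                        for c in n.codes
                    ],
                }
                for n in self.nodes.values()
            ],
            "designed": {
                str(t): format_barcode(self._designed[t]) for t in self.terminals
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CodeDatabase":
        payload = json.loads(text)
        nodes: dict[object, CodedNode] = {}
        for entry in payload["nodes"]:
            codes = [
                CladeCode(
                    id=c["id"],
                    states=tuple(c["states"]),
                    plesiomorphic=c.get("plesiomorphic"),
                    site=c.get("site"),
                    gene=c.get("gene"),
                )
                for c in entry["codes"]
            ]
            nodes[entry["key"]] = CodedNode(
                entry["key"], entry.get("name"), codes, entry.get("parent")
            )
        for n in nodes.values():
            if n.parent is not None:
                nodes[n.parent].children.append(n.key)
        designed = {
            key: parse_barcode(bc) for key, bc in payload.get("designed", {}).items()
        }
        return cls(nodes, designed)


def assign_ids(
    tree: RootedTree, coded_nodes: Iterable[int], prefix: str = ""
) -> dict[int, str]:
    """Sequential base-36 IDs over coded nodes in pre-order."""
    coded = set(coded_nodes)
    out: dict[int, str] = {}
    counter = 0
    for node in tree.preorder():
        if node.id in coded:
            out[node.id] = base36_id(counter, prefix)
            counter += 1
    return out


def build_database(
    selection: Mapping[int, Sequence[ScreeningDecision]],
    tree: RootedTree,
    prefix: str = "",
    names: Optional[Mapping[int, str]] = None,
) -> CodeDatabase:
    """Assign IDs and build the code database from a selection."""
    return CodeDatabase.from_selection(selection, tree, prefix, names)
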