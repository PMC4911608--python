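"""Aligned amino-acid matrices and gene partitions.

The substrate of the whole pipeline is a concatenated amino-acid alignment
(taxa x columns, 1-based columns) together with a gene-partition map that
says which contiguous column interval belongs to which orthologous gene.

Three distinct non-residue symbols are kept in storage:

* ``-``  alignment gap
* ``X``  missing residue within a sequenced gene
* ``?``  whole gene segment absent (e.g. not recovered in a transcriptome)

All three are "missing" for parsimony, but the X/? distinction matters for
the identification stage, which reports the provenance of missing states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the twenty standard amino acids, alphabetical one-letter codes
AA20 = "ACDEFGHIKLMNPQRSTVWY"

GAP = "-"
MISSING_RESIDUE = "X"
MISSING_GENE = "?"

#: symbols treated as missing data by the parsimony engine
MISSING_SYMBOLS = frozenset({GAP, MISSING_RESIDUE, MISSING_GENE})

ALPHABET = frozenset(AA20) | MISSING_SYMBOLS


def is_missing(symbol: str) -> bool:
    """True for gap, missing residue or missing gene symbols."""
    return symbol in MISSING_SYMBOLS


class AminoAcidMatrix:
    """Taxa x aligned amino-acid columns with missing/gap symbols.

    Rows are stored as plain strings; columns are addressed 1-based, the
    convention used throughout (positions are reported in alignment
    coordinates).
    """

    def __init__(self, taxa: Sequence[str], rows: Sequence[str]):
        taxa = list(taxa)
        rows = [str(r).upper() for r in rows]
        if len(taxa) != len(rows):
            raise ValueError("taxa and rows must have equal length")
        if not taxa:
            raise ValueError("empty matrix")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dupes}")
        ncol = len(rows[0])
        for t, r in zip(taxa, rows):
            if len(r) != ncol:
                raise ValueError(
                    f"ragged alignment: taxon {t!r} has length {len(r)}, "
                    f"expected {ncol}"
                )
        cleaned = []
        for t, r in zip(taxa, rows):
            bad = {ch for ch in r if ch not in ALPHABET}
            if bad:
                logger.warning(
                    "taxon %s: unknown symbols %s mapped to X",
                    t, "".join(sorted(bad)),
                )
                r = "".join(MISSING_RESIDUE if ch in bad else ch for ch in r)
            cleaned.append(r)
        self.taxa: list[str] = taxa
        self._rows: list[str] = cleaned
        self._index = {t: i for i, t in enumerate(taxa)}

    @property
    def columns(self) -> int:
        return len(self._rows[0])

    def row(self, taxon: str) -> str:
        return self._rows[self._index[taxon]]

    def cell(self, taxon: str, column: int) -> str:
        """Symbol at (taxon, column), column 1-based."""
        if not 1 <= column <= self.columns:
            raise IndexError(f"column {column} out of range 1..{self.columns}")
        return self._rows[self._index[taxon]][column - 1]

    def column_states(self, column: int) -> dict[str, str]:
        """Mapping taxon -> symbol for one column (1-based)."""
        if not 1 <= column <= self.columns:
            raise IndexError(f"column {column} out of range 1..{self.columns}")
        c = column - 1
        return {t: self._rows[i][c] for t, i in self._index.items()}

    def observed_states(self, column: int) -> set[str]:
        """Distinct non-missing symbols in a column."""
        c = column - 1
        return {r[c] for r in self._rows} - MISSING_SYMBOLS

    def restrict(self, sites: Sequence[int]) -> "AminoAcidMatrix":
        """New matrix keeping only ``sites`` (1-based), in the given order."""
        for s in sites:
            if not 1 <= s <= self.columns:
                raise IndexError(f"site {s} out of range 1..{self.columns}")
        idx = [s - 1 for s in sites]
        rows = ["".join(r[i] for i in idx) for r in self._rows]
        return AminoAcidMatrix(self.taxa, rows)

    def subset_taxa(self, taxa: Iterable[str]) -> "AminoAcidMatrix":
        taxa = list(taxa)
        return AminoAcidMatrix(taxa, [self.row(t) for t in taxa])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AminoAcidMatrix)
            and self.taxa == other.taxa
            and self._rows == other._rows
        )

    def __repr__(self) -> str:
        return f"AminoAcidMatrix({len(self.taxa)} taxa x {self.columns} columns)"


@dataclass(frozen=True)
class GenePartition:
    """Non-overlapping, sorted 1-based closed intervals, one per gene."""

    entries: tuple[tuple[str, int, int], ...] = ()

    #: label returned for columns not covered by any gene
    UNASSIGNED = "unassigned"

    def __post_init__(self):
        seen = set()
        prev_end = 0
        prev = None
        for name, start, end in self.entries:
            if name in seen:
                raise ValueError(f"duplicate gene name {name!r}")
            seen.add(name)
            if start < 1 or end < start:
                raise ValueError(f"invalid interval for {name!r}: {start}..{end}")
            if start <= prev_end:
                raise ValueError(
                    f"overlapping intervals: {prev!r} and {name!r}"
                )
            prev_end = end
            prev = name

    @staticmethod
    def from_entries(entries: Iterable[tuple[str, int, int]]) -> "GenePartition":
        return GenePartition(tuple(sorted(entries, key=lambda e: e[1])))

    def gene_of(self, column: int) -> str:
        for name, start, end in self.entries:
            if start <= column <= end:
                return name
        return self.UNASSIGNED

    def span(self, gene: str) -> tuple[int, int]:
        for name, start, end in self.entries:
            if name == gene:
                return start, end
        raise KeyError(gene)

    @property
    def genes(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def validate_against(self, columns: int) -> None:
        for name, start, end in self.entries:
            if end > columns:
                raise ValueError(
                    f"gene {name!r} interval {start}..{end} exceeds "
                    f"alignment length {columns}"
                )


# ---------------------------------------------------------------------------
# readers / writers


def read_alignment(path: str | Path, format: str = "fasta") -> AminoAcidMatrix:
    """Read a FASTA or relaxed-PHYLIP alignment into an AminoAcidMatrix.

    Symbols are upper-cased; letters outside the amino-acid alphabet are
    mapped to ``X`` with a logged warning.  Ragged FASTA rows raise an error
    naming the offending taxon.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"empty alignment file: {path}")
        return AminoAcidMatrix([r.id for r in records], [str(r.seq) for r in records])
    if fmt in {"phylip", "phylip-relaxed"}:
        aln = AlignIO.read(str(path), "phylip-relaxed")
        return AminoAcidMatrix([r.id for r in aln], [str(r.seq) for r in aln])
    raise ValueError(f"unsupported alignment format: {format!r}")


def write_alignment(matrix: AminoAcidMatrix, path: str | Path) -> None:
    """Write the matrix as FASTA, preserving taxon order."""
    records = [
        SeqRecord(Seq(matrix.row(t)), id=t, description="") for t in matrix.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_partition(path: str | Path) -> GenePartition:
    """Read a tabular partition file: ``gene<TAB>start<TAB>end`` per line.

    Whitespace-separated columns are accepted; ``#`` starts a comment.
    """
    path = Path(path)
    entries = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'gene start end'")
        name, start, end = parts[0], int(parts[1]), int(parts[2])
        entries.append((name, start, end))
    return GenePartition.from_entries(entries)


def write_gene_partition(partition: GenePartition, path: str | Path) -> None:
    lines = [f"{name}\t{start}\t{end}" for name, start, end in partition.entries]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_subdataset(
    matrix: AminoAcidMatrix,
    site_list: Sequence[int],
    path: str | Path,
    partition: GenePartition | None = None,
) -> Path:
    """Export the matrix restricted to ``site_list`` as FASTA.

    A sidecar TSV ``<path>.sites.tsv`` maps each new column to its original
    column and gene, so downstream positions remain interpretable in the
    coordinates of the full supermatrix.  Returns the sidecar path.
    """
    if not site_list:
        raise ValueError("empty site list")
    sub = matrix.restrict(site_list)
    write_alignment(sub, path)
    sidecar = Path(str(path) + ".sites.tsv")
    lines = ["new_column\toriginal_column\tgene"]
    for new_col, orig in enumerate(site_list, 1):
        gene = partition.gene_of(orig) if partition else GenePartition.UNASSIGNED
        lines.append(f"{new_col}\t{orig}\t{gene}")
    sidecar.write_text("\n".join(lines) + "\n")
    return sidecar
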