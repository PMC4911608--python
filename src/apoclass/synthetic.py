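"""Synthetic trees and alignments with planted apomorphies.

The generator emulates the structure the mining and identification stages
rely on in real supermatrices: a known rooted topology with one outgroup
taxon, a concatenated alignment partitioned into genes, clade-specific
derived amino acids planted on chosen columns (one or more per internal
ingroup clade), a tunable convergence (homoplasy) rate that re-derives a
planted state in one leaf outside the clade, and the two missing-data
processes seen in transcriptome assemblies: whole-gene absence (``?``) and
within-gene missing residues (``X``).

Background columns are fully conserved by default so the consistency index
of every planted column is analytically known: CI = 1 without homoplasy
and CI = 0.5 when the derived state arises a second time.  A low-rate
noisy background is available for stress tests.  All randomness flows from
a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import AA20, MISSING_GENE, MISSING_RESIDUE, AminoAcidMatrix, GenePartition
from .tree import Node, RootedTree

OUTGROUP_LABEL = "OUTGROUP"


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated dataset."""

    n_taxa: int = 32                      # ingroup leaves
    tree_shape: str = "balanced"          # balanced | caterpillar | random
    n_genes: int = 10
    sites_per_gene: int = 50
    apomorphies_per_clade: int = 1
    #: probability that a planted derived state re-arises in one outside leaf
    homoplasy_rate: float = 0.0
    gene_missing_p: float = 0.0
    site_missing_p: float = 0.0
    #: per-cell probability of a random background substitution
    background_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("homoplasy_rate", "gene_missing_p", "site_missing_p",
                     "background_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_taxa < 4:
            raise ValueError("need at least 4 ingroup taxa")
        if min(self.n_genes, self.sites_per_gene,
               self.apomorphies_per_clade) < 1:
            raise ValueError("counts must be positive")
        if self.tree_shape not in {"balanced", "caterpillar", "random"}:
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")


@dataclass(frozen=True)
class PlantedApomorphy:
    clade_node: int
    clade_leaves: tuple[str, ...]
    gene: str
    site: int
    from_state: str
    to_state: str
    homoplasy_leaf: Optional[str] = None


@dataclass
class TruthTable:
    planted: list[PlantedApomorphy] = field(default_factory=list)
    masked_genes: list[tuple[str, str]] = field(default_factory=list)   # (taxon, gene)
    masked_cells: list[tuple[str, int]] = field(default_factory=list)   # (taxon, column)

    def by_clade(self) -> dict[int, list[PlantedApomorphy]]:
        out: dict[int, list[PlantedApomorphy]] = {}
        for p in self.planted:
            out.setdefault(p.clade_node, []).append(p)
        return out


@dataclass
class SimulatedDataset:
    tree: RootedTree
    matrix: AminoAcidMatrix
    partition: GenePartition
    truth: TruthTable
    params: SimulationParams


# ---------------------------------------------------------------------------
# tree shapes


def _leaf_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def _balanced(labels: list[str]) -> Node:
    if len(labels) == 1:
        return Node(0, label=labels[0])
    mid = (len(labels) + 1) // 2
    node = Node(0)
    for part in (labels[:mid], labels[mid:]):
        child = _balanced(part)
        child.parent = node
        node.children.append(child)
    return node


def _caterpillar(labels: list[str]) -> Node:
    node = Node(0, label=labels[-1])
    for label in reversed(labels[:-1]):
        parent = Node(0)
        leaf = Node(0, label=label)
        for c in (leaf, node):
            c.parent = parent
            parent.children.append(c)
        node = parent
    return node


def _random_tree(labels: list[str], rng: np.random.Generator) -> Node:
    pool = [Node(0, label=lb) for lb in labels]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        parent = Node(0)
        for c in (a, b):
            c.parent = parent
            parent.children.append(c)
        pool.append(parent)
    return pool[0]


def simulate_tree(params: SimulationParams, rng: np.random.Generator) -> RootedTree:
    labels = _leaf_labels(params.n_taxa)
    builders = {
        "balanced": lambda: _balanced(labels),
        "caterpillar": lambda: _caterpillar(labels),
        "random": lambda: _random_tree(labels, rng),
    }
    ingroup = builders[params.tree_shape]()
    root = Node(0)
    out = Node(0, label=OUTGROUP_LABEL)
    for c in (ingroup, out):
        c.parent = root
        root.children.append(c)
    return RootedTree(root, outgroup=[OUTGROUP_LABEL])


# ---------------------------------------------------------------------------
# alignment planting


def simulate(params: SimulationParams) -> SimulatedDataset:
    """Generate (tree, matrix, partition, truth) deterministically from the
    seed."""
    rng = np.random.default_rng(params.seed)
    tree = simulate_tree(params, rng)

    columns = params.n_genes * params.sites_per_gene
    partition = GenePartition.from_entries(
        (f"gene{g + 1:02d}",
         g * params.sites_per_gene + 1,
         (g + 1) * params.sites_per_gene)
        for g in range(params.n_genes)
    )

    clades = [
        n for n in tree.preorder()
        if not n.is_leaf and n.parent is not None and tree.is_ingroup_node(n)
    ]
    n_planted = len(clades) * params.apomorphies_per_clade
    if n_planted > columns:
        raise ValueError(
            f"cannot plant {n_planted} apomorphies in {columns} columns"
        )

    taxa = tree.leaf_labels
    # conserved background, one random state per column
    aa = np.array(list(AA20))
    background = rng.choice(len(aa), size=columns)
    grid = np.tile(background, (len(taxa), 1))

    if params.background_noise > 0:
        noise_mask = rng.random(grid.shape) < params.background_noise
        grid = np.where(noise_mask, rng.integers(0, len(aa), size=grid.shape), grid)

    planted_sites = rng.choice(columns, size=n_planted, replace=False) + 1
    taxon_index = {t: i for i, t in enumerate(taxa)}

    truth = TruthTable()
    cursor = 0
    for clade in clades:
        clade_leaves = tuple(sorted(tree.leafset(clade)))
        for _ in range(params.apomorphies_per_clade):
            site = int(planted_sites[cursor])
            cursor += 1
            from_idx = int(background[site - 1])
            to_idx = int((from_idx + 1 + rng.integers(0, len(aa) - 1)) % len(aa))
            from_state, to_state = str(aa[from_idx]), str(aa[to_idx])
            col = site - 1
            grid[:, col] = from_idx  # wipe any background noise on this column
            for leaf in clade_leaves:
                grid[taxon_index[leaf], col] = to_idx
            homoplasy_leaf = None
            if rng.random() < params.homoplasy_rate:
                outside = [t for t in taxa if t not in clade_leaves]
                homoplasy_leaf = outside[int(rng.integers(0, len(outside)))]
                grid[taxon_index[homoplasy_leaf], col] = to_idx
            truth.planted.append(
                PlantedApomorphy(
                    clade_node=clade.id,
                    clade_leaves=clade_leaves,
                    gene=partition.gene_of(site),
                    site=site,
                    from_state=from_state,
                    to_state=to_state,
                    homoplasy_leaf=homoplasy_leaf,
                )
            )

    rows = ["".join(aa[grid[i]]) for i in range(len(taxa))]
    matrix = AminoAcidMatrix(taxa, rows)

    if params.gene_missing_p > 0 or params.site_missing_p > 0:
        matrix, mask = inject_missing(
            matrix, partition, params.gene_missing_p, params.site_missing_p, rng
        )
        truth.masked_genes = mask.masked_genes
        truth.masked_cells = mask.masked_cells

    return SimulatedDataset(tree, matrix, partition, truth, params)


@dataclass
class MaskRecord:
    masked_genes: list[tuple[str, str]] = field(default_factory=list)
    masked_cells: list[tuple[str, int]] = field(default_factory=list)


def inject_missing(
    matrix: AminoAcidMatrix,
    partition: GenePartition,
    gene_missing_p: float,
    site_missing_p: float,
    rng: np.random.Generator | int,
) -> tuple[AminoAcidMatrix, MaskRecord]:
    """Apply the two missing-data processes.

    Per (taxon, gene) the whole gene segment becomes ``?`` with probability
    ``gene_missing_p``; independently, each surviving cell becomes ``X``
    with probability ``site_missing_p``.  The mask is recorded.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    record = MaskRecord()
    rows = {t: list(matrix.row(t)) for t in matrix.taxa}
    for taxon in matrix.taxa:
        row = rows[taxon]
        gene_gone = set()
        for gene, start, end in partition.entries:
            if rng.random() < gene_missing_p:
                gene_gone.add(gene)
                record.masked_genes.append((taxon, gene))
                for col in range(start, end + 1):
                    row[col - 1] = MISSING_GENE
        for gene, start, end in partition.entries:
            if gene in gene_gone:
                continue
            for col in range(start, end + 1):
                if rng.random() < site_missing_p:
                    record.masked_cells.append((taxon, col))
                    row[col - 1] = MISSING_RESIDUE
        # columns outside any gene are also exposed to site missingness
        covered = {c for _, s, e in partition.entries for c in range(s, e + 1)}
        for col in range(1, matrix.columns + 1):
            if col not in covered and rng.random() < site_missing_p:
                record.masked_cells.append((taxon, col))
                row[col - 1] = MISSING_RESIDUE
    out = AminoAcidMatrix(matrix.taxa, ["".join(rows[t]) for t in matrix.taxa])
    return out, record
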