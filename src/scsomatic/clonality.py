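"""Shared-mutation analysis and clone-tree reconstruction within one individual.

A somatic mutation present in two or more cells of the same individual
marks a common ancestral cell.  Grouping mutations by their exact
cell-support set and nesting those sets from largest to smallest yields
a perfect-phylogeny tree whose edges carry mutation sets: internal edges
hold clonal (shared) mutations, leaf edges hold each cell's private
mutations.  Support sets that violate nesting — expected occasionally
from artifact calls — are surfaced as conflicts and their mutations
attached, flagged, to the first member cell's leaf edge so that every
distinct mutation is placed exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .variants import CellCallset, VariantKey

logger = logging.getLogger(__name__)


@dataclass
class SharingReport:
    individual_id: str
    pair_counts: pd.DataFrame  # cells x cells symmetric shared-mutation counts
    support_sets: dict[frozenset, set[VariantKey]]  # cell-support -> mutations
    percent_shared: float  # 100 * shared / distinct mutations
    n_distinct: int
    n_shared: int


@dataclass
class CloneNode:
    """A node of the clone tree; the edge to its parent carries ``mutations``."""

    cells: frozenset
    mutations: set[VariantKey] = field(default_factory=set)
    children: list["CloneNode"] = field(default_factory=list)
    conflict: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick_label(self) -> str:
        return sorted(self.cells)[0] if len(self.cells) == 1 else ""


@dataclass
class CloneTree:
    individual_id: str
    root: CloneNode
    conflicts: list[frozenset] = field(default_factory=list)

    def edges(self) -> list[CloneNode]:
        out: list[CloneNode] = []

        def walk(node: CloneNode) -> None:
            out.append(node)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def total_mutations(self) -> int:
        return sum(len(n.mutations) for n in self.edges())

    def leaf_path_union(self, cell_id: str) -> set[VariantKey]:
        """Union of edge mutation sets on the root-to-leaf path of one cell."""
        path: set[VariantKey] = set()
        node = self.root
        while True:
            path |= node.mutations
            if node.is_leaf:
                return path
            nxt = [c for c in node.children if cell_id in c.cells]
            if not nxt:
                return path
            node = nxt[0]

    def to_newick(self) -> str:
        def fmt(node: CloneNode) -> str:
            length = len(node.mutations)
            if node.is_leaf:
                return f"{node.newick_label()}:{length}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{length}"

        return fmt(self.root) + ";"


def _support_sets(cells: list[CellCallset]) -> dict[frozenset, set[VariantKey]]:
    by_mutation: dict[VariantKey, set[str]] = {}
    for cell in cells:
        for key in cell.calls:
            by_mutation.setdefault(key, set()).add(cell.cell_id)
    supports: dict[frozenset, set[VariantKey]] = {}
    for key, cell_ids in by_mutation.items():
        supports.setdefault(frozenset(cell_ids), set()).add(key)
    return supports


def sharing_analysis(cells: list[CellCallset]) -> SharingReport:
    """Quantify mutations shared among the cells of one individual.

    A mutation is shared iff its exact (chrom, pos, ref, alt) key occurs in
    at least 2 cells.  percent_shared uses the number of distinct mutations
    across the individual as denominator.
    """
    if len(cells) < 2:
        raise ValueError("sharing analysis needs at least 2 cells")
    individuals = {c.individual_id for c in cells}
    if len(individuals) != 1:
        raise ValueError(f"cells span multiple individuals: {sorted(individuals)}")
    supports = _support_sets(cells)
    cell_ids = sorted(c.cell_id for c in cells)
    pair = pd.DataFrame(0, index=cell_ids, columns=cell_ids, dtype=int)
    for a, b in combinations(cells, 2):
        n = len(set(a.calls) & set(b.calls))
        pair.loc[a.cell_id, b.cell_id] = n
        pair.loc[b.cell_id, a.cell_id] = n
    n_distinct = sum(len(m) for m in supports.values())
    n_shared = sum(len(m) for s, m in supports.items() if len(s) >= 2)
    pct = 100.0 * n_shared / n_distinct if n_distinct else 0.0
    return SharingReport(
        individual_id=cells[0].individual_id, pair_counts=pair,
        support_sets=supports, percent_shared=pct,
        n_distinct=n_distinct, n_shared=n_shared,
    )


def build_clone_tree(cells: list[CellCallset]) -> CloneTree:
    """Reconstruct the mutation-history tree of one individual's cells.

    Mutations are grouped by identical cell-support set; support sets are
    nested greedily from largest to smallest (ties broken lexicographically
    by sorted cell IDs).  The result is a rooted tree whose edge mutation
    sets are pairwise disjoint and sum to the distinct mutation count.
    """
    if len(cells) < 2:
        raise ValueError("clone tree needs at least 2 cells")
    supports = _support_sets(cells)
    all_cells = frozenset(c.cell_id for c in cells)
    root = CloneNode(cells=all_cells, mutations=set(supports.pop(all_cells, set())))
    # every cell gets a leaf, even without private mutations
    leaves = {cid: CloneNode(cells=frozenset([cid])) for cid in sorted(all_cells)}
    internal_order = sorted(
        (s for s in supports if len(s) >= 2),
        key=lambda s: (-len(s), sorted(s)),
    )
    nodes: list[CloneNode] = [root]
    conflicts: list[frozenset] = []
    for support in internal_order:
        muts = supports[support]
        # deepest existing node whose cell set contains this support
        parent = root
        while True:
            nxt = [c for c in parent.children if support <= c.cells]
            if not nxt:
                break
            parent = nxt[0]
        overlap = [c for c in parent.children if c.cells & support]
        if overlap:  # partial overlap with a sibling: not nestable
            conflicts.append(support)
            first = sorted(support)[0]
            leaves[first].mutations |= muts
            leaves[first].conflict = True
            continue
        node = CloneNode(cells=support, mutations=set(muts))
        parent.children.append(node)
        nodes.append(node)
    # attach private mutations and hang each leaf under its deepest clone
    for cid, leaf in leaves.items():
        leaf.mutations |= supports.get(frozenset([cid]), set())
        parent = root
        while True:
            deeper = [c for c in parent.children if len(c.cells) > 1 and cid in c.cells]
            if not deeper:
                break
            parent = deeper[0]
        parent.children.append(leaf)
    for node in nodes:
        node.children.sort(key=lambda c: sorted(c.cells))
    if conflicts:
        logger.info("clone tree for %s: %d conflicting support sets flagged",
                    cells[0].individual_id, len(conflicts))
    return CloneTree(individual_id=cells[0].individual_id, root=root, conflicts=conflicts)


def write_sharing_matrix(report: SharingReport, path) -> None:
    report.pair_counts.to_csv(path, sep="\t", index_label="cell_id")


def write_newick(tree: CloneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
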