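"""Screening candidate single-copy markers.

A usable marker gene family must (1) occur exactly once in every
required genome, (2) have the focal taxa (e.g. the fungi) monophyletic
in its gene tree, and (3) place them canonically: every grouping in a
user-supplied constraint set must be compatible, as a bipartition, with
the gene tree restricted to shared taxa.  Trees are treated as unrooted
and screened via bipartitions, so all decisions are invariant under
rerooting; polytomies are compatible with any grouping they do not
contradict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy


@dataclass
class OrthologTable:
    """Per-genome copy counts for candidate gene families."""

    counts: dict[str, dict[str, int]]  # family id -> genome id -> count

    def genomes(self) -> set[str]:
        out: set[str] = set()
        for row in self.counts.values():
            out.update(row)
        return out


@dataclass(frozen=True)
class ScreenResult:
    family_id: str
    single_copy: bool
    monophyletic: bool
    canonical: bool
    reasons: tuple[str, ...] = ()

    @property
    def passes(self) -> bool:
        return self.single_copy and self.monophyletic and self.canonical


def single_copy_screen(
    table: OrthologTable, required_genomes: Iterable[str]
) -> dict[str, bool]:
    """Pass iff the copy count is exactly 1 in every required genome.

    A genome where the family is absent (count 0 or no entry) fails —
    the criterion is presence in single copy in *all* genomes.
    """
    required = list(required_genomes)
    known = table.genomes()
    unknown = [g for g in required if g not in known]
    if unknown:
        raise ValueError(f"unknown genome id(s): {', '.join(unknown)}")
    return {
        family: all(row.get(g, 0) == 1 for g in required)
        for family, row in table.counts.items()
    }


def _bipartitions(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets under each internal edge of the (unrooted) tree."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 1 < len(side) < len(leaves):
            out.append(side)
    return out


def is_monophyletic(tree: dendropy.Tree, focal_taxa: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly the focal taxa."""
    focal = frozenset(focal_taxa)
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = focal - leaves
    if missing:
        raise ValueError(f"focal taxa absent from tree: {', '.join(sorted(missing))}")
    if len(focal) <= 1 or focal == leaves:
        return True
    rest = leaves - focal
    if len(rest) <= 1:
        return True
    for side in _bipartitions(tree):
        if side == focal or side == rest:
            return True
    return False


def _compatible(group: frozenset[str], side: frozenset[str],
                universe: frozenset[str]) -> bool:
    """Bipartition compatibility: some of the four intersections is empty."""
    g, s = group, side
    cg, cs = universe - g, universe - s
    return not (g & s) or not (g & cs) or not (cg & s) or not (cg & cs)


def is_canonical(
    tree: dendropy.Tree, constraint_groups: Sequence[Iterable[str]]
) -> bool:
    """True iff every constraint grouping is compatible with the tree.

    Each grouping is restricted to taxa shared with the tree (foreign
    taxa are dropped) and then compared, as a bipartition against the
    remaining tree leaves, with every internal edge of the tree.
    Groupings reduced to fewer than 2 taxa, or leaving fewer than 2 taxa
    outside, constrain nothing and are compatible by convention; the
    same holds for splits a polytomy does not resolve.
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    for group in constraint_groups:
        g = frozenset(group) & leaves
        if len(g) < 2 or len(leaves - g) < 2:
            continue
        for side in _bipartitions(tree):
            if not _compatible(g, side, leaves):
                return False
    return True


def monophyly_screen(
    tree: dendropy.Tree,
    focal_taxa: Iterable[str],
    constraint_groups: Sequence[Iterable[str]] | None = None,
    family_id: str = "",
    single_copy: bool = True,
) -> ScreenResult:
    """Combined phylogenetic screen of one gene family's tree."""
    mono = is_monophyletic(tree, focal_taxa)
    canon = (
        is_canonical(tree, constraint_groups) if constraint_groups else True
    )
    reasons = []
    if not single_copy:
        reasons.append("not single copy in all required genomes")
    if not mono:
        reasons.append("focal taxa not monophyletic")
    if not canon:
        reasons.append("conflicts with constraint groupings")
    return ScreenResult(
        family_id=family_id,
        single_copy=single_copy,
        monophyletic=mono,
        canonical=canon,
        reasons=tuple(reasons),
    )


def read_tree(path: str) -> dendropy.Tree:
    """Load a newick gene tree (leaf labels are taxon ids)."""
    return dendropy.Tree.get(path=path, schema="newick",
                             preserve_underscores=True)


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
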