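"""Gene/species-tree reconciliation and Dollo loss mapping.

Two complementary ways of placing gene-family events on a species
tree: (1) LCA reconciliation of a rooted gene tree, which marks a gene
node as a duplication when its species-tree image coincides with a
child's image and counts the implied losses from path-length
discrepancies; (2) Dollo parsimony on a presence/absence matrix, which
places a single gain at the LCA of all carriers and returns the unique
minimal set of loss branches (maximal subtrees devoid of the family).

Species-tree polytomies are allowed and treated as hard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Internal node labels and branch lengths are preserved; underscores
    in labels stay literal.
    """
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
    )
    tree.is_rooted = True
    return tree


def read_newick_file(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {lf.taxon.label: lf for lf in tree.leaf_node_iter()}


def _annotate_depths(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node._depth = 0 if node.parent_node is None else node.parent_node._depth + 1


def _species_lca(a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
    while a is not b:
        if a._depth >= b._depth:
            a = a.parent_node
        else:
            b = b.parent_node
    return a


@dataclass
class ReconciliationResult:
    duplications: list[str]          # species-tree branch (node name) per event
    losses: list[str]                # species-tree branch per loss
    n_duplications: int = field(init=False)
    n_losses: int = field(init=False)

    def __post_init__(self):
        self.n_duplications = len(self.duplications)
        self.n_losses = len(self.losses)


def lca_reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_species_map: Mapping[str, str],
) -> ReconciliationResult:
    """Standard LCA (most-parsimonious) reconciliation.

    Every gene-tree leaf maps to a species leaf via
    ``leaf_species_map``; internal gene nodes map to the LCA of their
    children's images. A gene node is a duplication iff its image
    equals the image of at least one child. Loss events are placed on
    the species branches skipped along each child's image path
    (including the image itself for duplication children that map
    strictly below the parent's image).
    """
    _annotate_depths(species_tree)
    sp_leaves = _leaf_map(species_tree)

    image: dict[int, dendropy.Node] = {}
    for leaf in gene_tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in leaf_species_map:
            raise KeyError(f"gene-tree leaf {name!r} has no species mapping")
        species = leaf_species_map[name]
        if species not in sp_leaves:
            raise KeyError(f"species {species!r} not in species tree")
        image[id(leaf)] = sp_leaves[species]

    duplications: list[str] = []
    losses: list[str] = []
    for node in gene_tree.postorder_internal_node_iter():
        kids = node.child_nodes()
        img = image[id(kids[0])]
        for c in kids[1:]:
            img = _species_lca(img, image[id(c)])
        image[id(node)] = img
        is_dup = any(image[id(c)] is img for c in kids)
        if is_dup:
            duplications.append(_node_name(img))
        for c in kids:
            child_img = image[id(c)]
            # walk up from the child's image to the parent's image,
            # recording the sibling species branches the gene lineage
            # must have been lost from
            steps = child_img._depth - img._depth
            walker = child_img
            for step in range(steps):
                parent = walker.parent_node
                skip_last = (not is_dup) and step == steps - 1
                if not skip_last:
                    for sib in parent.child_nodes():
                        if sib is not walker:
                            losses.append(_node_name(sib))
                walker = parent
    return ReconciliationResult(duplications=duplications, losses=sorted(losses))


@dataclass
class PresenceMatrix:
    """Species-by-family boolean presence table."""

    presence: dict[str, dict[str, bool]]  # species -> family -> present

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        rows: dict[str, dict[str, bool]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            families = header[1:]
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                rows[parts[0]] = {
                    fam: val.strip() in ("1", "yes", "true", "+")
                    for fam, val in zip(families, parts[1:])
                }
        return cls(rows)

    def present_species(self, family: str) -> set[str]:
        return {sp for sp, fams in self.presence.items() if fams.get(family, False)}

    def absent_species(self, family: str) -> set[str]:
        return {sp for sp, fams in self.presence.items() if not fams.get(family, True)}


def dollo_losses(
    species_tree: dendropy.Tree,
    presence: PresenceMatrix,
    family: str,
) -> list[str]:
    """Minimum loss set for a family under single-gain Dollo parsimony.

    The gain sits at the LCA of all species carrying the family;
    losses are the maximal branches below the gain whose entire leaf
    set lacks it. Species absent from the matrix are ignored (treated
    as unsampled, not absent).
    """
    present = presence.present_species(family)
    if not present:
        raise ValueError(f"family {family!r} is present in no species")
    absent = presence.absent_species(family)
    _annotate_depths(species_tree)
    sp_leaves = _leaf_map(species_tree)
    carriers = [sp_leaves[sp] for sp in sorted(present) if sp in sp_leaves]
    if not carriers:
        raise ValueError(f"no species carrying {family!r} found in the tree")
    gain = carriers[0]
    for node in carriers[1:]:
        gain = _species_lca(gain, node)

    def loss_status(node: dendropy.Node) -> str:
        """'lost' if every scored leaf below lacks the family,
        'mixed' otherwise, 'unsampled' if no leaf below is scored."""
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        scored = [lf for lf in leaves if lf in present or lf in absent]
        if not scored:
            return "unsampled"
        return "lost" if all(lf in absent for lf in scored) else "mixed"

    losses: list[str] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            status = loss_status(child)
            if status == "lost":
                losses.append(_node_name(child))
            elif status == "mixed":
                walk(child)

    walk(gain)
    return sorted(losses)


def read_leaf_species_map(path: str | Path) -> dict[str, str]:
    """TSV with columns ``gene`` and ``species``."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            mapping[parts[idx["gene"]]] = parts[idx["species"]]
    return mapping
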