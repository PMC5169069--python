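"""Gene tree input, leaf-to-species resolution, and seed-anchored rooting.

Trees arrive as Newick produced by whatever inference pipeline the user
ran (ML or otherwise).  The screen only needs topology, branch lengths,
and a species label per leaf; internal support labels are carried through
to reports but never used as evidence.

Rooting convention: the tree is re-rooted on the branch of the leaf that
is farthest (in cumulative branch length) from the seed sequence, so the
seed-to-root traversal crosses the deepest splits last.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterator, Mapping

import dendropy

__all__ = [
    "GeneTree",
    "GeneTreeError",
    "LeafMapper",
    "LeafResolutionError",
    "NewickParseError",
    "read_gene_tree",
    "read_leaf_map",
    "resolve_species",
    "root_at_farthest_leaf",
]


class GeneTreeError(ValueError):
    """Base error for gene-tree handling."""


class NewickParseError(GeneTreeError):
    """The Newick text could not be parsed."""


class LeafResolutionError(GeneTreeError):
    """A leaf name could not be resolved to a species label."""


@dataclass(frozen=True)
class LeafMapper:
    """Policy resolving a leaf name to a species label.

    Exactly one of the three modes applies:

    * ``table`` — explicit leaf-name -> species mapping;
    * ``separator`` — the species label is the text after the first
      occurrence of the separator character(s);
    * identity (both unset) — the leaf name is the species label.

    Under ``strict`` (default) an unresolvable leaf raises
    :class:`LeafResolutionError`; otherwise :meth:`resolve` returns ``None``
    and the caller excludes the leaf from species sets.
    """

    table: Mapping[str, str] | None = None
    separator: str | None = None
    strict: bool = True

    def __post_init__(self) -> None:
        if self.table is not None and self.separator is not None:
            raise ValueError("give a map table or a separator, not both")

    def resolve(self, leaf_name: str) -> str | None:
        if self.table is not None:
            species = self.table.get(leaf_name)
        elif self.separator is not None:
            _, sep, rest = leaf_name.partition(self.separator)
            species = rest if sep and rest else None
        else:
            species = leaf_name
        if species is None and self.strict:
            raise LeafResolutionError(
                f"cannot resolve leaf {leaf_name!r} to a species"
            )
        return species


def resolve_species(leaf_name: str, mapping: LeafMapper) -> str | None:
    """Resolve one leaf name under the given policy (pure function)."""
    return mapping.resolve(leaf_name)


def read_leaf_map(source: str | Path | IO[str]) -> dict[str, str]:
    """Read a two-column (leaf name, species label) TSV."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    mapping: dict[str, str] = {}
    for lineno, row in enumerate(
        csv.reader(io.StringIO(text), delimiter="\t"), start=1
    ):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 2 or not row[0] or not row[1]:
            raise GeneTreeError(
                f"leaf map line {lineno}: expected two non-empty columns"
            )
        mapping[row[0]] = row[1]
    return mapping


class GeneTree:
    """A rooted (possibly multifurcating) gene tree with species labels.

    Wraps a :class:`dendropy.Tree`.  Missing branch lengths are treated as
    1.0 wherever a metric is needed, which degrades gracefully to
    topological distance on cladograms.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        species_of: Mapping[str, str | None],
        seed_leaf: str | None = None,
    ):
        self.tree = tree
        #: leaf name -> species label (None for lenient-mode orphans)
        self.species_of = dict(species_of)
        self.unresolved = frozenset(
            k for k, v in self.species_of.items() if v is None
        )
        self.seed_leaf = seed_leaf

    # -- structure -------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def find_leaf(self, leaf_name: str) -> dendropy.Node:
        for lf in self.tree.leaf_node_iter():
            if lf.taxon.label == leaf_name:
                return lf
        raise GeneTreeError(f"leaf {leaf_name!r} not in tree")

    def leaves_under(self, node: dendropy.Node) -> frozenset[str]:
        """Leaf names in the clade of ``node``."""
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def species_under(self, node: dendropy.Node) -> frozenset[str]:
        """Species labels in the clade of ``node`` (orphan leaves skipped)."""
        out = set()
        for lf in node.leaf_iter():
            sp = self.species_of.get(lf.taxon.label)
            if sp is not None:
                out.add(sp)
        return frozenset(out)

    def species_of_leaves(self, leaf_names: frozenset[str]) -> frozenset[str]:
        return frozenset(
            sp
            for name in leaf_names
            if (sp := self.species_of.get(name)) is not None
        )

    # -- metric ----------------------------------------------------------

    def distances_from(self, leaf_name: str) -> dict[str, float]:
        """Cumulative branch-length distance from one leaf to every leaf.

        Treats the tree as unrooted; missing edge lengths count as 1.0.
        """
        adjacency: dict[int, list[tuple[dendropy.Node, float]]] = {}

        def edges(node: dendropy.Node) -> Iterator[tuple[dendropy.Node, float]]:
            if node.parent_node is not None:
                yield node.parent_node, (
                    node.edge.length if node.edge.length is not None else 1.0
                )
            for ch in node.child_nodes():
                yield ch, (ch.edge.length if ch.edge.length is not None else 1.0)

        start = self.find_leaf(leaf_name)
        dist: dict[int, float] = {id(start): 0.0}
        node_of: dict[int, dendropy.Node] = {id(start): start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nb, w in edges(node):
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(node)] + w
                    node_of[id(nb)] = nb
                    stack.append(nb)
        return {
            n.taxon.label: dist[i]
            for i, n in node_of.items()
            if n.is_leaf()
        }

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"


def read_gene_tree(
    newick: str | Path | IO[str], mapping: LeafMapper | None = None
) -> GeneTree:
    """Parse a Newick gene tree and resolve every leaf to a species.

    ``newick`` may be Newick text, a path, or a text stream.  Multifurcations
    and internal labels are preserved.  Resolution failures follow the
    mapper's strict/lenient policy.
    """
    if mapping is None:
        mapping = LeafMapper()
    if isinstance(newick, Path):
        text = newick.read_text(encoding="utf-8")
    elif isinstance(newick, str):
        p = Path(newick)
        if "(" not in newick and p.is_file():
            text = p.read_text(encoding="utf-8")
        else:
            text = newick
    else:
        text = newick.read()

    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"cannot parse Newick: {exc}") from exc

    species_of: dict[str, str | None] = {}
    for lf in tree.leaf_node_iter():
        if lf.taxon is None or not lf.taxon.label:
            raise NewickParseError("tree contains an unlabeled leaf")
        name = lf.taxon.label
        if name in species_of:
            raise GeneTreeError(f"duplicate leaf name {name!r}")
        species_of[name] = mapping.resolve(name)

    return GeneTree(tree, species_of)


def root_at_farthest_leaf(gtree: GeneTree, seed_leaf: str) -> GeneTree:
    """Re-root the tree on the branch of the leaf farthest from the seed.

    Distance is cumulative branch length (missing lengths count as 1.0);
    ties are broken by lexicographically smallest leaf name.  The tree is
    modified in place and returned with ``seed_leaf`` recorded.  Leaf-to-
    leaf path lengths are preserved: the root splits the chosen leaf's
    branch at its midpoint.
    """
    if gtree.n_leaves() < 3:
        raise GeneTreeError("rooting needs at least 3 leaves")
    gtree.find_leaf(seed_leaf)  # raises if absent

    dist = gtree.distances_from(seed_leaf)
    del dist[seed_leaf]
    best = max(dist.values())
    target = min(name for name, d in dist.items() if d == best)

    node = gtree.find_leaf(target)
    parent = node.parent_node
    already_root = (
        parent is gtree.tree.seed_node and len(parent.child_nodes()) == 2
    )
    if not already_root:
        length = node.edge.length if node.edge.length is not None else 1.0
        gtree.tree.reroot_at_edge(
            node.edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
    gtree.seed_leaf = seed_leaf
    return gtree
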