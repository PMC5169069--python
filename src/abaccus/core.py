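"""The incongruence screen: jump (J) and minimal-loss (L) statistics.

The algorithm walks the rooted gene tree from the seed leaf toward the
root.  At each node it compares the taxonomic classification of the node
(the lowest rank at which all its species share a taxon) with that of its
parent.  Two statistics decide whether the step looks like vertical
descent or like a transplant from another lineage:

* **J**, the jump: the number of rank steps between the node's and the
  parent's classification.  Under vertical descent with decent sampling,
  consecutive nodes climb the taxonomy one small step at a time; a large
  jump means the nearest relatives in the gene tree are taxonomically far
  from the seed.

* **L**, the minimal number of parallel losses that a purely vertical
  history would need to explain the same topology.  For each rank crossed
  by the jump, one loss is counted if and only if the species database
  contains at least one lineage at that rank that is absent from the
  compared clades — absence of evidence (a rank with no other known
  member) never counts as a loss.  By construction ``L <= J``.

A node with ``J >= 2`` and ``L >= 3`` (defaults) is a trigger; the call
is confirmed by re-testing the same seed-side clade against the next
sister branch rootward.  Only doubly-positive nodes are emitted, as
candidates for manual inspection; the two sister classifications bracket
the taxonomic range of the putative donor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .genetree import GeneTree
from .taxonomy import (
    N_RANKS,
    NO_COMMON_RANK,
    RANKS,
    RankedLineage,
    TaxonomyTable,
)

__all__ = [
    "CandidateEvent",
    "DetectionError",
    "DetectionResult",
    "NodeEvaluation",
    "Thresholds",
    "confirm_event",
    "count_minimal_losses",
    "detect_events",
    "evaluate_node",
    "scan",
    "taxonomic_jump",
]


class DetectionError(ValueError):
    """Raised on inputs the screen cannot evaluate."""


@dataclass(frozen=True)
class Thresholds:
    """Trigger cutoffs: a node is a candidate when J >= min_jump and
    L >= min_losses (applied to both the trigger and the confirmation)."""

    min_jump: int = 2
    min_losses: int = 3

    def __post_init__(self) -> None:
        if self.min_jump < 0 or self.min_losses < 0:
            raise ValueError("thresholds must be non-negative")

    def passed(self, jump: int, losses: int) -> bool:
        return jump >= self.min_jump and losses >= self.min_losses


@dataclass(frozen=True)
class NodeEvaluation:
    """J and L for one node-versus-sister comparison on the seed path."""

    node_leaves: frozenset[str]
    sister_leaves: frozenset[str]
    node_class: tuple[int, str | None]
    parent_class: tuple[int, str | None]
    sister_class: tuple[int, str | None]
    jump: int
    losses: int
    support: str | None = None

    def rank_name(self, which: str = "node") -> str:
        idx = {
            "node": self.node_class,
            "parent": self.parent_class,
            "sister": self.sister_class,
        }[which][0]
        return RANKS[idx] if idx < N_RANKS else "none"


@dataclass(frozen=True)
class CandidateEvent:
    """A doubly-confirmed incongruent clade, handed to manual inspection."""

    seed: str
    event_leaves: tuple[str, ...]
    trigger: NodeEvaluation
    confirmation: NodeEvaluation
    #: lowest taxon covering both sister branches: the range within which
    #: the donor lineage must sit
    donor_range: tuple[int, str | None]


@dataclass
class DetectionResult:
    """Events plus the full per-node audit trail of one traversal."""

    seed: str
    thresholds: Thresholds
    events: list[CandidateEvent] = field(default_factory=list)
    trail: list[NodeEvaluation] = field(default_factory=list)
    #: trigger evaluations whose confirmation failed or was impossible,
    #: with the reason ("confirmation_failed" | "root_reached")
    rejected: list[tuple[NodeEvaluation, str]] = field(default_factory=list)


def taxonomic_jump(
    node_class: tuple[int, str | None], parent_class: tuple[int, str | None]
) -> int:
    """Rank-step difference between a node's and its parent's
    classification.  Nesting guarantees the parent classifies at the same
    or a higher rank; a negative difference indicates a corrupt taxonomy."""
    diff = parent_class[0] - node_class[0]
    if diff < 0:
        raise DetectionError(
            f"parent classification {parent_class} below node "
            f"classification {node_class}: taxonomy is not nested"
        )
    return diff


def count_minimal_losses(
    table: TaxonomyTable,
    seed_lineage: RankedLineage,
    clade_species: frozenset[str] | set[str],
    sister_species: frozenset[str] | set[str],
    node_rank: int,
    shared_rank: int,
) -> int:
    """Minimal parallel losses a vertical history needs for this step.

    For each rank ``r`` crossed between ``node_rank`` (exclusive) and
    ``shared_rank`` (inclusive), one loss is counted iff the database holds
    a species inside the seed's taxon at ``r``, outside the seed's taxon at
    ``r - 1``, and outside ``clade_species | sister_species``.  At most one
    loss per crossed rank; no database evidence, no loss.  The sentinel
    shared rank (no common taxon) caps the scan at the domain rank, which
    has no super-taxon to provide evidence.
    """
    if not 0 <= node_rank <= NO_COMMON_RANK:
        raise DetectionError(f"node rank {node_rank} out of range")
    if not node_rank <= shared_rank <= NO_COMMON_RANK:
        raise DetectionError(
            f"shared rank {shared_rank} out of range {node_rank}..9"
        )
    if node_rank == shared_rank:
        return 0

    excluded = frozenset(clade_species) | frozenset(sister_species)
    losses = 0
    for r in range(node_rank + 1, min(shared_rank, N_RANKS - 1) + 1):
        members = table.species_in_taxon(r, seed_lineage.taxon_at(r))
        inner = table.species_in_taxon(r - 1, seed_lineage.taxon_at(r - 1))
        if members - inner - excluded:
            losses += 1
    return losses


def _sister_leaves(
    gtree: GeneTree, node: dendropy.Node
) -> frozenset[str]:
    """Leaves of all other children of ``node``'s parent (polytomies give
    the union)."""
    parent = node.parent_node
    return gtree.leaves_under(parent) - gtree.leaves_under(node)


def _classify(
    gtree: GeneTree, table: TaxonomyTable, leaves: frozenset[str]
) -> tuple[int, str | None]:
    species = gtree.species_of_leaves(leaves)
    if not species:
        return NO_COMMON_RANK, None
    return table.classification(species)


def evaluate_node(
    table: TaxonomyTable, gtree: GeneTree, node: dendropy.Node
) -> NodeEvaluation:
    """Compute J and L for one node on the seed-to-root path."""
    if node.parent_node is None:
        raise DetectionError("cannot evaluate the root (it has no parent)")
    if gtree.seed_leaf is None:
        raise DetectionError("gene tree has no designated seed leaf")

    seed_species = gtree.species_of[gtree.seed_leaf]
    if seed_species is None or seed_species not in table:
        raise DetectionError(
            f"seed species {seed_species!r} absent from the taxonomy table"
        )
    seed_lineage = table.lineage_of(seed_species)

    node_leaves = gtree.leaves_under(node)
    sister_leaves = _sister_leaves(gtree, node)
    node_class = _classify(gtree, table, node_leaves)
    parent_class = _classify(
        gtree, table, node_leaves | sister_leaves
    )
    sister_class = (
        _classify(gtree, table, sister_leaves)
        if sister_leaves
        else (NO_COMMON_RANK, None)
    )
    jump = taxonomic_jump(node_class, parent_class)
    losses = count_minimal_losses(
        table,
        seed_lineage,
        gtree.species_of_leaves(node_leaves),
        gtree.species_of_leaves(sister_leaves),
        node_class[0],
        parent_class[0],
    )
    return NodeEvaluation(
        node_leaves=node_leaves,
        sister_leaves=sister_leaves,
        node_class=node_class,
        parent_class=parent_class,
        sister_class=sister_class,
        jump=jump,
        losses=losses,
        support=getattr(node, "label", None),
    )


def confirm_event(
    table: TaxonomyTable, gtree: GeneTree, trigger_node: dendropy.Node
) -> NodeEvaluation | None:
    """Re-test a triggering clade against the next sister branch rootward.

    The seed-side clade and its classification are kept exactly as in the
    trigger; only the comparison branch changes to the sister of the
    trigger's parent.  Returns ``None`` when the parent is the root, i.e.
    no further sister exists and the event cannot be confirmed.
    """
    parent = trigger_node.parent_node
    if parent is None or parent.parent_node is None:
        return None
    next_sister = _sister_leaves(gtree, parent)
    if not next_sister:
        return None

    seed_species = gtree.species_of[gtree.seed_leaf]
    seed_lineage = table.lineage_of(seed_species)

    node_leaves = gtree.leaves_under(trigger_node)
    node_class = _classify(gtree, table, node_leaves)
    merged_class = _classify(gtree, table, node_leaves | next_sister)
    sister_class = _classify(gtree, table, next_sister)
    jump = taxonomic_jump(node_class, merged_class)
    losses = count_minimal_losses(
        table,
        seed_lineage,
        gtree.species_of_leaves(node_leaves),
        gtree.species_of_leaves(next_sister),
        node_class[0],
        merged_class[0],
    )
    return NodeEvaluation(
        node_leaves=node_leaves,
        sister_leaves=next_sister,
        node_class=node_class,
        parent_class=merged_class,
        sister_class=sister_class,
        jump=jump,
        losses=losses,
        support=getattr(trigger_node, "label", None),
    )


def scan(
    gtree: GeneTree,
    table: TaxonomyTable,
    thresholds: Thresholds = Thresholds(),
    *,
    continue_scan: bool = False,
) -> DetectionResult:
    """Walk from the seed leaf to the root, evaluating every node.

    Requires a tree already rooted (see
    :func:`~abaccus.genetree.root_at_farthest_leaf`) with ``seed_leaf``
    set.  A node passing both thresholds is confirmed against the next
    sister branch; on double success a :class:`CandidateEvent` is emitted
    and, by default, the traversal stops (``continue_scan=True`` resumes
    rootward to enumerate nested candidates).
    """
    if gtree.seed_leaf is None:
        raise DetectionError("gene tree has no designated seed leaf")
    seed_species = gtree.species_of.get(gtree.seed_leaf)
    if seed_species is None or seed_species not in table:
        raise DetectionError(
            f"seed species {seed_species!r} absent from the taxonomy table"
        )

    result = DetectionResult(seed=gtree.seed_leaf, thresholds=thresholds)
    node = gtree.find_leaf(gtree.seed_leaf)
    while node.parent_node is not None:
        evaluation = evaluate_node(table, gtree, node)
        result.trail.append(evaluation)
        if thresholds.passed(evaluation.jump, evaluation.losses):
            confirmation = confirm_event(table, gtree, node)
            if confirmation is None:
                result.rejected.append((evaluation, "root_reached"))
            elif thresholds.passed(confirmation.jump, confirmation.losses):
                donor_range = _classify(
                    gtree,
                    table,
                    evaluation.sister_leaves | confirmation.sister_leaves,
                )
                result.events.append(
                    CandidateEvent(
                        seed=gtree.seed_leaf,
                        event_leaves=tuple(sorted(evaluation.node_leaves)),
                        trigger=evaluation,
                        confirmation=confirmation,
                        donor_range=donor_range,
                    )
                )
                if not continue_scan:
                    break
            else:
                result.rejected.append((evaluation, "confirmation_failed"))
        node = node.parent_node
    return result


def detect_events(
    tree: GeneTree,
    table: TaxonomyTable,
    seed: str | None = None,
    thresholds: Thresholds = Thresholds(),
    *,
    continue_scan: bool = False,
) -> list[CandidateEvent]:
    """Root the tree at the farthest leaf from the seed and run the scan.

    ``seed`` may be omitted when the tree already carries a seed leaf.
    Returns the emitted candidate events (0 or 1 by default; possibly
    more with ``continue_scan``).
    """
    from .genetree import root_at_farthest_leaf

    seed_leaf = seed if seed is not None else tree.seed_leaf
    if seed_leaf is None:
        raise DetectionError("no seed leaf given")
    root_at_farthest_leaf(tree, seed_leaf)
    return scan(
        tree, table, thresholds, continue_scan=continue_scan
    ).events
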