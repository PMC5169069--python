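"""Synthetic taxonomies, gene trees, and implanted transfers.

Everything the screen consumes can be generated here, so the whole
pipeline is testable without downloads:

* a deterministic worked-example fixture — a seven-leaf fungal gene tree
  with a thirteen-species companion taxonomy in which a two-species
  *Fusarium* clade sits, incongruently, inside a Trichocomaceae
  neighbourhood;
* fully balanced random taxonomies with configurable breadth per rank;
* species-congruent ("vertical") gene trees sampled from a taxonomy;
* prune-and-regraft implantation of a transfer event, giving trees where
  the expected detection outcome is known by construction;
* a brute-force loss-counting oracle that applies the membership rules
  literally, species by species, with no indices — the independent check
  for the production loss counter.

The simulated trees carry branch lengths but no sequences: the screen is
purely topological, so sequence evolution is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import Thresholds, detect_events
from .genetree import GeneTree, GeneTreeError, LeafMapper, read_gene_tree
from .taxonomy import (
    N_RANKS,
    NO_COMMON_RANK,
    RANKS,
    RankedLineage,
    TaxonomyTable,
)

__all__ = [
    "SimConfig",
    "figure1_fixture",
    "fixture_map_tsv",
    "fixture_newick",
    "fixture_taxonomy_tsv",
    "implant_transfer",
    "oracle_losses",
    "simulate_hgt_instance",
    "simulate_taxonomy",
    "simulate_vertical_tree",
]

_MAX_SPECIES = 100_000

#: Short tags used to build deterministic taxon names, ordered from
#: domain (outermost) inward to species.
_RANK_TAGS = ("d", "sk", "k", "p", "c", "o", "f", "g", "s")


# ---------------------------------------------------------------------------
# Worked-example fixture
# ---------------------------------------------------------------------------

# 13 species; ranks: species, genus, family, order, class, phylum,
# kingdom, superkingdom, domain.  Six of them (Nectria, Gibberella,
# Hypocrea, Cordyceps, Magnaporthe, Saccharomyces) are database-only:
# absent from the gene tree, they are exactly what makes gene absences
# countable as losses.  Names with "sp." are fixture placeholders for
# lineages the example only requires to exist.
_FIXTURE_ROWS: tuple[tuple[str, ...], ...] = (
    ("F. oxysporum", "Fusarium", "Nectriaceae", "Hypocreales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("F. graminearum", "Fusarium", "Nectriaceae", "Hypocreales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Nectria sp.", "Nectria", "Nectriaceae", "Hypocreales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Gibberella sp.", "Gibberella", "Nectriaceae", "Hypocreales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Hypocrea sp.", "Hypocrea", "Hypocreaceae", "Hypocreales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Cordyceps sp.", "Cordyceps", "Cordycipitaceae", "Hypocreales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Magnaporthe sp.", "Magnaporthe", "Magnaporthaceae", "Magnaporthales",
     "Sordariomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("A. nidulans", "Aspergillus", "Trichocomaceae", "Eurotiales",
     "Eurotiomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Penicillium sp.", "Penicillium", "Trichocomaceae", "Eurotiales",
     "Eurotiomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Talaromyces sp.", "Talaromyces", "Trichocomaceae", "Eurotiales",
     "Eurotiomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Paecilomyces sp.", "Paecilomyces", "Trichocomaceae", "Eurotiales",
     "Eurotiomycetes", "Ascomycota", "Fungi", "Opisthokonta", "Eukaryota"),
    ("Saccharomyces sp.", "Saccharomyces", "Saccharomycetaceae",
     "Saccharomycetales", "Saccharomycetes", "Ascomycota", "Fungi",
     "Opisthokonta", "Eukaryota"),
    ("Outgroup sp.", "Outgenus", "Outfamily", "Outorder", "Outclass",
     "Outphylum", "Outkingdom", "Outsuperkingdom", "Bacteria"),
)

_FIXTURE_LEAF_MAP: dict[str, str] = {
    "Foxy_seed": "F. oxysporum",
    "Fgram": "F. graminearum",
    "Anid": "A. nidulans",
    "Peni": "Penicillium sp.",
    "Talaro": "Talaromyces sp.",
    "Paecilo": "Paecilomyces sp.",
    "Outgroup": "Outgroup sp.",
}

_FIXTURE_NEWICK = (
    "((((Foxy_seed:0.10,Fgram:0.10)0.99:0.10,Anid:0.20)0.95:0.10,"
    "(Peni:0.15,Talaro:0.15,Paecilo:0.15)0.90:0.10)0.85:0.10,"
    "Outgroup:2.00);\n"
)

FIXTURE_SEED_LEAF = "Foxy_seed"


def fixture_taxonomy_tsv() -> str:
    """The fixture's 13-row taxonomy table as TSV text."""
    lines = ["\t".join(("label",) + RANKS)]
    for row in _FIXTURE_ROWS:
        lines.append("\t".join((row[0],) + row))
    return "\n".join(lines) + "\n"


def fixture_newick() -> str:
    """The fixture gene tree as Newick text (outgroup branch longest)."""
    return _FIXTURE_NEWICK


def fixture_map_tsv() -> str:
    """The fixture's leaf-name -> species mapping as TSV text."""
    return "".join(
        f"{leaf}\t{sp}\n" for leaf, sp in _FIXTURE_LEAF_MAP.items()
    )


def figure1_fixture() -> tuple[GeneTree, TaxonomyTable, str]:
    """Deterministic worked-example inputs: (gene tree, taxonomy, seed leaf).

    The tree is returned as parsed (not yet rooted at the farthest leaf);
    the outgroup branch is long enough that seed-anchored rooting always
    places the root on it.
    """
    from .taxonomy import load_taxonomy

    table = load_taxonomy(fixture_taxonomy_tsv())
    gtree = read_gene_tree(
        _FIXTURE_NEWICK, LeafMapper(table=_FIXTURE_LEAF_MAP)
    )
    return gtree, table, FIXTURE_SEED_LEAF


# ---------------------------------------------------------------------------
# Random balanced taxonomies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters for synthetic taxonomy / tree / transfer generation.

    ``breadth`` gives the number of children per taxon at each rank below
    domain, ordered superkingdom -> species (8 entries); ``n_domains``
    tops the hierarchy.  ``branch_length_law`` is ``("exponential",
    scale)`` or ``("uniform", low, high)``.  ``loss_fraction`` is the
    probability that a sampled species' gene is nonetheless absent from a
    simulated vertical tree.
    """

    breadth: tuple[int, ...] = (1, 1, 2, 2, 2, 2, 2, 2)
    n_domains: int = 1
    loss_fraction: float = 0.0
    rng_seed: int = 0
    branch_length_law: tuple = ("exponential", 0.1)
    transfer_spec: tuple = ()

    def __post_init__(self) -> None:
        if len(self.breadth) != N_RANKS - 1:
            raise ValueError("breadth needs 8 entries (superkingdom..species)")
        if any(b < 1 for b in self.breadth) or self.n_domains < 1:
            raise ValueError("breadths must be >= 1")
        if not 0.0 <= self.loss_fraction < 1.0:
            raise ValueError("loss_fraction must be in [0, 1)")
        total = self.n_domains * math.prod(self.breadth)
        if total > _MAX_SPECIES:
            raise ValueError(
                f"configuration implies {total} species (> {_MAX_SPECIES})"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def draw_length(self, rng: np.random.Generator) -> float:
        law = self.branch_length_law
        if law[0] == "exponential":
            return float(rng.exponential(law[1]))
        if law[0] == "uniform":
            return float(rng.uniform(law[1], law[2]))
        raise ValueError(f"unknown branch length law {law[0]!r}")


def simulate_taxonomy(config: SimConfig) -> TaxonomyTable:
    """Fully balanced taxonomy with deterministic dotted names.

    Taxon names encode their path, e.g. species ``d1.sk1.k1.p2.c1.o2.f1.g2.s1``
    sits in genus ``d1.sk1.k1.p2.c1.o2.f1.g2``; no randomness is involved.
    """
    lineages: list[RankedLineage] = []

    def descend(name: str, level: int, path: tuple[str, ...]) -> None:
        # level indexes _RANK_TAGS: 0 = domain ... 8 = species
        if level == 8:
            lineages.append(
                RankedLineage(species_label=name, taxa=tuple(reversed(path)))
            )
            return
        for i in range(1, config.breadth[level] + 1):
            child = f"{name}.{_RANK_TAGS[level + 1]}{i}"
            descend(child, level + 1, path + (child,))

    for d in range(1, config.n_domains + 1):
        root = f"{_RANK_TAGS[0]}{d}"
        descend(root, 0, (root,))
    return TaxonomyTable(lineages)


# ---------------------------------------------------------------------------
# Species-congruent trees
# ---------------------------------------------------------------------------


def simulate_vertical_tree(
    table: TaxonomyTable,
    sampled: Iterable[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GeneTree:
    """Gene tree whose topology is the taxonomy restricted to ``sampled``.

    Single-child levels are collapsed, groups are ordered by taxon name,
    and branch lengths come from the config's law, so a fixed
    ``rng_seed`` yields a byte-identical Newick string.  Leaf names equal
    species labels.
    """
    sampled = sorted(set(sampled))
    if not sampled:
        raise GeneTreeError("cannot simulate a tree from an empty sample")
    missing = [s for s in sampled if s not in table]
    if missing:
        raise GeneTreeError(f"sampled species not in taxonomy: {missing[:3]}")
    if rng is None:
        rng = config.rng()
    if config.loss_fraction > 0.0 and len(sampled) > 1:
        kept = [
            s for s in sampled if rng.random() >= config.loss_fraction
        ]
        if kept:
            sampled = kept

    def build(species: Sequence[str], rank: int) -> str:
        if len(species) == 1:
            return f"{species[0]}:{config.draw_length(rng):.6f}"
        # group by taxon at the highest rank that still splits them
        r = rank
        while r > 0:
            groups: dict[str, list[str]] = {}
            for s in species:
                groups.setdefault(table.lineage_of(s).taxon_at(r - 1), []).append(s)
            if len(groups) > 1:
                parts = [
                    build(groups[name], r - 1) for name in sorted(groups)
                ]
                return (
                    "(" + ",".join(parts) + f"):{config.draw_length(rng):.6f}"
                )
            r -= 1
        # identical lineage (in-paralogs not simulated): rake them
        parts = [f"{s}:{config.draw_length(rng):.6f}" for s in species]
        return "(" + ",".join(parts) + f"):{config.draw_length(rng):.6f}"

    if len(sampled) == 1:
        newick = f"({sampled[0]}:{config.draw_length(rng):.6f});\n"
    else:
        body = build(sampled, N_RANKS)
        body = body.rsplit(":", 1)[0]  # the root carries no branch length
        if not body.startswith("("):
            body = f"({body})"
        newick = body + ";\n"
    return read_gene_tree(newick, LeafMapper())


# ---------------------------------------------------------------------------
# Transfer implantation
# ---------------------------------------------------------------------------


def implant_transfer(
    gtree: GeneTree,
    recipient_clade: Iterable[str],
    donor_taxon: tuple[int, str],
    rng: np.random.Generator,
    table: TaxonomyTable | None = None,
) -> GeneTree:
    """Prune a clade and regraft it inside the donor taxon's subtree.

    ``recipient_clade`` must be the exact leaf set of an existing clade;
    ``donor_taxon`` is ``(rank_index, taxon_name)`` and must have at least
    one leaf in the tree (membership is resolved through ``table`` when
    given, else by matching species labels against the taxon name).  The
    regraft edge is drawn uniformly among the edges strictly inside the
    donor subtree, so a fixed ``rng`` state reproduces the topology.
    """
    want = frozenset(recipient_clade)
    tree = gtree.tree
    tree.is_rooted = True

    recipient = None
    for node in tree.preorder_node_iter():
        if gtree.leaves_under(node) == want:
            recipient = node
            break
    if recipient is None or recipient.parent_node is None:
        raise GeneTreeError(
            f"recipient clade {sorted(want)} is not a proper clade"
        )

    rank, name = donor_taxon

    def in_donor(leaf) -> bool:
        sp = gtree.species_of.get(leaf.taxon.label)
        if sp is None:
            return False
        if table is not None:
            return table.lineage_of(sp).taxon_at(rank) == name
        return sp == name
    donor_leaves = [
        lf
        for lf in tree.leaf_node_iter()
        if in_donor(lf) and lf.taxon.label not in want
    ]
    if not donor_leaves:
        raise GeneTreeError(f"donor taxon {name!r} has no leaf in the tree")

    # detach the recipient clade
    parent = recipient.parent_node
    parent.remove_child(recipient)
    tree.suppress_unifurcations()

    if len(donor_leaves) == 1:
        mrca = donor_leaves[0]
        candidates = [mrca]
    else:
        mrca = tree.mrca(taxa=[lf.taxon for lf in donor_leaves])
        candidates = [
            n for n in mrca.preorder_iter() if n is not mrca
        ]
    target = candidates[int(rng.integers(len(candidates)))]

    # split the target's edge and hang the recipient off the new node
    graft_parent = target.parent_node
    new = type(target)()
    length = target.edge.length if target.edge.length is not None else 1.0
    graft_parent.remove_child(target)
    graft_parent.add_child(new)
    new.edge.length = length / 2.0
    new.add_child(target)
    target.edge.length = length / 2.0
    new.add_child(recipient)
    return gtree


# ---------------------------------------------------------------------------
# Brute-force loss oracle
# ---------------------------------------------------------------------------


def oracle_losses(
    table: TaxonomyTable,
    seed_lineage: RankedLineage,
    clade_species: Iterable[str],
    sister_species: Iterable[str],
    node_rank: int,
    shared_rank: int,
) -> int:
    """Literal re-statement of minimal-loss counting, for testing.

    Walks every database species at every crossed rank and applies the
    membership rules one comparison at a time — no reverse index, no
    shortcuts.  Intended for small tables (tens of species).
    """
    if not 0 <= node_rank <= NO_COMMON_RANK:
        raise ValueError(f"node rank {node_rank} out of range")
    if not node_rank <= shared_rank <= NO_COMMON_RANK:
        raise ValueError(f"shared rank {shared_rank} out of range")
    if node_rank == shared_rank:
        return 0
    excluded = set(clade_species) | set(sister_species)
    total = 0
    for r in range(node_rank + 1, min(shared_rank, N_RANKS - 1) + 1):
        found = False
        for s in table.species:
            if s in excluded:
                continue
            lin = table.lineage_of(s)
            if lin.taxon_at(r) != seed_lineage.taxon_at(r):
                continue
            if lin.taxon_at(r - 1) == seed_lineage.taxon_at(r - 1):
                continue
            found = True
            break
        if found:
            total += 1
    return total


# ---------------------------------------------------------------------------
# Benchmark instances with a known implanted transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HgtInstance:
    """One simulated screen input with ground truth."""

    gtree: GeneTree
    table: TaxonomyTable
    seed_leaf: str
    truth_clade: frozenset[str]
    #: database-only relatives of the recipient at intermediate ranks —
    #: the loss evidence the detection depends on
    planted_relatives: frozenset[str]


def simulate_hgt_instance(
    rng_seed: int, *, lone_representative: bool = False
) -> HgtInstance:
    """Simulate one inter-domain transfer with known ground truth.

    A two-domain balanced taxonomy (128 species) is built; a random
    two-species genus from the first domain is the recipient.  Three
    groups of its relatives — the sibling genus in its family, a sibling
    family in its order, and a sibling order in its class — are withheld
    from the tree sample, so they exist only in the database and provide
    loss evidence at three distinct intermediate ranks.  The recipient
    clade is then regrafted inside the second domain.

    With ``lone_representative=True`` the withheld relatives are also
    deleted from the taxonomy, emulating a lineage with no sampled
    relatives at intermediate ranks: the loss count can then never reach
    the default threshold and the event must go undetected.
    """
    config = SimConfig(
        breadth=(1, 1, 2, 2, 2, 2, 2, 2),
        n_domains=2,
        rng_seed=rng_seed,
        branch_length_law=("uniform", 0.05, 0.15),
    )
    table = simulate_taxonomy(config)
    rng = config.rng()

    genera = sorted(
        {
            table.lineage_of(s).taxon_at(1)
            for s in table.species
            if table.lineage_of(s).taxon_at(8) == "d1"
        }
    )
    genus = genera[int(rng.integers(len(genera)))]
    truth = table.species_in_taxon(1, genus)
    seed_species = sorted(truth)[0]
    lin = table.lineage_of(seed_species)

    def withheld_at(rank: int) -> frozenset[str]:
        outer = table.species_in_taxon(rank, lin.taxon_at(rank))
        inner = table.species_in_taxon(rank - 1, lin.taxon_at(rank - 1))
        return outer - inner

    planted = withheld_at(2) | withheld_at(3) | withheld_at(4)

    sample = table.species - planted
    gtree = simulate_vertical_tree(table, sample, config, rng)
    implant_transfer(gtree, truth, (8, "d2"), rng, table)

    if lone_representative:
        kept = [
            table.lineage_of(s)
            for s in table.species
            if s not in planted
        ]
        table = TaxonomyTable(kept)

    return HgtInstance(
        gtree=gtree,
        table=table,
        seed_leaf=seed_species,
        truth_clade=frozenset(truth),
        planted_relatives=frozenset(planted),
    )


def benchmark_recall(
    n_trees: int,
    rng_seed: int,
    thresholds: Thresholds = Thresholds(),
    *,
    lone_representative: bool = False,
) -> float:
    """Fraction of simulated transfers recovered exactly.

    A hit requires exactly one emitted event whose clade equals the
    implanted recipient clade.
    """
    hits = 0
    base = np.random.SeedSequence(rng_seed).generate_state(n_trees) % (2**31)
    for i in range(n_trees):
        inst = simulate_hgt_instance(
            int(base[i]), lone_representative=lone_representative
        )
        events = detect_events(
            inst.gtree, inst.table, inst.seed_leaf, thresholds
        )
        if (
            len(events) == 1
            and frozenset(events[0].event_leaves) == inst.truth_clade
        ):
            hits += 1
    return hits / n_trees


def benchmark_specificity(
    n_trees: int,
    rng_seed: int,
    thresholds: Thresholds = Thresholds(),
) -> float:
    """Fraction of fully sampled species-congruent trees with zero events.

    Complete sampling of a balanced taxonomy leaves nothing for the loss
    counter to count, so any emitted event is a false positive.
    """
    clean = 0
    base = np.random.SeedSequence(rng_seed).generate_state(n_trees) % (2**31)
    for i in range(n_trees):
        config = SimConfig(
            breadth=(1, 1, 2, 2, 2, 2, 2, 2),
            n_domains=2,
            rng_seed=int(base[i]),
            branch_length_law=("uniform", 0.05, 0.15),
        )
        table = simulate_taxonomy(config)
        rng = config.rng()
        gtree = simulate_vertical_tree(table, table.species, config, rng)
        species = sorted(table.species)
        seed_leaf = species[int(rng.integers(len(species)))]
        events = detect_events(gtree, table, seed_leaf, thresholds)
        if not events:
            clean += 1
    return clean / n_trees
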