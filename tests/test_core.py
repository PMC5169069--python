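"""Detection statistics: jump, minimal losses, traversal, confirmation."""

import pytest

from abaccus.core import (
    DetectionError,
    Thresholds,
    confirm_event,
    count_minimal_losses,
    detect_events,
    evaluate_node,
    scan,
    taxonomic_jump,
)
from abaccus.genetree import LeafMapper, read_gene_tree, root_at_farthest_leaf
from abaccus.simulate import (
    SimConfig,
    simulate_hgt_instance,
    simulate_taxonomy,
    simulate_vertical_tree,
)
from abaccus.taxonomy import RANKS, TaxonomyTable, load_taxonomy

HEADER = "\t".join(("label",) + RANKS)


@pytest.mark.parametrize(
    "node_class,parent_class,expected",
    [
        ((0, "F. oxysporum"), (1, "Fusarium"), 1),
        ((1, "Fusarium"), (5, "Ascomycota"), 4),
        ((3, "Hypocreales"), (3, "Hypocreales"), 0),
    ],
)
def test_taxonomic_jump_is_rank_difference(node_class, parent_class, expected):
    assert taxonomic_jump(node_class, parent_class) == expected


def test_taxonomic_jump_rejects_inverted_ranks():
    with pytest.raises(DetectionError):
        taxonomic_jump((5, "Ascomycota"), (1, "Fusarium"))


def test_losses_species_to_genus_step_is_zero(fig1):
    """No other Fusarium species exists in the database, so crossing
    species -> genus implies no loss."""
    _, table, _ = fig1
    lineage = table.lineage_of("F. oxysporum")
    assert (
        count_minimal_losses(
            table, lineage, {"F. oxysporum"}, {"F. graminearum"}, 0, 1
        )
        == 0
    )


def test_losses_genus_to_phylum_step_counts_four(fig1):
    """One loss each at Nectriaceae, Hypocreales, Sordariomycetes and
    Ascomycota: the database holds members of each that are absent from
    the compared clades."""
    _, table, _ = fig1
    lineage = table.lineage_of("F. oxysporum")
    clade = {"F. oxysporum", "F. graminearum"}
    assert (
        count_minimal_losses(table, lineage, clade, {"A. nidulans"}, 1, 5)
        == 4
    )


def test_losses_zero_when_database_adds_nothing():
    rows = [
        "A sp.\tA sp.\tG1\tF1\tO1\tC1\tP1\tK1\tSK1\tD1",
        "B sp.\tB sp.\tG2\tF1\tO1\tC1\tP1\tK1\tSK1\tD1",
    ]
    table = load_taxonomy(HEADER + "\n" + "\n".join(rows) + "\n")
    lineage = table.lineage_of("A sp.")
    assert (
        count_minimal_losses(table, lineage, {"A sp."}, {"B sp."}, 0, 8) == 0
    )


def test_losses_rank_range_validated(fig1):
    _, table, _ = fig1
    lineage = table.lineage_of("F. oxysporum")
    with pytest.raises(DetectionError):
        count_minimal_losses(table, lineage, set(), set(), -1, 5)
    with pytest.raises(DetectionError):
        count_minimal_losses(table, lineage, set(), set(), 5, 12)
    with pytest.raises(DetectionError):
        count_minimal_losses(table, lineage, set(), set(), 5, 2)


def _seed_path_nodes(gtree):
    node = gtree.find_leaf(gtree.seed_leaf)
    out = []
    while node.parent_node is not None:
        out.append(node)
        node = node.parent_node
    return out


def test_evaluate_node_reproduces_worked_example_steps(fig1_rooted):
    gtree, table, _ = fig1_rooted
    path = _seed_path_nodes(gtree)
    first = evaluate_node(table, gtree, path[0])
    assert (first.jump, first.losses) == (1, 0)
    assert first.node_class == (0, "F. oxysporum")
    assert first.parent_class == (1, "Fusarium")
    second = evaluate_node(table, gtree, path[1])
    assert (second.jump, second.losses) == (4, 4)
    assert second.sister_class == (0, "A. nidulans")


def test_evaluate_node_rejects_root(fig1_rooted):
    gtree, table, _ = fig1_rooted
    with pytest.raises(DetectionError):
        evaluate_node(table, gtree, gtree.root)


def test_confirmation_keeps_seed_clade_and_passes(fig1_rooted):
    """The trigger clade (the two Fusarium sequences) is re-tested
    against the three-genus Trichocomaceae branch and again gives
    J = 4, L = 4."""
    gtree, table, _ = fig1_rooted
    trigger_node = _seed_path_nodes(gtree)[1]
    conf = confirm_event(table, gtree, trigger_node)
    assert conf is not None
    assert (conf.jump, conf.losses) == (4, 4)
    assert conf.node_leaves == {"Foxy_seed", "Fgram"}
    assert conf.sister_leaves == {"Peni", "Talaro", "Paecilo"}
    assert conf.sister_class == (2, "Trichocomaceae")


def test_confirmation_impossible_at_root(fig1_rooted):
    gtree, table, _ = fig1_rooted
    below_root = _seed_path_nodes(gtree)[-1]
    assert confirm_event(table, gtree, below_root) is None


def test_detect_events_accepts_the_fusarium_clade(fig1):
    gtree, table, seed = fig1
    events = detect_events(gtree, table, seed)
    assert len(events) == 1
    assert set(events[0].event_leaves) == {"Foxy_seed", "Fgram"}
    assert events[0].donor_range == (2, "Trichocomaceae")


def test_congruent_fully_sampled_tree_yields_no_event():
    config = SimConfig(breadth=(1, 1, 2, 2, 2, 2, 2, 2), n_domains=2,
                       rng_seed=11)
    table = simulate_taxonomy(config)
    gtree = simulate_vertical_tree(table, table.species, config)
    seed = sorted(table.species)[5]
    assert detect_events(gtree, table, seed) == []


def test_lone_representative_lineage_cannot_trigger():
    """A seed whose genus..phylum have no other database member can never
    accumulate enough loss evidence, whatever the topology."""
    rows = [
        "Lone sp.\tLone sp.\tLg\tLf\tLo\tLc\tLp\tK1\tSK1\tD1",
        "B sp.\tB sp.\tBg\tBf\tBo\tBc\tBp\tK1\tSK1\tD1",
        "C1\t*\t*\t*\t*\t*\t*\t*\t*\tD2",
        "C2\t*\t*\t*\t*\t*\t*\t*\t*\tD2",
        "C3\t*\t*\t*\t*\t*\t*\t*\t*\tD2",
    ]
    table = load_taxonomy(HEADER + "\n" + "\n".join(rows) + "\n")
    # seed nested inside the foreign domain: maximal incongruence
    gtree = read_gene_tree(
        "((('Lone sp.':0.1,C1:0.1):0.1,C2:0.1):0.1,(C3:0.1,'B sp.':1.5):0.1);",
        LeafMapper(),
    )
    assert detect_events(gtree, table, "Lone sp.") == []


def test_seed_species_missing_from_table_aborts(fig1):
    gtree, _, seed = fig1
    tiny = load_taxonomy(
        HEADER + "\nB sp.\tB sp.\tBg\tBf\tBo\tBc\tBp\tK1\tSK1\tD1\n"
    )
    with pytest.raises(DetectionError):
        detect_events(gtree, tiny, seed)


def test_threshold_monotonicity(fig1):
    """Tighter thresholds can only lose events, never gain them."""
    loose = Thresholds(1, 1)
    default = Thresholds(2, 3)
    strict = Thresholds(5, 5)
    gtree, table, seed = fig1
    root_at_farthest_leaf(gtree, seed)

    def clades(thresholds):
        res = scan(gtree, table, thresholds, continue_scan=True)
        return {frozenset(ev.event_leaves) for ev in res.events}

    assert clades(strict) <= clades(default) <= clades(loose)

    for i in range(3):
        inst = simulate_hgt_instance(100 + i)
        root_at_farthest_leaf(inst.gtree, inst.seed_leaf)

        def sim_clades(thresholds, inst=inst):
            res = scan(
                inst.gtree, inst.table, thresholds, continue_scan=True
            )
            return {frozenset(ev.event_leaves) for ev in res.events}

        assert (
            sim_clades(strict) <= sim_clades(default) <= sim_clades(loose)
        )


def test_loss_monotonicity_under_database_growth(fig1_rooted):
    """Adding a species absent from the tree never decreases L."""
    gtree, table, _ = fig1_rooted
    base = [ev.losses for ev in scan(gtree, table).trail]
    extra_rows = [
        "New sp.\tNew sp.\tNewg\tNewf\tNewo\tNewc\tAscomycota\tFungi"
        "\tOpisthokonta\tEukaryota",
        "Far sp.\tFar sp.\tFarg\tFarf\tFaro\tFarc\tFarp\tFark\tFarsk\tFard",
    ]
    for row in extra_rows:
        grown = TaxonomyTable(
            [table.lineage_of(s) for s in table.species]
            + [
                load_taxonomy(HEADER + "\n" + row + "\n").lineage_of(
                    row.split("\t")[0]
                )
            ]
        )
        grown_losses = [ev.losses for ev in scan(gtree, grown).trail]
        assert all(g >= b for g, b in zip(grown_losses, base))


def test_losses_never_exceed_jump(fig1_rooted):
    gtree, table, _ = fig1_rooted
    for ev in scan(gtree, table).trail:
        assert 0 <= ev.losses <= ev.jump
    for i in range(5):
        inst = simulate_hgt_instance(200 + i)
        root_at_farthest_leaf(inst.gtree, inst.seed_leaf)
        for ev in scan(inst.gtree, inst.table).trail:
            assert 0 <= ev.losses <= ev.jump


def test_scan_is_deterministic(fig1):
    from abaccus.report import audit_json
    from abaccus.simulate import figure1_fixture

    runs = []
    for _ in range(2):
        gtree, table, seed = figure1_fixture()
        root_at_farthest_leaf(gtree, seed)
        runs.append(audit_json(scan(gtree, table)))
    assert runs[0] == runs[1]


def test_in_paralogs_do_not_inflate_jump_or_losses(fig1):
    """Two sequences from one species classify like one: species sets."""
    _, table, _ = fig1
    mapping = {
        "Foxy_seed": "F. oxysporum",
        "Foxy_2": "F. oxysporum",
        "Fgram": "F. graminearum",
        "Anid": "A. nidulans",
        "Outgroup": "Outgroup sp.",
    }
    gtree = read_gene_tree(
        "((((Foxy_seed:0.1,Foxy_2:0.1):0.1,Fgram:0.1):0.1,Anid:0.2):0.1,"
        "Outgroup:2.0);",
        LeafMapper(table=mapping),
    )
    root_at_farthest_leaf(gtree, "Foxy_seed")
    trail = scan(gtree, table).trail
    # duplicate-species node: same species on both sides, J <= 1, L = 0
    assert (trail[0].jump, trail[0].losses) == (0, 0)
    assert (trail[1].jump, trail[1].losses) == (1, 0)
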