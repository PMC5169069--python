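"""Taxonomy table: loading, validation, classification, reverse index."""

import itertools

import numpy as np
import pytest

from abaccus.simulate import fixture_taxonomy_tsv
from abaccus.taxonomy import (
    NO_COMMON_RANK,
    RANKS,
    TaxonomyError,
    UnknownSpeciesError,
    load_taxonomy,
)

HEADER = "\t".join(("label",) + RANKS)


def _table(rows):
    return load_taxonomy(HEADER + "\n" + "\n".join(rows) + "\n")


def test_fixture_table_loads_with_13_lineages(fig1):
    _, table, _ = fig1
    assert len(table) == 13
    assert table.lineage_of("F. oxysporum").taxon_at(5) == "Ascomycota"
    assert table.lineage_of("F. oxysporum").taxon_at(0) == "F. oxysporum"


def test_single_row_table_has_singleton_member_sets():
    row = "X sp.\tX sp.\tXg\tXf\tXo\tXc\tXp\tXk\tXsk\tXd"
    table = _table([row])
    for r in range(9):
        taxon = table.lineage_of("X sp.").taxon_at(r)
        assert table.species_in_taxon(r, taxon) == {"X sp."}


@pytest.mark.parametrize(
    "species,expected",
    [
        ({"F. oxysporum", "F. graminearum"}, (1, "Fusarium")),
        ({"F. oxysporum", "A. nidulans"}, (5, "Ascomycota")),
        ({"F. oxysporum"}, (0, "F. oxysporum")),
        ({"F. oxysporum", "Outgroup sp."}, (NO_COMMON_RANK, None)),
        (
            {"F. oxysporum", "Nectria sp.", "Gibberella sp."},
            (2, "Nectriaceae"),
        ),
    ],
)
def test_classification_resolves_lowest_shared_taxon(fig1, species, expected):
    _, table, _ = fig1
    assert table.classification(species) == expected


def test_classification_rejects_unknown_and_empty(fig1):
    _, table, _ = fig1
    with pytest.raises(UnknownSpeciesError):
        table.classification({"no such species"})
    with pytest.raises(ValueError):
        table.classification(set())


def test_species_in_taxon_membership(fig1):
    _, table, _ = fig1
    assert table.species_in_taxon(2, "Nectriaceae") == {
        "F. oxysporum",
        "F. graminearum",
        "Nectria sp.",
        "Gibberella sp.",
    }
    assert len(table.species_in_taxon(8, "Eukaryota")) == 12
    assert table.species_in_taxon(1, "NoSuchGenus") == frozenset()


def test_lineage_of_unknown_species_raises(fig1):
    _, table, _ = fig1
    with pytest.raises(UnknownSpeciesError):
        table.lineage_of("unknown")


@pytest.mark.parametrize(
    "bad_row,match",
    [
        ("A sp.\tA sp.\t\tAf\tAo\tAc\tAp\tAk\tAsk\tAd", "empty taxon"),
        ("A sp.\tWrong\tAg\tAf\tAo\tAc\tAp\tAk\tAsk\tAd", "differs"),
        ("A sp.\tA sp.\tAg\tAf\tAo\tAc\tAp\tAk\tAsk", "columns"),
    ],
)
def test_malformed_rows_rejected(bad_row, match):
    with pytest.raises(TaxonomyError, match=match):
        _table([bad_row])


def test_duplicate_label_rejected_and_dropped_when_lenient():
    row = "A sp.\tA sp.\tAg\tAf\tAo\tAc\tAp\tAk\tAsk\tAd"
    with pytest.raises(TaxonomyError, match="duplicate"):
        _table([row, row])
    table = load_taxonomy(
        HEADER + "\n" + row + "\n" + row + "\n", lenient=True
    )
    assert len(table) == 1


def test_genus_split_across_families_rejected():
    rows = [
        "A sp.\tA sp.\tG\tFam1\tO\tC\tP\tK\tSK\tD",
        "B sp.\tB sp.\tG\tFam2\tO\tC\tP\tK\tSK\tD",
        "C sp.\tC sp.\tG2\tFam1\tO\tC\tP\tK\tSK\tD",
    ]
    with pytest.raises(TaxonomyError, match="two\\s+parents"):
        _table(rows)


def test_bad_header_rejected():
    with pytest.raises(TaxonomyError, match="header"):
        load_taxonomy("species\tgenus\n")


def test_roundtrip_preserves_rows():
    text = fixture_taxonomy_tsv()
    table = load_taxonomy(text)
    again = load_taxonomy(table.to_tsv())
    assert again.species == table.species
    for s in table.species:
        assert again.lineage_of(s) == table.lineage_of(s)
    assert sorted(text.strip().splitlines()[1:]) == sorted(
        table.to_tsv().strip().splitlines()[1:]
    )


def test_filler_rows_resolve_at_domain_and_roundtrip():
    rows = [
        "Cluster1\t*\t*\t*\t*\t*\t*\t*\t*\tBacteria",
        "Cluster2\t*\t*\t*\t*\t*\t*\t*\t*\tBacteria",
        "E sp.\tE sp.\tEg\tEf\tEo\tEc\tEp\tEk\tEsk\tEukaryota",
    ]
    table = _table(rows)
    assert table.classification({"Cluster1", "Cluster2"}) == (8, "Bacteria")
    assert table.classification({"Cluster1", "E sp."}) == (
        NO_COMMON_RANK,
        None,
    )
    written = table.to_tsv()
    assert "Cluster1\t*\t*" in written
    assert load_taxonomy(written).classification({"Cluster1"}) == (
        0,
        "Cluster1",
    )


def test_domain_rank_may_not_be_filler():
    with pytest.raises(TaxonomyError, match="domain"):
        _table(["C1\t*\t*\t*\t*\t*\t*\t*\t*\t*"])


def test_membership_and_nesting_invariants(fig1):
    _, table, _ = fig1
    for s in table.species:
        lin = table.lineage_of(s)
        for r in range(9):
            members = table.species_in_taxon(r, lin.taxon_at(r))
            assert s in members
            if r < 8:
                assert members <= table.species_in_taxon(
                    r + 1, lin.taxon_at(r + 1)
                )


def test_classification_equals_pairwise_worst_case(fig1):
    """The lowest shared rank of a set is the deepest pairwise one."""
    _, table, _ = fig1
    rng = np.random.default_rng(7)
    species = sorted(table.species)
    for _ in range(40):
        k = int(rng.integers(2, 6))
        subset = [species[i] for i in rng.choice(len(species), k, False)]
        rank, _ = table.classification(subset)
        pairwise = max(
            table.classification({a, b})[0]
            for a, b in itertools.combinations(subset, 2)
        )
        assert rank == pairwise
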