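"""Balanced ranked taxonomy used as a proxy for the species phylogeny.

The screen needs, for every species that can appear in a gene tree, a
classification into exactly nine nested ranks (species through domain).
Using a rank-balanced table instead of a resolved species tree sidesteps
the unevenness of public taxonomies: every pair of species is comparable
at the same nine levels, so "how far apart are these lineages" is always
a well-defined number of rank steps.

The table is the evidence base for loss counting: a gene absence only
counts as a loss if the database actually contains a lineage that could
have retained the gene.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: The nine ranks, ordered from most specific (index 0) to most inclusive
#: (index 8).
RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
    "superkingdom",
    "domain",
)

N_RANKS = len(RANKS)

#: Sentinel rank index reported when a species set shares no taxon at any
#: rank, i.e. the set spans more than one domain.
NO_COMMON_RANK = 9

#: Reserved cell token for rows with no sub-domain resolution (e.g.
#: cluster-level prokaryotic references).  Internally each filler cell is
#: replaced by the row's own species label, so two filler rows never share
#: a taxon below domain and any comparison involving one resolves at the
#: domain rank.
FILLER = "*"

#: Expected TSV header: a label column followed by one column per rank.
TSV_HEADER: tuple[str, ...] = ("label",) + RANKS


class TaxonomyError(ValueError):
    """Raised when a taxonomy table violates the balanced-rank contract."""


class UnknownSpeciesError(KeyError):
    """Raised when a species label is not present in the taxonomy table."""


@dataclass(frozen=True)
class RankedLineage:
    """One species' taxon name at each of the nine ranks.

    ``taxa[0]`` is the species itself and equals ``species_label``;
    ``taxa[8]`` is the domain.  ``filler_ranks`` records which input cells
    held the :data:`FILLER` token (kept only so the table can be written
    back in its original form).
    """

    species_label: str
    taxa: tuple[str, ...]
    filler_ranks: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        if len(self.taxa) != N_RANKS:
            raise TaxonomyError(
                f"{self.species_label!r}: expected {N_RANKS} ranks, "
                f"got {len(self.taxa)}"
            )
        for idx, name in enumerate(self.taxa):
            if not name:
                raise TaxonomyError(
                    f"{self.species_label!r}: empty taxon at rank "
                    f"{RANKS[idx]!r}"
                )
        if self.taxa[0] != self.species_label:
            raise TaxonomyError(
                f"{self.species_label!r}: species-rank taxon "
                f"{self.taxa[0]!r} differs from the label"
            )

    @classmethod
    def from_row(cls, label: str, cells: Iterable[str]) -> "RankedLineage":
        """Build a lineage from raw TSV cells, expanding filler tokens."""
        cells = tuple(cells)
        filler = frozenset(i for i, c in enumerate(cells) if c == FILLER)
        if 8 in filler:
            raise TaxonomyError(f"{label!r}: domain rank may not be filler")
        taxa = tuple(label if c == FILLER else c for c in cells)
        return cls(species_label=label, taxa=taxa, filler_ranks=filler)

    def taxon_at(self, rank_index: int) -> str:
        if not 0 <= rank_index < N_RANKS:
            raise IndexError(f"rank index {rank_index} out of range 0..8")
        return self.taxa[rank_index]

    def row(self) -> tuple[str, ...]:
        """The lineage as a TSV row (filler cells restored)."""
        cells = tuple(
            FILLER if i in self.filler_ranks else t
            for i, t in enumerate(self.taxa)
        )
        return (self.species_label,) + cells


class TaxonomyTable:
    """The species database: lineages plus a taxon -> members reverse index.

    Taxa are keyed by ``(rank_index, name)``; the same name at two ranks
    denotes two different taxa.  Construction verifies that taxa nest: a
    taxon at rank *r* must map to a single parent taxon at rank *r + 1*
    across all of its member species, so the table describes a tree.
    """

    def __init__(self, lineages: Iterable[RankedLineage]):
        self._lineages: dict[str, RankedLineage] = {}
        for lin in lineages:
            if lin.species_label in self._lineages:
                raise TaxonomyError(
                    f"duplicate species label {lin.species_label!r}"
                )
            self._lineages[lin.species_label] = lin
        self._members: dict[tuple[int, str], frozenset[str]] = {}
        self._build_index()
        self._check_nesting()

    def _build_index(self) -> None:
        acc: dict[tuple[int, str], set[str]] = {}
        for label, lin in self._lineages.items():
            for r in range(N_RANKS):
                acc.setdefault((r, lin.taxa[r]), set()).add(label)
        self._members = {k: frozenset(v) for k, v in acc.items()}

    def _check_nesting(self) -> None:
        parent: dict[tuple[int, str], str] = {}
        for label, lin in self._lineages.items():
            for r in range(N_RANKS - 1):
                key = (r, lin.taxa[r])
                seen = parent.setdefault(key, lin.taxa[r + 1])
                if seen != lin.taxa[r + 1]:
                    raise TaxonomyError(
                        f"taxon {lin.taxa[r]!r} at rank {RANKS[r]!r} has two "
                        f"parents at rank {RANKS[r + 1]!r}: {seen!r} and "
                        f"{lin.taxa[r + 1]!r} (via {label!r})"
                    )

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._lineages)

    def __contains__(self, species: str) -> bool:
        return species in self._lineages

    def __iter__(self) -> Iterator[str]:
        return iter(self._lineages)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._lineages)

    def lineage_of(self, species: str) -> RankedLineage:
        try:
            return self._lineages[species]
        except KeyError:
            raise UnknownSpeciesError(species) from None

    def species_in_taxon(self, rank_index: int, taxon: str) -> frozenset[str]:
        """Members of ``(rank_index, taxon)``; empty set if the taxon is
        unknown."""
        if not 0 <= rank_index < N_RANKS:
            raise IndexError(f"rank index {rank_index} out of range 0..8")
        return self._members.get((rank_index, taxon), frozenset())

    def classification(
        self, species: Iterable[str]
    ) -> tuple[int, str | None]:
        """Lowest rank at which all given species share one taxon.

        Returns ``(rank_index, taxon_name)``, or ``(NO_COMMON_RANK, None)``
        when the set spans more than one domain.  Raises
        :class:`UnknownSpeciesError` for species absent from the table and
        :class:`ValueError` for an empty set.
        """
        lineages = [self.lineage_of(s) for s in species]
        if not lineages:
            raise ValueError("classification of an empty species set")
        for r in range(N_RANKS):
            names = {lin.taxa[r] for lin in lineages}
            if len(names) == 1:
                return r, names.pop()
        return NO_COMMON_RANK, None

    # -- serialization ---------------------------------------------------

    def to_tsv(self, stream: IO[str] | None = None) -> str | None:
        """Write the table as TSV; returns the text when no stream given."""
        own = stream is None
        out = io.StringIO() if own else stream
        out.write("\t".join(TSV_HEADER) + "\n")
        for label in sorted(self._lineages):
            out.write("\t".join(self._lineages[label].row()) + "\n")
        if own:
            return out.getvalue()  # type: ignore[union-attr]
        return None


def load_taxonomy(
    source: str | Path | IO[str], *, lenient: bool = False
) -> TaxonomyTable:
    """Load a taxonomy table from a TSV path, text, or stream.

    The file must carry the header ``label species genus ... domain``
    (tab-separated) and one row per species with all ten cells non-empty;
    the species cell must repeat the label (or be the filler token).

    With ``lenient=True``, rows with missing or empty cells and rows whose
    label was already seen are dropped with a logged warning instead of
    aborting the load.  Structural violations — a taxon with two parents —
    always abort: they cannot be repaired by dropping a row deterministically.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        p = Path(source)
        if "\n" not in source and "\t" not in source and p.is_file():
            text = p.read_text(encoding="utf-8")
        else:
            text = source
    else:
        text = source.read()

    reader = csv.reader(io.StringIO(text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise TaxonomyError("empty taxonomy source") from None
    if tuple(h.strip() for h in header) != TSV_HEADER:
        raise TaxonomyError(
            f"bad header: expected {list(TSV_HEADER)}, got {header}"
        )

    lineages: dict[str, RankedLineage] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        try:
            if len(row) != len(TSV_HEADER):
                raise TaxonomyError(
                    f"line {lineno}: expected {len(TSV_HEADER)} columns, "
                    f"got {len(row)}"
                )
            label = row[0]
            if not label:
                raise TaxonomyError(f"line {lineno}: empty species label")
            if label in lineages:
                raise TaxonomyError(
                    f"line {lineno}: duplicate species label {label!r}"
                )
            lin = RankedLineage.from_row(label, row[1:])
        except TaxonomyError as exc:
            if lenient:
                logger.warning("dropping malformed taxonomy row: %s", exc)
                continue
            raise
        lineages[label] = lin

    return TaxonomyTable(lineages.values())


def classification(
    table: TaxonomyTable, species: Iterable[str]
) -> tuple[int, str | None]:
    """Module-level alias for :meth:`TaxonomyTable.classification`."""
    return table.classification(species)


def species_in_taxon(
    table: TaxonomyTable, rank_index: int, taxon: str
) -> frozenset[str]:
    """Module-level alias for :meth:`TaxonomyTable.species_in_taxon`."""
    return table.species_in_taxon(rank_index, taxon)


def lineage_of(table: TaxonomyTable, species: str) -> RankedLineage:
    """Module-level alias for :meth:`TaxonomyTable.lineage_of`."""
    return table.lineage_of(species)
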