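"""Report writers and end-to-end run orchestration.

One detection run produces three artifacts next to each other under a
common output prefix:

* ``<prefix>.events.tsv`` — one row per accepted candidate event;
* ``<prefix>.audit.json`` — the full traversal trail (per-node J and L),
  thresholds, rooting choice, and rejected triggers, for audit;
* ``<prefix>.rooted.nwk`` — the tree as actually traversed, re-rooted at
  the farthest leaf from the seed.

All files are written atomically (temp file + rename) so an interrupted
batch never leaves truncated TSVs behind.  Outputs are deterministic:
identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .core import (
    CandidateEvent,
    DetectionResult,
    NodeEvaluation,
    Thresholds,
    scan,
)
from .genetree import (
    LeafMapper,
    read_gene_tree,
    read_leaf_map,
    root_at_farthest_leaf,
)
from .taxonomy import N_RANKS, RANKS, load_taxonomy

logger = logging.getLogger(__name__)

EVENTS_HEADER = (
    "seed",
    "event_leaves",
    "trigger_J",
    "trigger_L",
    "confirm_J",
    "confirm_L",
    "node_taxon",
    "donor_rank",
    "donor_taxon",
)


class RunError(RuntimeError):
    """A run-level failure (bad paths, unresolvable inputs)."""


@dataclass
class RunConfig:
    """Everything one detection run needs."""

    tree_path: Path
    taxonomy_path: Path
    seed_leaf: str
    out_prefix: Path = Path("abaccus_run")
    thresholds: Thresholds = field(default_factory=Thresholds)
    map_path: Path | None = None
    species_sep: str | None = None
    continue_scan: bool = False
    lenient: bool = False

    def mapper(self) -> LeafMapper:
        if self.map_path is not None:
            return LeafMapper(
                table=read_leaf_map(self.map_path), strict=not self.lenient
            )
        if self.species_sep is not None:
            return LeafMapper(
                separator=self.species_sep, strict=not self.lenient
            )
        return LeafMapper(strict=not self.lenient)


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent, prefix=f".{path.name}.", suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _rank_label(cls: tuple[int, str | None]) -> tuple[str, str]:
    rank, taxon = cls
    name = RANKS[rank] if rank < N_RANKS else "none"
    return name, taxon if taxon is not None else "-"


def events_tsv(events: Iterable[CandidateEvent]) -> str:
    lines = ["\t".join(EVENTS_HEADER)]
    for ev in events:
        donor_rank, donor_taxon = _rank_label(ev.donor_range)
        _, node_taxon = _rank_label(ev.trigger.node_class)
        lines.append(
            "\t".join(
                (
                    ev.seed,
                    ",".join(ev.event_leaves),
                    str(ev.trigger.jump),
                    str(ev.trigger.losses),
                    str(ev.confirmation.jump),
                    str(ev.confirmation.losses),
                    node_taxon,
                    donor_rank,
                    donor_taxon,
                )
            )
        )
    return "\n".join(lines) + "\n"


def _evaluation_record(ev: NodeEvaluation) -> dict:
    return {
        "node_leaves": sorted(ev.node_leaves),
        "sister_leaves": sorted(ev.sister_leaves),
        "node_class": list(ev.node_class),
        "parent_class": list(ev.parent_class),
        "sister_class": list(ev.sister_class),
        "J": ev.jump,
        "L": ev.losses,
        "support": ev.support,
    }


def audit_json(result: DetectionResult, meta: dict | None = None) -> str:
    doc = {
        "seed": result.seed,
        "thresholds": {
            "min_jump": result.thresholds.min_jump,
            "min_losses": result.thresholds.min_losses,
        },
        "trail": [_evaluation_record(ev) for ev in result.trail],
        "rejected": [
            {"evaluation": _evaluation_record(ev), "reason": reason}
            for ev, reason in result.rejected
        ],
        "events": [
            {
                "seed": ev.seed,
                "event_leaves": list(ev.event_leaves),
                "trigger": _evaluation_record(ev.trigger),
                "confirmation": _evaluation_record(ev.confirmation),
                "donor_range": list(ev.donor_range),
            }
            for ev in result.events
        ],
    }
    if meta:
        doc["meta"] = meta
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def run_detect(config: RunConfig) -> DetectionResult:
    """Load inputs, root, scan, and write the three report files."""
    for p in (config.tree_path, config.taxonomy_path, config.map_path):
        if p is not None and not Path(p).is_file():
            raise RunError(f"input file not found: {p}")

    table = load_taxonomy(Path(config.taxonomy_path), lenient=config.lenient)
    gtree = read_gene_tree(Path(config.tree_path), config.mapper())
    root_at_farthest_leaf(gtree, config.seed_leaf)
    logger.info(
        "seed=%s leaves=%d thresholds=J>=%d,L>=%d",
        config.seed_leaf,
        gtree.n_leaves(),
        config.thresholds.min_jump,
        config.thresholds.min_losses,
    )
    result = scan(
        gtree, table, config.thresholds, continue_scan=config.continue_scan
    )
    for ev in result.trail:
        logger.debug(
            "node=%s J=%d L=%d", sorted(ev.node_leaves), ev.jump, ev.losses
        )

    prefix = Path(config.out_prefix)
    meta = {
        "tree": str(config.tree_path),
        "taxonomy": str(config.taxonomy_path),
        "root_policy": "farthest-leaf-from-seed",
        "continue_scan": config.continue_scan,
    }
    _atomic_write(Path(str(prefix) + ".events.tsv"), events_tsv(result.events))
    _atomic_write(Path(str(prefix) + ".audit.json"), audit_json(result, meta))
    _atomic_write(Path(str(prefix) + ".rooted.nwk"), gtree.as_newick())
    return result


def run_batch(
    pairs: Iterable[tuple[Path, str]], config: RunConfig
) -> tuple[str, int, int]:
    """Run detection over (tree path, seed leaf) pairs.

    Shares the taxonomy and mapping policy from ``config``; per-tree
    failures are logged and skipped.  Returns the aggregated events TSV
    text (with a summary footer) plus (ok, failed) counts, and writes it
    to ``<out_prefix>.events.tsv``.
    """
    pairs = list(pairs)
    if not pairs:
        raise RunError("empty batch")

    table = load_taxonomy(Path(config.taxonomy_path), lenient=config.lenient)
    mapper = config.mapper()
    rows: list[str] = ["\t".join(EVENTS_HEADER)]
    ok = failed = 0
    for tree_path, seed_leaf in pairs:
        try:
            gtree = read_gene_tree(Path(tree_path), mapper)
            root_at_farthest_leaf(gtree, seed_leaf)
            result = scan(
                gtree,
                table,
                config.thresholds,
                continue_scan=config.continue_scan,
            )
        except Exception as exc:
            logger.warning("skipping %s (%s): %s", tree_path, seed_leaf, exc)
            failed += 1
            continue
        ok += 1
        text = events_tsv(result.events)
        rows.extend(text.splitlines()[1:])
    footer = f"# trees_processed={ok}\ttrees_skipped={failed}"
    body = "\n".join(rows + [footer]) + "\n"
    _atomic_write(Path(str(config.out_prefix) + ".events.tsv"), body)
    return body, ok, failed


def survey_summary(
    proteins_in_events: int, proteins_missed_by_survey: int
) -> dict[str, float]:
    """Summary arithmetic for a completed screen.

    ``proteins_in_events`` is the total number of proteins contained in
    the accepted events; ``proteins_missed_by_survey`` is how many of
    those the initial domain-based survey had not itself recovered.  The
    difference is the number of transferred proteins within the surveyed
    repertoire.
    """
    if proteins_missed_by_survey > proteins_in_events:
        raise ValueError("missed count exceeds total event proteins")
    transferred = proteins_in_events - proteins_missed_by_survey
    return {
        "proteins_in_events": proteins_in_events,
        "proteins_missed_by_survey": proteins_missed_by_survey,
        "transferred_in_repertoire": transferred,
    }
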