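# abaccus

Taxonomy-aware screening of single-gene phylogenies for horizontal gene
transfer (HGT) candidates.

## The problem

A gene acquired by horizontal transfer sits, in its gene tree, next to
sequences from taxonomically distant organisms. But an incongruent
placement alone is weak evidence: sparse sampling, gene loss, and
phylogenetic error produce incongruence too. The alternative, purely
vertical explanation is that the gene was present in the common ancestor
and was then lost independently in every intervening lineage — so the
strength of the HGT signal is measured by how many *parallel losses* the
vertical story would need, counting only losses for which the species
database actually documents a lineage that could have kept the gene.

`abaccus` implements this screen for users who already have gene trees
(from any inference pipeline) and want an automated, conservative first
pass that hands a short list of candidate events to manual curation. It
does not align sequences or build trees.

## The algorithm

Inputs: a Newick gene tree containing one designated **seed** sequence;
a **balanced nine-rank taxonomy** (species, genus, family, order, class,
phylum, kingdom, superkingdom, domain) covering every species in the
tree, used as a proxy species phylogeny; optionally a leaf-name →
species map.

1. Root the tree at the leaf farthest (in cumulative branch length) from
   the seed.
2. Walk from the seed leaf toward the root. At each node compute the
   taxonomic classification of the node and of its parent — the lowest
   rank at which all contained species share one taxon.
3. **J** (jump) = parent rank − node rank: how many rank steps the
   tree forces in one bifurcation.
4. **L** (minimal losses): for each rank crossed by the jump, count one
   loss if and only if the database holds a species at that rank, outside
   the previous rank's taxon and outside the compared clades. At most one
   loss per crossed rank, so L ≤ J; no database evidence, no loss.
5. A node with **J ≥ 2 and L ≥ 3** (defaults) is a trigger. It is
   confirmed by re-testing the *same* seed-side clade against the next
   sister branch rootward. Only doubly-positive nodes are emitted; the
   two sister classifications bracket the putative donor's taxonomic
   range.

The double check suppresses false positives from single misplaced
branches, and the evidence requirement makes the screen deliberately
blind to lineages with no sampled relatives at intermediate ranks — a
sole sequenced member of its phylum can never accumulate L ≥ 3, which is
a documented property, not a bug (see `docs/methods.md`).

## Worked example

The package ships a deterministic worked example: a seven-leaf fungal
gene tree in which a two-species *Fusarium* clade (the seed
*F. oxysporum* plus *F. graminearum*) is nested among Eurotiomycete
fungi, with a thirteen-species companion taxonomy.

```sh
abaccus fixture --out figure1
abaccus detect --tree figure1.nwk --taxonomy figure1.taxonomy.tsv \
        --map figure1.map.tsv --seed Foxy_seed --out run
cat run.events.tsv
```

prints

```
seed	event_leaves	trigger_J	trigger_L	confirm_J	confirm_L	node_taxon	donor_rank	donor_taxon
Foxy_seed	Fgram,Foxy_seed	4	4	4	4	Fusarium	family	Trichocomaceae
```

Reading the row: walking rootward from the seed, the first step
(seed vs. its *F. graminearum* sister) is innocuous — species to genus,
J = 1, and since no other *Fusarium* is in the database, L = 0. The next
step merges the *Fusarium* pair with *Aspergillus nidulans*: the shared
taxon is the phylum Ascomycota, four ranks up (J = 4), and the database
documents skipped lineages at family (Nectria, Gibberella), order
(Hypocrea, Cordyceps), class (a Magnaporthales representative) and
phylum (another Ascomycota class) — four independent losses (L = 4)
under a vertical story. The confirmation against the next sister branch
(three Trichocomaceae genera) again gives J = 4, L = 4, so the
*Fusarium* pair is accepted as a candidate event whose donor lies within
Trichocomaceae. The audit JSON (`run.audit.json`) records the full
per-node trail; `run.rooted.nwk` is the tree as traversed.

Other subcommands: `abaccus batch` screens a list of (tree, seed) pairs
against one taxonomy; `abaccus simulate` emits synthetic
taxonomy/tree/truth-manifest triples, either species-congruent
(`--mode vertical`) or with one implanted inter-domain transfer
(`--mode hgt`), for benchmarking.

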