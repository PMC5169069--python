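# Methods

## Model and assumptions

The screen treats a balanced nine-rank taxonomy as a stand-in for the
species phylogeny. Every species is classified at exactly the same nine
ranks (species, genus, family, order, class, phylum, kingdom,
superkingdom, domain), so the "taxonomic distance" between any two
lineages is a well-defined integer number of rank steps, regardless of
how unevenly the underlying groups have been studied. The cost of this
balance is that rank boundaries are nominal, not time-calibrated: a
genus-to-phylum jump in mammals and one in microsporidia are counted
identically. The taxonomy must describe a tree — each taxon has exactly
one parent at the next rank — and this is validated at load time.

The null hypothesis at every node is vertical descent: the gene was
present in the common ancestor of the node and its sister and survived
only in the observed leaves. The test statistic is the minimal number of
independent loss events (L) that story needs, counted conservatively:

* at most **one loss per crossed rank** — losing the gene in the stem
  lineage of a taxon accounts for all its absent members at once;
* a loss at rank *r* is only counted when the database contains at least
  one species inside the seed's taxon at *r*, outside the seed's taxon at
  *r − 1*, and outside the two clades being compared. Absence of
  database evidence never counts: a rank with no other known member
  contributes nothing.

Species that sit *elsewhere in the gene tree* but outside the compared
clades still count as loss evidence — the comparison is local to the
node and its sister, and a lineage represented in a different part of
the tree is precisely one whose gene copy the vertical story must lose
on the path under consideration.

Jumps are measured between classifications, where the classification of
a node is the lowest rank at which all its species share one taxon.
Nesting of the taxonomy guarantees parent rank ≥ node rank, hence J ≥ 0,
and the one-loss-per-rank cap gives L ≤ J. A species set spanning more
than one domain has no shared taxon; it is reported with a sentinel rank
of 9 ("no common taxon") rather than an error, so eukaryote–prokaryote
comparisons behave like one extra rank step above domain. Loss counting
caps its scan at the domain rank, which has no super-taxon to supply
evidence.

## Traversal, thresholds, confirmation

The tree is rooted on the branch of the leaf with maximal path length to
the seed (cumulative branch lengths; absent lengths count as 1.0, which
reduces to topological distance on cladograms; ties break on the
lexicographically smallest leaf name; the root splits the chosen branch
at its midpoint, preserving all leaf-to-leaf path lengths). The walk
then visits every node from the seed leaf to the root.

A node passing **J ≥ min_jump and L ≥ min_losses** (defaults 2 and 3) is
a trigger. Confirmation re-tests the *same* seed-side clade — not the
merged parent clade — against the sister of the trigger's parent. This
matters: after the merge the clade already classifies at the shared
rank, and J would collapse to 0; keeping the pre-merge clade is the only
reading under which the worked example's confirmation repeats J = 4.
When the trigger's parent is the root there is no further sister and the
event is rejected as unconfirmable (recorded in the audit trail as
`root_reached`).

By default the traversal stops at the first confirmed event: nested
scenarios (a transfer into a clade that itself received a transfer) are
better resolved by a curator than by the screen, and each emitted event
carries the audit trail needed for that. `--continue-scan` enumerates
all confirmed nodes on the path instead.

Other semantics chosen where the design was genuinely open:

* **Polytomies** are kept as read. The sister of a node is the union of
  all other children of its parent, and the "next sister" is the union
  of the parent's siblings. Unions can only lower J (more species,
  lower shared rank), so this is the conservative resolution and needs
  no arbitrary tie-breaking.
* **In-paralogs**: all comparisons operate on species *sets*, so
  multiple sequences from one species never inflate J or L.
* **Seed not in the taxonomy** aborts the run: every loss computation is
  anchored on the seed's lineage.
* Rows with no sub-domain resolution (e.g. cluster-level prokaryotic
  references) may use `*` at ranks below domain. Internally each filler
  cell is replaced by the row's own label, so such rows never share a
  sub-domain taxon with anything and any comparison involving one
  resolves at domain or above. This encoding is this package's
  convention for cluster-level references.
* Internal node support labels are parsed and carried into reports for
  the curator but never used as evidence.
* Taxonomy validation is strict by default; a lenient mode drops
  malformed rows (empty cells, duplicate labels) with a logged warning,
  since truncated rows are the common failure mode of hand-curated
  tables. Structural conflicts (a taxon with two parents) always abort.

## Thresholds

`min_jump = 2` excludes the two incongruence patterns that routine tree
error produces constantly (misplacement within a genus or family);
`min_losses = 3` demands that the vertical alternative require at least
three independent, database-documented losses. Both are integers with
obvious monotone semantics: raising either can only remove events
(verified as a property test). They are exposed as `--jump/--losses`.

## The synthetic-data generator

`simulate_taxonomy` builds fully balanced taxonomies with a configurable
number of children per rank and deterministic dotted names
(`d1.sk1.k1.p2...`). `simulate_vertical_tree` emits a gene tree whose
topology is the taxonomy restricted to a species sample, with branch
lengths drawn from a configurable law; `implant_transfer` prunes a clade
and regrafts it at a random edge inside a donor taxon's subtree. All
randomness flows through one seeded NumPy generator, so instances are
reproducible byte for byte.

The benchmark regime (`simulate_hgt_instance`) uses a two-domain,
128-species taxonomy (breadth 2 at phylum through species), a recipient
genus of two species, and an inter-domain graft. Three groups of the
recipient's relatives — its sibling genus, a sibling family, and a
sibling order — are withheld from the tree sample so they exist only in
the database, providing loss evidence at three distinct intermediate
ranks; branch lengths are uniform on (0.05, 0.15) so the
farthest-leaf-from-seed root choice is dominated by topological depth
and the construction guarantees J ≥ 2 and L ≥ 3 at the grafted clade.
Under these conditions recall is 1.0 by construction and specificity on
fully sampled congruent trees is 1.0 because complete sampling leaves no
loss evidence at any node — both are asserted over 100 replicates in the
test suite, with a brute-force per-species loss oracle cross-checking
the production counter on 200 randomized instances. Deleting the
withheld relatives from the taxonomy reproduces the lone-representative
blind spot: L cannot reach 3 and recall drops to 0.

What the generator does **not** emulate: sequence evolution and
phylogenetic error (trees are topologically exact), unbalanced and
misannotated taxonomies, rate heterogeneity, genuine loss processes
(absences are sampling choices, not evolutionary events), contamination,
and fragmented gene models. Passing the simulation suite therefore shows
the *algorithm* is implemented correctly under its own assumptions, not
that real screens are error-free — on real data the manual-inspection
step the tool's reports are designed to feed remains essential.

## Numerical and I/O choices

Classification and loss counting are exact set operations on interned
strings; no floating point enters any decision. Branch lengths matter
only for choosing the root. Reports are written atomically (temp file +
rename) and are byte-identical across reruns on identical inputs; the
events TSV carries one row per accepted event, the audit JSON one record
per traversed node.

## Known limitations

* Sensitivity is bounded by database density: lineages without sampled
  relatives at intermediate ranks are invisible (by design, reported,
  and reproduced as the blind-spot benchmark).
* The screen evaluates one seed per tree and does not deduplicate
  overlapping events across trees of the same family.
* No probabilistic reconciliation: J and L are parsimony scores, not
  likelihoods, and branch support is ignored when scoring.
* A transfer *into* the root-side outgroup, or one that leaves the seed
  clade monophyletic with its true relatives, produces no incongruence
  on the seed-to-root path and is out of reach.
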