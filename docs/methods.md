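# Methods

## The inference model

Annotation proceeds in two steps. First, a curator (or the suggester)
builds an explicit evolutionary model of a family: `GAIN(node, term,
supporting leaves)` and `LOSS(node, term, cause)` assertions on a rooted
reconciled tree. Second, the engine applies the model mechanically:

- one **IBD** annotation at each gain node, linked to the experimentally
  characterized descendant genes that support it;
- one **IBA** annotation at every strict descendant of the gain that is
  not inside a lost subtree — including leaves that already have
  experimental records, since the inferred and primary annotations are
  distinct records with distinct provenance;
- one negated annotation at each loss node: **IKR** when the cause is
  `KEY_RESIDUES` (or `UNSPECIFIED`), **IRD** for `RAPID_DIVERGENCE`.

The model is Dollo-style: one origin per lineage, arbitrarily many
losses below it. Independent gains of the same term on disjoint lineages
are legal; *nested* same-term gains are rejected as incoherent (the
function cannot first evolve below a point where it already existed).

### Ontology interaction

Closure follows the GO annotation-propagation convention: `is_a` and
`part_of` only. Regulates-type relations describe indirect influence and
closing over them would import exactly the indirect roles phylogenetic
annotation is meant to filter out.

Two asymmetric rules connect the tree model to the DAG:

- *Support* is true-path upward: a record to a descendant term supports a
  gain of a more general term.
- *Loss blocking* is term-downward: a loss of t′ blocks propagation of t
  iff t′ = t or t is an ontology descendant of t′. Losing a general
  capability entails losing its specializations. Loss of a
  sibling-related term never blocks; whether it should is unknowable from
  first principles, so only the downward rule is implemented.

Negative evidence also propagates downward: a NOT record to an ancestor
term denies the queried term. A leaf with both positive and negative
evidence for a term is kept in the presence set and flagged as
conflicting — positive experimental evidence is taken as the stronger
signal, but the conflict is surfaced rather than silently resolved.

### The suggester and its minimality guarantee

For presence set P and absence set N, the suggested gain is MRCA(P); the
suggested losses are the maximal subtrees strictly below the gain whose
leaves contain none of P and at least one of N. Maximal P-free subtrees
are pairwise disjoint, each needs at most one loss to cover its N leaves,
and every N leaf must lie in some blocked subtree that excludes P — so
this set has minimum cardinality among all Dollo explanations. The
acceptance checks verify this against exhaustive subset search on trees
up to 12 leaves.

Losses are only suggested where NOT-qualified records demand them.
Unobserved genes are left untouched: absence of annotation is not
absence of function. Curators add further losses manually (e.g. from
key-residue evidence) through the assertion file.

A single-support suggestion (|P| = 1) is legal but flagged
`single-support`; propagating a function observed in exactly one gene is
the classic weak-evidence trap and is left to curator judgment.
Ancestors of the suggested gain are reported as legal but less
parsimonious alternates.

### Events on the tree

Duplication nodes do not block propagation — families routinely conserve
function across duplications, and restricting a paralog is expressed by
an explicit loss. Horizontal-transfer nodes propagate like speciation
nodes, but every IBA whose path from the gain crosses one is tagged
`via_hgt` so reports can isolate them. Branch lengths are parsed and
preserved but unused: the model is event-based, not clock-based.
Taxon-range reasoning (is this process plausible in this clade?) is not
formalized; it is reduced to the explicit assertions a curator makes.

## Evidence policy

Only experimental codes (default EXP, IDA, IPI, IMP, IGI, IEP) can
support a gain. ISS/ISO/IEA/TAS/NAS/IC are themselves inferences and
would make propagation circular. High-throughput codes (HTP, HDA, HMP,
HGI, HEP) are excluded by default — HTP localization data in particular
carries enough false positives (transient ER/Golgi residence during
biosynthesis, purification artifacts) that it is routed to QA instead;
`htp_usable_for_inference` opts in deliberately. NOT-qualified
experimental records are never dropped: they are the negative-evidence
stream that places losses. The code table ships as a versioned TSV in
the package data.

The QA screens are deliberately config-driven: which process terms are
"phenotype-prone" and which component terms are "transient localizations"
are curator policy, not algorithms, so the shipped lists are empty.

## File formats and numerical conventions

- **Newick/NHX** with `ID=`, `Ev=` (S/D/H) and `S=` tags. Leaf labels are
  database-qualified (`DB:ACC`); the embedded colon is why the package
  carries its own tokenizer (a trailing `:<number>` is a branch length,
  a non-numeric tail belongs to the label). The writer is bit-stable:
  sorted NHX keys, 6-decimal branch lengths, every node id written, so
  parse∘write is the identity. Unrooted input is rejected (gain/loss
  direction needs a root); polytomies are accepted.
- **OBO 1.2/1.4**: `[Term]` stanzas, `is_a` and `relationship: part_of`
  edges, trailing `!` comments tolerated, cycles rejected with the cycle
  listed. Obsolete terms stay in the graph but never join closure;
  `resolve_term` follows `replaced_by` transitively and refuses
  `consider` (ambiguous, demands curator choice). Cross-namespace
  `part_of` edges are legal but flagged by `lint()`; aspect/namespace
  consistency is enforced at the GAF layer instead.
- **GAF**: reader accepts 2.1 and 2.2 (qualifier `NOT|relation` parsed,
  relation preserved verbatim); writer emits 2.1 sorted by (object,
  term, evidence) for byte-stable reruns. Inferred rows follow the
  PAINT conventions: ancestral objects as `PANTHER / <family>:<node>`,
  IBA with/from pointing to `PANTHER:<family>:<gain>` plus the support
  ids, reference `GO_REF:0000033`. The GAF date column defaults to a
  fixed constant so identical inputs give byte-identical outputs; pass
  `--date` to stamp a release.
- Output ordering everywhere is (term, preorder position), making
  propagation idempotent and CLI runs reproducible byte-for-byte.

## The synthetic generator

`simulate_family` grows a random binary tree by sequential leaf
attachment, labels internal nodes duplication with probability
`p_duplication` (else speciation), generates a random is_a/part_of DAG
guaranteed to give the target term at least one ancestor and one
descendant, places a single true gain uniformly on the internal nodes,
and drops loss subtrees below it with per-edge probability `p_loss`.
`simulate_annotations` then emulates a patchy literature: each functional
leaf is observed with probability `p_observe` (IDA, to the true term or a
random descendant term, exercising the true-path rule); non-functional
leaves pick up spurious IMP records with probability `p_false_positive`
(default 0.01, the false-discovery rate commonly tolerated in published
high-throughput data); non-functional leaves below the gain carry
NOT-IMP records with probability `p_negative`.

Defaults (32 leaves, p_duplication 0.2, p_loss 0.1, p_observe 0.7,
p_negative 0.1, 20 terms) describe a moderately studied family. Each
generation stage draws from its own named RNG substream keyed on
`(seed, stage)`, so adding a stage never perturbs earlier draws and all
outputs are bit-identical under a fixed seed.

What the generator does **not** emulate: species-tree reconciliation
(trees are grown directly, so duplication placement is unconstrained),
sequence evolution, realistic branch lengths, correlated annotation
effort across clades (model organisms are dramatically over-observed in
real corpora), and multi-term annotation profiles per gene. Passing
tests therefore demonstrate the *mechanics* — propagation, parsimony,
accounting, format fidelity — under a clean generative model, not
recovery performance on real PANTHER/GO snapshots, whose scale and bias
structure are different. No checked-in fixtures exist; every test input
is regenerated from seeds at run time.

## Verification set-up and problem sizes

The acceptance checks run the engine at these scales: 500 random
families (≤200 nodes, ≤5 gains, ≤5 losses) against an independent
reachability oracle for IBA targets; 300 trees of ≤12 leaves against
exhaustive loss-subset search; 50 replicates of the perfect-information
recovery experiment (p_loss 0, p_observe 1, no noise), where
MRCA-identifiability makes a 100% gain match rate provable; a 4-point
observation grid (1.0/0.8/0.6/0.4, 200 replicates each) for the
degradation trend; 100 random fixtures per format for round-trips; and
100 families for the counting oracles. Independent oracles live with the
tests; the implementation never calls them.

## Known limitations

- Losses attach to the nearest matching gain for provenance; with
  multiple same-term gains on disjoint lineages a loss below one lineage
  never affects the other, but its reported `gain_node` is chosen by
  (term, preorder) order among the gains that dominate it.
- `consider` tags on obsolete terms are ignored by design; maintenance
  reports surface the term for re-curation instead.
- The suggester proposes a single gain per term. Multi-origin models are
  expressed by editing the assertion file; the validator accepts them as
  long as same-term gains are not nested.
- Recovery rates from `recovery_experiment` count a no-evidence replicate
  as a miss, so rates are comparable across observation probabilities
  but conflate "wrong node" with "nothing to work with" at low
  `p_observe`.
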