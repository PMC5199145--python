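# phyloannot

Phylogenetic propagation of Gene Ontology (GO) annotations over gene
family trees: an engine for curating explicit models of function **gain
and loss** on a reconciled family tree and mechanically propagating
experimentally supported annotations from ancestral nodes to descendants.

## Who this is for

Most gene products have never been experimentally characterized, and even
well-studied human genes often lack direct evidence for their central
roles. Phylogenetic annotation closes that gap: experimental GO
annotations from ~100 organisms are integrated in the context of a gene
family tree, a curator asserts where in evolution each function first
arose (and where it was secondarily lost), and the engine then annotates
every descendant gene consistently. This package implements that engine —
the inference, the file formats, the QA screens, the bookkeeping — for
curators and tool builders working with PANTHER-style family trees, OBO
ontologies and GAF annotation files. A synthetic-family generator with
known ground truth makes the whole pipeline testable offline.

## The model

A family is a rooted tree whose internal nodes are speciation,
duplication or horizontal-transfer events and whose leaves are modern
genes. For a GO term *t*, the experimental evidence splits the leaves
into a presence set *P* (a usable experimental record to *t* or, by the
true-path rule, to any descendant term) and an absence set *N*
(NOT-qualified experimental records to *t* or an ancestor term).

The evolutionary model is Dollo-style — a function arises once per
lineage and may be lost many times:

- **Gain** of *t* at node *g*: proposed at *g* = MRCA(*P*). The gain node
  receives an annotation with evidence code **IBD** (inferred from
  biological descendant), linked to the supporting leaves.
- **Loss** of *t* at node *v* below *g*: placed only where negative
  evidence demands it — at each maximal subtree under *g* whose leaves
  contain none of *P* and at least one of *N*. This loss set is provably
  of minimum cardinality. Loss nodes receive negated annotations with
  evidence **IKR** (key residues) or **IRD** (rapid divergence).
  Absence of annotation is never treated as absence of function.
- **Propagation**: every strict descendant of *g* outside a lost subtree
  receives an **IBA** annotation (inferred from biological ancestor)
  carrying the gain node and the supporting leaves. A loss of *t′* blocks
  a term *t* iff *t′* = *t* or *t* is an ontology descendant of *t′* —
  losing a general capability entails losing its specializations.

Only experimental evidence codes (EXP, IDA, IPI, IMP, IGI, IEP) support
gains; high-throughput codes (HDA, HMP, ...) are excluded by default and
surfaced to QA, which also screens for phenotype-based over-annotation,
transient-localization component terms and aspect/namespace mismatches.

## Worked example

A three-leaf caspase-like family `((HUM1,MUS1)AN1,DRO1)AN0` where both
the human and mouse genes have direct-assay evidence for
"execution phase of apoptosis" (`GO:0000003` in the toy ontology):

```sh
phyloannot suggest --tree family.nhx --obo go.obo --gaf exp.gaf \
    --family-id PTHR10454 --term GO:0000003 --out-assertions model.tsv
```

writes the suggested model (gain at the human/mouse ancestor, no losses):

```
# family: PTHR10454
GAIN	AN1	GO:0000003	A:HUM1,B:MUS1
```

Applying it:

```sh
phyloannot infer --tree family.nhx --obo go.obo --gaf exp.gaf \
    --family-id PTHR10454 --assertions model.tsv \
    --out-gaf inferred.gaf --out-stats stats.tsv --out-conflicts conflicts.tsv
```

produces one ancestral IBD row and two descendant IBA rows (DRO1, outside
the gain, is untouched):

```
PANTHER	PTHR10454:AN1	AN1		GO:0000003	GO_REF:0000033	IBD	A:HUM1|B:MUS1	...
A	HUM1	HUM1		GO:0000003	GO_REF:0000033	IBA	PANTHER:PTHR10454:AN1|A:HUM1|B:MUS1	...
B	MUS1	MUS1		GO:0000003	GO_REF:0000033	IBA	PANTHER:PTHR10454:AN1|A:HUM1|B:MUS1	...
```

and the family statistics table:

```
family_id	protein_count	exp_proteins	exp_annotations	exp_terms	annotated_proteins	ibd_count	iba_count	inferred_terms
PTHR10454	3	2	2	1	2	1	2	1
```

Adding `LOSS <MUS1-node> GO:0000003 RAPID_DIVERGENCE` to the assertion
file turns the mouse IBA into a negated IRD row, and `phyloannot
check-update` will flag the model if a later ontology release obsoletes
the term or the supporting records disappear. `phyloannot simulate
--seed 5 --out-dir fam/` writes a complete synthetic family bundle
(tree, OBO, GAF, assertions, truth) with known ground truth.

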