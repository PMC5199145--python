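"""Synthetic families with known gain/loss ground truth.

Everything the engine consumes — a reconciled family tree, a small GO-like
DAG, a GAF of noisy experimental records and the true gain/loss model — is
generated here, so the whole package is testable without downloading
PANTHER or the GO database.

The generative story mirrors how real annotation corpora look to a curator:
a function arises once at an ancestral node, is lost independently on some
branches below it, and only a fraction of the truly functional modern genes
have been assayed (``p_observe``). Noise enters as spurious
mutant-phenotype records on non-functional genes (``p_false_positive``,
default 1%, the false-discovery rate journals commonly tolerate) and as
NOT-qualified records on non-functional genes below the gain
(``p_negative`` — the negative results curators capture).

RNG discipline: each generation stage draws from its own named substream
(``default_rng((seed, STAGE))``), so adding a stage never perturbs the
draws of earlier ones and every output is bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GenerationError
from .evo_model import EvolutionaryModel, GainEvent, LossEvent, suggest_model, presence_sets
from .gaf import AnnotationRecord, EvidenceConfig
from .gene_tree import GeneTree, TreeNode
from .ontology import OntologyGraph, Term
from .errors import NoEvidenceError

# named RNG substreams, one per generation stage
_STAGE_TREE = 0
_STAGE_ONTOLOGY = 1
_STAGE_GAIN = 2
_STAGE_LOSS = 3
_STAGE_ANNOT = 4


@dataclass
class SimParams:
    """Study conditions for one synthetic family.

    Defaults describe a moderately studied family: 32 genes, one fifth of
    internal nodes are duplications, a 10% per-branch chance of secondary
    loss, 70% of functional genes experimentally characterized, 1% spurious
    positives and a 10% chance that a non-functional gene below the gain has
    a recorded negative result.
    """

    n_leaves: int = 32
    p_duplication: float = 0.2
    p_loss: float = 0.1
    p_observe: float = 0.7
    p_false_positive: float = 0.01
    p_negative: float = 0.1
    n_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise GenerationError("n_leaves must be >= 2")
        if self.n_terms < 3:
            raise GenerationError("n_terms must be >= 3 (target term needs an ancestor and a descendant)")
        for name in ("p_duplication", "p_loss", "p_observe", "p_false_positive", "p_negative"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name} must be a probability, got {v}")


@dataclass
class SimTruth:
    gain_node: str
    loss_nodes: set[str]
    functional_leaves: set[str]  # gene ids
    term: str


@dataclass
class RecoverySummary:
    """Outcome of a simulate -> suggest -> compare experiment."""

    n_reps: int
    match_rate: float           # exact gain-node matches / n_reps (no-evidence counts as a miss)
    mean_loss_jaccard: float | None  # over informative replicates; None if there were none
    no_evidence: int = 0


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def simulate_family(params: SimParams, family_id: str | None = None,
                    ) -> tuple[GeneTree, OntologyGraph, SimTruth]:
    """Generate a random family tree, ontology and gain/loss ground truth."""
    fam = family_id or f"SIMF{params.seed % 100000:05d}"
    tree = _simulate_tree(params, fam)
    ontology, term = _simulate_ontology(params)
    truth = _simulate_truth(params, tree, term)
    return tree, ontology, truth


def _simulate_tree(params: SimParams, family_id: str) -> GeneTree:
    rng = _rng(params.seed, _STAGE_TREE)
    # sequential leaf attachment: replace a uniformly chosen leaf by a cherry
    leaves = [TreeNode()]
    root = leaves[0]
    for _ in range(params.n_leaves - 1):
        target = leaves[int(rng.integers(len(leaves)))]
        left, right = TreeNode(parent=target), TreeNode(parent=target)
        target.children = [left, right]
        leaves.remove(target)
        leaves.extend([left, right])
    leaf_no = 0
    internal_no = 0
    for node in root.preorder():
        if node.is_leaf:
            leaf_no += 1
            node.gene_id = f"SYN:G{leaf_no:04d}"
            node.species = f"SP{leaf_no:03d}"
            node.event = "leaf"
        else:
            node.node_id = f"AN{internal_no}"
            internal_no += 1
            node.event = ("duplication"
                          if rng.random() < params.p_duplication else "speciation")
    return GeneTree(root, family_id=family_id)


def _simulate_ontology(params: SimParams) -> tuple[OntologyGraph, str]:
    rng = _rng(params.seed, _STAGE_ONTOLOGY)
    n = params.n_terms
    ids = [f"GO:{i + 1:07d}" for i in range(n)]
    terms = {tid: Term(id=tid, name=f"synthetic process {i + 1}",
                       namespace="biological_process")
             for i, tid in enumerate(ids)}
    edges: set[tuple[str, str, str]] = set()
    # guaranteed chain ids[2] -> ids[1] -> ids[0]; target ids[1] thus has
    # >=1 ancestor and >=1 descendant
    edges.add((ids[1], ids[0], "is_a"))
    edges.add((ids[2], ids[1], "is_a"))
    for i in range(3, n):
        parent = int(rng.integers(i))
        rel = "is_a" if rng.random() < 0.85 else "part_of"
        edges.add((ids[i], ids[parent], rel))
        if rng.random() < 0.2:  # occasional second parent keeps it a DAG
            parent2 = int(rng.integers(i))
            if parent2 != parent:
                edges.add((ids[i], ids[parent2], "is_a"))
    return OntologyGraph(terms=terms, edges=edges), ids[1]


def _simulate_truth(params: SimParams, tree: GeneTree, term: str) -> SimTruth:
    rng_gain = _rng(params.seed, _STAGE_GAIN)
    internals = [n for n in tree.root.preorder()
                 if not n.is_leaf and len(tree.descendants(n.node_id, leaves_only=True)) >= 2]
    if not internals:
        raise GenerationError("no internal node with >=2 leaf descendants")
    gain = internals[int(rng_gain.integers(len(internals)))]

    rng_loss = _rng(params.seed, _STAGE_LOSS)
    loss_nodes: set[str] = set()

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if rng_loss.random() < params.p_loss:
                loss_nodes.add(child.node_id)  # whole subtree lost; do not descend
            else:
                walk(child)

    walk(gain)
    lost_leaves: set[str] = set()
    for v in loss_nodes:
        lost_leaves |= {tree.index[l].gene_id
                        for l in tree.descendants(v, leaves_only=True)}
        if tree.index[v].is_leaf:
            lost_leaves.add(tree.index[v].gene_id)
    functional = tree.leaf_genes_under(gain.node_id) - lost_leaves
    return SimTruth(gain_node=gain.node_id, loss_nodes=loss_nodes,
                    functional_leaves=functional, term=term)


def truth_model(truth: SimTruth, family_id: str) -> EvolutionaryModel:
    """The ground truth expressed as a curator model."""
    return EvolutionaryModel(
        family_id=family_id,
        gains=[GainEvent(node_id=truth.gain_node, go_id=truth.term,
                         supporting_leaves=sorted(truth.functional_leaves))],
        losses=[LossEvent(node_id=v, go_id=truth.term, cause="UNSPECIFIED")
                for v in sorted(truth.loss_nodes)],
    )


def simulate_annotations(tree: GeneTree, ontology: OntologyGraph,
                         truth: SimTruth, params: SimParams,
                         ) -> list[AnnotationRecord]:
    """Generate noisy experimental GAF records for a simulated family.

    Functional leaves are observed (IDA, to the true term or a uniformly
    chosen ontology descendant) with ``p_observe``; non-functional leaves
    pick up a spurious IMP with ``p_false_positive``; non-functional leaves
    below the gain get a NOT-IMP with ``p_negative``.
    """
    rng = _rng(params.seed, _STAGE_ANNOT)
    term_choices = [truth.term] + sorted(ontology.descendants(truth.term))
    below_gain = tree.leaf_genes_under(truth.gain_node)
    records: list[AnnotationRecord] = []

    def make(gene_id: str, go_id: str, code: str, negated: bool) -> AnnotationRecord:
        db, _, acc = gene_id.partition(":")
        node = tree.leaf_index[gene_id]
        return AnnotationRecord(
            db=db, object_id=acc, symbol=acc, go_id=go_id,
            evidence_code=code, negated=negated,
            references=["PMID:1000001"], aspect="P",
            taxon=f"taxon:{node.species}", date="20150415",
            assigned_by="SynthDB")

    for node in tree.root.preorder():  # preorder => deterministic draw order
        if not node.is_leaf:
            continue
        gene = node.gene_id
        if gene in truth.functional_leaves:
            if rng.random() < params.p_observe:
                go_id = term_choices[int(rng.integers(len(term_choices)))]
                records.append(make(gene, go_id, "IDA", negated=False))
        else:
            if rng.random() < params.p_false_positive:
                records.append(make(gene, truth.term, "IMP", negated=False))
            if gene in below_gain and rng.random() < params.p_negative:
                records.append(make(gene, truth.term, "IMP", negated=True))
    return records


def recovery_experiment(params: SimParams, n_reps: int,
                        config: EvidenceConfig | None = None) -> RecoverySummary:
    """Simulate -> suggest -> compare, ``n_reps`` times.

    The gain match rate counts exact gain-node recovery over *all*
    replicates (a replicate with no usable evidence counts as a miss), so
    rates are comparable across observation probabilities. The loss-set
    Jaccard is averaged over the informative replicates; two empty loss
    sets have similarity 1.
    """
    if n_reps < 1:
        raise GenerationError("n_reps must be >= 1")
    matches = 0
    no_evidence = 0
    jaccards: list[float] = []
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence(entropy=(params.seed, rep))
                       .generate_state(1)[0] % (2 ** 31))
        p = replace(params, seed=rep_seed)
        tree, ontology, truth = simulate_family(p)
        records = simulate_annotations(tree, ontology, truth, p)
        evidence = presence_sets(tree, records, ontology, truth.term, config)
        if not evidence.P:
            no_evidence += 1
            continue
        suggestion = suggest_model(tree, evidence, go_id=truth.term)
        gain = suggestion.model.gains[0].node_id
        if gain == truth.gain_node:
            matches += 1
        suggested_losses = {l.node_id for l in suggestion.model.losses}
        union = suggested_losses | truth.loss_nodes
        jaccards.append(1.0 if not union
                        else len(suggested_losses & truth.loss_nodes) / len(union))
    return RecoverySummary(
        n_reps=n_reps,
        match_rate=matches / n_reps,
        mean_loss_jaccard=(sum(jaccards) / len(jaccards)) if jaccards else None,
        no_evidence=no_evidence)
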