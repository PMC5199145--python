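"""The gain/loss inference engine.

Phylogenetic annotation is a two-step process. First, a curator builds an
explicit evolutionary model of a gene family: assertions that a GO function
was *gained* at a particular ancestral node (supported by experimentally
characterized descendant genes) and possibly *lost* again on particular
descendant branches (supported by key-residue changes or rapid sequence
divergence). Second, the model is applied mechanically: the gain node
receives an ancestral annotation with evidence code IBD (inferred from
biological descendant), every descendant outside a lost subtree receives
IBA (inferred from biological ancestor), and loss nodes receive negated
annotations with IKR (key residues) or IRD (rapid divergence).

The model is Dollo-style: a function arises once per lineage and may be
lost many times. :func:`suggest_model` proposes the most parsimonious such
model from the distribution of experimental evidence — the gain at the MRCA
of the positive leaves, and losses only where NOT-qualified (negative)
experimental records demand them. Absence of annotation is never treated as
absence of function.

Ontology interaction ("term-downward" blocking): losing a general
capability entails losing its specializations, so a loss of term t′ blocks
propagation of t iff t′ = t or t is an ontology descendant of t′.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import (
    AssertionFileError,
    ModelInvalidError,
    NoEvidenceError,
    UnknownNodeError,
    UnknownTermError,
)
from .gaf import (
    AnnotationRecord,
    EvidenceConfig,
    filter_experimental,
    negated_experimental,
)
from .gene_tree import GeneTree
from .ontology import NAMESPACE_TO_ASPECT, OntologyGraph, resolve_term

logger = logging.getLogger(__name__)

LOSS_CAUSES = ("KEY_RESIDUES", "RAPID_DIVERGENCE", "UNSPECIFIED")

#: Loss cause -> negated evidence code.
CAUSE_TO_EVIDENCE = {
    "KEY_RESIDUES": "IKR",
    "RAPID_DIVERGENCE": "IRD",
    "UNSPECIFIED": "IKR",
}


@dataclass
class GainEvent:
    """Assertion that ``go_id`` first evolved at tree node ``node_id``.

    ``supporting_leaves`` are the experimentally characterized genes the
    inference rests on; ``references`` carry their citations forward.
    """

    node_id: str
    go_id: str
    supporting_leaves: list[str]
    references: list[str] = field(default_factory=list)


@dataclass
class LossEvent:
    """Assertion that ``go_id`` was lost on the branch leading to ``node_id``."""

    node_id: str
    go_id: str
    cause: str = "UNSPECIFIED"


@dataclass
class EvolutionaryModel:
    family_id: str
    gains: list[GainEvent] = field(default_factory=list)
    losses: list[LossEvent] = field(default_factory=list)


@dataclass
class InferredAnnotation:
    """One IBD/IBA (or negated IKR/IRD) annotation produced by propagation.

    ``target_gene``/``target_species`` are filled when the target is a leaf,
    so downstream accounting does not need the tree. ``via_hgt`` marks IBA
    annotations whose path from the gain crosses a horizontal-transfer node.
    """

    target: str
    go_id: str
    evidence: str  # IBD | IBA | IKR | IRD
    gain_node: str
    supporting_leaves: list[str]
    negated: bool = False
    target_gene: str | None = None
    target_species: str | None = None
    via_hgt: bool = False


@dataclass
class Violation:
    rule: str  # unsupported_gain | gain_not_dominating | loss_without_gain | nested_gain | unknown_reference
    message: str
    node_id: str | None = None
    go_id: str | None = None


@dataclass
class PresenceSets:
    """Experimental evidence for one term, per leaf gene.

    ``P``: genes with usable positive evidence to the term or a descendant
    (true-path rule). ``N``: genes with negated experimental evidence to the
    term or an ancestor (negation propagates downward). A gene with both is
    kept in ``P`` and listed in ``conflicting``.
    """

    P: set[str] = field(default_factory=set)
    N: set[str] = field(default_factory=set)
    conflicting: set[str] = field(default_factory=set)

    def __iter__(self):
        return iter((self.P, self.N))


@dataclass
class Suggestion:
    model: EvolutionaryModel
    alternates: list[str]  # less parsimonious legal gain nodes, nearest first
    flags: list[str] = field(default_factory=list)


@dataclass
class Conflict:
    rule: str  # negative_evidence_under_propagation | experimental_evidence_under_loss
    gene_id: str
    go_id: str
    record: AnnotationRecord
    inferred: InferredAnnotation

    @property
    def message(self) -> str:
        if self.rule == "negative_evidence_under_propagation":
            return (f"IBA of {self.go_id} on {self.gene_id} contradicted by "
                    f"NOT-{self.record.evidence_code} to {self.record.go_id}")
        return (f"loss of {self.go_id} above {self.gene_id} contradicted by "
                f"{self.record.evidence_code} to {self.record.go_id}")


# -- assertion file ------------------------------------------------------

def parse_assertions(text: str, tree: GeneTree, ontology: OntologyGraph,
                     family_id: str | None = None) -> EvolutionaryModel:
    """Parse the curator assertion TSV into a model.

    Lines: ``GAIN\\t<node>\\t<GO id>\\t<leaf,leaf,...>`` or
    ``LOSS\\t<node>\\t<GO id>\\t<cause>``; ``#`` starts a comment. Terms are
    resolved through ``replaced_by`` (the rewrite is logged); stale node or
    term references raise with the offending line number.
    """
    model = EvolutionaryModel(family_id=family_id or tree.family_id)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise AssertionFileError(
                f"expected 4 tab-separated fields, found {len(cols)}", line=lineno)
        kind, node_id, go_id, tail = (c.strip() for c in cols)
        try:
            node = tree.node(node_id)
        except UnknownNodeError:
            raise AssertionFileError(f"unknown tree node {node_id!r}", line=lineno) from None
        try:
            resolved = resolve_term(ontology, go_id)
        except UnknownTermError:
            raise AssertionFileError(f"unknown GO term {go_id!r}", line=lineno) from None
        if resolved != go_id:
            logger.info("assertion line %d: term %s rewritten to %s via replaced_by",
                        lineno, go_id, resolved)
        if kind == "GAIN":
            leaves = [l.strip() for l in tail.split(",") if l.strip()]
            if not leaves:
                raise AssertionFileError("GAIN with no supporting leaves", line=lineno)
            for leaf in leaves:
                try:
                    leaf_node = tree.node(leaf)
                except UnknownNodeError:
                    raise AssertionFileError(
                        f"unknown supporting leaf {leaf!r}", line=lineno) from None
                if not tree.is_ancestor(node.node_id, leaf_node.node_id):
                    raise AssertionFileError(
                        f"gain node {node_id} is not ancestral to support {leaf}",
                        line=lineno)
            model.gains.append(GainEvent(node_id=node.node_id, go_id=resolved,
                                         supporting_leaves=leaves))
        elif kind == "LOSS":
            if tail not in LOSS_CAUSES:
                raise AssertionFileError(
                    f"unknown loss cause {tail!r} (expected one of {', '.join(LOSS_CAUSES)})",
                    line=lineno)
            model.losses.append(LossEvent(node_id=node.node_id, go_id=resolved, cause=tail))
        else:
            raise AssertionFileError(f"unknown assertion kind {kind!r}", line=lineno)
    return model


def write_assertions(model: EvolutionaryModel) -> str:
    """Serialize a model back to the assertion TSV (stable order)."""
    out = [f"# family: {model.family_id}"]
    for g in model.gains:
        out.append("\t".join(["GAIN", g.node_id, g.go_id, ",".join(g.supporting_leaves)]))
    for l in model.losses:
        out.append("\t".join(["LOSS", l.node_id, l.go_id, l.cause]))
    return "\n".join(out) + "\n"


# -- validation ----------------------------------------------------------

def _node_id(tree: GeneTree, ident: str) -> str | None:
    """Resolve a node id or gene accession to its node id; None if unknown."""
    try:
        return tree.node(ident).node_id
    except UnknownNodeError:
        return None


def _loss_matches_gain(loss: LossEvent, gain: GainEvent, tree: GeneTree,
                       ontology: OntologyGraph) -> bool:
    """Loss of t′ at v matches gain of t at g iff v is strictly below g and
    t′ is t or an ontology ancestor of t (term-downward blocking)."""
    if not tree.is_ancestor(gain.node_id, loss.node_id, reflexive=False):
        return False
    return ontology.implies(gain.go_id, loss.go_id)


def validate_model(model: EvolutionaryModel, tree: GeneTree,
                   ontology: OntologyGraph,
                   records: list[AnnotationRecord],
                   config: EvidenceConfig | None = None) -> list[Violation]:
    """Check a curator model against the tree, ontology and evidence.

    Violations are data, not exceptions. The model is valid when: every
    gain's supporting leaves each carry ≥1 usable experimental record to the
    gain term or an ontology descendant of it (true-path rule); every gain
    node dominates its support; every loss lies strictly below a matching
    gain; and no two gains of the same term are nested.

    ``records`` may be raw or prefiltered — the evidence filter is applied
    here (it is idempotent), so e.g. an IEA-only support is always caught.
    Event node references may use gene accessions; they are normalized to
    node ids in place.
    """
    violations: list[Violation] = []
    for event in (*model.gains, *model.losses):
        resolved = _node_id(tree, event.node_id)
        if resolved is not None:
            event.node_id = resolved
    usable_records, _ = filter_experimental(records, config)
    # usable evidence terms per gene
    terms_by_gene: dict[str, set[str]] = {}
    for rec in usable_records:
        terms_by_gene.setdefault(rec.gene_id, set()).add(rec.go_id)
        terms_by_gene.setdefault(rec.object_id, set()).add(rec.go_id)

    for gain in model.gains:
        if gain.node_id not in tree.index:
            violations.append(Violation("unknown_reference",
                                        f"gain node {gain.node_id} not in tree",
                                        gain.node_id, gain.go_id))
            continue
        if gain.go_id not in ontology:
            violations.append(Violation("unknown_reference",
                                        f"gain term {gain.go_id} not in ontology",
                                        gain.node_id, gain.go_id))
            continue
        if not gain.supporting_leaves:
            violations.append(Violation("unsupported_gain",
                                        f"gain of {gain.go_id} at {gain.node_id} has no support",
                                        gain.node_id, gain.go_id))
            continue
        for leaf in gain.supporting_leaves:
            try:
                leaf_node = tree.node(leaf)
            except UnknownNodeError:
                violations.append(Violation("unknown_reference",
                                            f"supporting leaf {leaf} not in tree",
                                            gain.node_id, gain.go_id))
                continue
            if not tree.is_ancestor(gain.node_id, leaf_node.node_id):
                violations.append(Violation(
                    "gain_not_dominating",
                    f"gain node {gain.node_id} is not ancestral to support {leaf}",
                    gain.node_id, gain.go_id))
            evidence_terms = terms_by_gene.get(leaf, set())
            if leaf_node.gene_id:
                evidence_terms = evidence_terms | terms_by_gene.get(leaf_node.gene_id, set())
            if not any(t in ontology and not ontology.terms[t].obsolete
                       and ontology.implies(t, gain.go_id)
                       for t in evidence_terms):
                violations.append(Violation(
                    "unsupported_gain",
                    f"support {leaf} carries no usable experimental record to "
                    f"{gain.go_id} or a descendant term",
                    gain.node_id, gain.go_id))

    # nested same-term gains
    for i, a in enumerate(model.gains):
        for b in model.gains[i + 1:]:
            if a.go_id != b.go_id or a.node_id == b.node_id:
                continue
            if a.node_id not in tree.index or b.node_id not in tree.index:
                continue
            if (tree.is_ancestor(a.node_id, b.node_id)
                    or tree.is_ancestor(b.node_id, a.node_id)):
                violations.append(Violation(
                    "nested_gain",
                    f"gains of {a.go_id} at {a.node_id} and {b.node_id} are nested",
                    a.node_id, a.go_id))

    for loss in model.losses:
        if loss.node_id not in tree.index:
            violations.append(Violation("unknown_reference",
                                        f"loss node {loss.node_id} not in tree",
                                        loss.node_id, loss.go_id))
            continue
        if loss.go_id not in ontology:
            violations.append(Violation("unknown_reference",
                                        f"loss term {loss.go_id} not in ontology",
                                        loss.node_id, loss.go_id))
            continue
        if not any(gain.node_id in tree.index and gain.go_id in ontology
                   and _loss_matches_gain(loss, gain, tree, ontology)
                   for gain in model.gains):
            violations.append(Violation(
                "loss_without_gain",
                f"loss of {loss.go_id} at {loss.node_id} lies under no matching gain",
                loss.node_id, loss.go_id))
    return violations


# -- evidence gathering --------------------------------------------------

def presence_sets(tree: GeneTree, records: list[AnnotationRecord],
                  ontology: OntologyGraph, go_id: str,
                  config: EvidenceConfig | None = None) -> PresenceSets:
    """Gather the experimental presence (P) and absence (N) leaf sets for a term.

    True-path rule: a positive record to a descendant term counts toward the
    queried term. Negation propagates the other way: a NOT record to an
    ancestor term denies the queried term too.
    """
    if go_id not in ontology:
        raise UnknownTermError(go_id)
    usable, excluded = filter_experimental(records, config)
    negatives = negated_experimental(excluded)
    out = PresenceSets()
    for rec in usable:
        leaf = tree.leaf_index.get(rec.gene_id) or tree.leaf_index.get(rec.object_id)
        if leaf is None:
            continue
        if rec.go_id in ontology and not ontology.terms[rec.go_id].obsolete \
                and ontology.implies(rec.go_id, go_id):
            out.P.add(leaf.gene_id)
    for rec in negatives:
        leaf = tree.leaf_index.get(rec.gene_id) or tree.leaf_index.get(rec.object_id)
        if leaf is None:
            continue
        if rec.go_id in ontology and not ontology.terms[rec.go_id].obsolete \
                and ontology.implies(go_id, rec.go_id):
            out.N.add(leaf.gene_id)
    out.conflicting = out.P & out.N
    out.N -= out.conflicting  # conflicted leaves stay positive, flagged
    if out.conflicting:
        logger.warning("conflicting positive and negative evidence for %s on: %s",
                       go_id, ", ".join(sorted(out.conflicting)))
    return out


# -- suggestion (Dollo parsimony) ---------------------------------------

def suggest_model(tree: GeneTree, P: set[str] | PresenceSets, N: set[str] | None = None,
                  go_id: str = "", family_id: str | None = None,
                  records: list[AnnotationRecord] | None = None) -> Suggestion:
    """Propose a single-gain Dollo model from presence/absence evidence.

    The gain is placed at the MRCA of the positive leaves. Losses are placed
    only where negative evidence demands it: at each maximal subtree
    strictly below the gain whose leaves contain none of P and at least one
    of N. Those maximal positive-free subtrees are pairwise disjoint and each
    needs exactly one loss, so this loss set has minimum cardinality among
    all Dollo explanations. Ancestors of the gain node are returned as legal
    but less parsimonious alternates; a single-support gain (|P| = 1) is
    flagged, echoing curator practice of not propagating from weak evidence.
    """
    if isinstance(P, PresenceSets):
        N = P.N
        P = P.P
    N = set(N or ())
    P = set(P)
    if not P:
        raise NoEvidenceError(f"no experimental presence evidence for {go_id or 'term'}")
    gain_node = tree.mrca(P)
    p_ids = {tree.node(g).node_id for g in P}
    n_ids = {tree.node(g).node_id for g in N}

    losses: list[LossEvent] = []

    def walk(node) -> None:
        for child in node.children:
            leaf_ids = {n.node_id for n in child.preorder() if n.is_leaf}
            if leaf_ids & p_ids:
                walk(child)
            elif leaf_ids & n_ids:
                losses.append(LossEvent(node_id=child.node_id, go_id=go_id,
                                        cause="UNSPECIFIED"))
            # no positive and no negative evidence below: leave untouched —
            # absence of annotation is not absence of function

    walk(tree.node(gain_node))
    losses.sort(key=lambda l: tree.preorder_position(l.node_id))

    references: list[str] = []
    if records:
        support_keys = {tree.node(g).gene_id for g in P}
        for rec in records:
            if rec.gene_id in support_keys and not rec.negated:
                references.extend(r for r in rec.references if r not in references)

    supporting = sorted(tree.node(g).gene_id for g in P)
    model = EvolutionaryModel(
        family_id=family_id or tree.family_id,
        gains=[GainEvent(node_id=gain_node, go_id=go_id,
                         supporting_leaves=supporting, references=references)],
        losses=losses,
    )
    alternates = [n.node_id for n in reversed(tree.root_path(gain_node)[:-1])]
    flags = ["single-support"] if len(P) == 1 else []
    return Suggestion(model=model, alternates=alternates, flags=flags)


# -- propagation ---------------------------------------------------------

def propagate(model: EvolutionaryModel, tree: GeneTree,
              ontology: OntologyGraph) -> list[InferredAnnotation]:
    """Apply a model: emit IBD at gains, IBA below them, IKR/IRD at losses.

    A subtree rooted at a loss of t′ blocks propagation of t iff t′ = t or
    t is an ontology descendant of t′. Leaves that already carry
    experimental records still receive IBA. Output order is
    (gain term, preorder position of target); rerunning is byte-stable.

    Structural model validity (domination, losses under matching gains,
    no nested same-term gains) is re-checked here; a violation raises
    :class:`ModelInvalidError` carrying the violations. Evidence-level
    validity needs the GAF and is the caller's job via
    :func:`validate_model`.
    """
    structural: list[Violation] = []
    for event in (*model.gains, *model.losses):
        resolved = _node_id(tree, event.node_id)
        if resolved is not None:
            event.node_id = resolved
    for gain in model.gains:
        if gain.node_id not in tree.index:
            structural.append(Violation("unknown_reference",
                                        f"gain node {gain.node_id} not in tree",
                                        gain.node_id, gain.go_id))
        if gain.go_id not in ontology:
            structural.append(Violation("unknown_reference",
                                        f"gain term {gain.go_id} not in ontology",
                                        gain.node_id, gain.go_id))
        if not gain.supporting_leaves:
            structural.append(Violation("unsupported_gain",
                                        f"gain at {gain.node_id} has no support",
                                        gain.node_id, gain.go_id))
    if not structural:
        for i, a in enumerate(model.gains):
            for b in model.gains[i + 1:]:
                if a.go_id == b.go_id and a.node_id != b.node_id and (
                        tree.is_ancestor(a.node_id, b.node_id)
                        or tree.is_ancestor(b.node_id, a.node_id)):
                    structural.append(Violation(
                        "nested_gain",
                        f"gains of {a.go_id} at {a.node_id} and {b.node_id} are nested",
                        a.node_id, a.go_id))
        for loss in model.losses:
            if loss.node_id not in tree.index or loss.go_id not in ontology:
                structural.append(Violation("unknown_reference",
                                            f"loss reference invalid at {loss.node_id}",
                                            loss.node_id, loss.go_id))
            elif not any(_loss_matches_gain(loss, g, tree, ontology)
                         for g in model.gains):
                structural.append(Violation(
                    "loss_without_gain",
                    f"loss of {loss.go_id} at {loss.node_id} lies under no matching gain",
                    loss.node_id, loss.go_id))
    if structural:
        raise ModelInvalidError(structural)

    pos = tree.preorder_position
    out: list[InferredAnnotation] = []

    gains_sorted = sorted(model.gains, key=lambda g: (g.go_id, pos(g.node_id)))
    for gain in gains_sorted:
        g_node = tree.node(gain.node_id)
        matching = [l for l in model.losses
                    if _loss_matches_gain(l, gain, tree, ontology)]
        blocked: set[str] = set()
        for loss in matching:
            blocked.add(loss.node_id)
            blocked |= tree.descendants(loss.node_id)
        out.append(InferredAnnotation(
            target=gain.node_id, go_id=gain.go_id, evidence="IBD",
            gain_node=gain.node_id, supporting_leaves=list(gain.supporting_leaves),
            target_gene=g_node.gene_id, target_species=g_node.species))

        def walk(node, hgt_seen: bool) -> None:
            for child in node.children:
                if child.node_id in blocked:
                    continue
                child_hgt = hgt_seen or child.event == "horizontal_transfer"
                out.append(InferredAnnotation(
                    target=child.node_id, go_id=gain.go_id, evidence="IBA",
                    gain_node=gain.node_id,
                    supporting_leaves=list(gain.supporting_leaves),
                    target_gene=child.gene_id, target_species=child.species,
                    via_hgt=child_hgt))
                walk(child, child_hgt)

        walk(g_node, g_node.event == "horizontal_transfer")

    # one negated annotation per loss event, linked to its nearest matching gain
    emitted_losses = set()
    for gain in gains_sorted:
        for loss in model.losses:
            key = (loss.node_id, loss.go_id, loss.cause)
            if key in emitted_losses:
                continue
            if not _loss_matches_gain(loss, gain, tree, ontology):
                continue
            emitted_losses.add(key)
            l_node = tree.node(loss.node_id)
            out.append(InferredAnnotation(
                target=loss.node_id, go_id=loss.go_id,
                evidence=CAUSE_TO_EVIDENCE[loss.cause],
                gain_node=gain.node_id,
                supporting_leaves=list(gain.supporting_leaves),
                negated=True, target_gene=l_node.gene_id,
                target_species=l_node.species))

    out.sort(key=lambda a: (a.go_id, pos(a.target), a.evidence))
    return out


def detect_conflicts(inferred: list[InferredAnnotation],
                     records: list[AnnotationRecord], tree: GeneTree,
                     ontology: OntologyGraph,
                     config: EvidenceConfig | None = None) -> list[Conflict]:
    """Find experimental records that contradict the propagation.

    Two rules: an IBA lands on a leaf holding a negated experimental record
    to the same term or an ontology ancestor; or a leaf inside a lost
    subtree holds a usable positive record to the lost term or a descendant.
    """
    usable, excluded = filter_experimental(records, config)
    negatives = negated_experimental(excluded)

    def leaf_records(recs):
        by_gene: dict[str, list[AnnotationRecord]] = {}
        for rec in recs:
            leaf = tree.leaf_index.get(rec.gene_id) or tree.leaf_index.get(rec.object_id)
            if leaf is not None:
                by_gene.setdefault(leaf.gene_id, []).append(rec)
        return by_gene

    pos_by_gene = leaf_records(usable)
    neg_by_gene = leaf_records(negatives)

    conflicts: list[Conflict] = []
    seen: set[tuple] = set()
    for ann in inferred:
        if ann.evidence == "IBA" and not ann.negated and ann.target_gene:
            for rec in neg_by_gene.get(ann.target_gene, ()):
                if rec.go_id in ontology and ontology.implies(ann.go_id, rec.go_id):
                    key = ("neg", ann.target_gene, ann.go_id, id(rec))
                    if key not in seen:
                        seen.add(key)
                        conflicts.append(Conflict(
                            "negative_evidence_under_propagation",
                            ann.target_gene, ann.go_id, rec, ann))
        elif ann.negated:  # a loss node: check the subtree below it
            genes = tree.leaf_genes_under(ann.target, inclusive=True)
            for gene in sorted(genes):
                for rec in pos_by_gene.get(gene, ()):
                    if rec.go_id in ontology and not ontology.terms[rec.go_id].obsolete \
                            and ontology.implies(rec.go_id, ann.go_id):
                        key = ("pos", gene, ann.go_id, id(rec))
                        if key not in seen:
                            seen.add(key)
                            conflicts.append(Conflict(
                                "experimental_evidence_under_loss",
                                gene, ann.go_id, rec, ann))
    return conflicts


# -- GAF export ----------------------------------------------------------

PAINT_REFERENCE = "GO_REF:0000033"


def inferred_to_gaf(inferred: list[InferredAnnotation], tree: GeneTree,
                    ontology: OntologyGraph, *, assigned_by: str = "phylo-annot",
                    date: str = "20000101") -> list[AnnotationRecord]:
    """Render inferred annotations as GAF records.

    Ancestral targets (IBD, and IBA/losses on internal nodes) get
    ``db=PANTHER`` and ``object_id=<family>:<node>``; leaf targets keep
    their own DB:ACC identity. IBA and loss rows point back to the gain node
    through with/from (``PANTHER:<family>:<gain>``) followed by the
    supporting gene ids, with the phylogenetic-inference reference.
    """
    fam = tree.family_id
    records = []
    for ann in inferred:
        node = tree.node(ann.target)
        if node.is_leaf:
            db, _, acc = node.gene_id.partition(":")
            symbol = acc
        else:
            db, acc = "PANTHER", f"{fam}:{node.node_id}"
            symbol = node.node_id
        if ann.evidence == "IBD":
            with_from = list(ann.supporting_leaves)
        else:
            with_from = [f"PANTHER:{fam}:{ann.gain_node}"] + list(ann.supporting_leaves)
        aspect = "P"
        if ann.go_id in ontology:
            aspect = NAMESPACE_TO_ASPECT[ontology.terms[ann.go_id].namespace]
        taxon = f"taxon:{node.species}" if node.species else "taxon:1"
        records.append(AnnotationRecord(
            db=db, object_id=acc, symbol=symbol, negated=ann.negated,
            go_id=ann.go_id, references=[PAINT_REFERENCE],
            evidence_code=ann.evidence, with_from=with_from, aspect=aspect,
            taxon=taxon, date=date, assigned_by=assigned_by))
    return records
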