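"""Family statistics, over-annotation QA flags, and maintenance diffs.

The statistics mirror the per-family accounting a phylogenetic-annotation
project reports: how many proteins are in the family, how many carry
experimental evidence, how many distinct IBD (ancestral) annotations the
curated model produced, and how many IBA annotations they fan out to.
"new annotations" are IBA annotations on genes that previously had no
experimental record to the same or a more specific term — the quantity that
makes phylogenetic annotation worthwhile even for well-studied genomes.

Maintenance matters because the inputs drift: ontology releases obsolete
and merge terms, primary annotations get retracted, and family trees are
rebuilt (occasionally moving whole clades between families). Every gain's
support must be re-checked against the updated inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from .evo_model import EvolutionaryModel, InferredAnnotation
from .gaf import AnnotationRecord, EvidenceConfig, filter_experimental
from .gene_tree import GeneTree
from .ontology import NAMESPACE_TO_ASPECT, OntologyGraph, resolve_term
from .errors import UnknownTermError, UnresolvableTermError

logger = logging.getLogger(__name__)

STATS_COLUMNS = [
    "family_id", "protein_count", "exp_proteins", "exp_annotations",
    "exp_terms", "annotated_proteins", "ibd_count", "iba_count",
    "inferred_terms",
]


@dataclass
class FamilyStats:
    """Per-family annotation accounting.

    ``inferred_terms`` may exceed or fall short of ``exp_terms``: inference
    deliberately uses more general or more specific terms than the raw
    experimental records. IBD rows never count toward per-protein totals;
    only leaf IBA annotations make a protein "annotated".
    """

    family_id: str
    protein_count: int = 0
    exp_proteins: int = 0
    exp_annotations: int = 0
    exp_terms: int = 0
    annotated_proteins: int = 0
    ibd_count: int = 0
    iba_count: int = 0
    inferred_terms: int = 0


@dataclass
class QAFlag:
    record: AnnotationRecord
    rule: str  # htp_evidence | phenotype_prone_term | transient_localization | aspect_mismatch
    note: str = ""


@dataclass
class QAConfig:
    """Curator policy for over-annotation screening.

    The term lists are policy, not algorithm — the shipped defaults are
    empty. ``phenotype_codes`` are the mutant-phenotype evidence codes whose
    combination with a phenotype-prone process term is suspect (the classic
    false positive: a deletion causes an apoptotic phenotype downstream
    without the gene acting in apoptosis execution itself).
    """

    evidence: EvidenceConfig = field(default_factory=EvidenceConfig)
    phenotype_prone_terms: set[str] = field(default_factory=set)
    transient_localization_terms: set[str] = field(default_factory=set)
    phenotype_codes: frozenset[str] = frozenset({"IMP", "IGI"})


@dataclass
class BrokenSupport:
    gain_node: str
    go_id: str
    reason: str  # term_obsoleted | term_merged | support_record_removed | leaf_missing_from_tree | leaf_moved_family
    detail: str = ""


@dataclass
class MaintenanceReport:
    broken_supports: list[BrokenSupport] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.broken_supports)


# -- statistics ----------------------------------------------------------

def family_stats(tree: GeneTree, usable_records: list[AnnotationRecord],
                 inferred: list[InferredAnnotation]) -> FamilyStats:
    """Count the nine per-family statistics.

    ``usable_records`` should already be the experimental stream from
    :func:`phyloannot.gaf.filter_experimental`. Records naming genes outside
    the tree are reported via logging and excluded from every count.
    """
    stats = FamilyStats(family_id=tree.family_id)
    stats.protein_count = len(tree.leaves)

    exp_genes: set[str] = set()
    exp_terms: set[str] = set()
    for rec in usable_records:
        leaf = tree.leaf_index.get(rec.gene_id) or tree.leaf_index.get(rec.object_id)
        if leaf is None:
            logger.warning("record for %s references no leaf of %s; excluded",
                           rec.gene_id, tree.family_id)
            continue
        stats.exp_annotations += 1
        exp_genes.add(leaf.gene_id)
        exp_terms.add(rec.go_id)
    stats.exp_proteins = len(exp_genes)
    stats.exp_terms = len(exp_terms)

    iba_genes: set[str] = set()
    gain_terms: set[str] = set()
    for ann in inferred:
        if ann.evidence == "IBD":
            stats.ibd_count += 1
            gain_terms.add(ann.go_id)
        elif ann.evidence == "IBA" and not ann.negated:
            stats.iba_count += 1
            if ann.target_gene:
                iba_genes.add(ann.target_gene)
    stats.annotated_proteins = len(iba_genes)
    stats.inferred_terms = len(gain_terms)
    return stats


def stats_to_tsv(stats_list: list[FamilyStats]) -> str:
    df = pd.DataFrame([asdict(s) for s in stats_list], columns=STATS_COLUMNS)
    return df.to_csv(sep="\t", index=False)


def new_annotations(inferred: list[InferredAnnotation],
                    usable_records: list[AnnotationRecord],
                    ontology: OntologyGraph,
                    species_filter: str | None = None) -> list[tuple[str, str]]:
    """(gene, term) pairs that inference adds beyond the experimental corpus.

    An IBA on a leaf is *new* when the gene has no usable experimental
    record to the same term or an ontology descendant of it — experimental
    support to a more general term does not cover the inferred, more
    specific one.
    """
    terms_by_gene: dict[str, set[str]] = {}
    for rec in usable_records:
        terms_by_gene.setdefault(rec.gene_id, set()).add(rec.go_id)

    out: set[tuple[str, str]] = set()
    for ann in inferred:
        if ann.evidence != "IBA" or ann.negated or not ann.target_gene:
            continue
        if species_filter and ann.target_species != species_filter:
            continue
        covered = any(
            t in ontology and not ontology.terms[t].obsolete
            and ontology.implies(t, ann.go_id)
            for t in terms_by_gene.get(ann.target_gene, ())
        )
        if not covered:
            out.add((ann.target_gene, ann.go_id))
    return sorted(out)


# -- over-annotation QA --------------------------------------------------

def flag_overannotation(records: list[AnnotationRecord],
                        ontology: OntologyGraph | None,
                        config: QAConfig | None = None) -> list[QAFlag]:
    """Screen primary annotations for the usual over-annotation patterns.

    One flag per (record, rule) hit: high-throughput evidence; a
    phenotype-prone term annotated with a mutant-phenotype code; a cellular
    component term from the transient-localization list; and an annotation
    whose aspect letter contradicts the term's namespace.
    """
    config = config or QAConfig()
    flags: list[QAFlag] = []
    for rec in records:
        if rec.evidence_code in config.evidence.htp_codes:
            flags.append(QAFlag(rec, "htp_evidence",
                                f"high-throughput code {rec.evidence_code}"))
        if (rec.go_id in config.phenotype_prone_terms
                and rec.evidence_code in config.phenotype_codes):
            flags.append(QAFlag(rec, "phenotype_prone_term",
                                f"{rec.evidence_code} to phenotype-prone term {rec.go_id}"))
        if rec.aspect == "C" and rec.go_id in config.transient_localization_terms:
            flags.append(QAFlag(rec, "transient_localization",
                                f"transient localization term {rec.go_id}"))
        if ontology is not None and rec.go_id in ontology:
            term = ontology.terms[rec.go_id]
            expected = NAMESPACE_TO_ASPECT.get(term.namespace)
            if expected and expected != rec.aspect:
                flags.append(QAFlag(rec, "aspect_mismatch",
                                    f"aspect {rec.aspect} but {rec.go_id} is {term.namespace}"))
    return flags


def flags_to_tsv(flags: list[QAFlag]) -> str:
    rows = [{
        "gene": f.record.gene_id, "go_id": f.record.go_id,
        "evidence_code": f.record.evidence_code, "rule": f.rule, "note": f.note,
    } for f in flags]
    df = pd.DataFrame(rows, columns=["gene", "go_id", "evidence_code", "rule", "note"])
    return df.to_csv(sep="\t", index=False)


# -- maintenance ---------------------------------------------------------

def maintenance_check(model: EvolutionaryModel, new_tree: GeneTree,
                      new_ontology: OntologyGraph,
                      new_records: list[AnnotationRecord],
                      config: EvidenceConfig | None = None,
                      cross_family_index: dict[str, str] | None = None,
                      ) -> MaintenanceReport:
    """Re-check every gain of a previously valid model against updated inputs.

    Unchanged inputs produce an empty report. Detected deltas: the gain term
    was obsoleted (with a proposed ``replaced_by`` rewrite when one exists —
    reported as a merge), a supporting leaf vanished from the tree (or moved
    family, when a cross-family gene index is supplied), and supporting
    records that no longer exist, which break a gain entirely when none
    survive.
    """
    report = MaintenanceReport()
    usable, _ = filter_experimental(new_records, config)
    terms_by_gene: dict[str, set[str]] = {}
    for rec in usable:
        terms_by_gene.setdefault(rec.gene_id, set()).add(rec.go_id)
        terms_by_gene.setdefault(rec.object_id, set()).add(rec.go_id)

    for gain in model.gains:
        current_term = gain.go_id
        if gain.go_id not in new_ontology:
            report.broken_supports.append(BrokenSupport(
                gain.node_id, gain.go_id, "term_obsoleted",
                "term no longer present in the ontology"))
            continue
        try:
            current_term = resolve_term(new_ontology, gain.go_id)
            if current_term != gain.go_id:
                report.broken_supports.append(BrokenSupport(
                    gain.node_id, gain.go_id, "term_merged",
                    f"merged into {current_term}"))
                report.actions.append(
                    f"rewrite gain at {gain.node_id}: {gain.go_id} -> {current_term}")
        except UnresolvableTermError:
            report.broken_supports.append(BrokenSupport(
                gain.node_id, gain.go_id, "term_obsoleted",
                "obsolete with no replacement; drop or re-curate"))
            continue
        except UnknownTermError:
            report.broken_supports.append(BrokenSupport(
                gain.node_id, gain.go_id, "term_obsoleted",
                "replacement chain leaves the ontology"))
            continue

        surviving = 0
        for leaf in gain.supporting_leaves:
            if leaf not in new_tree.leaf_index:
                moved_to = (cross_family_index or {}).get(leaf)
                if moved_to and moved_to != model.family_id:
                    report.broken_supports.append(BrokenSupport(
                        gain.node_id, gain.go_id, "leaf_moved_family",
                        f"{leaf} now in family {moved_to}"))
                    report.actions.append(
                        f"migrate annotations for {leaf} to family {moved_to}")
                else:
                    report.broken_supports.append(BrokenSupport(
                        gain.node_id, gain.go_id, "leaf_missing_from_tree",
                        f"{leaf} absent from updated tree"))
                continue
            leaf_gene = new_tree.leaf_index[leaf].gene_id
            evidence_terms = terms_by_gene.get(leaf, set()) | terms_by_gene.get(leaf_gene, set())
            if any(t in new_ontology and not new_ontology.terms[t].obsolete
                   and new_ontology.implies(t, current_term)
                   for t in evidence_terms):
                surviving += 1
        if surviving == 0:
            report.broken_supports.append(BrokenSupport(
                gain.node_id, gain.go_id, "support_record_removed",
                "no supporting leaf still carries a usable experimental record"))
            report.actions.append(
                f"re-curate gain of {gain.go_id} at {gain.node_id}: support gone")
    return report


def maintenance_to_tsv(report: MaintenanceReport) -> str:
    rows = [asdict(b) for b in report.broken_supports]
    df = pd.DataFrame(rows, columns=["gain_node", "go_id", "reason", "detail"])
    return df.to_csv(sep="\t", index=False)


def report_to_json(obj) -> str:
    """Serialize any report dataclass (or list of them) as pretty JSON."""
    def default(o):
        try:
            return asdict(o)
        except TypeError:
            return str(o)
    if isinstance(obj, list):
        return json.dumps([asdict(o) if hasattr(o, "__dataclass_fields__") else o
                           for o in obj], indent=2, default=default)
    return json.dumps(asdict(obj), indent=2, default=default)
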