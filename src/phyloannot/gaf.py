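"""GAF 2.1/2.2 reading, writing and evidence-class filtering.

Manual GO annotation summarizes experimental results from the literature
into Gene Association File rows; each row carries a three-letter evidence
code. Phylogenetic inference only ever builds on *experimental* codes
(IDA, IMP, ...): curated-similarity (ISS), author-statement (TAS/NAS),
curator (IC) and electronic (IEA) annotations are themselves inferences and
would make the propagation circular. High-throughput codes (HDA, HMP, ...)
are experimental in origin but carry enough false positives — especially
for subcellular localization — that they are excluded from inference by
default and surfaced to QA instead.

NOT-qualified experimental rows are *negative* evidence. They are never
discarded: the inference engine uses them to place function-loss events.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import NamedTuple

from .errors import GafFormatError, RecordValidationError
from .ontology import NAMESPACE_TO_ASPECT, OntologyGraph

GAF_COLUMNS = 17

#: Default experimental evidence codes usable as inference support.
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
#: Default high-throughput codes (excluded from inference by default).
HTP_CODES = frozenset({"HTP", "HDA", "HMP", "HGI", "HEP"})


def load_evidence_table() -> dict[str, str]:
    """Evidence code -> class, from the versioned table shipped in the package."""
    text = resources.files("phyloannot.data").joinpath("evidence_codes.tsv").read_text()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    return {row["code"]: row["class"] for row in reader}


KNOWN_EVIDENCE_CODES = frozenset(load_evidence_table())


@dataclass
class AnnotationRecord:
    """One GAF line.

    ``negated`` reflects a NOT qualifier; ``qualifier_rel`` preserves a GAF
    2.2 relation (``involved_in`` etc.) verbatim so round-trips lose
    nothing, but the engine only ever consults ``negated``.
    """

    db: str
    object_id: str
    symbol: str
    go_id: str
    evidence_code: str
    references: list[str] = field(default_factory=lambda: ["GO_REF:0000000"])
    negated: bool = False
    qualifier_rel: str = ""
    with_from: list[str] = field(default_factory=list)
    aspect: str = "P"
    object_name: str = ""
    synonyms: str = ""
    object_type: str = "protein"
    taxon: str = "taxon:1"
    date: str = "20000101"
    assigned_by: str = "phylo-annot"
    extension: str = ""
    form_id: str = ""

    @property
    def gene_id(self) -> str:
        return f"{self.db}:{self.object_id}"

    def validate(self, ontology: OntologyGraph | None = None) -> None:
        if not self.references:
            raise RecordValidationError("references", "must be nonempty")
        if self.evidence_code not in KNOWN_EVIDENCE_CODES:
            raise RecordValidationError(
                "evidence_code", f"unknown code {self.evidence_code!r}")
        if self.aspect not in ("F", "P", "C"):
            raise RecordValidationError("aspect", f"must be F/P/C, got {self.aspect!r}")
        if ontology is not None and self.go_id in ontology:
            ns = ontology.terms[self.go_id].namespace
            if NAMESPACE_TO_ASPECT.get(ns) != self.aspect:
                raise RecordValidationError(
                    "aspect", f"{self.aspect} inconsistent with namespace {ns} of {self.go_id}")


@dataclass
class EvidenceConfig:
    """Which evidence classes may support a gain inference."""

    experimental_codes: frozenset[str] = EXPERIMENTAL_CODES
    htp_codes: frozenset[str] = HTP_CODES
    htp_usable_for_inference: bool = False

    def __post_init__(self) -> None:
        self.experimental_codes = frozenset(self.experimental_codes)
        self.htp_codes = frozenset(self.htp_codes)
        if self.experimental_codes & self.htp_codes:
            raise ValueError("experimental and HTP code sets must be disjoint")


class ExcludedRecord(NamedTuple):
    record: AnnotationRecord
    reason: str  # non_experimental | htp | negated


def read_gaf(text: str) -> list[AnnotationRecord]:
    """Parse a GAF 2.1 or 2.2 document."""
    lines = text.splitlines()
    version = None
    for line in lines:
        if line.startswith("!gaf-version:"):
            version = line.split(":", 1)[1].strip()
            break
    if version not in ("2.1", "2.2"):
        raise GafFormatError(f"unknown or missing gaf-version: {version!r}")

    records = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) != GAF_COLUMNS:
            raise GafFormatError(
                f"expected {GAF_COLUMNS} columns, found {len(cols)}", line=lineno)
        qualifier = cols[3].strip()
        quals = [q for q in qualifier.split("|") if q]
        negated = "NOT" in quals
        rel = "|".join(q for q in quals if q != "NOT")
        records.append(AnnotationRecord(
            db=cols[0], object_id=cols[1], symbol=cols[2],
            negated=negated, qualifier_rel=rel,
            go_id=cols[4],
            references=[r for r in cols[5].split("|") if r],
            evidence_code=cols[6],
            with_from=[w for w in cols[7].split("|") if w],
            aspect=cols[8], object_name=cols[9], synonyms=cols[10],
            object_type=cols[11], taxon=cols[12], date=cols[13],
            assigned_by=cols[14], extension=cols[15], form_id=cols[16],
        ))
    return records


def write_gaf(records: list[AnnotationRecord], *, header_comments: list[str] | None = None,
              ontology: OntologyGraph | None = None) -> str:
    """Serialize to GAF 2.1, sorted by (object_id, go_id, evidence_code).

    Extra provenance lines (without the leading '!') may be passed in
    ``header_comments``; they are emitted after the version line.
    """
    out = ["!gaf-version: 2.1"]
    for comment in header_comments or ():
        out.append("!" + comment)
    for rec in sorted(records, key=lambda r: (r.object_id, r.go_id, r.evidence_code)):
        rec.validate(ontology)
        qual = "NOT" if rec.negated else ""
        out.append("\t".join([
            rec.db, rec.object_id, rec.symbol, qual, rec.go_id,
            "|".join(rec.references), rec.evidence_code,
            "|".join(rec.with_from), rec.aspect, rec.object_name,
            rec.synonyms, rec.object_type, rec.taxon, rec.date,
            rec.assigned_by, rec.extension, rec.form_id,
        ]))
    return "\n".join(out) + "\n"


def filter_experimental(
    records: list[AnnotationRecord],
    config: EvidenceConfig | None = None,
) -> tuple[list[AnnotationRecord], list[ExcludedRecord]]:
    """Split records into inference-usable support and tagged exclusions.

    A record is usable when its code is experimental (or HTP, if the config
    opts in) and it is not NOT-qualified. Exclusion reasons:

    - ``non_experimental``: code outside the experimental (+HTP) sets;
    - ``htp``: high-throughput code while HTP is not usable;
    - ``negated``: NOT-qualified record with an otherwise usable code — these
      are the negative-evidence stream, routed to loss placement, not noise.
    """
    config = config or EvidenceConfig()
    usable_codes = set(config.experimental_codes)
    if config.htp_usable_for_inference:
        usable_codes |= config.htp_codes
    usable: list[AnnotationRecord] = []
    excluded: list[ExcludedRecord] = []
    for rec in records:
        if rec.evidence_code not in usable_codes:
            if rec.evidence_code in config.htp_codes:
                excluded.append(ExcludedRecord(rec, "htp"))
            else:
                excluded.append(ExcludedRecord(rec, "non_experimental"))
        elif rec.negated:
            excluded.append(ExcludedRecord(rec, "negated"))
        else:
            usable.append(rec)
    return usable, excluded


def negated_experimental(excluded: list[ExcludedRecord]) -> list[AnnotationRecord]:
    """The negative-evidence stream from a filter_experimental exclusion list."""
    return [e.record for e in excluded if e.reason == "negated"]


def normalize(text: str) -> str:
    """Canonical form of a GAF document: parse then re-serialize."""
    return write_gaf(read_gaf(text))


__all__ = [
    "AnnotationRecord", "EvidenceConfig", "ExcludedRecord",
    "EXPERIMENTAL_CODES", "HTP_CODES", "KNOWN_EVIDENCE_CODES",
    "read_gaf", "write_gaf", "filter_experimental", "negated_experimental",
    "normalize", "load_evidence_table", "replace",
]
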