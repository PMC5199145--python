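"""Exception hierarchy.

Everything raised on purpose derives from :class:`PhyloAnnotError`, so CLI
commands can translate any domain failure into a message + exit code without
catching bare ``Exception``.
"""

from __future__ import annotations


class PhyloAnnotError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PhyloAnnotError):
    """A document could not be parsed.

    Carries ``line`` (1-based) or ``position`` (0-based character offset)
    when the format makes one meaningful.
    """

    def __init__(self, message: str, *, line: int | None = None,
                 position: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line})"
        elif position is not None:
            loc = f" (position {position})"
        super().__init__(message + loc)
        self.line = line
        self.position = position


class CycleError(ParseError):
    """The closure relations of an ontology contain a directed cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("cycle in closure relations: " + " -> ".join(self.cycle))


class UnknownTermError(PhyloAnnotError, KeyError):
    """A GO identifier is absent from the ontology."""

    def __init__(self, term_id: str):
        super().__init__(f"unknown ontology term: {term_id}")
        self.term_id = term_id


class ObsoleteTermError(PhyloAnnotError):
    """An obsolete term was used where a current one is required.

    ``replaced_by`` carries the replacement when the ontology names one.
    """

    def __init__(self, term_id: str, replaced_by: str | None):
        msg = f"term {term_id} is obsolete"
        if replaced_by:
            msg += f" (replaced_by {replaced_by})"
        super().__init__(msg)
        self.term_id = term_id
        self.replaced_by = replaced_by


class UnresolvableTermError(PhyloAnnotError):
    """An obsolete term has no replacement; the caller must drop or re-curate."""

    def __init__(self, term_id: str):
        super().__init__(f"term {term_id} is obsolete with no replacement")
        self.term_id = term_id


class UnknownNodeError(PhyloAnnotError, KeyError):
    """A node or gene identifier is absent from the tree."""

    def __init__(self, node_id: str):
        super().__init__(f"unknown tree node or gene: {node_id}")
        self.node_id = node_id


class TreeStructureError(PhyloAnnotError):
    """The tree violates a structural requirement (duplicate ids, bad leaf...)."""


class GafFormatError(ParseError):
    """A GAF document violates the format contract."""


class RecordValidationError(PhyloAnnotError):
    """An annotation record violates an invariant; names the offending field."""

    def __init__(self, field: str, message: str):
        super().__init__(f"invalid annotation record field '{field}': {message}")
        self.field = field


class AssertionFileError(ParseError):
    """A curator assertion file has a bad reference or enumeration value."""


class ModelInvalidError(PhyloAnnotError):
    """propagate() was handed a model that fails validation; carries them."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(v.message for v in self.violations)
        super().__init__(f"evolutionary model is invalid: {lines}")


class NoEvidenceError(PhyloAnnotError):
    """No experimental presence evidence exists for the queried term."""


class GenerationError(PhyloAnnotError):
    """Synthetic-data parameters are infeasible."""
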