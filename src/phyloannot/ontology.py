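"""GO ontology: OBO parsing and true-path-rule closure queries.

The Gene Ontology arranges terms for molecular functions, biological
processes and cellular components in a directed acyclic graph. Under the
true-path rule, an annotation to a term implies annotations to all of its
ancestors along ``is_a`` and ``part_of`` edges; those two are therefore the
*closure relations* here. Regulates-type relations describe indirect
influence, not participation, and are deliberately ignored.

Obsolete terms stay in the graph (old annotation sets refer to them) but
never participate in closure; :func:`resolve_term` rewrites them through
``replaced_by`` when the ontology names a replacement.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .errors import CycleError, ObsoleteTermError, ParseError, UnknownTermError, UnresolvableTermError

CLOSURE_RELATIONS = ("is_a", "part_of")

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

#: GAF aspect letter for each namespace.
NAMESPACE_TO_ASPECT = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class Term:
    """One ontology term.

    ``replaced_by`` is only meaningful when ``obsolete`` is true; it names the
    current term that absorbed this one (a merge or replacement).
    """

    id: str
    name: str = ""
    namespace: str = "biological_process"
    obsolete: bool = False
    replaced_by: str | None = None


@dataclass
class OntologyGraph:
    """Terms plus (child, parent, relation) edges over the closure relations.

    Edges always point from the more specific term to the more general one,
    so "ancestors" of a term are the more general terms it implies.
    """

    terms: dict[str, Term] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        for child, parent, rel in self.edges:
            if child not in self.terms:
                raise UnknownTermError(child)
            if parent not in self.terms:
                raise UnknownTermError(parent)
            if rel not in CLOSURE_RELATIONS:
                raise ValueError(f"unknown relation {rel!r}")
            # Closure never leaves an obsolete term.
            if self.terms[child].obsolete:
                continue
            self._parents.setdefault(child, set()).add(parent)
            self._children.setdefault(parent, set()).add(child)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, ps in self._parents.items() for p in ps)
        try:
            cycle_edges = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        cycle = [e[0] for e in cycle_edges] + [cycle_edges[-1][1]]
        raise CycleError(cycle)

    # -- queries ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def _require(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def ancestors(self, term_id: str, reflexive: bool = False) -> set[str]:
        """Transitive closure over is_a/part_of, toward the root(s).

        Raises :class:`ObsoleteTermError` for obsolete terms: their closure
        is undefined and callers must resolve them first.
        """
        term = self._require(term_id)
        if term.obsolete:
            raise ObsoleteTermError(term_id, term.replaced_by)
        out = self._reach(term_id, self._parents)
        if reflexive:
            out.add(term_id)
        return out

    def descendants(self, term_id: str, reflexive: bool = False) -> set[str]:
        """All terms whose closure includes ``term_id`` (more specific terms)."""
        term = self._require(term_id)
        if term.obsolete:
            raise ObsoleteTermError(term_id, term.replaced_by)
        out = self._reach(term_id, self._children)
        if reflexive:
            out.add(term_id)
        return out

    @staticmethod
    def _reach(start: str, adjacency: dict[str, set[str]]) -> set[str]:
        seen: set[str] = set()
        queue = deque(adjacency.get(start, ()))
        while queue:
            t = queue.popleft()
            if t in seen:
                continue
            seen.add(t)
            queue.extend(adjacency.get(t, ()))
        return seen

    def implies(self, specific: str, general: str) -> bool:
        """True-path test: does an annotation to ``specific`` imply ``general``?"""
        return specific == general or general in self.ancestors(specific)

    def roots(self) -> set[str]:
        """Non-obsolete terms with no outgoing closure edge."""
        return {
            t for t, term in self.terms.items()
            if not term.obsolete and not self._parents.get(t)
        }

    def lint(self) -> list[str]:
        """Advisory findings: cross-namespace part_of edges (legal, flagged)."""
        notes = []
        for child, parent, rel in sorted(self.edges):
            if rel != "part_of":
                continue
            ns_c = self.terms[child].namespace
            ns_p = self.terms[parent].namespace
            if ns_c != ns_p:
                notes.append(
                    f"cross-namespace part_of: {child} ({ns_c}) part_of "
                    f"{parent} ({ns_p})"
                )
        return notes

    def validate(self) -> list[str]:
        """Invariant check; returns human-readable problems (empty = clean)."""
        problems = []
        for tid, term in self.terms.items():
            if not _GO_ID_RE.match(tid):
                problems.append(f"{tid}: not a GO identifier")
            if term.replaced_by is not None:
                target = self.terms.get(term.replaced_by)
                if target is None:
                    problems.append(f"{tid}: replaced_by {term.replaced_by} not in graph")
                elif target.obsolete:
                    problems.append(f"{tid}: replaced_by {term.replaced_by} is itself obsolete")
        return problems


def resolve_term(graph: OntologyGraph, term_id: str) -> str:
    """Map a possibly-obsolete identifier to a current one.

    Current terms map to themselves; obsolete terms follow ``replaced_by``
    (transitively, in case the replacement was itself later merged).
    Obsolete terms without a replacement raise
    :class:`UnresolvableTermError` — the caller must drop or re-curate.
    """
    seen = set()
    current = term_id
    while True:
        term = graph._require(current)
        if not term.obsolete:
            return current
        if not term.replaced_by:
            raise UnresolvableTermError(current)
        if current in seen:  # defensive: replaced_by loop
            raise UnresolvableTermError(term_id)
        seen.add(current)
        current = term.replaced_by


def ancestors(graph: OntologyGraph, term_id: str, reflexive: bool = False) -> set[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term_id, reflexive=reflexive)


# -- OBO flat file -------------------------------------------------------

def _strip_comment(value: str) -> str:
    # OBO allows trailing "! human readable name" comments on value lines.
    return value.split(" ! ", 1)[0].split("\t!", 1)[0].strip()


def parse_obo(text: str) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are read; ``is_a`` and ``relationship: part_of``
    become closure edges; every other relationship type is ignored.
    A stanza with no ``id`` raises a parse error naming the stanza ordinal
    (1-based, counting ``[Term]`` stanzas only).
    """
    terms: dict[str, Term] = {}
    edges: set[tuple[str, str, str]] = set()

    stanzas: list[list[str]] = []
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("["):
            if line == "[Term]":
                current = []
                stanzas.append(current)
            else:
                current = None  # [Typedef] etc. — skipped
            continue
        if current is not None and line and not line.startswith("!"):
            current.append(line)

    if not stanzas:
        raise ParseError("no [Term] stanza found in OBO document")

    pending_edges: list[tuple[str, str, str]] = []
    for ordinal, stanza in enumerate(stanzas, start=1):
        tid = None
        name = ""
        namespace = "biological_process"
        obsolete = False
        replaced_by = None
        stanza_edges: list[tuple[str, str]] = []
        for line in stanza:
            if ":" not in line:
                raise ParseError(f"malformed line in [Term] stanza #{ordinal}: {line!r}")
            key, _, value = line.partition(":")
            key = key.strip()
            value = value.strip()
            if key == "id":
                tid = _strip_comment(value)
            elif key == "name":
                name = value
            elif key == "namespace":
                namespace = value
            elif key == "is_a":
                stanza_edges.append((_strip_comment(value), "is_a"))
            elif key == "relationship":
                parts = _strip_comment(value).split()
                if len(parts) >= 2 and parts[0] == "part_of":
                    stanza_edges.append((parts[1], "part_of"))
                # other relationship types (regulates, ...) ignored
            elif key == "is_obsolete":
                obsolete = _strip_comment(value).lower() == "true"
            elif key == "replaced_by":
                replaced_by = _strip_comment(value)
        if tid is None:
            raise ParseError(f"[Term] stanza #{ordinal} has no id")
        terms[tid] = Term(id=tid, name=name, namespace=namespace,
                          obsolete=obsolete, replaced_by=replaced_by)
        for parent, rel in stanza_edges:
            pending_edges.append((tid, parent, rel))

    for child, parent, rel in pending_edges:
        if parent not in terms:
            raise ParseError(f"edge references unknown term {parent} (from {child})")
        edges.add((child, parent, rel))

    return OntologyGraph(terms=terms, edges=edges)


def write_obo(graph: OntologyGraph) -> str:
    """Serialize to OBO, bit-stable: stanzas sorted by id, keys in fixed order."""
    out = ["format-version: 1.2", ""]
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in graph.edges:
        by_child.setdefault(child, []).append((rel, parent))
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        out.append("[Term]")
        out.append(f"id: {tid}")
        if term.name:
            out.append(f"name: {term.name}")
        out.append(f"namespace: {term.namespace}")
        for rel, parent in sorted(by_child.get(tid, [])):
            if rel == "is_a":
                out.append(f"is_a: {parent}")
            else:
                out.append(f"relationship: {rel} {parent}")
        if term.obsolete:
            out.append("is_obsolete: true")
        if term.replaced_by:
            out.append(f"replaced_by: {term.replaced_by}")
        out.append("")
    return "\n".join(out) + "\n"
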