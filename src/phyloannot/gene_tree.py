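"""Rooted gene family trees in Newick/NHX with per-node evolutionary events.

A reconciled gene family tree (PANTHER-style) labels every internal node
with the evolutionary event that produced it: a speciation, a gene
duplication, or a horizontal transfer. Gain/loss inference is directional,
so only rooted trees are accepted.

The dialect: standard Newick, with node metadata in NHX comment tags
``[&&NHX:ID=AN12:Ev=D:S=HUMAN]`` and leaf labels of the database-qualified
form ``DB:ACC`` (e.g. ``UniProtKB:P42574``). Note the colon inside leaf
labels — this file carries its own tokenizer because standard Newick
readers parse ``UniProtKB:P42574`` as a label plus branch length. Branch
lengths are parsed and preserved but never used by inference, which is
event-based rather than clock-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParseError, TreeStructureError, UnknownNodeError

EVENTS = ("leaf", "speciation", "duplication", "horizontal_transfer")

_EV_CODE = {"S": "speciation", "D": "duplication", "H": "horizontal_transfer"}
_EV_TO_CODE = {v: k for k, v in _EV_CODE.items()}


@dataclass
class TreeNode:
    node_id: str = ""
    event: str = "leaf"
    species: str | None = None
    gene_id: str | None = None
    branch_length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class GeneTree:
    """A fully indexed rooted family tree.

    ``index`` maps node ids; ``leaf_index`` maps gene ids (``DB:ACC``) and,
    when unambiguous, bare accessions, to leaves.
    """

    def __init__(self, root: TreeNode, family_id: str):
        self.family_id = family_id
        self.root = root
        self.index: dict[str, TreeNode] = {}
        self.leaf_index: dict[str, TreeNode] = {}
        self._preorder_pos: dict[str, int] = {}
        self._assign_ids_and_index()

    def _assign_ids_and_index(self) -> None:
        used = {n.node_id for n in self.root.preorder() if n.node_id}
        counter = 0
        for pos, node in enumerate(self.root.preorder()):
            if not node.node_id:
                while f"AN{counter}" in used:
                    counter += 1
                node.node_id = f"AN{counter}"
                used.add(node.node_id)
            if node.node_id in self.index:
                raise TreeStructureError(f"duplicate node id: {node.node_id}")
            self.index[node.node_id] = node
            self._preorder_pos[node.node_id] = pos
            if node.is_leaf:
                if not node.gene_id:
                    raise TreeStructureError(
                        f"leaf {node.node_id} has no gene accession"
                    )
                if node.gene_id in self.leaf_index:
                    raise TreeStructureError(f"duplicate gene id: {node.gene_id}")
                self.leaf_index[node.gene_id] = node
        # Bare-accession aliases, only where unambiguous.
        aliases: dict[str, TreeNode | None] = {}
        for gid, node in list(self.leaf_index.items()):
            if ":" in gid:
                acc = gid.split(":", 1)[1]
                aliases[acc] = None if acc in aliases else node
        for acc, node in aliases.items():
            if node is not None and acc not in self.leaf_index:
                self.leaf_index[acc] = node

    # -- lookup ----------------------------------------------------------

    def node(self, ident: str) -> TreeNode:
        """Look up by node id, gene id, or bare accession."""
        n = self.index.get(ident) or self.leaf_index.get(ident)
        if n is None:
            raise UnknownNodeError(ident)
        return n

    def preorder_position(self, node_id: str) -> int:
        return self._preorder_pos[self.node(node_id).node_id]

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.preorder() if n.is_leaf]

    # -- queries ---------------------------------------------------------

    def root_path(self, ident: str) -> list[TreeNode]:
        """Path root -> ... -> node, inclusive."""
        node = self.node(ident)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def mrca(self, idents) -> str:
        """Most recent common ancestor of a nonempty set of nodes/genes."""
        idents = list(idents)
        if not idents:
            raise ValueError("mrca of an empty set is undefined")
        paths = [self.root_path(i) for i in idents]
        deepest = None
        for level in zip(*paths):
            first = level[0]
            if all(n is first for n in level):
                deepest = first
            else:
                break
        assert deepest is not None  # all paths share the root
        return deepest.node_id

    def descendants(self, ident: str, leaves_only: bool = False) -> set[str]:
        """Strict descendants of a node (never includes the node itself)."""
        node = self.node(ident)
        out = set()
        for n in node.preorder():
            if n is node:
                continue
            if leaves_only and not n.is_leaf:
                continue
            out.add(n.node_id)
        return out

    def leaf_genes_under(self, ident: str, inclusive: bool = True) -> set[str]:
        """Gene ids of the leaves at-or-below a node."""
        node = self.node(ident)
        return {
            n.gene_id for n in node.preorder()
            if n.is_leaf and (inclusive or n is not node)
        }

    def is_ancestor(self, anc: str, desc: str, reflexive: bool = True) -> bool:
        a, d = self.node(anc), self.node(desc)
        if a is d:
            return reflexive
        while d.parent is not None:
            d = d.parent
            if d is a:
                return True
        return False

    def validate(self) -> list[str]:
        """Soft invariant check (species at leaves, arity) — advisory."""
        problems = []
        for node in self.root.preorder():
            if node.is_leaf:
                if node.event != "leaf":
                    problems.append(f"{node.node_id}: leaf with event {node.event}")
                if not node.species:
                    problems.append(f"{node.node_id}: leaf without species code")
            else:
                if len(node.children) < 2:
                    problems.append(f"{node.node_id}: internal node with one child")
                if node.event == "leaf":
                    problems.append(f"{node.node_id}: internal node with event 'leaf'")
        return problems


# -- Newick/NHX parsing --------------------------------------------------

_LABEL_END = set(",()[;")


def _parse_nhx(comment: str, position: int) -> dict[str, str]:
    if not comment.startswith("&&NHX"):
        return {}
    tags = {}
    body = comment[len("&&NHX"):]
    for chunk in body.split(":"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"malformed NHX tag {chunk!r}", position=position)
        k, _, v = chunk.partition("=")
        tags[k] = v
    return tags


def parse_tree(text: str, family_id: str = "") -> GeneTree:
    """Parse a single rooted Newick/NHX tree.

    Unlabeled internal nodes receive generated ids ``ANn`` in preorder;
    nodes without an ``Ev`` tag default to speciation. Leaf labels must be
    database-qualified accessions ``DB:ACC``; a trailing ``:<number>`` is a
    branch length.
    """
    s = text.strip()
    if not s:
        raise ParseError("empty tree document")
    if not s.endswith(";"):
        raise ParseError("tree does not end with ';'", position=len(s) - 1)
    s = s[:-1]
    pos = 0
    n = len(s)

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < n and s[pos] == "(":
            open_pos = pos
            pos += 1
            while True:
                child = parse_node()
                child.parent = node
                node.children.append(child)
                if pos >= n:
                    raise ParseError("unbalanced parentheses", position=open_pos)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise ParseError(f"unexpected character {s[pos]!r}", position=pos)
        # label / branch length token (may contain ':' inside DB:ACC labels)
        start = pos
        while pos < n and s[pos] not in _LABEL_END:
            pos += 1
        token = s[start:pos].strip()
        label, brlen = _split_label_brlen(token)
        # NHX comment
        tags = {}
        if pos < n and s[pos] == "[":
            close = s.find("]", pos)
            if close == -1:
                raise ParseError("unterminated comment", position=pos)
            tags = _parse_nhx(s[pos + 1:close], pos)
            pos = close + 1
            # branch length may follow the comment in some emitters
            if pos < n and s[pos] == ":":
                start = pos + 1
                pos = start
                while pos < n and s[pos] not in _LABEL_END:
                    pos += 1
                try:
                    brlen = float(s[start:pos])
                except ValueError:
                    raise ParseError("bad branch length", position=start) from None
        node.branch_length = brlen
        node.node_id = tags.get("ID", "")
        if node.children:
            node.event = _EV_CODE.get(tags.get("Ev", "S"))
            if node.event is None:
                raise ParseError(f"unknown Ev code {tags['Ev']!r}", position=start)
            node.species = tags.get("S")
        else:
            node.event = "leaf"
            node.species = tags.get("S")
            if not label:
                raise TreeStructureError("leaf without gene accession")
            if ":" not in label:
                raise TreeStructureError(
                    f"leaf label {label!r} is not a DB:ACC accession"
                )
            node.gene_id = label
        return node

    root = parse_node()
    if pos != n:
        raise ParseError("trailing characters after tree", position=pos)
    if not root.children:
        raise ParseError("single-leaf document is not a rooted family tree")
    return GeneTree(root, family_id=family_id)


def _split_label_brlen(token: str) -> tuple[str, float | None]:
    if not token:
        return "", None
    head, sep, tail = token.rpartition(":")
    if sep:
        try:
            return head, float(tail)
        except ValueError:
            pass  # the colon belongs to a DB:ACC label
    return token, None


def write_tree(tree: GeneTree) -> str:
    """Serialize bit-stably: sorted NHX keys, 6-decimal branch lengths.

    Every node's id is written, so ``parse_tree(write_tree(t))`` reproduces
    ids, events and species exactly.
    """

    def nhx(node: TreeNode) -> str:
        tags = {"ID": node.node_id}
        if not node.is_leaf:
            tags["Ev"] = _EV_TO_CODE[node.event]
        if node.species:
            tags["S"] = node.species
        body = ":".join(f"{k}={tags[k]}" for k in sorted(tags))
        return f"[&&NHX:{body}]"

    def emit(node: TreeNode) -> str:
        if node.is_leaf:
            core = node.gene_id
        else:
            core = "(" + ",".join(emit(c) for c in node.children) + ")"
        if node.branch_length is not None:
            core += f":{node.branch_length:.6f}"
        return core + nhx(node)

    return emit(tree.root) + ";"


def mrca(tree: GeneTree, idents) -> str:
    """Functional alias for :meth:`GeneTree.mrca`."""
    return tree.mrca(idents)


def descendants(tree: GeneTree, ident: str, leaves_only: bool = False) -> set[str]:
    """Functional alias for :meth:`GeneTree.descendants`."""
    return tree.descendants(ident, leaves_only=leaves_only)
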