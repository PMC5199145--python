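"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written against the *data* (edge sets,
parent pointers, record lists), not against the package's query methods, so
agreement is a real two-route check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx


# -- ontology ------------------------------------------------------------

def reachability_ancestors(graph, term_id: str) -> set[str]:
    """Closure via networkx on the raw edge set (skips obsolete sources)."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.terms)
    for child, parent, _rel in graph.edges:
        if not graph.terms[child].obsolete:
            g.add_edge(child, parent)
    return set(nx.descendants(g, term_id))


# -- trees ---------------------------------------------------------------

def ancestor_set(tree, ident: str) -> set[str]:
    node = tree.node(ident)
    out = set()
    while node is not None:
        out.add(node.node_id)
        node = node.parent
    return out


def mrca_by_path_intersection(tree, idents) -> str:
    """Deepest node in the intersection of all root paths."""
    common = None
    for i in idents:
        anc = ancestor_set(tree, i)
        common = anc if common is None else common & anc
    depth = {}
    for nid in common:
        d = 0
        node = tree.node(nid)
        while node.parent is not None:
            d += 1
            node = node.parent
        depth[nid] = d
    return max(sorted(common), key=lambda n: depth[n])


def subtree_nodes(tree, ident: str) -> set[str]:
    """Node + all descendants, by recursive child enumeration."""
    node = tree.node(ident)

    def rec(n):
        out = {n.node_id}
        for c in n.children:
            out |= rec(c)
        return out

    return rec(node)


# -- propagation ---------------------------------------------------------

def iba_targets_oracle(tree, gain_node: str, losses: list[str]) -> set[str]:
    """Strict descendants of the gain minus the union of lost subtrees."""
    targets = subtree_nodes(tree, gain_node) - {gain_node}
    blocked = set()
    for v in losses:
        blocked |= subtree_nodes(tree, v)
    return targets - blocked


def blocking_losses(model, gain, tree, ontology) -> list[str]:
    """Loss nodes that block a given gain, per the term-downward rule."""
    out = []
    for loss in model.losses:
        below = tree.is_ancestor(gain.node_id, loss.node_id, reflexive=False)
        downward = loss.go_id == gain.go_id or loss.go_id in ontology.ancestors(gain.go_id)
        if below and downward:
            out.append(loss.node_id)
    return out


# -- Dollo minimality ----------------------------------------------------

def minimum_loss_set_size(tree, gain_node: str, P: set[str], N: set[str]) -> int | None:
    """Exhaustive search: smallest k such that k loss subtrees strictly below
    the gain cover every N leaf and no P leaf. None if even the full
    candidate set cannot separate them (a P and an N leaf coincide)."""
    p_leaves = {tree.node(g).node_id for g in P}
    # only N leaves inside the gain subtree can (and need to) be covered
    n_leaves = {tree.node(g).node_id for g in N} & subtree_nodes(tree, gain_node)
    sub = {nid: frozenset(subtree_nodes(tree, nid) & n_leaves)
           for nid in subtree_nodes(tree, gain_node) - {gain_node}
           if not (subtree_nodes(tree, nid) & p_leaves)}
    candidates = sorted(sub)
    if not n_leaves:
        return 0
    for k in range(0, len(candidates) + 1):
        for combo in combinations(candidates, k):
            covered = set()
            for v in combo:
                covered |= sub[v]
            if n_leaves <= covered:
                return k
    return None


# -- counting ------------------------------------------------------------

def recount_family_stats(tree, usable_records, inferred) -> dict:
    """Re-derive the nine statistics with plain set/loop arithmetic."""
    leaf_genes = {n.gene_id for n in tree.leaves}
    accs = {g.split(":", 1)[1]: g for g in leaf_genes}
    known = []
    for r in usable_records:
        g = f"{r.db}:{r.object_id}"
        if g in leaf_genes:
            known.append((g, r.go_id))
        elif r.object_id in accs:
            known.append((accs[r.object_id], r.go_id))
    ibd = [a for a in inferred if a.evidence == "IBD"]
    iba = [a for a in inferred if a.evidence == "IBA" and not a.negated]
    return {
        "family_id": tree.family_id,
        "protein_count": len(leaf_genes),
        "exp_proteins": len({g for g, _ in known}),
        "exp_annotations": len(known),
        "exp_terms": len({t for _, t in known}),
        "annotated_proteins": len({a.target_gene for a in iba if a.target_gene}),
        "ibd_count": len(ibd),
        "iba_count": len(iba),
        "inferred_terms": len({a.go_id for a in ibd}),
    }


def recount_new_annotations(tree, usable_records, inferred, ontology) -> set[tuple[str, str]]:
    """Brute-force set difference for the new-annotation definition."""
    leaf_genes = {n.gene_id for n in tree.leaves}
    exp_pairs = set()
    for r in usable_records:
        g = f"{r.db}:{r.object_id}"
        if g not in leaf_genes:
            continue
        # experimental support covers the term and everything it implies
        if r.go_id in ontology.terms and not ontology.terms[r.go_id].obsolete:
            for t in ontology.ancestors(r.go_id, reflexive=True):
                exp_pairs.add((g, t))
    out = set()
    for a in inferred:
        if a.evidence == "IBA" and not a.negated and a.target_gene:
            if (a.target_gene, a.go_id) not in exp_pairs:
                out.add((a.target_gene, a.go_id))
    return out
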