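import numpy as np
import pytest

from phyloannot import (
    EvolutionaryModel,
    GainEvent,
    LossEvent,
    detect_conflicts,
    parse_assertions,
    presence_sets,
    propagate,
    suggest_model,
    validate_model,
    write_assertions,
)
from phyloannot.errors import AssertionFileError, ModelInvalidError, NoEvidenceError
from phyloannot.synthetic import SimParams, simulate_family, _simulate_ontology, _simulate_tree

from conftest import T0, T1, T2, OBSOLETE_MERGED, ida
from oracles import blocking_losses, iba_targets_oracle, minimum_loss_set_size


class TestParseAssertions:
    def test_single_gain(self, fixture_tree, chain_ontology):
        model = parse_assertions(f"GAIN\tAN1\t{T2}\tHUM1\n", fixture_tree, chain_ontology)
        assert len(model.gains) == 1 and not model.losses
        assert model.gains[0].node_id == "AN1"

    def test_gain_then_loss(self, fixture_tree, chain_ontology):
        text = f"GAIN\tAN1\t{T2}\tHUM1\nLOSS\tMUS1\t{T2}\tRAPID_DIVERGENCE\n"
        model = parse_assertions(text, fixture_tree, chain_ontology)
        assert len(model.losses) == 1
        assert model.losses[0].cause == "RAPID_DIVERGENCE"

    def test_gain_not_dominating_support_is_reference_error(self, fixture_tree, chain_ontology):
        with pytest.raises(AssertionFileError, match="not ancestral"):
            parse_assertions(f"GAIN\tAN1\t{T2}\tDRO1\n", fixture_tree, chain_ontology)

    def test_unknown_node_names_line(self, fixture_tree, chain_ontology):
        with pytest.raises(AssertionFileError, match="line 2"):
            parse_assertions(f"# comment\nGAIN\tNOPE\t{T2}\tHUM1\n",
                             fixture_tree, chain_ontology)

    def test_bad_cause_is_enumeration_error(self, fixture_tree, chain_ontology):
        with pytest.raises(AssertionFileError, match="cause"):
            parse_assertions(f"LOSS\tMUS1\t{T2}\tBECAUSE\n", fixture_tree, chain_ontology)

    def test_obsolete_term_rewritten_via_replaced_by(self, fixture_tree, chain_ontology):
        model = parse_assertions(f"GAIN\tAN1\t{OBSOLETE_MERGED}\tHUM1\n",
                                 fixture_tree, chain_ontology)
        assert model.gains[0].go_id == T1

    def test_write_parse_round_trip(self, fixture_tree, chain_ontology):
        text = f"GAIN\tAN1\t{T2}\tA:HUM1\nLOSS\tMUS1\t{T2}\tKEY_RESIDUES\n"
        model = parse_assertions(text, fixture_tree, chain_ontology)
        model2 = parse_assertions(write_assertions(model), fixture_tree, chain_ontology)
        assert model2 == model


class TestValidateModel:
    def test_valid_single_gain(self, fixture_tree, chain_ontology, single_gain_model, hum1_records):
        assert validate_model(single_gain_model, fixture_tree, chain_ontology,
                              hum1_records) == []

    def test_support_via_descendant_term_counts(self, fixture_tree, chain_ontology):
        # evidence at t2 supports a gain asserted at the more general t1
        model = EvolutionaryModel("F", gains=[GainEvent("AN1", T1, ["A:HUM1"])])
        assert validate_model(model, fixture_tree, chain_ontology,
                              [ida("A:HUM1", T2)]) == []

    def test_gain_without_usable_evidence(self, fixture_tree, chain_ontology, single_gain_model):
        # an IEA record is not experimental support
        violations = validate_model(single_gain_model, fixture_tree, chain_ontology,
                                    [ida("A:HUM1", T2, evidence_code="IEA")])
        assert any(v.rule == "unsupported_gain" for v in violations)

    def test_nested_same_term_gains(self, fixture_tree, chain_ontology, hum1_records):
        model = EvolutionaryModel("F", gains=[
            GainEvent("AN0", T2, ["A:HUM1"]),
            GainEvent("AN1", T2, ["A:HUM1"]),
        ])
        violations = validate_model(model, fixture_tree, chain_ontology, hum1_records)
        assert any(v.rule == "nested_gain" for v in violations)

    def test_disjoint_same_term_gains_allowed(self, fixture_tree, chain_ontology):
        mus1 = fixture_tree.node("MUS1").node_id
        dro1 = fixture_tree.node("DRO1").node_id
        model = EvolutionaryModel("F", gains=[
            GainEvent(mus1, T2, ["B:MUS1"]),
            GainEvent(dro1, T2, ["C:DRO1"]),
        ])
        records = [ida("B:MUS1", T2), ida("C:DRO1", T2)]
        assert validate_model(model, fixture_tree, chain_ontology, records) == []

    def test_loss_needs_matching_gain_below_it(self, fixture_tree, chain_ontology, hum1_records):
        model = EvolutionaryModel("F",
            gains=[GainEvent("AN1", T2, ["A:HUM1"])],
            losses=[LossEvent("DRO1", T2)])  # DRO1 is not below AN1
        violations = validate_model(model, fixture_tree, chain_ontology, hum1_records)
        assert any(v.rule == "loss_without_gain" for v in violations)

    def test_loss_of_ancestor_term_matches(self, fixture_tree, chain_ontology, hum1_records):
        # losing the general t1 below a gain of the specific t2 is legal
        model = EvolutionaryModel("F",
            gains=[GainEvent("AN1", T2, ["A:HUM1"])],
            losses=[LossEvent(fixture_tree.node("MUS1").node_id, T1)])
        assert validate_model(model, fixture_tree, chain_ontology, hum1_records) == []


class TestPresenceSets:
    def test_true_path_pulls_descendant_evidence(self, fixture_tree, chain_ontology):
        ev = presence_sets(fixture_tree, [ida("A:HUM1", T2)], chain_ontology, T1)
        assert ev.P == {"A:HUM1"}

    def test_negation_propagates_downward(self, fixture_tree, chain_ontology):
        recs = [ida("B:MUS1", T1, evidence_code="IMP", negated=True)]
        ev = presence_sets(fixture_tree, recs, chain_ontology, T2)
        assert ev.N == {"B:MUS1"} and not ev.P

    def test_conflicting_leaf_stays_positive_and_flagged(self, fixture_tree, chain_ontology):
        recs = [ida("A:HUM1", T2), ida("A:HUM1", T2, evidence_code="IMP", negated=True)]
        ev = presence_sets(fixture_tree, recs, chain_ontology, T2)
        assert ev.P == {"A:HUM1"} and not ev.N
        assert ev.conflicting == {"A:HUM1"}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan(self, seed):
        from phyloannot.synthetic import simulate_annotations
        params = SimParams(n_leaves=30, p_observe=0.6, p_negative=0.3,
                           p_false_positive=0.1, seed=seed)
        tree, ontology, truth = simulate_family(params)
        records = simulate_annotations(tree, ontology, truth, params)
        ev = presence_sets(tree, records, ontology, truth.term)
        # brute force: scan records x closure directly
        P, N = set(), set()
        for r in records:
            gene = f"{r.db}:{r.object_id}"
            if gene not in tree.leaf_index:
                continue
            if r.evidence_code in {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"}:
                up = ontology.ancestors(r.go_id, reflexive=True)
                if not r.negated and truth.term in up:
                    P.add(gene)
                if r.negated and truth.term in ontology.descendants(r.go_id, reflexive=True):
                    N.add(gene)
        assert ev.P == P
        assert ev.N == N - P


class TestSuggestModel:
    def test_clean_pair_gain_at_mrca_no_losses(self, fixture_tree):
        s = suggest_model(fixture_tree, {"A:HUM1", "B:MUS1"}, set(), T2)
        assert s.model.gains[0].node_id == "AN1"
        assert not s.model.losses
        assert s.alternates == ["AN0"]
        assert not s.flags

    def test_negative_evidence_places_loss(self, fixture_tree):
        s = suggest_model(fixture_tree, {"A:HUM1", "C:DRO1"}, {"B:MUS1"}, T2)
        assert s.model.gains[0].node_id == "AN0"
        assert [l.node_id for l in s.model.losses] == [fixture_tree.node("MUS1").node_id]
        assert s.model.losses[0].cause == "UNSPECIFIED"

    def test_absence_without_negation_is_not_loss(self, fixture_tree):
        s = suggest_model(fixture_tree, {"A:HUM1", "C:DRO1"}, set(), T2)
        assert s.model.gains[0].node_id == "AN0"
        assert not s.model.losses  # MUS1 is merely unobserved

    def test_single_support_flagged(self, fixture_tree):
        s = suggest_model(fixture_tree, {"A:HUM1"}, set(), T2)
        assert "single-support" in s.flags

    def test_empty_presence_raises(self, fixture_tree):
        with pytest.raises(NoEvidenceError):
            suggest_model(fixture_tree, set(), set(), T2)

    @pytest.mark.parametrize("seed", range(25))
    def test_loss_set_is_minimum_cardinality(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(4, 13))
        tree = _simulate_tree(SimParams(n_leaves=n_leaves, seed=seed), "F")
        genes = [n.gene_id for n in tree.leaves]
        rng.shuffle(genes)
        n_p = int(rng.integers(2, max(3, len(genes) - 1)))
        P = set(genes[:n_p])
        N = set(g for g in genes[n_p:] if rng.random() < 0.5)
        s = suggest_model(tree, P, N, T2)
        g = s.model.gains[0].node_id
        assert len(s.model.losses) == minimum_loss_set_size(tree, g, P, N)
        # the suggested losses really do exclude all N below g and none of P
        blocked = set()
        for l in s.model.losses:
            blocked |= tree.descendants(l.node_id) | {l.node_id}
        p_ids = {tree.node(x).node_id for x in P}
        n_ids = {tree.node(x).node_id for x in N}
        assert not (blocked & p_ids)
        assert n_ids & set(tree.descendants(g)) <= blocked


class TestPropagate:
    def test_worked_fixture_no_loss(self, fixture_tree, chain_ontology, single_gain_model):
        inf = propagate(single_gain_model, fixture_tree, chain_ontology)
        by_ev = {(a.evidence, a.target_gene or a.target) for a in inf}
        assert by_ev == {("IBD", "AN1"), ("IBA", "A:HUM1"), ("IBA", "B:MUS1")}
        assert all(a.gain_node == "AN1" for a in inf)
        assert all(a.supporting_leaves == ["A:HUM1"] for a in inf)

    def test_worked_fixture_with_loss(self, fixture_tree, chain_ontology, single_gain_model):
        single_gain_model.losses.append(
            LossEvent(fixture_tree.node("MUS1").node_id, T2, "RAPID_DIVERGENCE"))
        inf = propagate(single_gain_model, fixture_tree, chain_ontology)
        assert [(a.evidence, a.target_gene or a.target, a.negated) for a in inf] == [
            ("IBD", "AN1", False),
            ("IBA", "A:HUM1", False),
            ("IRD", "B:MUS1", True),
        ]

    def test_unspecified_and_key_residue_losses_use_ikr(self, fixture_tree, chain_ontology,
                                                        single_gain_model):
        mus1 = fixture_tree.node("MUS1").node_id
        for cause in ("KEY_RESIDUES", "UNSPECIFIED"):
            model = EvolutionaryModel("F", gains=list(single_gain_model.gains),
                                      losses=[LossEvent(mus1, T2, cause)])
            inf = propagate(model, fixture_tree, chain_ontology)
            assert any(a.evidence == "IKR" and a.negated for a in inf)

    def test_loss_of_ancestor_term_blocks_specific_gain(self, fixture_tree, chain_ontology):
        mus1 = fixture_tree.node("MUS1").node_id
        model = EvolutionaryModel("F",
            gains=[GainEvent("AN1", T2, ["A:HUM1"])],
            losses=[LossEvent(mus1, T1)])  # ancestor term lost below
        inf = propagate(model, fixture_tree, chain_ontology)
        iba_targets = {a.target_gene for a in inf if a.evidence == "IBA"}
        assert iba_targets == {"A:HUM1"}

    def test_sibling_term_loss_does_not_block(self, fixture_tree):
        # t_b is not an ancestor of t_a, so its loss cannot block t_a
        from phyloannot.ontology import OntologyGraph, Term
        onto = OntologyGraph(
            terms={t: Term(id=t) for t in ("GO:0000001", "GO:0000002", "GO:0000003")},
            edges={("GO:0000002", "GO:0000001", "is_a"),
                   ("GO:0000003", "GO:0000001", "is_a")})
        mus1 = fixture_tree.node("MUS1").node_id
        model = EvolutionaryModel("F",
            gains=[GainEvent("AN1", "GO:0000002", ["A:HUM1"]),
                   GainEvent("AN1", "GO:0000003", ["A:HUM1"])],
            losses=[LossEvent(mus1, "GO:0000003")])
        inf = propagate(model, fixture_tree, onto)
        t2_iba = {a.target_gene for a in inf if a.evidence == "IBA" and a.go_id == "GO:0000002"}
        assert t2_iba == {"A:HUM1", "B:MUS1"}

    def test_invalid_model_rejected_with_violations(self, fixture_tree, chain_ontology):
        model = EvolutionaryModel("F", gains=[GainEvent("AN1", T2, ["A:HUM1"])],
                                  losses=[LossEvent("DRO1", T2)])
        with pytest.raises(ModelInvalidError) as err:
            propagate(model, fixture_tree, chain_ontology)
        assert any(v.rule == "loss_without_gain" for v in err.value.violations)

    def test_idempotent_output(self, fixture_tree, chain_ontology, single_gain_model):
        a = propagate(single_gain_model, fixture_tree, chain_ontology)
        b = propagate(single_gain_model, fixture_tree, chain_ontology)
        assert a == b

    def test_hgt_paths_tagged(self, chain_ontology):
        from phyloannot import parse_tree
        nwk = ("((A:H1[&&NHX:S=SP1],B:H2[&&NHX:S=SP2])[&&NHX:ID=AN1:Ev=H],"
               "C:H3[&&NHX:S=SP3])[&&NHX:ID=AN0:Ev=S];")
        tree = parse_tree(nwk, "F")
        model = EvolutionaryModel("F", gains=[GainEvent("AN0", T2, ["A:H1"])])
        inf = propagate(model, tree, chain_ontology)
        tagged = {a.target_gene or a.target: a.via_hgt
                  for a in inf if a.evidence == "IBA"}
        assert tagged["AN1"] and tagged["A:H1"] and tagged["B:H2"]
        assert not tagged["C:H3"]

    @pytest.mark.parametrize("seed", range(30))
    def test_iba_targets_match_reachability_oracle(self, seed):
        tree, ontology, model = random_family_model(seed)
        inf = propagate(model, tree, ontology)
        for gain in model.gains:
            got = {a.target for a in inf
                   if a.evidence == "IBA" and a.gain_node == gain.node_id
                   and a.go_id == gain.go_id}
            expected = iba_targets_oracle(
                tree, gain.node_id, blocking_losses(model, gain, tree, ontology))
            assert got == expected
            # conservation: exactly one IBD per gain
            assert sum(1 for a in inf if a.evidence == "IBD"
                       and a.gain_node == gain.node_id and a.go_id == gain.go_id) == 1


def random_family_model(seed, max_nodes=200, max_gains=5, max_losses=5):
    """A random valid-shaped model on a random tree and ontology."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(4, (max_nodes + 1) // 2 + 1))
    tree = _simulate_tree(SimParams(n_leaves=n_leaves, seed=seed), f"F{seed}")
    ontology, _ = _simulate_ontology(SimParams(n_leaves=2, n_terms=15, seed=seed))
    terms = sorted(ontology.terms)
    internals = [n.node_id for n in tree.root.preorder() if not n.is_leaf]
    gains = []
    for _ in range(int(rng.integers(1, max_gains + 1))):
        node = internals[int(rng.integers(len(internals)))]
        term = terms[int(rng.integers(len(terms)))]
        if any(g.go_id == term and (tree.is_ancestor(g.node_id, node)
                                    or tree.is_ancestor(node, g.node_id))
               for g in gains):
            continue  # would be a nested same-term gain
        support = sorted(tree.leaf_genes_under(node))[:3]
        gains.append(GainEvent(node, term, support))
    losses = []
    for _ in range(int(rng.integers(0, max_losses + 1))):
        gain = gains[int(rng.integers(len(gains)))]
        below = sorted(tree.descendants(gain.node_id))
        if not below:
            continue
        node = below[int(rng.integers(len(below)))]
        anc = sorted(ontology.ancestors(gain.go_id, reflexive=True))
        term = anc[int(rng.integers(len(anc)))]
        losses.append(LossEvent(node, term))
    return tree, ontology, EvolutionaryModel(f"F{seed}", gains=gains, losses=losses)


class TestDetectConflicts:
    def test_negative_evidence_under_propagation(self, fixture_tree, chain_ontology,
                                                 single_gain_model):
        inf = propagate(single_gain_model, fixture_tree, chain_ontology)
        # IBA of t2 lands on MUS1, which carries NOT to the ancestor t1
        recs = [ida("B:MUS1", T1, evidence_code="IMP", negated=True)]
        conflicts = detect_conflicts(inf, recs, fixture_tree, chain_ontology)
        assert len(conflicts) == 1
        assert conflicts[0].rule == "negative_evidence_under_propagation"
        assert conflicts[0].gene_id == "B:MUS1"

    def test_experimental_evidence_under_loss(self, fixture_tree, chain_ontology,
                                              single_gain_model):
        single_gain_model.losses.append(
            LossEvent(fixture_tree.node("MUS1").node_id, T2, "KEY_RESIDUES"))
        inf = propagate(single_gain_model, fixture_tree, chain_ontology)
        recs = [ida("B:MUS1", T2)]
        conflicts = detect_conflicts(inf, recs, fixture_tree, chain_ontology)
        assert len(conflicts) == 1
        assert conflicts[0].rule == "experimental_evidence_under_loss"

    def test_consistent_fixture_has_none(self, fixture_tree, chain_ontology,
                                         single_gain_model, hum1_records):
        inf = propagate(single_gain_model, fixture_tree, chain_ontology)
        assert detect_conflicts(inf, hum1_records, fixture_tree, chain_ontology) == []


def test_suggest_then_propagate_covers_all_positive_leaves(fixture_tree):
    """Soundness: after suggestion, IBA reaches every supporting leaf."""
    from phyloannot.ontology import OntologyGraph, Term
    onto = OntologyGraph(terms={T2: Term(id=T2)}, edges=set())
    s = suggest_model(fixture_tree, {"A:HUM1", "C:DRO1"}, {"B:MUS1"}, T2)
    inf = propagate(s.model, fixture_tree, onto)
    iba_genes = {a.target_gene for a in inf if a.evidence == "IBA" and a.target_gene}
    assert {"A:HUM1", "C:DRO1"} <= iba_genes
    assert "B:MUS1" not in iba_genes
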