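import pytest

from phyloannot import (
    AnnotationRecord,
    EvolutionaryModel,
    GainEvent,
    parse_obo,
    parse_tree,
)

FIXTURE_NEWICK = (
    "((A:HUM1[&&NHX:S=HUMAN],B:MUS1[&&NHX:S=MOUSE])[&&NHX:ID=AN1:Ev=D],"
    "C:DRO1[&&NHX:S=DROME])[&&NHX:ID=AN0:Ev=S];"
)

CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: t0
namespace: biological_process

[Term]
id: GO:0000002
name: t1
namespace: biological_process
is_a: GO:0000001 ! t0

[Term]
id: GO:0000003
name: t2
namespace: biological_process
is_a: GO:0000002 ! t1

[Term]
id: GO:0000044
name: dead term
namespace: biological_process
is_obsolete: true
replaced_by: GO:0000002

[Term]
id: GO:0000055
name: dead end
namespace: biological_process
is_obsolete: true
"""

T0, T1, T2 = "GO:0000001", "GO:0000002", "GO:0000003"
OBSOLETE_MERGED, OBSOLETE_DEAD = "GO:0000044", "GO:0000055"


@pytest.fixture
def fixture_tree():
    """The 3-leaf worked fixture: ((HUM1,MUS1)AN1,DRO1)AN0."""
    return parse_tree(FIXTURE_NEWICK, "PTHRTEST")


@pytest.fixture
def chain_ontology():
    """t2 is_a t1 is_a t0, plus an obsolete-merged and a dead-end term."""
    return parse_obo(CHAIN_OBO)


def ida(gene_id: str, go_id: str, **kw) -> AnnotationRecord:
    db, _, acc = gene_id.partition(":")
    kw.setdefault("evidence_code", "IDA")
    kw.setdefault("references", ["PMID:1"])
    return AnnotationRecord(db=db, object_id=acc, symbol=acc, go_id=go_id, **kw)


@pytest.fixture
def hum1_records():
    return [ida("A:HUM1", T2)]


@pytest.fixture
def single_gain_model():
    return EvolutionaryModel(
        "PTHRTEST", gains=[GainEvent("AN1", T2, ["A:HUM1"], references=["PMID:1"])])
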