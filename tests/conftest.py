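import pytest

from edgetic.knowledgebase import KnowledgeBase


def make_kb(entities, reactions=(), pathways=()):
    """Build a validated KnowledgeBase from plain dicts."""
    return KnowledgeBase.from_dict(
        {"entities": entities, "reactions": list(reactions), "pathways": list(pathways)}
    )


def protein(acc, name=None):
    return {"id": f"E:{acc}", "kind": "protein", "accession": acc, "name": name or acc}


def chemical(cid, name):
    return {"id": f"E:{cid}", "kind": "chemical", "accession": cid, "name": name}


def complex_(cid, members):
    return {"id": cid, "kind": "complex", "name": cid, "components": list(members)}


def entity_set(sid, members):
    return {"id": sid, "kind": "entity_set", "name": sid, "components": list(members)}


@pytest.fixture
def tp53_family_kb():
    """The in-text worked example: one reaction whose outputs are the four
    complexes TP63:PPP1R13B, TP73:PPP1R13B, TP53:PPP1R13B and TP53:TP53BP2."""
    prots = ["TP53", "TP63", "TP73", "PPP1R13B", "TP53BP2"]
    entities = [protein(p) for p in prots] + [
        complex_("CX1", ["E:TP63", "E:PPP1R13B"]),
        complex_("CX2", ["E:TP73", "E:PPP1R13B"]),
        complex_("CX3", ["E:TP53", "E:PPP1R13B"]),
        complex_("CX4", ["E:TP53", "E:TP53BP2"]),
    ]
    reactions = [
        {
            "id": "R1",
            "name": "TP53 family members bind PPP1R13B or TP53BP2",
            "inputs": [f"E:{p}" for p in prots],
            "outputs": ["CX1", "CX2", "CX3", "CX4"],
        }
    ]
    return make_kb(entities, reactions)


@pytest.fixture
def toy_kb():
    """Small hand-countable KB: 3 proteins, 1 chemical, 1 complex,
    2 reactions, 2-level pathway hierarchy."""
    entities = [
        protein("P1"),
        protein("P2"),
        protein("P3"),
        chemical("CHEBI:1", "CHEM1"),
        complex_("CX", ["E:P1", "E:P2"]),
    ]
    reactions = [
        {"id": "R1", "inputs": ["E:P1", "E:P2"], "outputs": ["CX"]},
        {"id": "R2", "inputs": ["CX", "E:CHEBI:1"], "outputs": ["E:P3"],
         "catalysts": ["E:P3"]},
    ]
    pathways = [
        {"id": "T", "child_pathway_ids": ["L"], "reaction_ids": []},
        {"id": "L", "parent_pathway_id": "T", "reaction_ids": ["R1", "R2"]},
    ]
    return make_kb(entities, reactions, pathways)


@pytest.fixture
def chain_kb():
    """Five reactions wired so the hand-derived reaction-network edge list
    is {(r1,r2), (r3,r4), (r4,r5), (r5,r2)}; the r2->r3 link runs only
    through ATP and must be removed by currency filtering."""
    entities = [
        protein("A"),
        protein("Y"),
        chemical("CHEBI:ATP", "ATP"),
        complex_("X", ["E:A", "E:Y"]),
        complex_("Z", ["E:A", "E:Y"]),
    ]
    reactions = [
        {"id": "r1", "inputs": ["E:A"], "outputs": ["X"]},
        {"id": "r2", "inputs": ["X"], "outputs": ["E:CHEBI:ATP"]},
        {"id": "r3", "inputs": ["E:CHEBI:ATP"], "outputs": ["E:Y"]},
        {"id": "r4", "inputs": ["E:A"], "outputs": ["Z"], "catalysts": ["E:Y"]},
        {"id": "r5", "inputs": ["E:A"], "outputs": ["X"], "regulators": ["Z"]},
    ]
    return make_kb(entities, reactions)


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
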