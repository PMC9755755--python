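import json

import pytest
from hypothesis import given, settings, strategies as st

from edgetic.knowledgebase import (
    CyclicCompositionError,
    CyclicPathwayError,
    DuplicateIdError,
    KnowledgeBase,
    MissingReferenceError,
    build_reaction_network,
    extract_functional_interactions,
    load_kb,
    rollup_pathways,
    write_sif,
)

from conftest import chemical, complex_, entity_set, make_kb, protein


def fi_pairs(fis):
    return {(fi.a, fi.b) for fi in fis}


class TestLoadAndValidate:
    def test_empty_document(self, tmp_path):
        p = tmp_path / "kb.json"
        p.write_text(json.dumps({"entities": [], "reactions": [], "pathways": []}))
        kb = load_kb(p)
        assert len(kb.reactions) == 0

    def test_toy_fixture_counts(self, toy_kb, tmp_path):
        p = tmp_path / "kb_toy.json"
        toy_kb.save(p)
        kb = load_kb(p)
        assert len(kb.reactions) == 2
        tops = [pw for pw in kb.pathways.values() if not pw.parent_pathway_id]
        assert len(tops) == 1 and tops[0].id == "T"

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_kb(tmp_path / "nope.json")

    def test_dangling_reference_names_offender(self):
        with pytest.raises(MissingReferenceError, match="P_X"):
            make_kb([protein("P1"), complex_("CX", ["E:P1", "P_X"])])

    def test_cyclic_complex(self):
        doc = {
            "entities": [
                {"id": "A", "kind": "complex", "components": ["B"]},
                {"id": "B", "kind": "complex", "components": ["A"]},
            ],
            "reactions": [],
            "pathways": [],
        }
        with pytest.raises(CyclicCompositionError):
            KnowledgeBase.from_dict(doc)

    def test_cyclic_pathways(self):
        doc = {
            "entities": [],
            "reactions": [],
            "pathways": [
                {"id": "A", "parent_pathway_id": "B", "child_pathway_ids": ["B"]},
                {"id": "B", "parent_pathway_id": "A", "child_pathway_ids": ["A"]},
            ],
        }
        with pytest.raises(CyclicPathwayError):
            KnowledgeBase.from_dict(doc)

    def test_duplicate_id(self):
        with pytest.raises(DuplicateIdError):
            make_kb([protein("P1"), protein("P1")])


class TestExtractFunctionalInteractions:
    def test_tp53_family_expansion(self, tp53_family_kb):
        """The four-complex binding reaction expands into exactly four FIs."""
        fis = extract_functional_interactions(tp53_family_kb)
        assert fi_pairs(fis) == {
            ("PPP1R13B", "TP63"),
            ("PPP1R13B", "TP73"),
            ("PPP1R13B", "TP53"),
            ("TP53", "TP53BP2"),
        }
        assert all(fi.source_reaction_ids == frozenset({"R1"}) for fi in fis)

    def test_free_proteins_yield_nothing(self):
        kb = make_kb(
            [protein("P1"), protein("P2")],
            [{"id": "R1", "inputs": ["E:P1"], "outputs": ["E:P2"]}],
        )
        assert extract_functional_interactions(kb) == set()

    def test_kinase_reaction_manual_enumeration(self):
        """catalyst K, inputs {S, ATP}, output complex S:P: rule (a) gives
        P-S, rule (b) gives K-S and ATP-K, rule (c) nothing."""
        kb = make_kb(
            [
                protein("K"),
                protein("S"),
                protein("P"),
                chemical("CHEBI:ATP", "ATP"),
                complex_("SP", ["E:S", "E:P"]),
            ],
            [
                {
                    "id": "R1",
                    "inputs": ["E:S", "E:CHEBI:ATP"],
                    "outputs": ["SP"],
                    "catalysts": ["E:K"],
                }
            ],
        )
        fis = extract_functional_interactions(kb)
        assert fi_pairs(fis) == {("P", "S"), ("K", "S"), ("CHEBI:ATP", "K")}
        kinds = {fi.pair: fi.fi_kind for fi in fis}
        assert kinds[("CHEBI:ATP", "K")] == "protein_chemical"
        assert kinds[("P", "S")] == "protein_protein"

    def test_set_members_are_alternatives(self):
        """Members of one entity set are never paired with each other, but
        each pairs with the rest of the containing complex."""
        kb = make_kb(
            [
                protein("A"),
                protein("B"),
                protein("C"),
                entity_set("S1", ["E:A", "E:B"]),
                complex_("CX", ["S1", "E:C"]),
            ],
            [{"id": "R1", "inputs": [], "outputs": ["CX"]}],
        )
        assert fi_pairs(extract_functional_interactions(kb)) == {("A", "C"), ("B", "C")}

    def test_chemical_chemical_discarded(self):
        kb = make_kb(
            [
                chemical("CHEBI:1", "c1"),
                chemical("CHEBI:2", "c2"),
                complex_("CX", ["E:CHEBI:1", "E:CHEBI:2"]),
            ],
            [{"id": "R1", "outputs": ["CX"], "inputs": []}],
        )
        assert extract_functional_interactions(kb) == set()

    def test_toy_kb_fis_and_sources(self, toy_kb):
        fis = {fi.pair: fi for fi in extract_functional_interactions(toy_kb)}
        assert set(fis) == {("P1", "P2"), ("P1", "P3"), ("P2", "P3"), ("CHEBI:1", "P3")}
        assert fis[("P1", "P2")].source_reaction_ids == frozenset({"R1", "R2"})

    def test_extraction_invariant_under_reaction_order(self, toy_kb):
        doc = toy_kb.to_dict()
        doc["reactions"] = doc["reactions"][::-1]
        kb2 = KnowledgeBase.from_dict(doc)
        assert extract_functional_interactions(kb2) == extract_functional_interactions(
            toy_kb
        )

    def test_fi_reaction_maps_mutually_consistent(self, toy_kb):
        from edgetic.knowledgebase import _reaction_fis

        fis = extract_functional_interactions(toy_kb)
        for fi in fis:
            for rid, rxn in toy_kb.reactions.items():
                per_rxn = {(a, b) for a, b, _k in _reaction_fis(toy_kb, rxn)}
                assert (rid in fi.source_reaction_ids) == (fi.pair in per_rxn)


class TestReactionNetwork:
    def test_chain_fixture_edges(self, chain_kb):
        net = build_reaction_network(chain_kb)
        assert net.edges == {("r1", "r2"), ("r3", "r4"), ("r4", "r5"), ("r5", "r2")}

    def test_currency_only_link_produces_no_edge(self, chain_kb):
        net = build_reaction_network(chain_kb)
        assert ("r2", "r3") not in net.edges

    def test_complex_output_to_catalyst_edge(self, chain_kb):
        assert ("r3", "r4") in build_reaction_network(chain_kb).edges

    def test_currency_edges_subset_of_unfiltered(self, chain_kb, toy_kb):
        for kb in (chain_kb, toy_kb):
            filtered = build_reaction_network(kb).edges
            unfiltered = build_reaction_network(kb, frozenset()).edges
            assert filtered <= unfiltered

    def test_sif_export(self, chain_kb, tmp_path):
        net = build_reaction_network(chain_kb)
        p = tmp_path / "net.sif"
        write_sif(net, p)
        lines = set(p.read_text().splitlines())
        assert "r1\tprecedes\tr2" in lines
        assert len(lines) == len(net.edges)


class TestRollup:
    def test_two_level(self, toy_kb):
        rollup = rollup_pathways(toy_kb)
        assert rollup["R1"] == {("L", "T"), ("T", "T")}

    def test_reaction_in_no_pathway(self):
        kb = make_kb(
            [protein("P1")],
            [{"id": "R1", "inputs": ["E:P1"], "outputs": []}],
        )
        assert rollup_pathways(kb)["R1"] == set()

    def test_three_level_transitive_closure(self):
        kb = make_kb(
            [protein("P1")],
            [
                {"id": "Ra", "inputs": ["E:P1"], "outputs": []},
                {"id": "Rb", "inputs": ["E:P1"], "outputs": []},
            ],
            [
                {"id": "T", "child_pathway_ids": ["M"]},
                {"id": "M", "parent_pathway_id": "T", "child_pathway_ids": ["L"],
                 "reaction_ids": ["Rb"]},
                {"id": "L", "parent_pathway_id": "M", "reaction_ids": ["Ra"]},
            ],
        )
        rollup = rollup_pathways(kb)
        assert rollup["Ra"] == {("L", "T"), ("M", "T"), ("T", "T")}
        assert rollup["Rb"] == {("M", "T"), ("T", "T")}


@st.composite
def nested_complex_kb(draw):
    """Random acyclic composition: leaves are proteins, containers reference
    only earlier-defined entities (guaranteeing acyclicity)."""
    n_leaves = draw(st.integers(2, 6))
    entities = [protein(f"P{i}") for i in range(n_leaves)]
    ids = [e["id"] for e in entities]
    n_containers = draw(st.integers(1, 5))
    for j in range(n_containers):
        members = draw(
            st.lists(st.sampled_from(ids), min_size=2, max_size=4, unique=True)
        )
        kind = draw(st.sampled_from(["complex", "entity_set"]))
        cid = f"C{j}"
        entities.append(
            {"id": cid, "kind": kind, "name": cid, "components": members}
        )
        ids.append(cid)
    return make_kb(entities), ids[-1]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(nested_complex_kb())
def test_flattening_terminates_and_counts_leaf_paths(case):
    """Flattening any acyclic composition terminates and yields one leaf
    entry per distinct containment path."""
    kb, root = case

    def count_paths(eid):
        ent = kb.entities[eid]
        if not ent.components:
            return 1
        return sum(count_paths(c) for c in ent.components)

    leaves = kb.flatten(root)
    assert len(leaves) == count_paths(root)
    assert all(kb.entities[l].kind in {"protein", "chemical"} for l, _ in leaves)
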