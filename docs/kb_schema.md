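# Knowledgebase JSON schema

One JSON document with three sections. All ids are strings and must be
unique within their section; every cross-reference must resolve.

```json
{
 "entities": [
  {"id": "E:P00001", "kind": "protein",  "name": "G00001", "accession": "P00001"},
  {"id": "E:CHEBI:10000", "kind": "chemical", "name": "CHEM1", "accession": "CHEBI:10000"},
  {"id": "CPLX001", "kind": "complex",    "name": "CPLX001",
   "components": ["E:P00001", "E:CHEBI:10000"]},
  {"id": "SET01",   "kind": "entity_set", "name": "SET01",
   "components": ["E:P00001", "E:P00002"]}
 ],
 "reactions": [
  {"id": "RXN001", "name": "reaction 1",
   "inputs": ["E:P00001"], "outputs": ["CPLX001"],
   "catalysts": ["E:P00002"], "regulators": []}
 ],
 "pathways": [
  {"id": "PW01", "name": "pathway PW01", "reaction_ids": ["RXN001"],
   "child_pathway_ids": ["PW02"], "parent_pathway_id": ""}
 ]
}
```

## Entities

| field | meaning |
| --- | --- |
| `kind` | one of `protein`, `chemical`, `complex`, `entity_set` |
| `accession` | UniProt-style for proteins, ChEBI-style for chemicals; empty for containers |
| `components` | member entity ids; required (non-empty) for `complex` / `entity_set`, forbidden for leaves |

Composition must be acyclic. Complex members interact with each other;
entity-set members are *alternatives* and never interact with each
other.

## Reactions

`inputs`, `outputs`, `catalysts`, `regulators` are lists of entity ids
(any kind). These four roles drive both FI extraction and
reaction-network construction.

## Pathways

`parent_pathway_id` empty means top-level. The hierarchy must be a
forest, and `child_pathway_ids` must agree with the children's
`parent_pathway_id`. A reaction may appear in any number of pathways;
rollup maps it to every containing pathway and that pathway's root.

## Validation errors

Loading raises a distinct error naming the offending id for: a missing
file, a dangling reference (`MissingReferenceError`), cyclic composition
(`CyclicCompositionError`), a cyclic pathway hierarchy
(`CyclicPathwayError`) and duplicate ids (`DuplicateIdError`).
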