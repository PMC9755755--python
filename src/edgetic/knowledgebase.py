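"""Reactome-style knowledgebase: entities, reactions, pathway hierarchy.

The knowledgebase is the source of two derived structures used throughout
the pipeline:

* the set of **functional interactions** (FIs) — protein–protein or
  protein–chemical pairs inferred from curated reactions via co-complex
  membership, catalysis and regulation; and
* the **reaction network** — a directed graph connecting reaction ``r1``
  to ``r2`` whenever an output of ``r1`` is an input, catalyst or
  regulator of ``r2``, after removing ubiquitous currency metabolites
  (ATP, H2O, ...) that would otherwise create spurious links.

The on-disk format is a bespoke JSON schema documented in
``docs/kb_schema.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "PhysicalEntity",
    "Reaction",
    "Pathway",
    "FunctionalInteraction",
    "ReactionNetwork",
    "KnowledgeBase",
    "KBValidationError",
    "MissingReferenceError",
    "CyclicCompositionError",
    "CyclicPathwayError",
    "DuplicateIdError",
    "DEFAULT_CURRENCY_METABOLITES",
    "load_kb",
    "extract_functional_interactions",
    "build_reaction_network",
    "rollup_pathways",
    "fis_by_reaction",
    "fis_by_pathway",
    "write_sif",
    "write_graphml",
    "write_fi_tsv",
]

#: Small molecules excluded when linking reactions, matched by display name.
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {"ATP", "ADP", "Pi", "H2O", "GTP", "GDP", "CO2", "H+"}
)

ENTITY_KINDS = {"protein", "chemical", "complex", "entity_set"}
LEAF_KINDS = {"protein", "chemical"}


class KBValidationError(ValueError):
    """Base class for knowledgebase validation failures."""


class MissingReferenceError(KBValidationError):
    """A referenced id does not exist in the knowledgebase."""


class CyclicCompositionError(KBValidationError):
    """Complex / entity-set composition contains a cycle."""


class CyclicPathwayError(KBValidationError):
    """Pathway hierarchy contains a cycle."""


class DuplicateIdError(KBValidationError):
    """An id is declared more than once."""


@dataclass(frozen=True)
class PhysicalEntity:
    id: str
    kind: str  # protein | chemical | complex | entity_set
    name: str = ""
    accession: str = ""  # UniProt-style for proteins, ChEBI-style for chemicals
    components: tuple[str, ...] = ()  # member entity ids (complex / entity_set)

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise KBValidationError(f"unknown entity kind {self.kind!r} for {self.id!r}")
        if self.kind in LEAF_KINDS and self.components:
            raise KBValidationError(f"leaf entity {self.id!r} must not have components")
        if self.kind not in LEAF_KINDS and not self.components:
            raise KBValidationError(f"container entity {self.id!r} has no components")


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    inputs: tuple[str, ...] = ()
    outputs: tuple[str, ...] = ()
    catalysts: tuple[str, ...] = ()
    regulators: tuple[str, ...] = ()

    def participant_ids(self) -> tuple[str, ...]:
        return self.inputs + self.outputs + self.catalysts + self.regulators


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str = ""
    reaction_ids: tuple[str, ...] = ()
    child_pathway_ids: tuple[str, ...] = ()
    parent_pathway_id: str = ""  # empty = top-level


@dataclass(frozen=True)
class FunctionalInteraction:
    """An unordered protein–protein or protein–chemical pair.

    ``a`` and ``b`` are stored in lexicographic order; ``a`` is a protein
    accession, ``b`` an accession or chemical id.
    """

    a: str
    b: str
    fi_kind: str  # protein_protein | protein_chemical
    source_reaction_ids: frozenset[str]

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@dataclass
class ReactionNetwork:
    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]  # (r1, r2): r1 precedes r2
    excluded_small_molecules: frozenset[str]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass
class KnowledgeBase:
    entities: dict[str, PhysicalEntity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_dict(cls, doc: Mapping) -> "KnowledgeBase":
        kb = cls()
        for section, factory, target in (
            ("entities", PhysicalEntity, kb.entities),
            ("reactions", Reaction, kb.reactions),
            ("pathways", Pathway, kb.pathways),
        ):
            for raw in doc.get(section, []):
                raw = dict(raw)
                for key, val in list(raw.items()):
                    if isinstance(val, list):
                        raw[key] = tuple(val)
                obj = factory(**raw)
                if obj.id in target:
                    raise DuplicateIdError(f"duplicate {section} id {obj.id!r}")
                target[obj.id] = obj
        kb.validate()
        return kb

    def to_dict(self) -> dict:
        def _clean(obj) -> dict:
            out = {}
            for key, val in obj.__dict__.items():
                out[key] = list(val) if isinstance(val, tuple) else val
            return out

        return {
            "entities": [_clean(e) for e in self.entities.values()],
            "reactions": [_clean(r) for r in self.reactions.values()],
            "pathways": [_clean(p) for p in self.pathways.values()],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    # ----------------------------------------------------------- validation

    def validate(self) -> None:
        for ent in self.entities.values():
            for cid in ent.components:
                if cid not in self.entities:
                    raise MissingReferenceError(
                        f"entity {ent.id!r} references missing entity {cid!r}"
                    )
        self._check_acyclic_composition()
        for rxn in self.reactions.values():
            for eid in rxn.participant_ids():
                if eid not in self.entities:
                    raise MissingReferenceError(
                        f"reaction {rxn.id!r} references missing entity {eid!r}"
                    )
        self._check_pathways()

    def _check_acyclic_composition(self) -> None:
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(eid: str) -> None:
            if state.get(eid) == 2:
                return
            if state.get(eid) == 1:
                raise CyclicCompositionError(f"cyclic composition through entity {eid!r}")
            state[eid] = 1
            for cid in self.entities[eid].components:
                visit(cid)
            state[eid] = 2

        for eid in self.entities:
            visit(eid)

    def _check_pathways(self) -> None:
        for pw in self.pathways.values():
            for rid in pw.reaction_ids:
                if rid not in self.reactions:
                    raise MissingReferenceError(
                        f"pathway {pw.id!r} references missing reaction {rid!r}"
                    )
            for cid in pw.child_pathway_ids:
                if cid not in self.pathways:
                    raise MissingReferenceError(
                        f"pathway {pw.id!r} references missing pathway {cid!r}"
                    )
            if pw.parent_pathway_id and pw.parent_pathway_id not in self.pathways:
                raise MissingReferenceError(
                    f"pathway {pw.id!r} references missing parent "
                    f"{pw.parent_pathway_id!r}"
                )
        # parent links must agree with child lists
        for pw in self.pathways.values():
            for cid in pw.child_pathway_ids:
                child = self.pathways[cid]
                if child.parent_pathway_id != pw.id:
                    raise KBValidationError(
                        f"pathway {cid!r} parent link inconsistent with child "
                        f"list of {pw.id!r}"
                    )
        # forest: no cycles when following parent links
        for pid in self.pathways:
            seen = set()
            cur = pid
            while cur:
                if cur in seen:
                    raise CyclicPathwayError(f"cyclic pathway hierarchy through {pid!r}")
                seen.add(cur)
                cur = self.pathways[cur].parent_pathway_id

    # ------------------------------------------------------------- helpers

    def flatten(self, entity_id: str) -> list[tuple[str, frozenset[str]]]:
        """Flatten to accessioned leaves.

        Returns ``(leaf_id, set_path)`` pairs where ``set_path`` collects
        the ids of every entity set traversed to reach the leaf. Members
        of one entity set are alternative molecules, so two leaves whose
        set paths intersect must never be paired with each other.
        """
        out: list[tuple[str, frozenset[str]]] = []

        def walk(eid: str, path: frozenset[str]) -> None:
            ent = self.entities[eid]
            if ent.kind in LEAF_KINDS:
                out.append((eid, path))
                return
            child_path = path | {eid} if ent.kind == "entity_set" else path
            for cid in ent.components:
                walk(cid, child_path)

        walk(entity_id, frozenset())
        return out

    def top_level_of(self, pathway_id: str) -> str:
        cur = pathway_id
        while self.pathways[cur].parent_pathway_id:
            cur = self.pathways[cur].parent_pathway_id
        return cur


def load_kb(path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledgebase JSON document."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return KnowledgeBase.from_dict(json.loads(path.read_text()))


# --------------------------------------------------------------------- FIs


def _fi_key(kb: KnowledgeBase, leaf_id: str) -> tuple[str, str]:
    """(identifier, kind) for one leaf: accession when present, else id."""
    ent = kb.entities[leaf_id]
    return (ent.accession or ent.id, ent.kind)


def _emit_pairs(
    kb: KnowledgeBase,
    side_a: Iterable[tuple[str, frozenset[str]]],
    side_b: Iterable[tuple[str, frozenset[str]]],
    sink: set[tuple[str, str, str]],
) -> None:
    side_b = list(side_b)
    for la, pa in side_a:
        ka, kind_a = _fi_key(kb, la)
        for lb, pb in side_b:
            if la == lb:
                continue
            kb_, kind_b = _fi_key(kb, lb)
            if ka == kb_:
                continue
            if kind_a == "chemical" and kind_b == "chemical":
                continue
            if pa & pb:  # alternatives from one entity set: never paired
                continue
            a, b = sorted((ka, kb_))
            fi_kind = (
                "protein_protein"
                if kind_a == "protein" and kind_b == "protein"
                else "protein_chemical"
            )
            sink.add((a, b, fi_kind))


def _reaction_fis(kb: KnowledgeBase, rxn: Reaction) -> set[tuple[str, str, str]]:
    pairs: set[tuple[str, str, str]] = set()

    # (a) co-membership in any complex among inputs/outputs
    def complex_nodes(eid: str, path: frozenset[str]):
        ent = kb.entities[eid]
        if ent.kind in LEAF_KINDS:
            return
        if ent.kind == "complex":
            yield eid
        next_path = path | {eid} if ent.kind == "entity_set" else path
        for cid in ent.components:
            yield from complex_nodes(cid, next_path)

    for eid in rxn.inputs + rxn.outputs:
        for cx in complex_nodes(eid, frozenset()):
            leaves = kb.flatten(cx)
            _emit_pairs(kb, leaves, leaves, pairs)

    # (b) catalyst leaf × input leaf
    cat_leaves = [lv for eid in rxn.catalysts for lv in kb.flatten(eid)]
    in_leaves = [lv for eid in rxn.inputs for lv in kb.flatten(eid)]
    _emit_pairs(kb, cat_leaves, in_leaves, pairs)

    # (c) regulator leaf × (catalyst or output) leaf
    reg_leaves = [lv for eid in rxn.regulators for lv in kb.flatten(eid)]
    out_leaves = [lv for eid in rxn.outputs for lv in kb.flatten(eid)]
    _emit_pairs(kb, reg_leaves, cat_leaves + out_leaves, pairs)
    return pairs


def extract_functional_interactions(kb: KnowledgeBase) -> set[FunctionalInteraction]:
    """Extract deduplicated FIs from every reaction.

    Per reaction, after recursively flattening complexes and entity sets
    to accessioned leaves, an FI is emitted for (a) every distinct pair of
    leaves co-occurring in one complex among the reaction's inputs or
    outputs, (b) every catalyst–input leaf pair, and (c) every
    regulator–(catalyst or output) leaf pair. Chemical–chemical pairs are
    discarded, and members of one entity set (alternative molecules) are
    never paired with each other.
    """
    acc: dict[tuple[str, str, str], set[str]] = {}
    for rxn in kb.reactions.values():
        for key in _reaction_fis(kb, rxn):
            acc.setdefault(key, set()).add(rxn.id)
    return {
        FunctionalInteraction(a, b, kind, frozenset(rids))
        for (a, b, kind), rids in acc.items()
    }


# --------------------------------------------------------- reaction network


def build_reaction_network(
    kb: KnowledgeBase,
    excluded: frozenset[str] | set[str] = DEFAULT_CURRENCY_METABOLITES,
) -> ReactionNetwork:
    """Connect r1 → r2 when an output of r1 is an input, catalyst or
    regulator of r2, ignoring currency metabolites (matched by chemical
    display name). Entities connect as whole ids; complexes are not
    flattened here."""
    excluded = frozenset(excluded)

    def usable(eids: Iterable[str]) -> set[str]:
        out = set()
        for eid in eids:
            ent = kb.entities[eid]
            if ent.kind == "chemical" and ent.name in excluded:
                continue
            out.add(eid)
        return out

    outputs = {rid: usable(r.outputs) for rid, r in kb.reactions.items()}
    intake = {
        rid: usable(r.inputs + r.catalysts + r.regulators)
        for rid, r in kb.reactions.items()
    }
    edges = {
        (r1, r2)
        for r1 in kb.reactions
        for r2 in kb.reactions
        if r1 != r2 and outputs[r1] & intake[r2]
    }
    return ReactionNetwork(
        nodes=tuple(kb.reactions),
        edges=frozenset(edges),
        excluded_small_molecules=excluded,
    )


# ------------------------------------------------------------ pathway rollup


def rollup_pathways(kb: KnowledgeBase) -> dict[str, set[tuple[str, str]]]:
    """Map each reaction to every (pathway, top-level pathway) containing
    it, directly or through descendant pathways."""
    out: dict[str, set[tuple[str, str]]] = {rid: set() for rid in kb.reactions}
    for pw in kb.pathways.values():
        lineage: list[str] = []
        cur: str | None = pw.id
        while cur:
            lineage.append(cur)
            cur = kb.pathways[cur].parent_pathway_id or None
        top = lineage[-1]
        for rid in pw.reaction_ids:
            for anc in lineage:
                out[rid].add((anc, top))
    return out


def fis_by_reaction(
    fis: Iterable[FunctionalInteraction],
) -> dict[str, set[FunctionalInteraction]]:
    out: dict[str, set[FunctionalInteraction]] = {}
    for fi in fis:
        for rid in fi.source_reaction_ids:
            out.setdefault(rid, set()).add(fi)
    return out


def fis_by_pathway(
    fis: Iterable[FunctionalInteraction], kb: KnowledgeBase
) -> dict[str, set[FunctionalInteraction]]:
    """FIs mediated by each pathway (through its reactions, transitively)."""
    rollup = rollup_pathways(kb)
    per_rxn = fis_by_reaction(fis)
    out: dict[str, set[FunctionalInteraction]] = {}
    for rid, pws in rollup.items():
        for pid, _top in pws:
            out.setdefault(pid, set()).update(per_rxn.get(rid, ()))
    return out


# ------------------------------------------------------------------ exports


def write_sif(network: ReactionNetwork, path: str | Path) -> None:
    lines = [f"{r1}\tprecedes\t{r2}" for r1, r2 in sorted(network.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(network: ReactionNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), str(path))


def write_fi_tsv(fis: Iterable[FunctionalInteraction], path: str | Path) -> None:
    rows = sorted((fi.a, fi.b, ";".join(sorted(fi.source_reaction_ids))) for fi in fis)
    with open(path, "w") as fh:
        fh.write("a\tb\treaction_ids\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
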