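"""Fully seeded synthetic inputs for the whole pipeline.

Generates a small proteome with a Reactome-style knowledgebase over it,
structure-like interface annotations for the knowledgebase's functional
interactions, chemical fingerprints, a cohort of samples carrying
missense mutations (uniform placement over protein positions, optionally
with planted interface hotspots), and clinical records with an optional
proportional-hazards survival effect for carriers of a chosen pathway.

Null placement deliberately matches the within-protein shuffle null:
positions are uniform over the protein and the reference residue is read
from the sequence, so with no hotspots the observed cohort and the
shuffled background follow the same law.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .interface_mapping import Fingerprint, InterfaceRecord, call_perturbations
from .enrichment import aggregate_to_units
from .interface_mapping import match_fis_to_interfaces, write_fingerprints, write_interfaces
from .knowledgebase import (
    KnowledgeBase,
    PhysicalEntity,
    Pathway,
    Reaction,
    extract_functional_interactions,
    fis_by_pathway,
)
from .variant_io import Cohort, ProteinVariant

__all__ = ["SimConfig", "SyntheticDataset", "generate_all", "simulate"]

AA = "ACDEFGHIKLMNPQRSTVWY"
CURRENCY = ("ATP", "ADP", "Pi", "H2O", "GTP", "GDP", "CO2", "H+")
FP_BITS = 64

MAF_HEADER = (
    "gene_symbol\tsample_id\tcancer_type\tvariant_classification\t"
    "transcript_length_aa\tprotein_accession\tprotein_change"
)


@dataclass
class SimConfig:
    """All knobs of the generator; every draw derives from ``seed``."""

    seed: int = 0
    n_proteins: int = 25
    n_chemicals: int = 8
    n_reactions: int = 15
    n_pathways: int = 7
    hierarchy_depth: int = 2
    protein_length_range: tuple[int, int] = (150, 350)
    interface_coverage: float = 0.8  # fraction of proteins with >=1 interface
    interface_size_range: tuple[int, int] = (12, 48)
    # template identity sampled uniformly per partner kind
    identity_distribution: dict = field(
        default_factory=lambda: {"protein": (70.0, 100.0), "other": (30.0, 100.0)}
    )
    n_samples: int = 200
    mutations_per_sample_range: tuple[int, int] = (20, 60)
    hotspots: list[tuple[str, float]] = field(default_factory=list)
    survival_effect: tuple[str, float] | None = None  # (pathway_id, true HR)
    censoring_rate: float = 0.2
    baseline_hazard: float = 1.0 / 1000.0  # events per day
    cancer_type: str = "SYN"
    # planted violations, for exercising the drop tallies
    n_silent_rows: int = 0
    n_malformed_rows: int = 0
    n_length_violations: int = 0
    n_ref_violations: int = 0

    def validate(self) -> None:
        for lo, hi in (
            self.protein_length_range,
            self.interface_size_range,
            self.mutations_per_sample_range,
        ):
            if lo > hi or lo <= 0:
                raise ValueError(f"bad range ({lo}, {hi})")
        for frac in (self.interface_coverage, self.censoring_rate):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        for _, prob in self.hotspots:
            if not 0 <= prob <= 1:
                raise ValueError(f"hotspot probability {prob} outside [0, 1]")
        if self.hierarchy_depth > max(self.n_pathways, 1):
            raise ValueError("hierarchy deeper than the number of pathways")
        for n in (self.n_proteins, self.n_samples):
            if n <= 0:
                raise ValueError("counts must be positive")


@dataclass
class SyntheticDataset:
    config: SimConfig
    sequences: dict[str, str]
    kb: KnowledgeBase
    interfaces: list[InterfaceRecord]
    fingerprints: dict[str, Fingerprint]
    maf_rows: list[str]  # TSV body lines, header excluded
    clinical: pd.DataFrame
    carriers: frozenset[str]  # samples perturbing the survival-effect pathway

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "sequences.fasta", "w") as fh:
            for acc in sorted(self.sequences):
                fh.write(f">{acc}\n{self.sequences[acc]}\n")
        self.kb.save(outdir / "kb.json")
        write_interfaces(self.interfaces, outdir / "interfaces.tsv")
        write_fingerprints(self.fingerprints, outdir / "fingerprints.tsv")
        with open(outdir / "cohort.maf.tsv", "w") as fh:
            fh.write(MAF_HEADER + "\n")
            for row in self.maf_rows:
                fh.write(row + "\n")
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        manifest = {
            "config": dataclasses.asdict(self.config),
            "counts": {
                "proteins": len(self.sequences),
                "reactions": len(self.kb.reactions),
                "pathways": len(self.kb.pathways),
                "interfaces": len(self.interfaces),
                "maf_rows": len(self.maf_rows),
                "samples": int(self.clinical.shape[0]),
                "survival_carriers": len(self.carriers),
            },
            "files": [
                "sequences.fasta",
                "kb.json",
                "interfaces.tsv",
                "fingerprints.tsv",
                "cohort.maf.tsv",
                "clinical.tsv",
            ],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest


# ------------------------------------------------------------------ pieces


def _generate_sequences(cfg: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    lo, hi = cfg.protein_length_range
    seqs = {}
    for i in range(cfg.n_proteins):
        acc = f"P{i + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        seqs[acc] = "".join(rng.choice(list(AA), size=length))
    return seqs


def generate_kb(cfg: SimConfig, rng: np.random.Generator, accessions: list[str]) -> KnowledgeBase:
    """Random acyclic knowledgebase: complexes covering every protein,
    chain-wired reactions (so the reaction network is connected with high
    probability), currency chemicals, and a pathway forest."""
    entities: dict[str, PhysicalEntity] = {}
    for acc in accessions:
        eid = f"E:{acc}"
        entities[eid] = PhysicalEntity(id=eid, kind="protein", name=f"G{acc[1:]}", accession=acc)
    chem_ids = []
    for i in range(cfg.n_chemicals):
        eid = f"E:CHEBI:{10000 + i}"
        entities[eid] = PhysicalEntity(
            id=eid, kind="chemical", name=f"CHEM{i + 1}", accession=f"CHEBI:{10000 + i}"
        )
        chem_ids.append(eid)
    currency_ids = {}
    for i, name in enumerate(CURRENCY):
        eid = f"E:CHEBI:{90000 + i}"
        entities[eid] = PhysicalEntity(
            id=eid, kind="chemical", name=name, accession=f"CHEBI:{90000 + i}"
        )
        currency_ids[name] = eid

    # complexes of 2-3 proteins covering the proteome; some carry a chemical
    order = list(rng.permutation(accessions))
    complexes: list[str] = []
    i = 0
    while i < len(order):
        size = int(rng.integers(2, 4))
        members = [f"E:{acc}" for acc in order[i : i + size]]
        i += size
        if len(members) < 2:  # leftover single protein joins the last complex
            if complexes:
                prev = entities[complexes[-1]]
                entities[complexes[-1]] = PhysicalEntity(
                    id=prev.id,
                    kind="complex",
                    name=prev.name,
                    components=prev.components + tuple(members),
                )
                break
            members.append(f"E:{order[0]}")
        if chem_ids and rng.random() < 0.3:
            members.append(str(rng.choice(chem_ids)))
        cid = f"CPLX{len(complexes) + 1:03d}"
        entities[cid] = PhysicalEntity(
            id=cid, kind="complex", name=cid, components=tuple(members)
        )
        complexes.append(cid)

    # a couple of entity sets (alternative members)
    sets: list[str] = []
    if len(accessions) >= 4:
        for s in range(2):
            members = tuple(
                f"E:{acc}" for acc in rng.choice(accessions, size=2, replace=False)
            )
            sid = f"SET{s + 1:02d}"
            entities[sid] = PhysicalEntity(
                id=sid, kind="entity_set", name=sid, components=members
            )
            sets.append(sid)

    reactions: dict[str, Reaction] = {}
    prev_output: str | None = None
    for r in range(cfg.n_reactions):
        rid = f"RXN{r + 1:03d}"
        cplx = complexes[r % len(complexes)] if complexes else None
        inputs: list[str] = []
        outputs: list[str] = []
        catalysts: list[str] = []
        regulators: list[str] = []
        if cplx is not None:
            outputs.append(cplx)
            # free members as inputs
            for m in entities[cplx].components:
                if entities[m].kind == "protein":
                    inputs.append(m)
        if prev_output is not None and rng.random() < 0.7:
            inputs.append(prev_output)
        if rng.random() < 0.6:
            catalysts.append(f"E:{rng.choice(accessions)}")
        if sets and rng.random() < 0.25:
            regulators.append(str(rng.choice(sets)))
        elif rng.random() < 0.2:
            regulators.append(f"E:{rng.choice(accessions)}")
        if chem_ids and rng.random() < 0.5:
            inputs.append(str(rng.choice(chem_ids)))
        if rng.random() < 0.5:  # currency wiring, excluded when linking
            inputs.append(currency_ids["ATP"])
            outputs.append(currency_ids["ADP"])
        reactions[rid] = Reaction(
            id=rid,
            name=f"reaction {r + 1}",
            inputs=tuple(dict.fromkeys(inputs)),
            outputs=tuple(dict.fromkeys(outputs)),
            catalysts=tuple(catalysts),
            regulators=tuple(regulators),
        )
        prev_output = cplx

    # pathway forest of the requested depth; every reaction in one pathway
    pathways: dict[str, Pathway] = {}
    n_top = max(1, cfg.n_pathways // 3)
    parent_of: dict[str, str] = {}
    depth_of: dict[str, int] = {}
    ids = [f"PW{i + 1:02d}" for i in range(cfg.n_pathways)]
    for i, pid in enumerate(ids):
        if i < n_top:
            parent_of[pid] = ""
            depth_of[pid] = 1
        else:
            eligible = [q for q in ids[:i] if depth_of[q] < cfg.hierarchy_depth]
            parent = str(rng.choice(eligible)) if eligible else ids[0]
            parent_of[pid] = parent
            depth_of[pid] = depth_of[parent] + 1
    rxn_home: dict[str, list[str]] = {pid: [] for pid in ids}
    for rid in reactions:
        rxn_home[str(rng.choice(ids))].append(rid)
    for pid in ids:
        pathways[pid] = Pathway(
            id=pid,
            name=f"pathway {pid}",
            reaction_ids=tuple(rxn_home[pid]),
            child_pathway_ids=tuple(q for q in ids if parent_of[q] == pid),
            parent_pathway_id=parent_of[pid],
        )

    kb = KnowledgeBase(entities=entities, reactions=reactions, pathways=pathways)
    kb.validate()
    return kb


def _random_fp(rng: np.random.Generator) -> tuple[int, ...]:
    return tuple(int(b) for b in rng.random(FP_BITS) < 0.25)


def _perturbed_fp(fp: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
    """Flip ~6% of bits: Tanimoto with the original stays well above 0.5."""
    bits = list(fp)
    for i in range(FP_BITS):
        if rng.random() < 0.06:
            bits[i] = 1 - bits[i]
    if not any(bits):
        bits[0] = 1
    return tuple(bits)


def _generate_interfaces(
    cfg: SimConfig,
    rng: np.random.Generator,
    sequences: dict[str, str],
    kb: KnowledgeBase,
) -> tuple[list[InterfaceRecord], dict[str, Fingerprint]]:
    fis = sorted(
        extract_functional_interactions(kb), key=lambda fi: (fi.a, fi.b, fi.fi_kind)
    )
    covered = set(
        rng.choice(
            sorted(sequences),
            size=int(round(cfg.interface_coverage * len(sequences))),
            replace=False,
        )
    )
    fingerprints: dict[str, Fingerprint] = {}
    for ent in kb.entities.values():
        if ent.kind == "chemical":
            fingerprints[ent.accession] = Fingerprint(ent.accession, _random_fp(rng))

    lo, hi = cfg.interface_size_range
    records: list[InterfaceRecord] = []

    def add(protein: str, partner: str, kind: str) -> None:
        seq = sequences[protein]
        size = min(int(rng.integers(lo, hi + 1)), len(seq))
        positions = frozenset(
            int(p) for p in rng.choice(np.arange(1, len(seq) + 1), size=size, replace=False)
        )
        id_lo, id_hi = cfg.identity_distribution["protein" if kind == "protein" else "other"]
        records.append(
            InterfaceRecord(
                interface_id=f"IF{len(records) + 1:04d}",
                protein=protein,
                partner_id=partner,
                partner_kind=kind,
                positions=positions,
                template_identity_pct=float(np.round(rng.uniform(id_lo, id_hi), 1)),
                best_match_evalue=float(10.0 ** rng.uniform(-12, -5)),
            )
        )

    for fi in fis:
        if fi.fi_kind == "protein_protein":
            if fi.a in covered:
                add(fi.a, fi.b, "protein")
            elif fi.b in covered:
                add(fi.b, fi.a, "protein")
        else:
            protein, chem = (fi.a, fi.b) if fi.a in sequences else (fi.b, fi.a)
            if protein in covered:
                ligand = f"LIG:{chem}"
                if ligand not in fingerprints:
                    fingerprints[ligand] = Fingerprint(
                        ligand, _perturbed_fp(fingerprints[chem].bits, rng)
                    )
                add(protein, ligand, "chemical")
    # a few nucleic-acid interfaces: carried through, no FI counterpart
    for protein in sorted(covered)[: max(1, len(covered) // 10)]:
        add(protein, "DNA1", "nucleic_acid")
    return records, fingerprints


def _generate_maf(
    cfg: SimConfig,
    rng: np.random.Generator,
    sequences: dict[str, str],
    interfaces: list[InterfaceRecord],
) -> list[str]:
    accs = sorted(sequences)
    lengths = np.array([len(sequences[a]) for a in accs], dtype=float)
    weights = lengths / lengths.sum()  # mutation rate proportional to length
    by_id = {rec.interface_id: rec for rec in interfaces}
    for iid, _prob in cfg.hotspots:
        if iid not in by_id:
            raise ValueError(f"unknown hotspot interface id {iid!r}")
    lo, hi = cfg.mutations_per_sample_range
    rows: list[str] = []

    def emit(sample: str, acc: str, pos: int, ref: str, alt: str,
             length: int | None = None, klass: str = "Missense_Mutation") -> None:
        seq_len = length if length is not None else len(sequences[acc])
        rows.append(
            f"G{acc[1:]}\t{sample}\t{cfg.cancer_type}\t{klass}\t"
            f"{seq_len}\t{acc}\t{ref}{pos}{alt}"
        )

    for s in range(cfg.n_samples):
        sample = f"S{s + 1:04d}"
        n_mut = int(rng.integers(lo, hi + 1))
        taken: set[tuple[str, int]] = set()
        for _ in range(n_mut):
            acc = accs[int(rng.choice(len(accs), p=weights))]
            seq = sequences[acc]
            pos = int(rng.integers(1, len(seq) + 1))
            if (acc, pos) in taken:
                continue
            taken.add((acc, pos))
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AA if a != ref]))
            emit(sample, acc, pos, ref, alt)
        for iid, prob in cfg.hotspots:
            if rng.random() < prob:
                rec = by_id[iid]
                seq = sequences[rec.protein]
                pos = int(rng.choice(sorted(rec.positions)))
                if (rec.protein, pos) in taken:
                    continue  # background variant already hit this site
                taken.add((rec.protein, pos))
                ref = seq[pos - 1]
                alt = str(rng.choice([a for a in AA if a != ref]))
                emit(sample, rec.protein, pos, ref, alt)

    # planted violations (all default 0): exercised by drop-tally tests
    first = accs[0]
    seq = sequences[first]
    for _ in range(cfg.n_silent_rows):
        emit("S0001", first, 1, seq[0], seq[0], klass="Silent")
    for _ in range(cfg.n_malformed_rows):
        rows.append(
            f"G{first[1:]}\tS0001\t{cfg.cancer_type}\tMissense_Mutation\t"
            f"{len(seq)}\t{first}\tnot-a-change"
        )
    for _ in range(cfg.n_length_violations):
        ref = seq[0]
        alt = "A" if ref != "A" else "C"
        emit("S0001", first, 1, ref, alt, length=len(seq) + 7)
    for _ in range(cfg.n_ref_violations):
        ref = "A" if seq[1] != "A" else "C"
        alt = "G"
        emit("S0001", first, 2, ref, alt)
    return rows


def _cohort_from_rows(cfg: SimConfig, rows: list[str], sequences: dict[str, str]) -> Cohort:
    """In-memory equivalent of parse_maf + map_to_protein on clean rows."""
    variants = []
    samples = set()
    seen = set()
    for row in rows:
        gene, sample, ctype, klass, tlen, acc, change = row.split("\t")
        samples.add(sample)
        if klass != "Missense_Mutation":
            continue
        ref, pos, alt = change[0], int(change[1:-1]), change[-1]
        if int(tlen) != len(sequences[acc]) or sequences[acc][pos - 1] != ref:
            continue
        key = (acc, pos, ref, alt, sample)
        if key in seen:
            continue
        seen.add(key)
        variants.append(ProteinVariant(acc, pos, ref, alt, sample, ctype))
    return Cohort(variants=variants, samples=samples, cancer_type=cfg.cancer_type,
                  sequences=sequences)


def _derive_carriers(
    cfg: SimConfig,
    rows: list[str],
    sequences: dict[str, str],
    kb: KnowledgeBase,
    interfaces: list[InterfaceRecord],
    fingerprints: dict[str, Fingerprint],
) -> frozenset[str]:
    """Samples perturbing the survival-effect pathway, via the real
    perturbation-calling and aggregation machinery."""
    if cfg.survival_effect is None:
        return frozenset()
    pathway_id, _hr = cfg.survival_effect
    if pathway_id not in kb.pathways:
        raise ValueError(f"unknown survival-effect pathway {pathway_id!r}")
    cohort = _cohort_from_rows(cfg, rows, sequences)
    events = call_perturbations(cohort, interfaces)
    fis = extract_functional_interactions(kb)
    fi_map = match_fis_to_interfaces(fis, interfaces, fingerprints)
    table = aggregate_to_units(
        events, fi_map, fis_by_pathway(fis, kb), "pathway", cohort.samples
    )
    return frozenset(table.incidence.get(pathway_id, frozenset()))


def generate_clinical(
    cfg: SimConfig,
    rng: np.random.Generator,
    samples: list[str],
    carriers: frozenset[str],
) -> pd.DataFrame:
    """Exponential survival with proportional hazards for carriers, and
    independent exponential censoring tuned to the requested rate."""
    hr = cfg.survival_effect[1] if cfg.survival_effect else 1.0
    rows = []
    for sample in samples:
        lam = cfg.baseline_hazard * (hr if sample in carriers else 1.0)
        t_event = rng.exponential(1.0 / lam)
        if cfg.censoring_rate >= 1.0:
            t_cens = rng.exponential(1.0 / lam)
            dead = False
        elif cfg.censoring_rate <= 0.0:
            t_cens = np.inf
            dead = True
        else:
            # competing exponentials: P(censor first) = censoring_rate
            lam_c = lam * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
            t_cens = rng.exponential(1.0 / lam_c)
            dead = t_event <= t_cens
        time = round(min(t_event, t_cens) + 0.5, 1)  # strictly positive days
        age = float(np.clip(np.round(rng.normal(60.0, 12.0), 1), 20.0, 90.0))
        gender = "male" if rng.random() < 0.5 else "female"
        rows.append(
            {
                "sample_id": sample,
                "vital_status": "dead" if dead else "alive",
                "gender": gender,
                "days_to_death": time if dead else "",
                "days_to_last_follow_up": "" if dead else time,
                "age_at_diagnosis": age,
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- entry point


def generate_all(cfg: SimConfig) -> SyntheticDataset:
    """Generate the complete, mutually consistent input bundle."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sequences = _generate_sequences(cfg, rng)
    kb = generate_kb(cfg, rng, sorted(sequences))
    interfaces, fingerprints = _generate_interfaces(cfg, rng, sequences, kb)
    maf_rows = _generate_maf(cfg, rng, sequences, interfaces)
    carriers = _derive_carriers(cfg, maf_rows, sequences, kb, interfaces, fingerprints)
    if cfg.survival_effect is not None and not carriers:
        import logging

        logging.getLogger(__name__).warning(
            "survival effect requested for %s but no sample perturbs it",
            cfg.survival_effect[0],
        )
    samples = sorted({row.split("\t")[1] for row in maf_rows})
    clinical = generate_clinical(cfg, rng, samples, carriers)
    return SyntheticDataset(
        config=cfg,
        sequences=sequences,
        kb=kb,
        interfaces=interfaces,
        fingerprints=fingerprints,
        maf_rows=maf_rows,
        clinical=clinical,
        carriers=carriers,
    )


def simulate(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate and write the full bundle; returns the manifest."""
    return generate_all(cfg).write(outdir)
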