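"""Structure-derived interaction interfaces and perturbation calling.

Interfaces come from a Mechismo-style annotation table: for one protein,
the residue positions in contact with one partner (protein, chemical or
nucleic acid), together with the sequence identity of the structural
template the contact was inferred from. Confidence tiers follow the
template identity: protein–protein interfaces require close homologs
(>= 70% identity) while chemical and nucleic-acid interfaces are
accepted down to 30%.

Functional interactions are matched to interfaces by UniProt accession
for proteins and, for chemicals, by topological-fingerprint Tanimoto
similarity strictly greater than 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .knowledgebase import FunctionalInteraction
from .variant_io import Cohort, ProteinVariant

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceRecord",
    "Fingerprint",
    "PerturbationEvent",
    "load_interfaces",
    "write_interfaces",
    "confidence_filter",
    "tanimoto",
    "read_fingerprints",
    "write_fingerprints",
    "match_fis_to_interfaces",
    "call_perturbations",
    "fingerprint_from_smiles",
]

PARTNER_KINDS = {"protein", "chemical", "nucleic_acid"}

INTERFACE_COLUMNS = (
    "interface_id",
    "protein",
    "partner_id",
    "partner_kind",
    "positions",
    "template_identity_pct",
    "best_match_evalue",
)


@dataclass(frozen=True)
class InterfaceRecord:
    interface_id: str
    protein: str  # UniProt-style accession
    partner_id: str  # accession (protein) or ligand id (chemical/NA)
    partner_kind: str
    positions: frozenset[int]  # 1-based residue indices on `protein`
    template_identity_pct: float
    best_match_evalue: float

    def __post_init__(self) -> None:
        if self.partner_kind not in PARTNER_KINDS:
            raise ValueError(f"unknown partner kind {self.partner_kind!r}")
        if not self.positions:
            raise ValueError(f"interface {self.interface_id!r} has no positions")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length topological fingerprint bit vector."""

    chemical_id: str
    bits: tuple[int, ...]  # 0/1

    @classmethod
    def from_bitstring(cls, chemical_id: str, s: str) -> "Fingerprint":
        return cls(chemical_id, tuple(int(c) for c in s))


@dataclass(frozen=True)
class PerturbationEvent:
    """One missense variant hitting one interface (per-interface semantics:
    a variant in two overlapping interfaces yields two events)."""

    sample_id: str
    interface_id: str
    variant: ProteinVariant


def load_interfaces(
    path: str | Path, max_evalue: float = 1e-4
) -> list[InterfaceRecord]:
    """Load interface records; drop those whose best structural match has
    E-value above the threshold (default 0.0001)."""
    records: list[InterfaceRecord] = []
    seen: set[str] = set()
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in INTERFACE_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"interface table missing columns: {missing}")
                idx = {c: header.index(c) for c in INTERFACE_COLUMNS}
                continue
            row = {c: fields[idx[c]] for c in INTERFACE_COLUMNS}
            try:
                positions = frozenset(int(p) for p in row["positions"].split(","))
            except ValueError as err:
                raise ValueError(
                    f"malformed positions for {row['interface_id']!r}: "
                    f"{row['positions']!r}"
                ) from err
            rec = InterfaceRecord(
                interface_id=row["interface_id"],
                protein=row["protein"],
                partner_id=row["partner_id"],
                partner_kind=row["partner_kind"],
                positions=positions,
                template_identity_pct=float(row["template_identity_pct"]),
                best_match_evalue=float(row["best_match_evalue"]),
            )
            if rec.interface_id in seen:
                raise ValueError(f"duplicate interface_id {rec.interface_id!r}")
            seen.add(rec.interface_id)
            if rec.best_match_evalue > max_evalue:
                continue
            records.append(rec)
    return records


def write_interfaces(records: Iterable[InterfaceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(INTERFACE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.interface_id,
                        r.protein,
                        r.partner_id,
                        r.partner_kind,
                        ",".join(str(p) for p in sorted(r.positions)),
                        f"{r.template_identity_pct:g}",
                        f"{r.best_match_evalue:g}",
                    ]
                )
                + "\n"
            )


def confidence_filter(
    records: Iterable[InterfaceRecord],
    ppi_identity: float = 70.0,
    other_identity: float = 30.0,
) -> list[InterfaceRecord]:
    """Keep protein-partner interfaces at >= 70% template identity and
    chemical / nucleic-acid interfaces at >= 30% (both bounds inclusive)."""
    out = []
    for r in records:
        bound = ppi_identity if r.partner_kind == "protein" else other_identity
        if r.template_identity_pct >= bound:
            out.append(r)
    return out


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b|; 0 when both are all-zero."""
    if len(fp_a.bits) != len(fp_b.bits):
        raise ValueError(
            f"fingerprint length mismatch: {len(fp_a.bits)} != {len(fp_b.bits)}"
        )
    a = np.asarray(fp_a.bits, dtype=bool)
    b = np.asarray(fp_b.bits, dtype=bool)
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    """Read a two-column TSV (chemical_id, bitstring)."""
    fps: dict[str, Fingerprint] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chemical_id"):
            raise ValueError("fingerprint table must start with a chemical_id header")
        for line in fh:
            chem, bits = line.rstrip("\n").split("\t")
            fps[chem] = Fingerprint.from_bitstring(chem, bits)
    lengths = {len(fp.bits) for fp in fps.values()}
    if len(lengths) > 1:
        raise ValueError(f"fingerprints of mixed lengths: {sorted(lengths)}")
    return fps


def write_fingerprints(fps: Mapping[str, Fingerprint], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chemical_id\tbits\n")
        for chem in sorted(fps):
            fh.write(f"{chem}\t{''.join(str(b) for b in fps[chem].bits)}\n")


def fingerprint_from_smiles(
    chemical_id: str, smiles: str, n_bits: int = 2048
) -> Fingerprint:
    """Optional adapter: RDKit topological fingerprint from a SMILES string.

    Requires the ``chem`` extra; the core pipeline only needs precomputed
    bit vectors.
    """
    from rdkit import Chem  # local import: optional dependency

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {chemical_id!r}")
    fp = Chem.RDKFingerprint(mol, fpSize=n_bits)
    return Fingerprint(chemical_id, tuple(int(fp.GetBit(i)) for i in range(n_bits)))


def match_fis_to_interfaces(
    fis: Iterable[FunctionalInteraction],
    records: Sequence[InterfaceRecord],
    fingerprints: Mapping[str, Fingerprint] | None = None,
    tanimoto_threshold: float = 0.5,
) -> dict[FunctionalInteraction, set[str]]:
    """Match knowledgebase FIs to structural interfaces.

    Protein–protein FIs match an interface when the unordered accession
    pairs coincide. Protein–chemical FIs match when the protein accession
    matches and the Tanimoto similarity between the FI chemical's
    fingerprint and the interface ligand's fingerprint is strictly above
    the threshold. Candidate pairs with a missing fingerprint are skipped
    and reported.
    """
    fingerprints = fingerprints or {}
    by_pair: dict[frozenset[str], set[str]] = {}
    chem_records = []
    for rec in records:
        if rec.partner_kind == "protein":
            by_pair.setdefault(
                frozenset((rec.protein, rec.partner_id)), set()
            ).add(rec.interface_id)
        elif rec.partner_kind == "chemical":
            chem_records.append(rec)

    out: dict[FunctionalInteraction, set[str]] = {}
    missing_fp: set[str] = set()
    for fi in fis:
        matches: set[str] = set()
        if fi.fi_kind == "protein_protein":
            matches |= by_pair.get(frozenset((fi.a, fi.b)), set())
        else:
            # one side is a protein accession, the other a chemical id
            for rec in chem_records:
                if rec.protein == fi.a:
                    chem = fi.b
                elif rec.protein == fi.b:
                    chem = fi.a
                else:
                    continue
                fp_chem = fingerprints.get(chem)
                fp_lig = fingerprints.get(rec.partner_id)
                if fp_chem is None or fp_lig is None:
                    missing_fp.add(chem if fp_chem is None else rec.partner_id)
                    continue
                if tanimoto(fp_chem, fp_lig) > tanimoto_threshold:
                    matches.add(rec.interface_id)
        out[fi] = matches
    if missing_fp:
        logger.warning(
            "no fingerprint for %d chemical(s); candidate pairs skipped: %s",
            len(missing_fp),
            sorted(missing_fp)[:10],
        )
    return out


def call_perturbations(
    cohort: Cohort, records: Sequence[InterfaceRecord]
) -> list[PerturbationEvent]:
    """Call every (variant, interface) co-localisation event.

    A variant perturbs an interface when it falls on the interface's
    protein at one of its contact positions. Indexed by (protein,
    position); equivalent to the exhaustive double loop over variants and
    interfaces.
    """
    index: dict[tuple[str, int], list[str]] = {}
    for rec in records:
        for pos in rec.positions:
            index.setdefault((rec.protein, pos), []).append(rec.interface_id)
    events: list[PerturbationEvent] = []
    for v in cohort.variants:
        for iid in index.get((v.protein, v.position), ()):
            events.append(PerturbationEvent(v.sample_id, iid, v))
    return events
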