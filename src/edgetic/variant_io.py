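"""Parsing of MAF-like mutation tables and mapping onto protein sequences.

Two mapping filters gate every variant entering the pipeline: the stated
transcript peptide length must equal the length of the provided protein
sequence, and the reference amino acid of the substitution must match
the sequence letter at the (1-based) position. Duplicate substitutions
within one sample are collapsed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "MafRecord",
    "ProteinVariant",
    "Cohort",
    "DEFAULT_KEEP_CLASSES",
    "parse_maf",
    "read_fasta",
    "map_to_protein",
    "unique_variants",
    "write_drop_tally",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*")
DEFAULT_KEEP_CLASSES = frozenset({"Missense_Mutation"})

MAF_COLUMNS = (
    "gene_symbol",
    "sample_id",
    "cancer_type",
    "variant_classification",
    "transcript_length_aa",
    "protein_accession",
    "protein_change",
)

_CHANGE_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


@dataclass(frozen=True)
class MafRecord:
    gene_symbol: str
    sample_id: str
    cancer_type: str
    variant_classification: str
    transcript_length_aa: int
    protein_accession: str
    ref_aa: str
    position: int  # 1-based
    alt_aa: str


@dataclass(frozen=True)
class ProteinVariant:
    protein: str
    position: int  # 1-based
    ref_aa: str
    alt_aa: str
    sample_id: str
    cancer_type: str = ""


@dataclass
class Cohort:
    """Per-sample protein missense variants after the mapping filters."""

    variants: list[ProteinVariant]
    samples: set[str]
    cancer_type: str
    sequences: dict[str, str]
    drop_tally: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for v in self.variants:
            assert v.sample_id in self.samples
            seq = self.sequences[v.protein]
            assert 1 <= v.position <= len(seq)
            assert seq[v.position - 1] == v.ref_aa


def parse_maf(
    path: str | Path,
    keep_classes: frozenset[str] = DEFAULT_KEEP_CLASSES,
    return_report: bool = False,
):
    """Parse a MAF-subset TSV, keeping only the requested variant classes.

    ``#`` comment lines are ignored. Rows with a malformed
    ``protein_change`` are skipped with a warning; the skip count is
    available via ``return_report=True`` as ``{"malformed": n}``.
    """
    path = Path(path)
    records: list[MafRecord] = []
    report = {"malformed": 0}
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in MAF_COLUMNS if c not in header]
                if missing:
                    raise ValueError(f"MAF file {path} missing columns: {missing}")
                idx = {c: header.index(c) for c in MAF_COLUMNS}
                continue
            row = {c: fields[idx[c]] for c in MAF_COLUMNS}
            if row["variant_classification"] not in keep_classes:
                continue
            m = _CHANGE_RE.match(row["protein_change"])
            if not m or not (m.group(1) in AA_ALPHABET and m.group(3) in AA_ALPHABET):
                logger.warning(
                    "skipping malformed protein_change %r (%s:%s)",
                    row["protein_change"],
                    row["sample_id"],
                    row["protein_accession"],
                )
                report["malformed"] += 1
                continue
            records.append(
                MafRecord(
                    gene_symbol=row["gene_symbol"],
                    sample_id=row["sample_id"],
                    cancer_type=row["cancer_type"],
                    variant_classification=row["variant_classification"],
                    transcript_length_aa=int(row["transcript_length_aa"]),
                    protein_accession=row["protein_accession"],
                    ref_aa=m.group(1),
                    position=int(m.group(2)),
                    alt_aa=m.group(3),
                )
            )
    if return_report:
        return records, report
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by accession (first token of the header)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def map_to_protein(
    records: list[MafRecord],
    sequences: dict[str, str],
    cancer_type: str | None = None,
) -> Cohort:
    """Map records onto protein sequences, applying both retention filters.

    A record is kept iff its accession is present, the transcript peptide
    length equals the sequence length, and the reference residue matches
    the sequence at the stated position. Drops are tallied by reason;
    duplicate (protein, position, ref, alt, sample) rows collapse to one
    variant.
    """
    tally = {
        "unknown_accession": 0,
        "length_mismatch": 0,
        "ref_mismatch": 0,
        "position_out_of_range": 0,
        "duplicate": 0,
    }
    seen: set[tuple] = set()
    variants: list[ProteinVariant] = []
    samples: set[str] = set()
    ctype = cancer_type
    for rec in records:
        samples.add(rec.sample_id)
        if ctype is None:
            ctype = rec.cancer_type
        seq = sequences.get(rec.protein_accession)
        if seq is None:
            tally["unknown_accession"] += 1
            continue
        if rec.transcript_length_aa != len(seq):
            tally["length_mismatch"] += 1
            continue
        if rec.position > len(seq):
            tally["position_out_of_range"] += 1
            continue
        if seq[rec.position - 1] != rec.ref_aa:
            tally["ref_mismatch"] += 1
            continue
        key = (rec.protein_accession, rec.position, rec.ref_aa, rec.alt_aa, rec.sample_id)
        if key in seen:
            tally["duplicate"] += 1
            continue
        seen.add(key)
        variants.append(
            ProteinVariant(
                protein=rec.protein_accession,
                position=rec.position,
                ref_aa=rec.ref_aa,
                alt_aa=rec.alt_aa,
                sample_id=rec.sample_id,
                cancer_type=rec.cancer_type,
            )
        )
    dropped = {k: v for k, v in tally.items() if v}
    if dropped:
        logger.info("map_to_protein drops: %s", dropped)
    return Cohort(
        variants=variants,
        samples=samples,
        cancer_type=ctype or "",
        sequences=sequences,
        drop_tally=tally,
    )


def unique_variants(cohort: Cohort) -> set[tuple[str, int, str, str]]:
    """Sample-agnostic deduplication to unique protein variants."""
    return {(v.protein, v.position, v.ref_aa, v.alt_aa) for v in cohort.variants}


def write_drop_tally(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason, count in sorted(cohort.drop_tally.items()):
            fh.write(f"{reason}\t{count}\n")
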