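"""End-to-end orchestration: inputs -> perturbation events -> enrichment
at interface / reaction / pathway level -> survival screen -> result bundle.

One invocation analyses one cohort (one cancer type); a thin wrapper can
loop over types. All outputs are plain text (TSV / SIF / GraphML / JSON)
and are byte-reproducible given the same inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .enrichment import (
    aggregate_to_units,
    estimate_background,
    interface_table,
    test_enrichment,
    write_enrichment_tsv,
)
from .interface_mapping import (
    call_perturbations,
    confidence_filter,
    load_interfaces,
    match_fis_to_interfaces,
    read_fingerprints,
)
from .knowledgebase import (
    build_reaction_network,
    extract_functional_interactions,
    fis_by_pathway,
    fis_by_reaction,
    load_kb,
    rollup_pathways,
    write_fi_tsv,
    write_graphml,
    write_sif,
)
from .survival import derive_survival, read_clinical, run_survival_screen, write_survival_tsv
from .variant_io import map_to_protein, parse_maf, read_fasta, write_drop_tally

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "report"]

LEVELS = ("interface", "reaction", "pathway")


@dataclass
class RunConfig:
    maf: str
    fasta: str
    interfaces: str
    kb: str
    clinical: str = ""
    fingerprints: str = ""
    cancer_type: str = ""
    evalue: float = 1e-4
    ppi_identity: float = 70.0
    chem_identity: float = 30.0
    tanimoto: float = 0.5
    fdr: float = 0.05
    background_replicates: int = 100
    seed: int = 0
    survival_mode: str = "significant"  # or "all"
    excluded_small_molecules: list[str] = field(
        default_factory=lambda: ["ATP", "ADP", "Pi", "H2O", "GTP", "GDP", "CO2", "H+"]
    )

    def validate(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")
        if self.survival_mode not in {"significant", "all"}:
            raise ValueError("survival_mode must be 'significant' or 'all'")
        if self.background_replicates < 1:
            raise ValueError("background_replicates must be >= 1")
        for p in (self.maf, self.fasta, self.interfaces, self.kb):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    doc = json.dumps(dataclasses.asdict(config), sort_keys=True)
    h = hashlib.sha256(doc.encode())
    for p in (config.maf, config.fasta, config.interfaces, config.kb,
              config.fingerprints, config.clinical):
        if p and Path(p).exists():
            h.update(_sha256_file(p).encode())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the result bundle; returns the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- knowledgebase-derived structures
    kb = load_kb(config.kb)
    fis = extract_functional_interactions(kb)
    network = build_reaction_network(kb, frozenset(config.excluded_small_molecules))
    rollup = rollup_pathways(kb)
    rxn_fis = fis_by_reaction(fis)
    pw_fis = fis_by_pathway(fis, kb)
    logger.info("knowledgebase: %d reactions, %d FIs, %d network edges",
                len(kb.reactions), len(fis), len(network.edges))

    # --- cohort
    sequences = read_fasta(config.fasta)
    records, parse_report = parse_maf(config.maf, return_report=True)
    cohort = map_to_protein(records, sequences, cancer_type=config.cancer_type or None)
    logger.info("cohort: %d samples, %d mapped variants (drops %s, malformed %d)",
                len(cohort.samples), len(cohort.variants),
                {k: v for k, v in cohort.drop_tally.items() if v},
                parse_report["malformed"])

    # --- interfaces and FI matching
    ifaces = confidence_filter(
        load_interfaces(config.interfaces, max_evalue=config.evalue),
        ppi_identity=config.ppi_identity,
        other_identity=config.chem_identity,
    )
    fingerprints = read_fingerprints(config.fingerprints) if config.fingerprints else {}
    fi_map = match_fis_to_interfaces(
        fis, ifaces, fingerprints, tanimoto_threshold=config.tanimoto
    )

    # --- perturbation events and incidence tables
    events = call_perturbations(cohort, ifaces)
    aggregators = {
        "interface": lambda ev: interface_table(ev, cohort.samples),
        "reaction": lambda ev: aggregate_to_units(ev, fi_map, rxn_fis, "reaction", cohort.samples),
        "pathway": lambda ev: aggregate_to_units(ev, fi_map, pw_fis, "pathway", cohort.samples),
    }
    tables = {level: build(events) for level, build in aggregators.items()}

    # --- shuffle background and enrichment tests
    background = estimate_background(
        cohort, ifaces, aggregators, R=config.background_replicates, seed=config.seed
    )
    iface_by_id = {r.interface_id: r for r in ifaces}
    gene_of = {acc: f"G{acc[1:]}" for acc in sequences}

    def meta_for(level):
        if level == "interface":
            return {
                iid: (frozenset({gene_of.get(iface_by_id[iid].protein,
                                             iface_by_id[iid].protein)}), 1)
                for iid in tables[level].incidence
            }
        unit_fis = rxn_fis if level == "reaction" else pw_fis
        meta = {}
        for unit in tables[level].incidence:
            genes, ifids = set(), set()
            for fi in unit_fis.get(unit, ()):
                for side in (fi.a, fi.b):
                    if side in sequences:
                        genes.add(gene_of.get(side, side))
                ifids |= fi_map.get(fi, set())
            meta[unit] = (frozenset(genes), len(ifids))
        return meta

    results = {
        level: test_enrichment(tables[level], background, unit_meta=meta_for(level))
        for level in LEVELS
    }
    for level in LEVELS:
        write_enrichment_tsv(
            results[level],
            outdir / f"enrichment_{level}.tsv",
            cancer_type=cohort.cancer_type,
            alpha=config.fdr,
        )

    # --- survival screen
    survival_counts = {}
    if config.clinical:
        surv_table, surv_tally = derive_survival(read_clinical(config.clinical))
        for level in LEVELS:
            if config.survival_mode == "significant":
                units = [r.unit_id for r in results[level] if r.q_value < config.fdr]
            else:
                units = [r.unit_id for r in results[level]]
            carrier_sets = {u: tables[level].incidence.get(u, frozenset()) for u in units}
            surv = run_survival_screen(carrier_sets, surv_table, level)
            write_survival_tsv(surv, outdir / f"survival_{level}.tsv", alpha=config.fdr)
            survival_counts[level] = len(surv)
    else:
        surv_tally = {}

    # --- network / mapping / bookkeeping outputs
    write_sif(network, outdir / "reaction_network.sif")
    write_graphml(network, outdir / "reaction_network.graphml")
    write_fi_tsv(fis, outdir / "functional_interactions.tsv")
    with open(outdir / "fi_interface_map.tsv", "w") as fh:
        fh.write("a\tb\tfi_kind\tinterface_ids\n")
        for fi in sorted(fi_map, key=lambda f: (f.a, f.b)):
            fh.write(f"{fi.a}\t{fi.b}\t{fi.fi_kind}\t"
                     f"{';'.join(sorted(fi_map[fi]))}\n")
    write_drop_tally(cohort, outdir / "drop_tally.tsv")

    manifest = {
        "tool_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "cancer_type": cohort.cancer_type,
        "counts": {
            "samples": len(cohort.samples),
            "mapped_variants": len(cohort.variants),
            "malformed_maf_rows": parse_report["malformed"],
            "interfaces_considered": len(ifaces),
            "perturbation_events": len(events),
            "fis": len(fis),
            "tested_units": {lv: len(results[lv]) for lv in LEVELS},
            "significant_units": {
                lv: sum(r.q_value < config.fdr for r in results[lv]) for lv in LEVELS
            },
            "survival_fits": survival_counts,
            "clinical_drops": surv_tally,
        },
        "top_level_pathways": sorted(
            p.id for p in kb.pathways.values() if not p.parent_pathway_id
        ),
        "reaction_top_level": {
            rid: sorted({top for _p, top in pws}) for rid, pws in sorted(rollup.items())
        },
        "outputs": {},
    }
    for name in sorted(p.name for p in outdir.iterdir() if p.suffix in {".tsv", ".sif", ".graphml"}):
        manifest["outputs"][name] = _sha256_file(outdir / name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ----------------------------------------------------------------- report


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh]


def report(bundle_path: str | Path, figure: bool = False) -> Path:
    """Summarise a result bundle per top-level pathway.

    Emits ``pathway_summary.tsv`` with, for every top-level pathway having
    at least one significant unit: the number of unique perturbed samples,
    the number of FI interfaces involved, and the number of significant
    reactions mapping to it. Verifies recorded output hashes first.
    """
    bundle = Path(bundle_path)
    manifest = json.loads((bundle / "manifest.json").read_text())
    for name, digest in manifest["outputs"].items():
        actual = _sha256_file(bundle / name)
        if actual != digest:
            raise ValueError(f"bundle file {name} does not match its manifest hash")

    pathway_rows = _read_tsv(bundle / "enrichment_pathway.tsv")
    reaction_rows = _read_tsv(bundle / "enrichment_reaction.tsv")
    top_level = set(manifest["top_level_pathways"])
    rxn_top = manifest["reaction_top_level"]

    sig_reactions_per_top: dict[str, int] = {}
    for row in reaction_rows:
        if row["significant"] == "True":
            for top in rxn_top.get(row["unit_id"], []):
                sig_reactions_per_top[top] = sig_reactions_per_top.get(top, 0) + 1
    pw_by_id = {row["unit_id"]: row for row in pathway_rows}

    out_rows = []
    for top in sorted(top_level):
        row = pw_by_id.get(top)
        top_sig = row is not None and row["significant"] == "True"
        n_sig_rxn = sig_reactions_per_top.get(top, 0)
        if not top_sig and n_sig_rxn == 0:
            continue
        out_rows.append(
            {
                "top_level_pathway": top,
                "unique_samples": row["c"] if row else "0",
                "n_fi_interfaces": row["n_interfaces"] if row else "0",
                "n_significant_reactions": str(n_sig_rxn),
            }
        )
    out_path = bundle / "pathway_summary.tsv"
    cols = ("top_level_pathway", "unique_samples", "n_fi_interfaces",
            "n_significant_reactions")
    with open(out_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in out_rows:
            fh.write("\t".join(row[c] for c in cols) + "\n")

    if figure and out_rows:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 0.5 * len(out_rows) + 1.5))
        sizes = [40 * int(r["unique_samples"]) ** 0.5 for r in out_rows]
        shades = [int(r["n_fi_interfaces"]) for r in out_rows]
        ax.scatter(
            [int(r["n_significant_reactions"]) for r in out_rows],
            range(len(out_rows)),
            s=sizes,
            c=shades,
            cmap="viridis",
        )
        ax.set_yticks(range(len(out_rows)))
        ax.set_yticklabels([r["top_level_pathway"] for r in out_rows])
        ax.set_xlabel("significant reactions")
        fig.tight_layout()
        fig.savefig(bundle / "pathway_summary.png", dpi=120)
        plt.close(fig)
    return out_path
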