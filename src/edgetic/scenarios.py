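"""Reference validation scenarios for the statistical machinery.

Each function runs a fully seeded synthetic experiment end to end through
the public pipeline primitives and returns per-seed outcomes. They fix
the study conditions used to validate the method:

* ``null_calibration`` — cohorts with uniform placement and no planted
  signal; measures the attained level of the binomial enrichment test and
  the FDR false-positive behaviour.
* ``hotspot_recovery`` — a planted interface hotspot (per-sample hit
  probability 0.15 over 300 samples, on an interface whose background
  placement probability is verified to be <= 0.02 before planting);
  measures detection at interface level and at every reaction and
  pathway containing the interface's functional interaction.
* ``survival_recovery`` — a proportional-hazards effect (true HR) planted
  on the pathway with null carrier fraction closest to 1/2; measures
  hazard-ratio recovery, null confidence-interval coverage and whether
  the planted pathway attains the smallest adjusted p of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import (
    aggregate_to_units,
    estimate_background,
    interface_table,
    test_enrichment,
)
from .interface_mapping import call_perturbations, match_fis_to_interfaces
from .knowledgebase import (
    extract_functional_interactions,
    fis_by_pathway,
    fis_by_reaction,
    rollup_pathways,
)
from .survival import derive_survival, fit_cox_for_unit, run_survival_screen
from .synthetic_data import SimConfig, _cohort_from_rows, generate_all

__all__ = [
    "CALIBRATION_CONDITIONS",
    "RECOVERY_CONDITIONS",
    "SURVIVAL_CONDITIONS",
    "null_calibration",
    "hotspot_recovery",
    "survival_recovery",
]

#: Null cohorts at the generator's default density.
CALIBRATION_CONDITIONS: dict = dict(n_samples=200)

#: Sparse cohort over long proteins with small interfaces, so single
#: interfaces have low background placement probability and reaction /
#: pathway units are far from saturation.
RECOVERY_CONDITIONS: dict = dict(
    n_samples=300,
    n_proteins=30,
    n_reactions=20,
    n_pathways=10,
    protein_length_range=(300, 500),
    interface_size_range=(6, 10),
    interface_coverage=0.5,
    mutations_per_sample_range=(3, 8),
)

#: Moderate-density cohort large enough for survival contrasts.
SURVIVAL_CONDITIONS: dict = dict(
    n_samples=600,
    n_proteins=25,
    protein_length_range=(150, 350),
    interface_size_range=(12, 48),
    mutations_per_sample_range=(5, 12),
    censoring_rate=0.2,
)


def _dataset_views(ds):
    cohort = _cohort_from_rows(ds.config, ds.maf_rows, ds.sequences)
    fis = extract_functional_interactions(ds.kb)
    fi_map = match_fis_to_interfaces(fis, ds.interfaces, ds.fingerprints)
    rxn_fis = fis_by_reaction(fis)
    pw_fis = fis_by_pathway(fis, ds.kb)
    aggregators = {
        "interface": lambda ev: interface_table(ev, cohort.samples),
        "reaction": lambda ev: aggregate_to_units(
            ev, fi_map, rxn_fis, "reaction", cohort.samples
        ),
        "pathway": lambda ev: aggregate_to_units(
            ev, fi_map, pw_fis, "pathway", cohort.samples
        ),
    }
    return cohort, fi_map, aggregators


@dataclass
class CalibrationOutcome:
    raw_p_rate: float  # fraction of tested interfaces with raw p < 0.05
    n_tested: int
    n_fdr_significant: int


def null_calibration(n_seeds: int, base_seed: int = 0, R: int = 50) -> list[CalibrationOutcome]:
    out = []
    for k in range(n_seeds):
        ds = generate_all(SimConfig(seed=base_seed + k, **CALIBRATION_CONDITIONS))
        cohort, _fi_map, agg = _dataset_views(ds)
        iface_agg = {"interface": agg["interface"]}
        bm = estimate_background(
            cohort, ds.interfaces, iface_agg, R=R,
            seed=base_seed + 100_000 + 1000 * k,
        )
        events = call_perturbations(cohort, ds.interfaces)
        results = test_enrichment(agg["interface"](events), bm)
        out.append(
            CalibrationOutcome(
                raw_p_rate=float(np.mean([r.p_value < 0.05 for r in results])),
                n_tested=len(results),
                n_fdr_significant=sum(r.q_value < 0.05 for r in results),
            )
        )
    return out


@dataclass
class RecoveryOutcome:
    interface_significant: bool
    all_reactions_significant: bool
    all_pathways_significant: bool
    hierarchy_consistent: bool
    background_placement: float  # null placement probability of the hotspot


def _pick_hotspot(ds0, cohort0, fi_map, rollup, seed: int, max_placement: float = 0.02):
    """Choose the FI-matched protein interface with the lowest estimated
    null placement probability (must be <= max_placement)."""
    bm0 = estimate_background(
        cohort0, ds0.interfaces,
        {"interface": lambda ev: interface_table(ev, cohort0.samples)},
        R=20, seed=seed + 5_000_000,
    )
    candidates = []
    for rec in ds0.interfaces:
        if rec.partner_kind != "protein":
            continue
        for fi, ifs in fi_map.items():
            if rec.interface_id in ifs and any(
                rollup[r] for r in fi.source_reaction_ids
            ):
                p0 = bm0.p_r("interface", rec.interface_id)
                if p0 <= max_placement:
                    candidates.append((p0, rec.interface_id, fi))
                break
    if not candidates:
        raise RuntimeError("no eligible hotspot interface in this dataset")
    return min(candidates)


def hotspot_recovery(
    n_seeds: int, base_seed: int = 0, R: int = 50, hit_probability: float = 0.15
) -> list[RecoveryOutcome]:
    out = []
    for k in range(n_seeds):
        seed = base_seed + k
        ds0 = generate_all(SimConfig(seed=seed, **RECOVERY_CONDITIONS))
        cohort0, fi_map, _ = _dataset_views(ds0)
        rollup = rollup_pathways(ds0.kb)
        p0, iface_id, fi = _pick_hotspot(ds0, cohort0, fi_map, rollup, seed)

        ds = generate_all(
            SimConfig(seed=seed, hotspots=[(iface_id, hit_probability)],
                      **RECOVERY_CONDITIONS)
        )
        cohort, fi_map, agg = _dataset_views(ds)
        bm = estimate_background(
            cohort, ds.interfaces, agg, R=R, seed=seed + 100_000
        )
        events = call_perturbations(cohort, ds.interfaces)
        tables = {level: build(events) for level, build in agg.items()}
        results = {
            level: {r.unit_id: r for r in test_enrichment(tables[level], bm)}
            for level in tables
        }
        reactions = set(fi.source_reaction_ids)
        pathways = {p for r in reactions for p, _top in rollup[r]}
        hier = all(
            tables["reaction"].c(r) >= tables["interface"].c(iface_id)
            for r in reactions
        ) and all(
            tables["pathway"].c(p) >= tables["reaction"].c(r)
            for r in reactions
            for p, _top in rollup[r]
        )
        out.append(
            RecoveryOutcome(
                interface_significant=results["interface"][iface_id].q_value < 0.05,
                all_reactions_significant=all(
                    results["reaction"][r].q_value < 0.05 for r in reactions
                ),
                all_pathways_significant=all(
                    results["pathway"][p].q_value < 0.05 for p in pathways
                ),
                hierarchy_consistent=hier,
                background_placement=p0,
            )
        )
    return out


@dataclass
class SurvivalOutcome:
    hazard_ratio: float
    in_band: bool  # recovered HR within [1.6, 2.5]
    null_ci_covers_one: bool
    planted_ranks_first: bool
    n_carriers: int


def survival_recovery(
    n_seeds: int, base_seed: int = 0, true_hr: float = 2.0,
    band: tuple[float, float] = (1.6, 2.5),
) -> list[SurvivalOutcome]:
    out = []
    for k in range(n_seeds):
        seed = base_seed + k
        ds0 = generate_all(SimConfig(seed=seed, **SURVIVAL_CONDITIONS))
        cohort0, _fi_map, agg0 = _dataset_views(ds0)
        table0 = agg0["pathway"](call_perturbations(cohort0, ds0.interfaces))
        n = ds0.config.n_samples
        target = min(
            table0.incidence,
            key=lambda u: (abs(len(table0.incidence[u]) / n - 0.5), u),
        )
        ds = generate_all(
            SimConfig(seed=seed, survival_effect=(target, true_hr),
                      **SURVIVAL_CONDITIONS)
        )
        clin, _ = derive_survival(ds.clinical)
        res = fit_cox_for_unit(clin, table0.incidence[target], unit_id=target)
        screen = run_survival_screen(dict(table0.incidence), clin, "pathway")
        best_q = min(r.q_value for r in screen)
        ranks_first = any(
            r.unit_id == target and r.q_value == best_q for r in screen
        )
        clin_null, _ = derive_survival(ds0.clinical)  # same carriers, HR = 1
        res_null = fit_cox_for_unit(clin_null, table0.incidence[target])
        out.append(
            SurvivalOutcome(
                hazard_ratio=res.hazard_ratio,
                in_band=band[0] <= res.hazard_ratio <= band[1],
                null_ci_covers_one=res_null.ci_low <= 1.0 <= res_null.ci_high,
                planted_ranks_first=ranks_first,
                n_carriers=len(table0.incidence[target]),
            )
        )
    return out
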