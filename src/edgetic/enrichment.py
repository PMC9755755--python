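"""Shuffle-null background model and binomial enrichment testing.

The null model keeps each sample's substitution spectrum fixed and
randomises only placement: every variant's position is redrawn uniformly
among the *equivalent positions* of its protein — positions carrying the
same wild-type residue — without replacement within each
(sample, protein, residue-class) group. Replaying the perturbation
calling on ``R`` shuffled cohorts yields, for every unit (interface,
reaction or pathway), an add-one-smoothed estimate of the per-sample
probability ``P_r`` that the unit is perturbed by chance.

Observed unique-sample counts ``c`` out of ``N`` are then scored with a
one-sided upper-tail binomial test

    p = sum_{k=c}^{N} C(N, k) P_r^k (1 - P_r)^(N-k)

and adjusted per level with the Benjamini–Hochberg step-up; adjusted
p < 0.05 is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interface_mapping import InterfaceRecord, PerturbationEvent, call_perturbations
from .knowledgebase import FunctionalInteraction
from .variant_io import Cohort, ProteinVariant

__all__ = [
    "PerturbationTable",
    "BackgroundEstimate",
    "BackgroundModel",
    "EnrichmentResult",
    "shuffle_cohort",
    "estimate_background",
    "binomial_tail",
    "bh_adjust",
    "interface_table",
    "aggregate_to_units",
    "test_enrichment",
    "write_enrichment_tsv",
]

_TINY = 5e-324  # smallest positive float: keeps p-values in (0, 1]


@dataclass
class PerturbationTable:
    """Binary unit × sample incidence of '>=1 perturbing mutation'.

    Stored sparsely: ``incidence[unit]`` is the set of samples carrying at
    least one perturbing mutation mapped to the unit; units with c = 0 may
    be absent.
    """

    unit_level: str  # interface | reaction | pathway
    samples: tuple[str, ...]
    incidence: dict[str, frozenset[str]]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def c(self, unit_id: str) -> int:
        return len(self.incidence.get(unit_id, ()))

    def units(self) -> list[str]:
        return sorted(self.incidence)


@dataclass(frozen=True)
class BackgroundEstimate:
    unit_id: str
    p_r: float
    replicates: int
    hits: int  # (replicate, sample) pairs with >=1 perturbing event
    seed: int


@dataclass
class EnrichmentResult:
    unit_id: str
    unit_level: str
    c: int
    N: int
    p_r: float
    p_value: float
    q_value: float
    member_genes: frozenset[str] = frozenset()
    n_interfaces: int = 0


# ------------------------------------------------------------------ shuffle


class _ClassIndex:
    """Per-protein map residue -> array of 1-based positions carrying it."""

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences = sequences
        self._cache: dict[str, dict[str, np.ndarray]] = {}

    def positions(self, protein: str, residue: str) -> np.ndarray:
        per_protein = self._cache.get(protein)
        if per_protein is None:
            per_protein = {}
            for i, ch in enumerate(self._sequences[protein]):
                per_protein.setdefault(ch, []).append(i + 1)
            per_protein = {ch: np.asarray(v) for ch, v in per_protein.items()}
            self._cache[protein] = per_protein
        return per_protein[residue]


def shuffle_cohort(
    cohort: Cohort,
    seed: int | np.random.Generator,
    class_index: _ClassIndex | None = None,
) -> Cohort:
    """Randomly re-place each sample's substitutions among equivalent
    positions (same protein, same wild-type residue), without replacement
    within each group. Alt-residue multisets per group are preserved."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = class_index or _ClassIndex(cohort.sequences)
    groups: dict[tuple[str, str, str], list[int]] = {}
    for i, v in enumerate(cohort.variants):
        groups.setdefault((v.sample_id, v.protein, v.ref_aa), []).append(i)
    positions: list[int] = [0] * len(cohort.variants)
    # singleton groups (the common case) are drawn in one vectorised pass
    singles: list[int] = []
    single_eligible: list[np.ndarray] = []
    for (sample, protein, ref), idxs in groups.items():
        eligible = index.positions(protein, ref)
        if len(idxs) > len(eligible):
            raise AssertionError(
                f"{len(idxs)} variants but only {len(eligible)} positions of "
                f"{ref!r} in {protein!r} (sample {sample!r})"
            )
        if len(idxs) == 1:
            singles.append(idxs[0])
            single_eligible.append(eligible)
        else:
            drawn = rng.choice(eligible, size=len(idxs), replace=False)
            for i, pos in zip(idxs, drawn):
                positions[i] = int(pos)
    if singles:
        sizes = np.fromiter((len(e) for e in single_eligible), dtype=np.int64)
        slots = (rng.random(len(singles)) * sizes).astype(np.int64)
        for i, eligible, slot in zip(singles, single_eligible, slots):
            positions[i] = int(eligible[slot])
    new_variants = [
        ProteinVariant(
            protein=old.protein,
            position=positions[i],
            ref_aa=old.ref_aa,
            alt_aa=old.alt_aa,
            sample_id=old.sample_id,
            cancer_type=old.cancer_type,
        )
        for i, old in enumerate(cohort.variants)
    ]
    return Cohort(
        variants=new_variants,
        samples=set(cohort.samples),
        cancer_type=cohort.cancer_type,
        sequences=cohort.sequences,
    )


# --------------------------------------------------------------- background


@dataclass
class BackgroundModel:
    """Per-unit background hit counts accumulated over R shuffled cohorts.

    ``p_r = (hits + 1) / (R*N + 1)`` with hits capped at ``R*N - 1`` so the
    probability stays strictly inside (0, 1); units never hit in the
    background get the minimal pseudocount probability ``1 / (R*N + 1)``.
    """

    replicates: int
    n_samples: int
    seed: int
    hits: dict[str, dict[str, int]] = field(default_factory=dict)  # level -> unit -> n

    def p_r(self, level: str, unit_id: str) -> float:
        rn = self.replicates * self.n_samples
        h = min(self.hits.get(level, {}).get(unit_id, 0), rn - 1)
        return (h + 1) / (rn + 1)

    def estimate(self, level: str, unit_id: str) -> BackgroundEstimate:
        return BackgroundEstimate(
            unit_id=unit_id,
            p_r=self.p_r(level, unit_id),
            replicates=self.replicates,
            hits=self.hits.get(level, {}).get(unit_id, 0),
            seed=self.seed,
        )

    def estimates(self, level: str) -> list[BackgroundEstimate]:
        return [self.estimate(level, u) for u in sorted(self.hits.get(level, {}))]


def estimate_background(
    cohort: Cohort,
    records: Sequence[InterfaceRecord],
    aggregators: Mapping[str, Callable[[list[PerturbationEvent]], PerturbationTable]],
    R: int = 100,
    seed: int = 0,
) -> BackgroundModel:
    """Run R within-protein shuffles and replay perturbation calling.

    ``aggregators`` maps each unit level to a callable turning an event
    list into a :class:`PerturbationTable` (see :func:`interface_table`
    and :func:`aggregate_to_units`). Replicate i uses seed ``seed + i``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    N = len(cohort.samples)
    model = BackgroundModel(replicates=R, n_samples=N, seed=seed)
    model.hits = {level: {} for level in aggregators}
    index = _ClassIndex(cohort.sequences)
    for i in range(R):
        shuffled = shuffle_cohort(cohort, seed + i, class_index=index)
        events = call_perturbations(shuffled, records)
        for level, build in aggregators.items():
            table = build(events)
            acc = model.hits[level]
            for unit, sample_set in table.incidence.items():
                acc[unit] = acc.get(unit, 0) + len(sample_set)
    return model


# -------------------------------------------------------------- statistics


def binomial_tail(c: int, N: int, p: float) -> float:
    """One-sided upper-tail binomial probability P(X >= c), X ~ Bin(N, p).

    Computed through the survival function for numerical stability.
    """
    if not 0 <= c <= N:
        raise ValueError(f"c must be in [0, N]; got c={c}, N={N}")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1); got {p}")
    if c == 0:
        return 1.0
    return max(float(stats.binom.sf(c - 1, N, p)), _TINY)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


# -------------------------------------------------------------- aggregation


def interface_table(
    events: Iterable[PerturbationEvent], samples: Iterable[str]
) -> PerturbationTable:
    """Interface-level incidence: unique samples per perturbed interface."""
    incidence: dict[str, set[str]] = {}
    for ev in events:
        incidence.setdefault(ev.interface_id, set()).add(ev.sample_id)
    return PerturbationTable(
        unit_level="interface",
        samples=tuple(sorted(samples)),
        incidence={u: frozenset(s) for u, s in incidence.items()},
    )


def aggregate_to_units(
    events: Iterable[PerturbationEvent],
    fi_to_interfaces: Mapping[FunctionalInteraction, set[str]],
    unit_to_fis: Mapping[str, set[FunctionalInteraction]],
    level: str,
    samples: Iterable[str],
) -> PerturbationTable:
    """Roll interface events up to reactions or pathways.

    A sample counts once for a unit when it has >=1 event at any interface
    matched to any of the unit's FIs.
    """
    if level not in {"reaction", "pathway"}:
        raise ValueError(f"level must be 'reaction' or 'pathway', got {level!r}")
    samples_by_iface: dict[str, set[str]] = {}
    for ev in events:
        samples_by_iface.setdefault(ev.interface_id, set()).add(ev.sample_id)
    incidence: dict[str, frozenset[str]] = {}
    for unit, fis in unit_to_fis.items():
        hit: set[str] = set()
        for fi in fis:
            for iid in fi_to_interfaces.get(fi, ()):
                hit |= samples_by_iface.get(iid, set())
        if hit:
            incidence[unit] = frozenset(hit)
    return PerturbationTable(
        unit_level=level, samples=tuple(sorted(samples)), incidence=incidence
    )


# ----------------------------------------------------------------- testing


def test_enrichment(
    table: PerturbationTable,
    background: BackgroundModel,
    unit_meta: Mapping[str, tuple[frozenset[str], int]] | None = None,
) -> list[EnrichmentResult]:
    """Score every unit with c >= 1 against its background probability.

    Units with c = 0 are not tested and do not enter the BH family. The
    family is all tested units of one level (callers run one cancer type
    per invocation). Results are sorted by q, then by c descending.
    """
    units = table.units()
    N = table.n_samples
    results: list[EnrichmentResult] = []
    p_values: list[float] = []
    for unit in units:
        c = table.c(unit)
        if c == 0:
            continue
        p_r = background.p_r(table.unit_level, unit)
        pv = binomial_tail(c, N, p_r)
        genes, n_ifaces = (unit_meta or {}).get(unit, (frozenset(), 0))
        results.append(
            EnrichmentResult(
                unit_id=unit,
                unit_level=table.unit_level,
                c=c,
                N=N,
                p_r=p_r,
                p_value=pv,
                q_value=1.0,
                member_genes=genes,
                n_interfaces=n_ifaces,
            )
        )
        p_values.append(pv)
    for res, q in zip(results, bh_adjust(p_values)):
        res.q_value = max(float(q), _TINY)
    results.sort(key=lambda r: (r.q_value, -r.c, r.unit_id))
    return results


def write_enrichment_tsv(
    results: Iterable[EnrichmentResult],
    path: str | Path,
    cancer_type: str = "",
    alpha: float = 0.05,
) -> None:
    """Results table mirroring the per-level supplementary-table layout."""
    cols = (
        "unit_id",
        "level",
        "cancer_type",
        "genes",
        "n_interfaces",
        "c",
        "N",
        "p_r",
        "p_value",
        "q_value",
        "significant",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.unit_id,
                        r.unit_level,
                        cancer_type,
                        ";".join(sorted(r.member_genes)),
                        str(r.n_interfaces),
                        str(r.c),
                        str(r.N),
                        f"{r.p_r:.6g}",
                        f"{r.p_value:.6g}",
                        f"{r.q_value:.6g}",
                        str(r.q_value < alpha),
                    ]
                )
                + "\n"
            )
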