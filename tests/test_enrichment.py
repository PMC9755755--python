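from fractions import Fraction
from math import comb

import numpy as np
import pytest

from edgetic.enrichment import (
    BackgroundModel,
    aggregate_to_units,
    bh_adjust,
    binomial_tail,
    estimate_background,
    interface_table,
    shuffle_cohort,
)
from edgetic.enrichment import test_enrichment as score_enrichment
from edgetic.interface_mapping import InterfaceRecord, PerturbationEvent
from edgetic.knowledgebase import FunctionalInteraction
from edgetic.variant_io import Cohort, ProteinVariant


def exact_binomial_tail(c, N, p: Fraction) -> Fraction:
    """Independent oracle: exact rational upper-tail summation."""
    return sum(comb(N, k) * p**k * (1 - p) ** (N - k) for k in range(c, N + 1))


def bh_reference(ps):
    """Independent five-line step-up implementation."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    qs, running = [0.0] * m, 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * m / rank)
        qs[i] = running
    return qs


def make_cohort(variants, sequences):
    return Cohort(
        variants=variants,
        samples={v.sample_id for v in variants} or set(),
        cancer_type="SYN",
        sequences=sequences,
    )


class TestShuffle:
    def test_single_eligible_site_unchanged(self):
        seqs = {"P1": "AXAAB".replace("X", "W")}  # exactly one W, at position 2
        cohort = make_cohort([ProteinVariant("P1", 2, "W", "R", "S1")], seqs)
        out = shuffle_cohort(cohort, seed=0)
        assert out.variants[0].position == 2

    def test_empty_cohort(self):
        cohort = make_cohort([], {"P1": "AAAA"})
        out = shuffle_cohort(cohort, seed=1)
        assert out.variants == []

    def test_conservation_on_random_cohort(self):
        rng = np.random.default_rng(7)
        seqs = {f"P{i}": "".join(rng.choice(list("ACDEFG"), size=60)) for i in range(3)}
        variants = []
        for s in range(5):
            for _ in range(10):
                p = f"P{rng.integers(3)}"
                pos = int(rng.integers(1, 61))
                variants.append(
                    ProteinVariant(p, pos, seqs[p][pos - 1], "Y", f"S{s}")
                )
        cohort = make_cohort(variants, seqs)

        def signature(c):
            d = {}
            for v in c.variants:
                d.setdefault((v.sample_id, v.protein, v.ref_aa), []).append(v.alt_aa)
            return {k: sorted(v) for k, v in d.items()}

        for seed in range(20):
            out = shuffle_cohort(cohort, seed)
            assert signature(out) == signature(cohort)
            for v in out.variants:
                assert seqs[v.protein][v.position - 1] == v.ref_aa

    def test_without_replacement_within_group(self):
        seqs = {"P1": "GAGAG"}
        cohort = make_cohort(
            [ProteinVariant("P1", 1, "G", "R", "S1"),
             ProteinVariant("P1", 3, "G", "R", "S1")],
            seqs,
        )
        for seed in range(50):
            out = shuffle_cohort(cohort, seed)
            ps = [v.position for v in out.variants]
            assert len(set(ps)) == 2 and set(ps) <= {1, 3, 5}


class TestBackground:
    def test_pseudocount_for_never_hit_unit(self):
        model = BackgroundModel(replicates=10, n_samples=10, seed=0,
                                hits={"interface": {}})
        assert model.p_r("interface", "I_unseen") == pytest.approx(1 / 101)

    def test_saturation_cap(self):
        model = BackgroundModel(replicates=10, n_samples=10, seed=0,
                                hits={"interface": {"I1": 100}})
        assert model.p_r("interface", "I1") == pytest.approx(100 / 101)

    def test_single_interface_closed_form(self):
        """1 eligible position of 10 sits at the interface and each sample
        carries one variant: per-sample background hit probability is 1/10."""
        seqs = {"P1": "A" * 10}
        N = 20
        cohort = make_cohort(
            [ProteinVariant("P1", 1 + s % 10, "A", "V", f"S{s:02d}") for s in range(N)],
            seqs,
        )
        rec = InterfaceRecord("I1", "P1", "P2", "protein", frozenset({3}), 90.0, 1e-9)
        R = 2000
        model = estimate_background(
            cohort, [rec],
            {"interface": lambda ev: interface_table(ev, cohort.samples)},
            R=R, seed=5,
        )
        se = (0.1 * 0.9 / (R * N)) ** 0.5
        assert model.p_r("interface", "I1") == pytest.approx(0.1, abs=3 * se)

    def test_nonpositive_R_rejected(self):
        cohort = make_cohort([], {"P1": "AAAA"})
        with pytest.raises(ValueError):
            estimate_background(cohort, [], {}, R=0, seed=0)


class TestBinomialTail:
    def test_trivial_values(self):
        assert binomial_tail(0, 10, 0.2) == 1.0
        assert binomial_tail(1, 1, 0.3) == pytest.approx(0.3, rel=1e-12)

    def test_against_exact_rational_oracle(self):
        expected = exact_binomial_tail(7, 20, Fraction(1, 10))
        got = binomial_tail(7, 20, 0.1)
        assert got == pytest.approx(float(expected), rel=1e-12)

    @pytest.mark.parametrize("p", [0.01, 0.1, 0.3, 0.5])
    def test_oracle_grid_small(self, p):
        pf = Fraction(p).limit_denominator(100)
        for N in (5, 13, 30):
            pmf = [comb(N, k) * pf**k * (1 - pf) ** (N - k) for k in range(N + 1)]
            tail = Fraction(0)
            exact = [Fraction(0)] * (N + 2)
            for k in range(N, -1, -1):
                tail += pmf[k]
                exact[k] = tail
            for c in range(1, N + 1):
                assert binomial_tail(c, N, p) == pytest.approx(
                    float(exact[c]), rel=1e-10
                )

    def test_monotone_in_c(self):
        vals = [binomial_tail(c, 50, 0.2) for c in range(51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binomial_tail(5, 4, 0.1)
        with pytest.raises(ValueError):
            binomial_tail(1, 4, 0.0)


class TestBHAdjust:
    def test_single_and_hand_case(self):
        assert bh_adjust([0.04]) == [pytest.approx(0.04)]
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ps = list(rng.uniform(1e-6, 1.0, size=rng.integers(1, 40)))
            assert bh_adjust(ps) == pytest.approx(bh_reference(ps), rel=1e-12)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(3)
        ps = list(rng.uniform(0.001, 1.0, size=25))
        qs = bh_adjust(ps)
        perm = list(rng.permutation(25))
        qs_perm = bh_adjust([ps[i] for i in perm])
        assert qs_perm == pytest.approx([qs[i] for i in perm])

    def test_empty(self):
        assert bh_adjust([]) == []


def fi(a, b, rxns):
    aa, bb = sorted((a, b))
    return FunctionalInteraction(aa, bb, "protein_protein", frozenset(rxns))


def ev(sample, iid):
    v = ProteinVariant("P1", 1, "A", "G", sample)
    return PerturbationEvent(sample, iid, v)


class TestAggregation:
    def test_same_sample_on_two_fis_counts_once(self):
        f1, f2 = fi("A", "B", ["R1"]), fi("C", "D", ["R1"])
        fi_map = {f1: {"I1"}, f2: {"I2"}}
        unit_map = {"R1": {f1, f2}}
        table = aggregate_to_units(
            [ev("S1", "I1"), ev("S1", "I2")], fi_map, unit_map, "reaction", {"S1", "S2"}
        )
        assert table.c("R1") == 1

    def test_pathway_superset_monotone(self):
        f1, f2 = fi("A", "B", ["R1"]), fi("C", "D", ["R2"])
        fi_map = {f1: {"I1"}, f2: {"I2"}}
        events = [ev("S1", "I1"), ev("S2", "I2")]
        samples = {"S1", "S2", "S3"}
        rxn = aggregate_to_units(events, fi_map, {"R1": {f1}, "R2": {f2}},
                                 "reaction", samples)
        pw = aggregate_to_units(events, fi_map, {"PW": {f1, f2}}, "pathway", samples)
        assert pw.c("PW") >= max(rxn.c("R1"), rxn.c("R2"))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(23)
        fis = [fi(f"A{i}", f"B{i}", [f"R{rng.integers(3)}", f"R{rng.integers(3)}"])
               for i in range(6)]
        fi_map = {f: {f"I{j}" for j in rng.choice(10, size=2, replace=False)}
                  for f in fis}
        unit_map = {}
        for f in fis:
            for r in f.source_reaction_ids:
                unit_map.setdefault(r, set()).add(f)
        samples = [f"S{k}" for k in range(8)]
        events = [ev(rng.choice(samples), f"I{rng.integers(10)}") for _ in range(40)]
        table = aggregate_to_units(events, fi_map, unit_map, "reaction", samples)
        # oracle: exhaustive traversal of (sample, reaction, FI, interface)
        expected = {}
        for s in samples:
            for r, fset in unit_map.items():
                for f in fset:
                    for i in fi_map[f]:
                        if any(e.sample_id == s and e.interface_id == i for e in events):
                            expected.setdefault(r, set()).add(s)
        assert {u: set(v) for u, v in table.incidence.items()} == expected


class TestEnrichment:
    def test_zero_count_units_not_tested(self):
        table = interface_table([], ["S1", "S2"])
        model = BackgroundModel(2, 2, 0, hits={"interface": {}})
        assert score_enrichment(table, model) == []

    def test_strong_signal_is_significant(self):
        samples = [f"S{i}" for i in range(100)]
        events = [ev(s, "I1") for s in samples[:30]]
        table = interface_table(events, samples)
        # p_r = 0.01 via hits: (hits+1)/(R*N+1) with R=100, N=100
        model = BackgroundModel(100, 100, 0, hits={"interface": {"I1": 100}})
        assert model.p_r("interface", "I1") == pytest.approx(101 / 10001, rel=1e-9)
        res = score_enrichment(table, model)[0]
        assert res.p_value < 1e-20
        assert res.q_value < 0.05

    def test_monotone_unique_sample_counts(self):
        samples = ["S1", "S2", "S3"]
        events = [ev("S1", "I1")]
        more = events + [ev("S2", "I1"), ev("S2", "I2")]
        t1 = interface_table(events, samples)
        t2 = interface_table(more, samples)
        for u in t1.incidence:
            assert t2.c(u) >= t1.c(u)
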