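# Methods

## Model and procedure

The pipeline treats a tumour cohort as a set of samples, each carrying
missense substitutions on a shared proteome. A substitution *perturbs*
an interface when its (1-based) position lies among the interface's
contact residues; events are counted per interface with per-sample
deduplication, and rolled up to reactions and pathways through the
knowledgebase: a sample counts once for a reaction (pathway) when it
perturbs any interface matched to any functional interaction (FI) the
reaction (pathway) mediates. This makes the three levels nested by
construction: c(pathway) ≥ c(reaction) ≥ c(interface) for contained
units, which the test suite asserts.

### FI extraction

Reactome-style reactions are expanded to FIs by three rules, applied
after recursively flattening complexes and entity sets to accessioned
leaves (proteins, chemicals):

(a) every pair of distinct leaves co-occurring in one complex among the
    reaction's inputs or outputs;
(b) every (catalyst leaf, input leaf) pair;
(c) every (regulator leaf, catalyst-or-output leaf) pair.

Chemical–chemical pairs are discarded. Members of one entity set are
alternative molecules, never interaction partners, so two leaves whose
flattening paths traversed the same set are never paired. This rule set
is a deliberate minimal choice: it is deterministic, auditable, and
reproduces the canonical four-FI expansion of the TP53-family binding
reaction used as the worked example. Richer FI sources (predicted
interactions, non-reaction annotations) are out of scope.

### Reaction network

r1 → r2 whenever an output entity of r1 is an input, catalyst or
regulator of r2, by entity id (complexes connect as whole entities; they
are not flattened here). Currency metabolites — ATP, ADP, Pi, H2O, GTP,
GDP, CO2, H+ — are removed before the intersection, since they would
connect nearly everything to nearly everything. Matching is by chemical
display name (case-sensitive, configurable list) because currency
species are named, not accessioned, consistently across sources.

### Background model and test

The null preserves each sample's substitution spectrum and randomises
placement only: within each (sample, protein, wild-type residue) group,
positions are redrawn uniformly, without replacement, among the
protein's positions carrying that residue. "Equivalent positions" is not
further constrained; same-residue is the weakest condition under which
"the same substitution" remains well defined (an A→V at one alanine can
move to any other alanine). Sampling without replacement prevents two of
a sample's mutations collapsing onto one site, mirroring the observed
data where duplicate (sample, protein, position) rows are collapsed.

R shuffled cohorts (default R = 100; the validation scenarios use R = 50)
are replayed through the identical perturbation-calling and aggregation
code. For unit *u*, `hits` counts (replicate, sample) pairs with ≥ 1
event, and

    P_r = (min(hits, R·N − 1) + 1) / (R·N + 1)

The add-one rule keeps P_r strictly inside (0, 1) — units never hit in
the background get the minimal pseudocount 1/(R·N+1), and a unit hit in
every replicate-sample is capped below 1 — so the binomial tail is
always defined. Replicate i uses seed `seed + i`.

The reported p-value is the one-sided upper binomial tail
P(X ≥ c), X ~ Binom(N, P_r), computed through the survival function
(never by naive factorial summation); the enrichment direction is the
only one tested. BH adjustment is applied per unit level within one
cohort (one cancer type per invocation); units with c = 0 are not tested
and do not enter the family. Significance is adjusted p < 0.05.

A single shared P_r per unit is used for all samples, as the
single-parameter binomial form implies. Two consequences, measured in
the validation battery and worth knowing:

* the counts are discrete, so the attained level of a p < 0.05 rule sits
  below 0.05 by roughly half the pmf mass at the rejection boundary;
* the background conditions on each sample's substitution composition,
  so observed counts are mildly under-dispersed relative to the marginal
  binomial (standardized-residual sd ≈ 0.93 in the null battery).

Both push the same way: the test is conservative. On null synthetic
cohorts (200 samples, R = 50) the measured fraction of tested interfaces
with raw p < 0.05 is ≈ 0.027, not 0.05, and essentially no unit survives
FDR. Power is nevertheless high for real signals: a planted hotspot with
per-sample hit probability 0.15 against background placement ≤ 0.02 is
recovered at interface, reaction and pathway level in ≈ 100% of seeded
runs (see `edgetic/scenarios.py`).

### Survival screen

Clinical records contribute event = 1 with time = days_to_death for the
dead, event = 0 with time = days_to_last_follow_up for the alive; rows
with missing required fields, genders outside {male, female}, or
non-positive times are dropped with tallied reasons. Each screened unit
is fit with Cox proportional hazards over {carrier, age, sex} using the
Efron tie approximation; the carrier indicator is exactly the unit's
incidence row from the perturbation table (no re-derivation). Units need
≥ 2 carriers, ≥ 2 non-carriers and ≥ 1 event; non-convergent fits are
skipped with a logged reason. Hazard ratio = exp(carrier coefficient),
95% CI from the coefficient's standard error; BH per level. By default
only enrichment-significant units are screened ("significant" mode); the
"all" mode screens every tested unit.

## Synthetic data

The generator emulates the statistical structure the method assumes:
uniform substitution placement over protein positions (with per-protein
rates proportional to length), structure-like interfaces annotated for
knowledgebase FIs, and exponential survival with proportional hazards.
Null placement is deliberately identical in law to the shuffle null —
positions uniform, reference residues read from the sequence — so
calibration experiments measure the test, not a generator mismatch.
Interfaces are generated *from* the extracted FIs (protein partners by
accession, chemical partners as ligands whose fingerprints are
perturbed copies of the matching chemical's), plus unmatched and
nucleic-acid extras, so FI↔interface matching is exercised end to end.
Hotspots add one variant at a uniformly chosen interface position with a
stated per-sample probability; survival effects multiply the baseline
hazard (default 1/1000 per day) for carriers of a chosen pathway, with
carriers derived through the real pipeline mappings, and independent
exponential censoring tuned so that the requested fraction of samples is
censored. Everything derives from one integer seed; two runs with one
config are byte-identical.

Default cohort conditions: 25 proteins of 150–350 residues, 200 samples,
20–60 missense mutations per sample concentrated on this annotated
sub-proteome, interfaces of 12–48 residues covering 80% of proteins.
These were chosen so that per-interface carrier counts (≈ 15–60 of 200)
are informative for a count statistic while staying at desk scale. The
validation scenarios in `edgetic/scenarios.py` state their own
conditions: recovery uses a sparse cohort (300 samples, 3–8 mutations,
6–10-residue interfaces on 300–500-residue proteins) so that single
interfaces have background placement ≤ 0.02 and pathway units are far
from saturation; the survival scenario uses 600 samples with 20%
censoring and plants HR = 2 on the pathway whose null carrier fraction
is closest to 1/2 (best contrast).

What the generator does **not** emulate: trinucleotide mutational
signatures, per-gene selection, hypermutator tails, isoform choice,
correlated interface geometry, or informative censoring. Passing
validation therefore demonstrates the statistical machinery is correct
under its own assumptions, not that those assumptions hold in any real
cohort.

## Numerical and design choices

* Positions are 1-based everywhere; no 0-based coordinates exist in the
  pipeline.
* Identity thresholds are inclusive (≥ 70, ≥ 30); the Tanimoto threshold
  is strict (> 0.5); the E-value threshold is ≤ 1e-4.
* "Non-synonymous" defaults to {Missense_Mutation}; nonsense and indel
  classes are excluded because interface perturbation is defined
  positionally for substitutions (configurable).
* Transcript-length equality stands in for external transcript–protein
  reconciliation: it accepts exactly the records whose stated peptide
  length matches the provided sequence.
* Tanimoto of two all-zero fingerprints is defined as 0.
* p- and q-values are clamped to ≥ 5e-324 so they remain in (0, 1].
* Enrichment results sort by (q, −c, unit id); survival results by
  (q, p, unit id) — deterministic under ties.
* BH families: per level, per cohort, for both enrichment and survival.
* The shuffle's singleton groups (one variant in a residue class) are
  drawn in one vectorised pass; multi-variant groups use explicit
  without-replacement draws. The two paths are statistically identical.

## Known limitations

* The calibration deficit described above: raw-p rates on null data run
  ≈ 2.5–3% at nominal 5%. Conservative, never anti-conservative, in all
  measured conditions.
* At desk scale the knowledgebase has few, large pathways; pathway-level
  saturation (c → N) can mask planted signals in dense cohorts. Real
  knowledgebases, with thousands of small pathways, sit closer to the
  recovery scenario's sparse regime.
* Nucleic-acid interfaces are carried to the interface level only; the
  knowledgebase FIs cover protein–protein and protein–chemical pairs.
* One cohort per invocation; pan-cancer analyses loop over cohorts.
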