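# Methods

## Scope and data model

The package analyses enhancer-swap experiments coded at the level of
*pattern relations*: whether two expression patterns are alike or different
is taken as upstream curation, not re-derived from images. Any detectable
difference — spatial, ectopic, or timing — counts as "different"; expression
that is weaker but spatially correct counts as "alike" (intensity is not
modelled; the relation is the datum). Each record carries the donor and
host taxa (the host is always one of the two anchor species), a set of
clade-stratum tags, the controlled flag, the three relations, the original
study's stated expectation (conservation / divergence / unstated), and —
for sex-specific enhancers — curated sex- and tissue-fidelity flags.
Fidelity is deliberately a recorded observation rather than a function of
the category: a swap can diverge in mode yet still drive proper
sex-specific expression.

Deduplication keeps one record per (enhancer, donor, host) triple,
preferring the record flagged as the longest tested fragment. Two fields
(`enhancer`, `fragment_longest`) exist purely to make that rule executable.

## Classification

`classify_controlled` is a total map over the 5 consistent relation triples
(see README table); the 3 inconsistent triples raise with an explanation.
The rubric is parsimony-based: each consistent triple is assigned the
simplest mechanism that produces it, so the amount of regulatory evolution
is if anything underestimated. Non-controlled experiments use the two-way
map (alike → Category I, different → Category II). Category II is kept as
its own "unresolved" mode-axis value rather than pooled into misregulation;
the distant-nematode comparison, which mixes Categories 4, 5 and II in
print, is reproduced by an explicit pooled tally over {C4, C5, NC_II}, so
no information is silently discarded elsewhere.

## Dataset reconstruction from marginal tallies

Row-level codings of the 230-experiment corpus are not recoverable from the
published aggregates, so the packaged dataset is a *constraint-satisfying
reconstruction*: 35 published marginals (full-corpus counts, per-clade
category tables, expectation-stratified counts, sex-fidelity counts,
per-gene counts for *yellow*) are encoded as subset predicates with
expected counts, and `build_fixture` solves for non-negative integer
multiplicities of row *templates* — the cross product of a fixed catalog of
cohort profiles (close *Caenorhabditis* pairs, distant nematodes, four
*Drosophila*/insect cohorts including the two sex-specific ones) with
category, expectation, sex flags and gene — such that every constraint is
met exactly. The program is solved with HiGHS (`scipy.optimize.milp`,
deterministic); an infeasible constraint set is reported with a minimal
conflicting subset found by a deletion filter. The seed controls only
presentational randomness (row order, identifier assignment, species/gene
name cycling, which side of a non-controlled swap is the known one), so
identical seeds give identical tables and different seeds give identical
tallies.

Design points worth recording:

- The published strata overlap and do not partition the corpus (the
  per-clade table covers only the 146 controlled experiments). Each
  constraint is evaluated over its own declared subset; no global partition
  is imposed.
- Close-nematode arithmetic: 34 conserved / 30 diverged among close worm
  pairs, of which the controlled portion is 7/11/6 by category; the
  reconstruction therefore carries 27 Category-I and 13 Category-II
  non-controlled close-worm rows — the only allocation consistent with both
  printed tallies.
- The distant-nematode row prints the same "(Category 4, 5, II)" label with
  count 10 under both divergence and misregulation. The reconstruction
  encodes two disjoint sets of ten (a pooled tally of 20) and flags the
  constraint with a note. Counting the controlled experiments shows the
  three category-labelled clade rows already sum to exactly 146, so none of
  these 20 rows can be controlled; all are Category II here.
- Unknown relations use the literal sentinel `unknown`; an empty cell is a
  load error, never a default, because silent defaults corrupt tallies.
- The expectation marginals (141 + 89 = 230) imply every reconstructed row
  carries a stated expectation; `unstated` remains legal for curated data.
- One printed percentage is internally rounded inconsistently in the
  source: 72/141 is described as 50% but computes to 51.06%. The report
  keeps the computed value and records the discrepancy in the entry note.

What passing validation shows — and what it does not: the reconstruction
demonstrates that the rubric, the groupings and all 35 printed marginals
are *jointly* satisfiable and that the full pipeline (constraint solver →
classifier → grouping → recount) is internally consistent. It cannot
validate row-level claims (which gene diverged in which species pair);
those require the original curated table.

## Statistics

Fisher's exact test is computed by full enumeration of the hypergeometric
support at fixed margins using exact integer binomial weights; the
two-sided p-value sums the probabilities of all tables whose point
probability is at most the observed one, with a 1e-7 relative slack on the
comparison (absorbing ties without floating-point hazards). This
minimum-likelihood convention is the dominant one and reproduces the
published p = 0.46 for the close-worm vs *obscura* comparison; one-sided
variants are provided but unused by the report. A zero row or column margin
returns p = 1 with a degeneracy flag. The implementation is cross-checked
in the test suite against an independent rational-arithmetic brute-force
enumerator (exact agreement over every table with grand total ≤ 16 plus a
seeded sample up to total 40) and against scipy.

The two-proportion z-test uses the pooled-variance form with a one-tailed
normal p-value; a pooled proportion of 0 or 1 is flagged degenerate with
p = 1. It is cross-checked against statsmodels at 1e-9. The published
z = 5.01 for insect Category 3 vs Category 2 cannot be recomputed from the
printed text because the per-category insect counts appear only in a
figure; the report computes the statistic on the reconstruction (where the
C2/C3 split within the divergence tallies is constrained only by the
*yellow*-gene counts) and attaches no reference value to it.

Percent display follows the source's per-entry rounding (e.g. 40/84 shown
as 48%), with raw count pairs always retained. No multiple-testing
correction is applied, matching the original analysis.

## Simulator

The generative model is the simplest one that realizes every outcome
category mechanistically. A genotype is a multiset of binding sites (each a
specificity label) on one cis element plus a set of activating factors
(label + expression-domain set); the output pattern is the union of domains
of factors whose label matches at least one site. Activator-only logic with
union semantics — no repression, cooperativity, or dosage — is an explicit
simplification (extension point, not a claim about real enhancers).

Default configuration: alphabet of 12 labels, 10 expression domains, 3
ancestral factors with distinct labels and disjoint domains, 2 ancestral
sites. Default per-step event probabilities: site gain 0.05, site loss
0.05, trans domain change 0.05, conserving coevolution 0.03, diverging
coevolution 0.03 (at most one event per lineage per step; probabilities
must sum to ≤ 1). These rates make single-mechanism divergence common at
short times while coevolution accumulates over tens of steps, so all five
categories occur at moderate frequencies.

Events: *site gain* adds a site matching a uniformly chosen existing
factor; *site loss* removes a uniform site (a no-op on an empty element,
logged as such); *trans domain change* resamples one factor's domain set
(guaranteed different from the current set); *conserving coevolution*
jointly relabels one matched factor and all its sites to a fresh,
lineage-private label, provably leaving the output unchanged (factor labels
are always distinct, so no other factor is affected); *diverging
coevolution* additionally resamples the factor's domains, changing the
output and making the cis element depend on a private label. Fresh labels
are drawn from a lineage-tagged namespace outside the ancestral alphabet,
which is what guarantees that a swap separates coevolved partners.

A swap experiment clones the ancestor into donor and host lineages, evolves
each independently for `divergence_time` steps, and reads the donor cis
element in the host trans background. The true mode is derived from the
event log: any coevolution event ⇒ coevolution (conserved vs divergent by
whether the endogenous patterns still match); otherwise independent cis and
trans events jointly ⇒ divergent coevolution; otherwise cis-only /
trans-only / none. Reproducibility: one seed spawns an independent
substream per experiment (numpy `SeedSequence`), consumed by the two
lineages in fixed order.

Detection noise models missed subtle differences: with probability ε each
truly-different relation is recorded as alike. Independent flips can
produce a triple the rubric rejects; such triples are repaired to all-alike
on the reasoning that an observer who missed one difference would miss the
entailed one. This preserves the two properties that matter: at ε = 1
everything is recorded as conservation, and the recorded diverged fraction
is non-increasing in ε.

### What the simulator does and does not emulate

It emulates the *logical* structure of swap experiments — which mechanisms
produce which relation triples, and how coevolution accumulates relative to
single-step changes. It does not emulate sequence-level evolution, motif
turnover, selection, unequal lineage rates, or the literature's ascertainment
biases. Identifiability results on simulated cohorts therefore validate the
rubric's internal logic, not the field's curation of real patterns.

### Study problem sizes and a known limitation

The identifiability study uses 1000 replicates per single-mechanism regime
at divergence time 10 with ε = 0; the tempo study uses 5000 replicates per
point on the doubling time grid (1, 2, 4, 8, 16). The grid deliberately
spans the pre-saturation regime: because patterns live in a finite
10-domain space, deep divergence (beyond roughly 20 steps at default rates)
saturates it, and accidental pattern coincidences — e.g. donor and host
both losing all expression — register as apparent trans-type divergence,
so the misregulation share plateaus and can jitter slightly downward. This
is a property of any finite-pattern model, consistent across seeds, and
documented here rather than hidden; within the default grid the share of
misregulation among diverged outcomes rises monotonically, the mechanistic
counterpart of misregulation increasing with phylogenetic distance.

## Numerical and degenerate-input conventions

- Percentages are computed at full precision and rounded only for display
  (half-up, one decimal in `proportion_summary`).
- An empty experiment set yields (0, 0, percent = not applicable), never a
  division error.
- Empty 2×2 tables are rejected; degenerate margins are flagged, p = 1.
- The constraint solver minimizes total table size when the total is
  unconstrained, making small examples reproducible.
- All randomness flows through explicit seeds; no global RNG state is used.

## Known limitations

- The reconstruction is one member of the feasible set; statistics that the
  constraints do not pin down (e.g. the insect C2/C3 split beyond the
  *yellow* counts) are arbitrary within feasibility and must not be
  interpreted.
- The simulator's event rates are not fitted to data; only qualitative,
  rate-robust properties (identifiability, monotone tempo trend before
  saturation) are asserted.
- Vertebrate swaps, hybrid expression studies, and sequence-level analyses
  are out of scope.
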