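# Methods

This note documents the models behind `famseg`, the choices made where the
design was genuinely open, and what the synthetic-data experiments do and
do not establish.

## Pedigree model and meioses counting

A pedigree is a validated directed acyclic graph of individuals with
parent→child edges.  Parentage is all-or-nothing (a half-specified parent
pair is rejected), founders are the members with no parents, and unknown
sex is permitted for founders only — deep genealogies often lack sex for
apical ancestors, but parent roles lower down are always resolvable.

The *connecting subgraph* of a carrier set is the ancestral subgraph of
minimum total meioses linking all carriers, found by exhaustive search
over candidate apex ancestors with exact enumeration over path
combinations (affordable because carrier sets in this design are small,
≤ ~10).  One meiosis is one parent→child transmission event, and a mated
couple acts as a single transmitting node: parent–child = 1, full siblings
= 2, first cousins = 4.  The subgraph's node set additionally lists the
marry-in co-parent at each transmission, but the meioses count is the
number of transmission events, not a naive edge count over nodes — with a
couple at the apex the two conventions differ, and only the transmission
count matches genealogical usage.  Tie-breaking is deterministic: a
couple-forming apex is preferred, then the lexicographically smallest
apex id; all tied apexes are reported in the result.

An apex couple counts as **one** introduction point (either spouse may
carry the allele); every other pedigree founder inside the subgraph is a
marry-in spouse, an independent potential source of the allele from the
population.  When the apex is itself a carrier it introduces alone — the
allele is known to be in that individual, not merely somewhere in the
couple.  A carrier set consisting of both spouses of a couple plus their
descent line places both spouses at the apex jointly; two spouses alone,
with no carrier descendant, are reported as disconnected (they share no
transmission path).

Kinship coefficients use the classical recursion (φ(a,a) = (1+F_a)/2,
recursing through the parents of the individual that cannot be the
other's ancestor).  On loop-free pedigrees kinship and meioses satisfy
φ = n_apex · (1/2)^(M+1), which the tests assert on generator output.

## High-risk family screen

Expected affected counts sum per-member risks under stratified population
rates; members of unknown affection status are excluded from both the
observed and the expected count, so unobservables cannot bias the SIR.
Two rate modes exist: cumulative lifetime risk per person (default; no
person-years needed) and rate per person-year (used when years-at-risk
are available).  The test linking O and E is the exact one-sided Poisson
upper tail P(X ≥ O | mean = E) — per-family expecteds are ≪ 1, where
normal approximations to the SIR fail, and the exact tail is conservative
under discreteness (the realized null flag rate sits below the nominal
α; the calibration experiments confirm this at α = 0.01).  The screen
applies no multiple-testing correction — ascertainment uses a fixed
nominal threshold — but Bonferroni-adjusted flags are emitted as
supplementary output.

## Segregation probabilities

Null model: founder genotypes i.i.d. Hardy–Weinberg(q), fair Mendelian
transmission, one biallelic locus, no mutation, no linkage.  Carriers are
coded dominantly (≥ 1 copy); the motivating data contain only
heterozygous carriers, so homozygote refinement is not modelled.  The
allele frequency input is the *control-population* frequency — the null
hypothesis is population transmission, not case enrichment.

Three routes, kept deliberately independent:

* **Closed form on the connecting subgraph** — a structured sum over the
  apex genotypes (one or two Hardy–Weinberg draws) and the marry-in
  co-parent at each transmission, propagated down the descent tree.  It is
  exact whenever the subgraph is loop-free and every co-parent is a
  pedigree founder, the situation the extended-family model targets; a
  co-parent with in-pedigree ancestry is approximated as a population
  draw.  It also returns an exact per-configuration term table: the
  probability that exactly a given set of founders (apex and/or specific
  marry-ins) carries the allele and all carriers received it; the table
  sums to the total sharing probability.
* **Exact peeling** — generic sum-product variable elimination over
  genotype variables on the pedigree pruned to the ancestral closure of
  the carriers, eliminating deepest individuals first.  It handles
  inbreeding loops exactly and is the reference implementation, bounded
  at 25 pruned individuals (beyond that the elimination width can grow;
  the error message points to the Monte Carlo route).
* **Gene dropping** — vectorized Monte Carlo with per-(family, variant)
  keyed substreams (order-independent cohort runs, bit-exact under a
  fixed seed) and Wilson 95% intervals (well-behaved at the near-zero
  probabilities of rare variants, unlike Wald).

Reported quantities, and why there are several:

* `p_single_introduction = [1 − (1−q)^(2c)] · (1/2)^M` — the headline
  decomposition "introduction at the apex, then one fair coin per
  meiosis".  It halves exactly per additional meiosis, which makes it the
  right quantity for comparing relationship depths; it is the small-q
  leading order of the exact single-origin probability.
* `p_single_introduction_exact` — the joint probability that the apex
  carries, no marry-in does, and every carrier received a copy (equals
  the apex-only mass of the term table).
* `p_any_sharing` — the unconditional probability that all carriers
  carry, all introduction routes included.
* Two conditionals, because both conventions exist: `p_conditional`
  conditions on *at least one* carrier carrying, while
  `p_conditional_index` conditions on a *designated index* carrier
  (any non-inbred member is marginally Hardy–Weinberg, so it equals
  `p_any_sharing / (1 − (1−q)²)`).  They answer different questions and
  have different rare-allele limits for a sibling pair: 1/3 and 1/2
  respectively — the familiar "a rare allele in one sib is in the other
  half the time" is the index-conditioned statement.

One counterintuitive exact result, asserted in the tests: a sibling pair
shares slightly *more* often than a parent–child pair
(q + 2q² vs. q + q² − q³ to leading orders), because either parent can be
the single origin for siblings.  Strict per-meiosis monotonicity holds
for the single-introduction term, not for the exact total.

### Numerical policy

All probability algebra runs in linear-space double precision.  The
products involved contain at most a few dozen factors bounded below by
q², so for q ≥ 1e-8 (the enforced domain) intermediate values stay many
orders of magnitude above the ~1e-308 underflow threshold, and the
1e-9 / 1e-12 agreement tolerances used in the tests are met without
log-space transforms.  Degenerate inputs (q outside the domain, empty
carrier sets, carriers with no common ancestor, oversized pruned
pedigrees) raise typed errors rather than returning approximations.

## Variant filters

Both prioritization stages are conjunctions of explicit predicates; the
surviving set is therefore order-independent, while elimination counts
attribute each record to the *first* failing rule in a fixed, documented
order (family stage: sharing → impact → control frequency; cohort stage:
consequence → annotations → carriers → case frequency → control
frequency), so the per-rule tallies always sum to the eliminated count.
"Medium" impact maps to the MODERATE tier of standard consequence
vocabularies and both spellings are accepted.  PolyPhen "possibly
damaging" passes alongside "probably damaging".  The carrier-count rule
counts carriers, not alleles (a homozygote counts once), and is enforced
independently of the case-frequency rule — the two coincide at the
motivating cohort size but need not in general.  Multiple control panels
are conjunctive: a variant must be rare in *all* of them.  Frequencies
are compared at full precision; 4-decimal rounding is display only.
The case-control comparison is a two-sided Fisher exact test on the 2×2
allele-count table with Haldane–Anscombe odds ratios when a cell is zero.

## Synthetic data: what it emulates and what it does not

`generate_pedigree` grows a family as a branching process: one founder
couple, Poisson(mean 2.5) offspring per mating by default, and every
reproducing member mated to a brand-new marry-in founder.  Defaults are
the study conditions: 7 generations, sex-stratified lifetime risks of
0.025 (male) / 0.007 (female) — the order of lifetime suicide mortality
in high-burden US state populations — risk multiplier 1 (null family),
allele frequency 0.001.  Affection is independent Bernoulli at
rate × multiplier given lineage membership; there is no liability
threshold, no assortative mating, no consanguinity (so generator output
is loop-free by construction, which also keeps exact peeling tractable),
no genotyping error, and no realistic demography.  Stochastic extinction
of a particular draw is allowed (the family simply ends early);
configurations that can *never* produce grandchildren are rejected.

Consequently, passing tests establish the internal correctness and
calibration of the statistics under their stated assumptions — not
robustness to the violations real genealogies exhibit (inbreeding loops
are exercised only through hand-built fixtures via the peeling route,
missing parentage and misattributed paternity not at all).

Every experiment's ground truth (lineage membership, introducer, forced
transmission path) is recorded in a JSON sidecar at generation time;
recovery tests score against the sidecar rather than re-deriving truth.

## Problem sizes

The shipped experiments use sizes chosen to make the statistical
assertions sharp at interactive runtimes: gene-drop oracle comparisons at
10^6 replicates per fixture (3-SE bands a factor ~40 below the exact
values at q = 1e-3), null calibration on 10,000 four-generation families,
planted-signal recovery on 400 five-generation families with a 10×
multiplier in 5% of them, and rare-allele limits evaluated at q = 1e-6
where the O(q) correction (~1e-6) sits three orders below the 1e-4
assertion tolerance.

## Known limitations

* The closed-form route requires a loop-free connecting subgraph; with
  consanguinity it defers to peeling, and beyond 25 pruned individuals
  to Monte Carlo.
* The single-introduction label is degenerate when both apex spouses are
  carriers (two copies must then be present at the apex); the exact
  quantities remain correct.
* Person-year standardization is implemented but the shipped generator
  produces lifetime-risk strata only.
* The VCF adapter targets the minimal GT-only VCFs this package writes;
  production VCFs with rich CSQ annotation should be flattened to the
  TSV interface upstream.
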