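# Methods

`lakelock` implements the population-genomic half of a landlocking study
of an amphidromous fish: given biallelic SNP genotypes for five groups —
a mainland coastal population (MC), an island coastal population (CIC)
and three landlocked lake clusters (CILL1, CILL2, CILL3) — it quantifies
diversity and differentiation, and infers how many times (and roughly
when) landlocking occurred, by approximate Bayesian computation with
random forests (ABC-RF) over a space of 18 divergence scenarios.

## Genotype model and filters

Genotypes are unphased alternate-allele dosages (0/1/2) with missing
cells; phase separators are ignored and half-calls are treated as
missing. Three locus filters mirror a typical GBS protocol, with
boundary semantics applied literally:

- **call rate**: keep loci genotyped in at least 80% of samples
  (inclusive);
- **heterozygosity**: remove loci whose heterozygote fraction *among
  called genotypes* exceeds 65% (strict; candidate merged paralogs).
  Restricting to called genotypes keeps missingness from diluting the
  paralog signal;
- **MAF**: before ABC, remove loci with pooled minor allele frequency
  below 0.05 (inclusive retention at exactly 0.05); minor-allele counts
  are compared as integers so the boundary is exact.

The ABC stage also removes loci with zero called genotypes. A locus
failing several criteria is counted once, under the first filter in the
chain — so chained report counts depend on filter order only for
multi-failure loci.

## Diversity statistics

Per-locus Nei & Chesser (1983) bias-corrected components, with s
population units, per-unit allele frequency p, called diploid counts n
(harmonic mean ñ) and observed heterozygote fraction:

    HO = mean(het);  HS = ñ/(ñ−1)·(1 − mean(p²+q²) − HO/2ñ)
    HT = 1 − (p̄²+q̄²) + HS/(ñs) − HO/(2ñs);  DST = HT − HS
    DEST = s/(s−1)·(HT−HS)/(1−HS)

Genome-wide values average per-locus components first and form ratios
from the averages (ratio-of-averages): FST = mean(DST)/mean(HT), FIS =
1 − mean(HO)/mean(HS). Averaging per-locus ratios instead would be a
noisier estimator at low-diversity loci; ratio-of-averages is the
convention here and is what the oracle tests pin down. Loci with an uncalled unit, or with harmonic-mean called size
ñ ≤ 1 (where the ñ/(ñ−1) correction is undefined), are dropped. With a
single unit the convention is DST = FST = 0, HT = HS, and DEST is
undefined — the natural convention for table rows that contain a
single sampling site. Negative estimates are reported, never clamped.

Pairwise FST is Weir & Cockerham's (1984) θ as a ratio of averages
across loci. A seeded bootstrap resamples loci with replacement (default
100 replicates, one shared resampling plan for all pairs) for 95%
percentile intervals; a pair is "significant" iff its interval excludes
zero (bootstrap-interval significance is this package's documented
choice; no single convention dominates the field's tables). PCA standardizes each locus by
2p̂ and √(2p̂(1−p̂)) and imputes missing cells to the locus mean, the
common GBS practice.

## Scenario space

Each scenario is a rooted divergence tree over the five sampled groups
plus ancestral nodes, with one constant diploid Ne per branch and split
times in generations; the MC–CIC split is the root everywhere (the
island was colonised by a diadromous ancestor). The 18 scenarios fall in
three blocks of six:

- **1–6, three landlocking events**: each cluster diverges directly from
  CIC; the six orderings of the three divergence times. Scenario 1 has
  CILL3 (Lake Huro) first, then CILL2, then CILL1.
- **7–12, two events**: a ghost landlocked ancestor (own Ne) founded
  from CIC later splits into a pair of clusters; the third cluster
  diverges from CIC separately. Three pairings × two time-orders of the
  two landlocking events.
- **13–18, one event**: a single landlocked ancestor splits twice. The
  ancestor branch is modelled as continuous with the last-remaining
  cluster's lineage (that cluster's Ne applies along it); three choices
  of first-diverging cluster × two choices of second-diverger. A
  symmetric ghost representation would collapse these six into three
  distinguishable histories, so the continuation form is used. The
  identities of scenarios 2–18 (which ordering or pairing carries which
  id) are conventions of this package; only the 6/6/6 block structure
  and scenario 1's ordering are fixed by the study design. The whole
  space can be swapped via the plain-text scenario file format
  (`lakelock scenarios --export`).

Priors are independent uniforms on 10¹–10⁶ for every time and size
parameter, with each scenario's time-ordering constraints enforced by
rejection sampling (acceptance 1/k! for a k-time total order).

## Coalescent simulator

Per locus, an exact continuous-time structured coalescent: within a
population of diploid size N, k lineages coalesce at rate k(k−1)/2 ÷ 2N;
at each divergence event (backward in time) the derived population's
lineages join the ancestral population; the process runs past the root
to a single lineage. One mutation is then placed on a branch drawn with
probability proportional to branch length — every locus carries exactly
one SNP, the convention of SNP-mode ABC simulators, which avoids a
mutation-rate parameter for unlinked GBS markers. Loci failing the
pooled-sample MAF threshold are redrawn (new genealogy and mutation, cap
10,000 per locus so degenerate parameters fail loudly). Haploid lineages
are paired consecutively within populations into diploids (random
mating, no inbreeding parameter).

The kernel is numba-compiled with an inline xorshift64* generator
(splitmix64-seeded), making byte-identical runs a function of the seed
alone (~12 µs per 338-lineage genealogy). Validation: E[TMRCA] and
E[total length] match closed forms; two-population TMRCA matches
msprime on the same model; pure-drift FST matches 1−exp(−t/2N); and the
site-frequency spectrum, *weighted by total tree length*, matches the
neutral (1/i)/H law. The weighting matters: conditioning each locus on
exactly one SNP samples frequency classes with probability E[L_i/L_tot],
not E[L_i]/E[L_tot], giving a slight singleton excess exactly as in
`ms -s 1`; length-weighting provably recovers the classical form, and
that is what the test asserts.

## ABC summary statistics

A fixed-order 60-statistic vector: per-group expected heterozygosity
(2p(1−p)·2n/(2n−1), 5), per-group monomorphic-locus proportion (5),
pairwise WC FST (10), pairwise Nei (1972) standard distance (10), and
f3(T; A, B) for every target and donor pair (30). Nei's D and f3 are
used without finite-sample correction — simulated and observed vectors
are computed identically, so the O(1/2n) offsets cancel in the ABC
comparison (the test suite accounts for the offset where it checks null
values). The set reconstructs typical SNP-mode ABC defaults; it is
versioned in code and swappable.

**Noise matching.** Because summary-vector comparison is only valid when
both sides carry the same sampling noise, the observed vector is always
computed on a seeded locus subsample equal to the reference table's
per-simulation locus count (datasets at or below that count are used in
full).

## Random-forest ABC

*Scenario choice*: a 500-tree classification forest on the summary
statistics augmented with linear-discriminant axes (toggleable). Votes
are the fraction of trees choosing each scenario at the observed point;
ties break to the lowest scenario id. The winner's posterior probability
is 1 minus the prediction of a regression forest trained on the
out-of-bag misclassification indicators; the global (prior) error is the
out-of-bag misclassification rate; the local (posterior) error
re-weights out-of-bag errors over pseudo-observed draws taken from the
winning scenario's rows with leaf-co-occurrence weights around the
observed point. The per-parameter error report is out-of-bag mean
absolute error normalized by the parameter's range — one reasonable
convention among several; it is a diagnostic, not a calibrated
probability.

*Parameter estimation*: one quantile regression forest per parameter
(500 trees, leaf size 5, mtry = p/3 — the regression-forest convention;
the classifier uses √p). The point estimate is the leaf-weighted mean
and the 95% interval the 2.5%/97.5% weighted quantiles of the training
responses, so the interval brackets the point estimate by construction.
Times are reported in generations and in years at one generation per
year (an identity conversion for this annual species).

## Synthetic study data

`generate_study_dataset` emulates the study's post-genotyping product:
169 diploids (MC = 18; island group sizes 40/30/50/31 are placeholders —
the real per-cluster counts are not public), scenario 1 with the
divergence-time estimates reported for this system as truth
(t_CILL3 = 179,163, t_CILL2
= 169,467, t_CILL1 = 156,273, root = 340,000 generations) and
order-of-magnitude placeholder sizes (coastal 10⁵, landlocked 10⁴,
giving the observed lower landlocked diversity), 21,135 loci at full
scale (2,000 by default at desk scale), and independent per-genotype
missingness (default 10%, applied after simulation so it is independent
of genotype value; a locus-level beta-distributed option is deliberately
out of scope here — uniform missingness is what the tests rely on). The
truth record regenerates the dataset byte for byte. What this generator
does *not* emulate: real site-frequency spectra, linked loci, genotyping
error, or locus/sample missingness structure — so green tests certify
the pipeline's statistical machinery, not its behaviour on any real
dataset.

## Problem sizes and runtime

Desk-scale defaults, chosen once as this package's working sizes:
training simulations use 300 loci per dataset for scenario choice and
500 for parameter estimation; observed datasets 2,000 loci; reference
tables 1,000 rows/scenario (choice) and 5,000 rows (single-scenario
estimation) in the recovery experiments, with the original analysis's
20,000 and 1,000,000 reachable through configuration. All randomness
flows from explicit integer seeds (per-stage offsets in the pipeline;
`SeedSequence`-spawned per-simulation seeds in table building).

## Identifiability: what the recovery experiments can and cannot show

With one polymorphic SNP per locus and no mutation rate, the simulated
data distribution is *exactly invariant* to rescaling all times and
sizes by a common factor — only ratios t/N (and size ratios) are
identifiable. The data constrain a one-dimensional family of parameter
vectors, and the posterior along that family is set by the uniform prior
box, whose volume grows like c^(k−1) in the rescaling c for k
parameters: absolute-time estimates are therefore pulled toward the
largest rescaling the 10⁶ bound permits. With the synthetic truth above,
drift on every branch is saturated (t/2N ≈ 2–18; e.g. simulated
FST(MC, CIC) ≈ 0.74), which (a) pushes the scale even less constrained
upward — the recovered absolute times land well above the truth — and
(b) makes the three near-simultaneous landlocking divergences
(156k–179k generations) hard to tell apart from a two-event history
with a pair split and a singleton split at similar times, which needs
only two of the prior's ordered-uniform times to coincide rather than
three. Under these conditions scenario-class recovery sits near the
decision boundary (the three-event class wins by a modest vote margin,
and under some random seeds a two-event scenario takes the plurality)
and the absolute divergence-time estimates land well above the truth;
the end-to-end tests record these outcomes honestly rather than
asserting a recovery the model cannot deliver. Real datasets in the moderate-drift regime, where ratio
constraints cap the feasible rescaling well below the prior bound, are
where absolute-time estimation with this machinery is informative.

## Known limitations

- No migration, admixture edges, bottlenecks or size changes in the
  scenario space; no recombination, linkage or sequencing error in the
  simulator.
- Scenario identities 2–18 are a reconstruction (see above).
- Nei D is +∞ for fully fixed differences (J_AB = 0); it propagates
  as `inf` rather than being clamped.
- The multi-scenario reference table stores the union of parameter
  columns with NaN where a scenario lacks a parameter; statistic columns
  are always complete.
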