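# Methods

## Problem setting

`cervidyn` analyses longitudinal 16S-profiled vaginal microbiota from a
three-visit cohort design (baseline, month 3, month 6) in which each
participant belongs to a PrEP or non-PrEP arm and carries per-visit
clinical covariates (Nugent score, STI status, antibiotic treatment,
vaginal pH). The pipeline asks two questions: (i) how do rule-defined
community classes ("cervicotypes") move between visits, stratified by
study arm and antibiotic exposure; and (ii) does the study arm leave any
signature in community composition (beta-diversity) at any visit.

## Cervicotype model

Each sample's relative-abundance vector is mapped to one of four classes:

| CT | rule |
|----|------|
| CT1 | summed non-*iners* *Lactobacillus* fraction >= 0.5 |
| CT2 | otherwise, *L. iners* is the plurality (argmax) taxon |
| CT3 | otherwise, *G. vaginalis* is the plurality taxon |
| CT4 | otherwise (mixed, anaerobe-rich, BV-associated) |

Choices made where the rules are underdetermined:

- the CT1 threshold is inclusive (>= 0.5);
- CT1 sums over **all** non-*iners* *Lactobacillus* taxa, including
  genus-level reads without a species call (conservative reading of a rule
  stated for the species group, not a single species);
- exact ties at the maximum resolve by fixed precedence CT2 > CT3 > CT4.
  Ties have measure zero in real data; the precedence only pins down
  behaviour on degenerate synthetic inputs.

Assignment is scale-invariant (counts are normalized internally), total and
exclusive; zero-depth samples are flagged invalid and excluded, never
zero-filled.

## Transition estimation

For every subject and every pair of *consecutive* visits with both
endpoints observed, one transition is tallied into the 4x4 count matrix of
that interval's stratum; probabilities are raw row proportions (no
pseudocounts, no shrinkage). Conventions:

- the antibiotic stratum of an interval is the flag at the interval's
  **starting** visit: treatment dispensed at a visit acts during the
  following interval;
- gaps are never bridged (a baseline -> month-6 pair with month 3 missing
  contributes nothing);
- the two intervals are pooled by default, with `interval` available as an
  explicit stratifier;
- a row with zero observations carries NaN probabilities and an explicit
  undefined marker;
- a missing antibiotic flag becomes its own `"NA"` stratum level, so
  pooled counts always equal the sum over any full stratification.

## Diversity and ordination

Alpha diversity: bias-corrected Chao1, `S_obs + F1(F1-1)/(2(F2+1))`
(defined when doubletons are absent); Simpson's evenness as inverse-Simpson
over observed richness, `E = (1/sum p_i^2)/S_obs` (the most common reading
of "Simpson's E"; a convention choice, flagged here); Faith's PD as the
branch-length sum of the minimal rooted spanning subtree, path to the root
included (the dominant implementation convention). Chao1 is computed on raw
counts without rarefaction. Beta diversity is Bray-Curtis on relative
abundances (a count-based variant is provided). These metrics are computed
through scikit-bio; the test suite verifies each against independent
straight-line formula or brute-force subtree oracles.

NMDS is implemented directly: Kruskal stress-1 minimized by alternating
isotonic regression (pool-adjacent-violators via
`scipy.optimize.isotonic_regression`) of configuration distances on
dissimilarity ranks with Guttman-transform updates; a step-halving line
search keeps the stress trace monotone non-increasing; defaults are k = 2,
20 random restarts plus one classical-scaling start, tolerance 1e-6, 500
iterations.

PERMANOVA is the one-factor distance-based pseudo-F

    SS_total = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = (SS_between/(a-1)) / (SS_within/(N-a)),  R^2 = SS_between/SS_total

with whole-label permutations (default 9999) and the (+1)/(+1) p-value
convention, so p >= 1/(permutations+1). An exhaustive mode enumerates all
distinct labellings for small designs. With semi-metric dissimilarities
(Bray-Curtis) SS_between can be marginally negative; R^2 is reported as
computed. The analysis design is cross-sectional per timepoint with no
multiplicity correction, matching the workflow the pipeline mirrors.
Fisher's exact test is two-sided by point-probability summation (with a
1 + 1e-7 relative slack against float ties), the chi-square has no
continuity correction, and the Mann-Whitney U uses midranks with exact
enumeration for m + n <= 12 without ties, otherwise a tie- and
continuity-corrected normal approximation.

## Synthetic cohort generator

The generator is the package's test bed and replaces the study's raw reads.
Structure per subject: arm ~ Bernoulli(0.64 PrEP); baseline cervicotype ~
(0.11, 0.47, 0.26, 0.16); antibiotic use per visit ~ Bernoulli conditional
on the current cervicotype (0.18/0.36/0.73/0.88 — the per-class
Nugent >= 4 rates, since high-Nugent visits trigger metronidazole);
subsequent states follow the (arm, antibiotic) stratum chain. Default
stratum matrices pin the reported diagram entries (PrEP CT1 self 0.5; CT2
self 0.62 in both arms; PrEP/no-antibiotic CT3 self 0.47, CT4 self 1.00;
PrEP/antibiotic CT3 -> CT2 0.55, CT4 self 0.56; non-PrEP CT1 -> CT2 0.6,
CT4 -> CT2 0.38) and spread the unreported remainder uniformly; the
"0.47" entry is read as the CT3 self-loop. Clinical labels: Nugent
category per class (with the >= 4 mass split 60/40 between intermediate
and high, matching the baseline cohort-wide split), a uniform integer
within the category; STI ~ (0.10, 0.13, 0.23, 0.25); pH is a noisy
increasing function of the Nugent score (plausibility only — no published
calibration).

Compositions are drawn from per-class Dirichlet distributions over a fixed
20-taxon panel and rejection-sampled (cap 1000) until the rule-based
classifier returns the intended class, making the simulator's ground truth
exact by construction rather than relying on concentration tuning. The
concentrations themselves are free parameters chosen to give realistic
dominance patterns (dominant-taxon concentration ~22-25 against a 0.15
background); no public per-class dispersion estimates exist to calibrate
them. Read depth is negative-binomial (mean 10,000, dispersion 10; a
`None` dispersion makes depth deterministic) with multinomial counts.
Reproducibility: one master seed, with independent child streams per
component spawned via `numpy.random.SeedSequence`.

What the generator does **not** emulate: compositional autocorrelation
beyond the Markov class structure, strain-level dynamics, contamination or
batch effects, depth-composition coupling, and covariate-driven
composition shifts within a class. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
properties of any real cohort.

## Validation experiments

- **Worked examples.** The packaged per-stratum transition counts and
  baseline cross-tabulations are row-normalized through the estimator and
  must reproduce every printed percentage at its printed precision.
- **Parameter recovery.** 2000 subjects, 3 visits, two balanced strata
  with known sticky chains (entries {0.9, 0.1}, doubly stochastic so state
  occupancy stays uniform and every row expects ~500 transitions); the
  estimated probabilities must land within sup-norm 0.05 of truth for all
  rows with expected count >= 50. The matrices were designed for
  identifiability: with ~500-observation rows, 0.9/0.1 entries give a
  sup-norm failure probability well under 1%, whereas rows containing
  0.5-entries at counts near 50 would make the same bound a coin flip.
- **PERMANOVA calibration.** Exact agreement with an exhaustive-enumeration
  oracle on n <= 8 designs, and a type-I error rate within [0.03, 0.07] at
  alpha = 0.05 over 1000 null simulations (n = 20, 999 permutations).
- **Null pipeline.** 200 scaled-down cohorts (30 subjects, depth 2000,
  199 permutations) simulated with arm-independent dynamics; per-timepoint
  PrEP vs non-PrEP PERMANOVA p-values must be uniform (KS p > 0.01),
  the desk-scale analogue of a no-arm-effect finding. Problem sizes for
  all experiments were chosen to keep each run in seconds-to-minutes on a
  single core while preserving the statistical power the checks need.

## Known limitations

- The four-class rules are operational definitions, not a model-based
  clustering; communities near rule boundaries are assigned hard labels.
- Empirical transition probabilities are undefined for unobserved source
  states and noisy for rare ones; no smoothing is applied by design.
- The per-timepoint PERMANOVA ignores repeated measures on the same
  subject across visits (as does the workflow it mirrors).
- Simpson's-evenness and Faith's-PD root-path conventions are fixed
  choices, documented above; users needing a different convention should
  compute the metric directly from the exported tables and tree.
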