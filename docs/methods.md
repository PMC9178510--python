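# Methods

## Screen model

A screen is a set of independent pedigrees. Each pedigree descends from one
mutagenized G0 male through a G1 founder son who is heterozygous for the
pedigree's full mutation set (the set identified by exome sequencing of G1).
G2 females (G1 × wild type) receive each mutation with probability ½ and are
therefore HET or REF only; G3 females (G2 backcrossed to the G1 sire) can be
homozygous mutant only where the dam is HET. Enumerating the cross gives the
G3 class probabilities REF:HET:VAR = 3/8 : 1/2 : 1/8 marginally — but
per-locus counts are overdispersed relative to a binomial because sibling
G3s share the realized dam genotype; the test suite checks frequencies
against the enumeration-derived mean and variance, not a naive binomial.
Because screened cohorts mix G2 and G3 females, genotype counts are not
expected to follow Mendelian ratios; the simulator reproduces this mixture
by construction.

Only G2/G3 females are phenotyped (the screen design restricts phenotyping
to females, the sex with the higher baseline incidence).

## Onset law

Latent onset ages are Weibull with proportional hazards. The baseline is
parameterized by two observable quantities rather than shape/scale:

* cumulative incidence by the 40-week horizon (default **0.80**, the
  reported female incidence of the high-incidence NOD subline), and
* median onset age among affected females (default **22 weeks**; not
  reported for the unmutagenized colony, so this is a free parameter chosen
  as a plausible mid-screen onset — it shifts event times but none of the
  tested contrasts).

Solving S(40) = 0.20 and F(22) = 0.40 gives shape ≈ 1.92, scale ≈ 31.2
weeks. A planted effect multiplies the hazard by `hazard_multiplier^dose`
with dose from its inheritance model (recessive 0/0/1, additive 0/½/1,
dominant 0/1/1 for REF/HET/VAR); multiplier 0 makes fully expressing mice
immune. An optional log-normal dam-level frailty (default sd 0) induces
litter clustering for exercising the mixed-model variant.

Weekly monitoring is modeled by ceiling the latent time to the next whole
week; ties are therefore heavy and every statistic must tolerate them. A
mouse whose latent onset exceeds 40 weeks is censored at 40.0 with
`event=False`; an onset observed at the week-40 check is an event at 40.0.
Consequently `event=False` implies week 40, and any week < 40 implies an
event, but a week-40 record can be either.

## The linkage test

The association statistic is a likelihood-ratio test from a Weibull
proportional-hazards regression of onset age on the encoded dose,
right-censored at 40 weeks — a log-linear model of the hazard that handles
censoring honestly and nests cleanly for LRTs. The likelihood is maximized
over (log shape, β) after profiling out the rate analytically (its optimum
given the other parameters is closed-form), using damped Newton ascent with
analytic gradient and Hessian and an L-BFGS-B fallback; β is bounded at ±30,
which is where separation (an immune genotype class) drives it. Onsets are
treated as exact at their recorded week by default; an interval-censored
mode (week w as (w−1, w]) is available. The default likelihood is the
fixed-effect one; `cluster=` adds a shared normal random intercept on the
log hazard per dam, integrated by 15-node Gauss–Hermite quadrature, to both
null and alternative fits.

### Small-sample calibration

At screen-sized pedigrees (~100 females, recessive VAR classes of ~10–20
mice, heavy weekly ties) the χ²₁ reference for the LRT is accurate in the
bulk but runs ~1.2–2× hot in the far tail — exactly where a
Bonferroni-corrected screen decision lives. The scan therefore calibrates
in two stages, both deterministic given `calibration_seed`:

1. **Bartlett rescaling.** For each inheritance model the mean LRT under
   dose permutation, pooled over the pedigree's loci (16 permutations per
   locus), estimates the null mean, which should be 1; statistics are
   divided by this factor. The mean needs far fewer resamples than any tail
   quantity, and permutation is the exact null for an independence test.
2. **Exact refinement.** Any test whose corrected Bonferroni p falls below
   0.25 is decided by an exact dose-permutation test of the model's *score*
   statistic. Evaluated at the null fit, the score for β is linear in the
   dose vector (U = Σ xᵢcᵢ, cᵢ = dᵢ − D·wᵢ/S), so a permutation replicate
   is one vector product: 4,000 shuffles, escalated to 200,000 when the
   estimate falls below 0.02. The reported p for these tests is the exact
   permutation p of this asymptotically equivalent statistic; the LRT value
   is still reported as the test statistic.

Simulation (1,500 null screens of 42 mutations × 3 models, 100-female
pedigrees) puts the family-wise error of the calibrated scan at ~4.3% after
Bonferroni, against ~5.5% for the raw χ² reference. `lrt_association`
itself returns the uncalibrated LRT and χ² p — oracle comparisons and any
single-locus use get the plain statistic; calibration is a property of the
scan. The mixed (frailty) scan skips calibration.

### Multiplicity, direction, flags

Bonferroni m = (mutations in the pedigree) × (number of models), applied
within each pedigree: each pedigree is an independent scan with its own
Manhattan plot, so the family is the pedigree's test set. Direction is the
sign of β̂ (positive log-hazard effect = accelerate); for results passing
Bonferroni 0.05 it is cross-checked against the Kaplan–Meier median order
of the affected class versus REF and flagged `direction_discordant` on
disagreement (the check is skipped for clearly null results, where KM
medians are noise). Untestable loci (constant dose after dropping MISSING,
or no events) carry `not_testable`/`no_events` flags and a NaN p;
non-converged fits are flagged and excluded from candidate calling.

## Kaplan–Meier and logrank

Curve estimation uses the product-limit estimator (via lifelines) over the
tied weekly grid; censored-at-40 mice contribute to risk sets only. The
two-group comparison is the Mantel–Cox logrank statistic in the standard
tied-data hypergeometric form, implemented vectorized so that a group-label
permutation p (default 10,000 shuffles) is available alongside the
asymptotic χ²₁ p. On toy cohorts of a dozen mice the permutation p is the
meaningful one — a 4-mouse permutation null is discrete with atoms of 1/6,
which no asymptotic reference can match.

## Candidate calling

A mutation is called when all four criteria pass: ≥ 20 G3 females in the
pedigree, ≥ 2 homozygous mutant and ≥ 2 homozygous reference mice among
*phenotyped* animals (the criterion concerns phenotypic evidence, so
genotyped-but-unphenotyped mice do not count), and best-model Bonferroni
p < α = 0.05. The best model is the minimum corrected p with the fixed
tie-break recessive > additive > dominant. If two models both pass α with
opposite directions the mutation is flagged and not called; sub-threshold
models' directions are noise and do not veto. Every call records a complete
four-entry criteria trace. Accelerating calls are reported as `accelerate`,
suppressing ones as `delay`.

## Saturation and footprint

"Damaging and/or null" is operationalized as predicted damage class in
{probably_damaging, probably_null} (an input annotation, never recomputed).
Genome saturation = (genes with such alleles phenotyped ≥ 2× homozygous) /
(annotated autosomal protein-coding genes, default 20,000 — configurable,
since the denominator is a catalog choice). Footprint = hits / saturation,
reported raw and rounded half-away to the nearest 100.

## Defaults of the built-in screen design

`DEFAULT_SCREEN_DESIGN` encodes 14 pedigrees carrying 594 mutations in
total (six pedigrees of 43 and eight of 42; mean 42.4) and 844 phenotyped
G2+G3 females, with ten pedigrees of ≤ 14 G3 females each — small enough
that candidate criterion 1 excludes them, as in the screen design this
emulates. Per-pedigree litter sizes are approximations chosen to reproduce
those aggregates; they are not a published table. Mutations are placed
uniformly over the 19 autosomes (1-based positions, built-in length table)
with damage-class frequencies 30/25/35/10% for probably_damaging /
possibly_damaging / benign / probably_null, a plausible split for induced
coding variation. Missing genotype calls are off by default and applied
per-cell at a configurable rate to the *observed* matrix only (phenotypes
always derive from the true transmission).

## What the simulator does not emulate

Mutation spectra (base changes are uniform, not transition-biased), linkage
between loci on the same chromosome (transmissions are independent across
loci, so co-segregation of nearby mutations is absent), sex-chromosome
loci, variable litter sizes, male phenotypes, and any non-proportional or
time-varying effect of a modifier. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to these real-data features.

### Power at small homozygote counts

Dam-clustered transmission makes the per-locus homozygous-mutant count
overdispersed (a 10-dam, 90-G3 pedigree draws its VAR count with sd ≈ 4.6
around a mean of ~11). When a replicate draws only a handful of homozygotes,
the exact conditional p has a hard combinatorial floor — the probability,
under exchangeability, of the observed arrangement's orbit (for a fully
suppressing allele, all n_VAR mice landing in the censored set:
C(n_censored, n_VAR) / C(n, n_VAR)) — and with ≤ 6 homozygotes this floor
can exceed the Bonferroni threshold, making the locus undetectable by *any*
validly calibrated test in that replicate. An uncalibrated χ² reference
reports smaller p's there, but that is precisely the anticonservatism the
calibration removes. Screen designs with more, smaller litters (more dams
per pedigree) tighten the homozygote-count distribution and avoid these
floors more often.

## Problem sizes used by the statistical test suite

Family-wise error: 500 simulated null screens of 42 mutations in a
100-female pedigree (10 G2 dams × 9 G3 daughters). Power: 200 replicates of
the same design with one fully penetrant recessive suppressor. Oracle
agreements use ≤ 12-mouse toys (grid-search likelihood, 20,000-shuffle
permutation logrank); transmission-frequency checks use a 600-G3 pedigree.
These sizes make the whole suite run in minutes while leaving the binomial
error of each check well inside its stated bound.
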